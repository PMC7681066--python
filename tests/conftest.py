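import numpy as np
import pandas as pd
import pytest

from longevipept.pipeline import demo_simulation_config
from longevipept.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def demo_study():
    """Small cohort with MNAR missingness shared across unit tests."""
    return simulate_study(demo_simulation_config(seed=1))


@pytest.fixture(scope="session")
def midsize_study():
    """A 600-participant cohort with clean structure for recovery checks."""
    config = SimulationConfig(
        n_participants=600,
        n_proteins=12,
        n_signal_proteins=3,
        signal_log10_effects=(-0.08, -0.06, -0.05),
        signal_peptide_counts=(10, 6, 4),
        signal_block_sizes=(2, 1),
        n_null_blocks=3,
        mean_null_peptides=6.0,
        n_qc_pools=25,
        seed=5,
    )
    return simulate_study(config)


def make_effects(protein_id, betas, ses, n_obs=500):
    """Peptide-effects frame for meta-analysis tests."""
    return pd.DataFrame(
        {
            "protein_id": protein_id,
            "peptide_id": [f"{protein_id}_p{i}" for i in range(len(betas))],
            "beta1": np.asarray(betas, dtype=float),
            "se": np.asarray(ses, dtype=float),
            "n_obs": n_obs,
            "converged": True,
        }
    )
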