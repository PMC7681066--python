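"""Generator contracts: determinism, planted truth, missingness mechanism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from longevipept.synthetic_data import (
    ConfigurationError,
    SimulationConfig,
    apply_missingness,
    read_study,
    simulate_cohort,
    simulate_peptides,
    simulate_study,
    write_study,
)


def small_config(**kw):
    base = dict(
        n_participants=300,
        n_proteins=8,
        n_signal_proteins=2,
        signal_log10_effects=(-0.08, -0.05),
        signal_peptide_counts=(6, 4),
        signal_block_sizes=(2,),
        n_null_blocks=2,
        mean_null_peptides=5.0,
        n_qc_pools=12,
        seed=0,
    )
    base.update(kw)
    return SimulationConfig(**base)


@pytest.mark.parametrize(
    "field,value",
    [
        ("n_participants", 0),
        ("age_range", (84.0, 73.0)),
        ("n_signal_proteins", 9),
        ("block_correlation", 1.5),
        ("technical_cv", -0.1),
        ("imputed_rate", 1.5),
    ],
)
def test_invalid_config_names_the_field(field, value):
    with pytest.raises(ConfigurationError):
        small_config(**{field: value})


def test_same_seed_is_byte_identical():
    a = simulate_study(small_config())
    b = simulate_study(small_config())
    pd.testing.assert_frame_equal(a.participants, b.participants)
    pd.testing.assert_frame_equal(a.peptides.abundance, b.peptides.abundance)
    pd.testing.assert_frame_equal(a.truth, b.truth)


def test_ages_stay_inside_the_configured_range():
    cohort = simulate_cohort(small_config(n_participants=2000))
    assert cohort["age"].min() >= 73.0
    assert cohort["age"].max() <= 84.0
    assert cohort["site"].nunique() == 6


def test_health_link_calibration_hits_the_spearman_target():
    # Monte Carlo across seeds: realized Spearman(latent, index) ~ target 0.15
    rs = []
    for seed in range(12):
        config = small_config(
            n_participants=2000, health_link={"frailty_index": 0.15}, seed=seed
        )
        cohort = simulate_cohort(config)
        r, _ = stats.spearmanr(cohort["latent"], cohort["frailty_index"])
        rs.append(r)
    assert abs(np.mean(rs) - 0.15) < 0.05


def test_zero_survival_link_decouples_death_from_latent():
    cohort = simulate_cohort(small_config(n_participants=4000, survival_link=0.0))
    r = np.corrcoef(cohort["latent"], cohort["died"])[0, 1]
    assert abs(r) < 0.05


def test_null_effects_give_zero_group_differences(midsize_study=None):
    config = small_config(signal_log10_effects=(0.0, 0.0), n_participants=800)
    study = simulate_peptides(simulate_cohort(config), config)
    lab = study.participants["alive90th"].astype(bool).to_numpy()
    prot = study.peptides.abundance.T.groupby(study.peptides.peptide_to_protein).mean().T
    diff = prot[lab].mean() - prot[~lab].mean()
    se = prot.std().to_numpy() * np.sqrt(1 / lab.sum() + 1 / (~lab).sum())
    assert (np.abs(diff.to_numpy()) < 3 * se).all()


def test_planted_fold_of_1_2_is_recovered_by_naive_means():
    # log10(1.2) = 0.0792; naive per-protein mean difference within +-0.01
    config = small_config(
        n_participants=1200,
        signal_log10_effects=(-0.0792, -0.05),
        signal_peptide_counts=(10, 4),
    )
    study = simulate_peptides(simulate_cohort(config), config)
    lab = study.participants["alive90th"].astype(bool).to_numpy()
    prot = study.peptides.abundance.T.groupby(study.peptides.peptide_to_protein).mean().T
    diff = prot[lab].mean()["P001"] - prot[~lab].mean()["P001"]
    assert abs(diff - (-0.0792)) < 0.01


def test_block_correlation_is_close_to_target():
    rs = []
    for seed in range(5):
        config = small_config(
            n_participants=1200,
            n_proteins=10,
            n_signal_proteins=5,
            signal_log10_effects=(0.0,) * 5,
            signal_peptide_counts=(2,) * 5,
            signal_block_sizes=(5,),
            block_correlation=0.6,
            factor_share=0.0,
            peptide_noise_sd=0.0,
            technical_cv=0.0,
            seed=seed,
        )
        study = simulate_peptides(simulate_cohort(config), config)
        prot = study.peptides.abundance.T.groupby(study.peptides.peptide_to_protein).mean().T
        corr = prot[[f"P00{i}" for i in range(1, 6)]].corr().to_numpy()
        rs.append(corr[np.triu_indices(5, 1)].mean())
    assert abs(np.mean(rs) - 0.6) < 0.1


def test_missingness_mechanism():
    config = small_config(n_participants=500)
    study = simulate_peptides(simulate_cohort(config), config)

    # a large, b = 0: nothing is missing
    none = apply_missingness(
        study,
        small_config(missingness_intercept=8.0, missingness_slope=0.0,
                     missingness_base_slope=0.0, missingness_quality_sd=0.0),
    )
    assert none.peptides.abundance.notna().all().all()

    # a = 0, b = 0: Phi(0) = 0.5 missing overall
    half = apply_missingness(
        study,
        small_config(missingness_intercept=0.0, missingness_slope=0.0,
                     missingness_base_slope=0.0, missingness_quality_sd=0.0),
    )
    frac = float(half.peptides.abundance.isna().mean().mean())
    assert abs(frac - 0.5) < 0.02

    # b > 0: missing fraction decreases across abundance deciles
    mnar = apply_missingness(
        study,
        small_config(missingness_intercept=0.5, missingness_slope=1.0,
                     missingness_base_slope=1.0, missingness_quality_sd=0.0),
    )
    complete = study.peptides.abundance.to_numpy().ravel()
    missing = mnar.peptides.abundance.isna().to_numpy().ravel()
    deciles = pd.qcut(complete, 10, labels=False)
    rates = pd.Series(missing).groupby(deciles).mean().to_numpy()
    assert (np.diff(rates) < 0).all()

    # QC pool is never masked
    assert mnar.peptides.qc_pool.notna().all().all()


def test_every_peptide_keeps_at_least_one_observation():
    config = small_config(missingness_intercept=-1.5, missingness_slope=0.3)
    study = simulate_study(config)
    assert (study.peptides.abundance.notna().sum(axis=0) >= 1).all()


def test_roundtrip_through_tsv(tmp_path):
    study = simulate_study(small_config())
    write_study(study, tmp_path)
    data, participants = read_study(tmp_path)
    assert data.abundance.shape == study.peptides.abundance.shape
    assert set(participants.columns) >= {"age", "alive90th", "followup_years"}
    orig = study.peptides.abundance.round(6)
    assert np.allclose(
        data.abundance.loc[orig.index, orig.columns].fillna(-999).to_numpy(),
        orig.fillna(-999).to_numpy(),
        atol=1e-5,
    )


def test_config_yaml_roundtrip(tmp_path):
    config = small_config(seed=42)
    path = tmp_path / "cfg.yaml"
    config.save(path)
    again = SimulationConfig.load(path)
    assert again == config
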