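"""Shared in-memory containers for the pipeline stages.

Conventions
-----------
* Peptide abundances live in a participants x peptides :class:`pandas.DataFrame`
  of log10 values; missing cells are ``NaN``.
* Every peptide maps to exactly one protein (``peptide_to_protein`` is total).
* The participant table is indexed by participant id and carries the
  covariates of the association model (age, birth-cohort cumulative hazard,
  clinical site), the longevity label ``alive90th``, the survival outcome
  (``followup_years``, ``died``) and four health indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HEALTH_INDICES = ["self_rated_health", "sf12_pcs", "healthy_aging_index", "frailty_index"]

PARTICIPANT_COLUMNS = [
    "age",
    "cumhazard",
    "site",
    "alive90th",
    "followup_years",
    "died",
] + HEALTH_INDICES


class ValidationError(ValueError):
    """A container violated one of its structural invariants."""


@dataclass
class PeptideDataset:
    """Sparse participants x peptides log10 abundance matrix plus metadata.

    Attributes
    ----------
    abundance : DataFrame
        log10 abundances, NaN where a peptide was not detected in a sample.
    peptide_to_protein : Series
        Maps every peptide id (index) to its protein id.
    imputed_flag : DataFrame
        Boolean, same shape as ``abundance``; marks cells whose value was
        filled upstream of this pipeline (used as a model covariate).
    qc_pool : DataFrame
        Technical-replicate measurements (replicates x peptides) of a pooled
        control sample; never masked by missingness.
    technical_cv : Series or None
        Per-peptide technical coefficient of variation, populated by
        normalization.
    """

    abundance: pd.DataFrame
    peptide_to_protein: pd.Series
    imputed_flag: pd.DataFrame | None = None
    qc_pool: pd.DataFrame | None = None
    technical_cv: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.imputed_flag is None:
            self.imputed_flag = pd.DataFrame(
                False, index=self.abundance.index, columns=self.abundance.columns
            )
        missing_map = set(self.abundance.columns) - set(self.peptide_to_protein.index)
        if missing_map:
            raise ValidationError(
                f"{len(missing_map)} peptides lack a protein mapping, e.g. "
                f"{sorted(missing_map)[:3]}"
            )
        observed = self.abundance.to_numpy()
        if not np.isfinite(observed[~np.isnan(observed)]).all():
            raise ValidationError("observed abundances must be finite")

    @property
    def peptides(self) -> pd.Index:
        return self.abundance.columns

    @property
    def proteins(self) -> pd.Index:
        return pd.Index(self.peptide_to_protein.unique())

    def protein_peptides(self, protein_id: str) -> list[str]:
        """Peptide ids mapping to ``protein_id`` (in column order)."""
        members = set(self.peptide_to_protein.index[self.peptide_to_protein == protein_id])
        return [p for p in self.abundance.columns if p in members]

    def observed_counts(self) -> pd.Series:
        return self.abundance.notna().sum(axis=0)

    def copy(self) -> "PeptideDataset":
        return PeptideDataset(
            abundance=self.abundance.copy(),
            peptide_to_protein=self.peptide_to_protein.copy(),
            imputed_flag=self.imputed_flag.copy(),
            qc_pool=None if self.qc_pool is None else self.qc_pool.copy(),
            technical_cv=None if self.technical_cv is None else self.technical_cv.copy(),
        )


def validate_participants(table: pd.DataFrame) -> pd.DataFrame:
    """Check the participant-table invariants and return the table."""
    missing = [c for c in PARTICIPANT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"participant table missing columns: {missing}")
    if not table["alive90th"].isin([0, 1]).all():
        raise ValidationError("alive90th must be binary")
    if (table["followup_years"] <= 0).any():
        raise ValidationError("followup_years must be positive")
    return table


@dataclass
class PeptideEffect:
    """Per-peptide longevity association estimate."""

    peptide_id: str
    protein_id: str
    beta1: float
    se: float
    n_obs: int
    heckman_lambda_coef: float = np.nan
    converged: bool = True

    def as_dict(self) -> dict:
        return {
            "peptide_id": self.peptide_id,
            "protein_id": self.protein_id,
            "beta1": self.beta1,
            "se": self.se,
            "n_obs": self.n_obs,
            "heckman_lambda_coef": self.heckman_lambda_coef,
            "converged": self.converged,
        }


def effects_frame(effects: list[PeptideEffect]) -> pd.DataFrame:
    """Stack peptide effects into the peptide-effects table schema."""
    return pd.DataFrame([e.as_dict() for e in effects])


@dataclass
class ProteinMetaEffect:
    """Protein-level posterior summary from the Bayesian meta-analysis."""

    protein_id: str
    n_peptides: int
    meta_effect: float
    meta_fold: float
    meta_p: float
    ci95: tuple[float, float]
    tau2: float
    mcmc_samples_used: int
    mu_chain: np.ndarray | None = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {
            "protein_id": self.protein_id,
            "n_peptides": self.n_peptides,
            "meta_effect": self.meta_effect,
            "meta_fold": self.meta_fold,
            "meta_p": self.meta_p,
            "ci_lo": self.ci95[0],
            "ci_hi": self.ci95[1],
            "tau2": self.tau2,
            "mcmc_samples_used": self.mcmc_samples_used,
        }
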