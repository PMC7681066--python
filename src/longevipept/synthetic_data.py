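"""Synthetic serum-proteomics cohorts with known ground truth.

The generator emulates the statistical structure of a discovery-proteomics
longevity study in older men: ~2-58 tryptic peptides per protein on a log10
abundance scale, proteins organised into correlation blocks (pairwise r in
the 0.33-0.89 range), a subset of "signal" proteins whose abundance differs
between long-lived men and men who died earlier by log10 effects of
0.041-0.085 (folds 1.10-1.22, lower in the long-lived), abundance-dependent
(MNAR) missingness, pooled-QC technical replicates, and linkage of the
proteome to survival and health indices through a single latent
"inflammation" factor.

Model
-----
Each participant carries a latent factor ``f ~ N(0, 1)``.  The longevity
label is Bernoulli with logit ``a0 + a1*f`` (``a1 < 0``: high inflammation
disfavours longevity); survival time is exponential with log-hazard linear
in age and ``f``; health indices are monotone Gaussian transforms of ``f``
calibrated to target Spearman correlations.  Signal-protein abundance loads
on ``f`` and on a block factor, plus a direct group-label term.  The direct
coefficient is adjusted (by Gauss-Hermite quadrature of ``E[f | label]``) so
that the *total* expected group difference equals the configured effect
exactly; the stored truth table is therefore exactly recoverable from the
generating process.

All randomness flows from a single integer seed through fixed named
sub-streams, so stages can be re-run independently and byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import expit

from .datatypes import HEALTH_INDICES, PeptideDataset, validate_participants
from .reference_tables import tier1_log10_effects, tier1_peptide_counts


class ConfigurationError(ValueError):
    """A simulation parameter violated its constraints."""


# Gompertz parameters for a male birth-cohort hazard, used both to build the
# cumulative-hazard covariate and as the age trend of the simulated hazard.
_GOMPERTZ_H0 = 8e-5  # hazard per year at age 0 reference
_GOMPERTZ_THETA = 0.09  # log-hazard slope per year of age


def cumulative_hazard(age: np.ndarray) -> np.ndarray:
    """Population (life-table style) cumulative hazard at ``age`` in years."""
    age = np.asarray(age, dtype=float)
    return (_GOMPERTZ_H0 / _GOMPERTZ_THETA) * (np.exp(_GOMPERTZ_THETA * age) - 1.0)


def _default_signal_blocks() -> tuple[int, ...]:
    # 25 signal proteins in 5 correlation blocks (largest first), mirroring
    # the 5 clusters the longevity-associated proteins fell into.
    return (8, 6, 5, 4, 2)


@dataclass
class SimulationConfig:
    """Full parameterisation of the synthetic cohort.

    Defaults are the paper-scale study conditions: 1196 participants aged
    73-84 from 6 clinical sites, 224 proteins of which 25 carry the
    published fold changes (with the published peptide counts), ~3800
    peptides in total, MNAR missingness, and 102 pooled-QC replicates.
    """

    n_participants: int = 1196
    age_range: tuple[float, float] = (73.0, 84.0)
    n_proteins: int = 224
    peptides_per_protein: tuple[int, int] = (2, 58)
    mean_null_peptides: float = 17.4
    n_signal_proteins: int = 25
    signal_log10_effects: tuple[float, ...] | None = None  # default: published folds
    signal_peptide_counts: tuple[int, ...] | None = None  # default: published counts
    signal_block_sizes: tuple[int, ...] = field(default_factory=_default_signal_blocks)
    n_null_blocks: int = 7
    block_correlation: float = 0.6
    factor_share: float = 0.25  # share of signal-protein variance from the latent factor
    protein_sd: float = 0.13  # marginal biological SD, log10 units
    protein_age_slope: float = 0.004  # log10 per year of age, signal proteins
    proximity_slope: float = 0.0  # log10 per year of time-to-death, signal proteins
    peptide_noise_sd: float = 0.15  # log10 units
    peptide_effect_sd: float = 0.05  # between-peptide group-effect heterogeneity (log10)
    technical_cv: float = 0.20  # fraction, natural scale
    n_qc_pools: int = 102
    missingness_intercept: float = 1.2  # probit intercept (centred abundance)
    missingness_slope: float = 0.6  # within-peptide probit slope per log10 unit; >0 => MNAR
    missingness_base_slope: float = 0.25  # between-peptide slope on the peptide's base level
    missingness_quality_sd: float = 0.8  # per-participant sample-quality probit SD
    label_intercept: float = -0.15
    label_slope: float = -0.5
    survival_link: float = 0.35  # log-hazard per unit latent score
    followup_horizon: float = 15.0  # administrative censoring, years
    health_link: dict[str, float] = field(
        default_factory=lambda: {
            "self_rated_health": -0.15,
            "sf12_pcs": -0.16,
            "healthy_aging_index": 0.18,
            "frailty_index": 0.23,
        }
    )
    imputed_rate: float = 0.05
    n_sites: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal_log10_effects is None:
            eff = tier1_log10_effects()[: self.n_signal_proteins]
            if len(eff) < self.n_signal_proteins:
                raise ConfigurationError(
                    "signal_log10_effects must be given explicitly for more than "
                    f"{len(tier1_log10_effects())} signal proteins"
                )
            self.signal_log10_effects = tuple(eff)
        if self.signal_peptide_counts is None:
            k = tier1_peptide_counts()
            if len(k) >= self.n_signal_proteins:
                self.signal_peptide_counts = tuple(int(x) for x in k[: self.n_signal_proteins])
            else:
                lo, hi = self.peptides_per_protein
                self.signal_peptide_counts = tuple(
                    int(x) for x in np.linspace(lo, hi, self.n_signal_proteins).round()
                )
        self.validate()

    def validate(self) -> None:
        def _bad(name: str, why: str) -> ConfigurationError:
            return ConfigurationError(f"invalid {name}: {why}")

        for name in ("n_participants", "n_proteins", "n_qc_pools", "n_sites"):
            if getattr(self, name) <= 0:
                raise _bad(name, "must be a positive count")
        if not self.age_range[0] < self.age_range[1]:
            raise _bad("age_range", "must be a non-empty interval [lo, hi]")
        lo, hi = self.peptides_per_protein
        if not (1 <= lo <= hi):
            raise _bad("peptides_per_protein", "need 1 <= lo <= hi")
        if self.n_signal_proteins > self.n_proteins:
            raise _bad("n_signal_proteins", "cannot exceed n_proteins")
        if len(self.signal_log10_effects) != self.n_signal_proteins:
            raise _bad("signal_log10_effects", "length must equal n_signal_proteins")
        if sum(self.signal_block_sizes) != self.n_signal_proteins:
            raise _bad("signal_block_sizes", "sizes must sum to n_signal_proteins")
        if not (0.0 < self.block_correlation < 1.0):
            raise _bad("block_correlation", "must lie in (0, 1)")
        if not (0.0 <= self.factor_share < self.block_correlation):
            raise _bad(
                "factor_share",
                "must be in [0, block_correlation) so block variance is positive",
            )
        if self.protein_sd <= 0 or self.peptide_noise_sd < 0:
            raise _bad("protein_sd / peptide_noise_sd", "must be positive")
        if self.peptide_effect_sd < 0:
            raise _bad("peptide_effect_sd", "must be non-negative")
        if self.technical_cv < 0:
            raise _bad("technical_cv", "must be non-negative")
        if not np.isfinite([self.missingness_intercept, self.missingness_slope]).all():
            raise _bad("missingness", "probit coefficients must be finite")
        if self.missingness_quality_sd < 0:
            raise _bad("missingness_quality_sd", "must be non-negative")
        unknown = set(self.health_link) - set(HEALTH_INDICES)
        if unknown:
            raise _bad("health_link", f"unknown indices {sorted(unknown)}")
        if not (0 <= self.imputed_rate < 1):
            raise _bad("imputed_rate", "must lie in [0, 1)")

    # -- (de)serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = dict(d)
        for key in (
            "age_range",
            "peptides_per_protein",
            "signal_log10_effects",
            "signal_peptide_counts",
            "signal_block_sizes",
        ):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


@dataclass
class SimulatedStudy:
    """A simulated cohort: participants, peptides, and the generating truth."""

    participants: pd.DataFrame
    peptides: PeptideDataset
    truth: pd.DataFrame  # protein_id, true_effect, block, is_signal
    latent: pd.Series  # per-participant latent factor score

    def __post_init__(self) -> None:
        mapped = set(self.peptides.peptide_to_protein.unique())
        if not mapped <= set(self.truth["protein_id"]):
            raise ConfigurationError("truth table must cover every protein")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # Fixed-offset sub-streams: stage k always sees the same stream for a
    # given seed, independent of which stages ran before it.
    return np.random.default_rng([config.seed, stream])


def _label_shift(config: SimulationConfig) -> float:
    """E[f | label=1] - E[f | label=0] under the logistic label model."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    w = weights / weights.sum()
    p = expit(config.label_intercept + config.label_slope * nodes)
    p_marg = float(np.sum(w * p))
    e1 = float(np.sum(w * p * nodes)) / p_marg
    e0 = float(np.sum(w * (1 - p) * nodes)) / (1 - p_marg)
    return e1 - e0


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw the participant table: covariates, label, survival, health.

    Ages are uniform on ``age_range``; the longevity label follows a
    logistic model on the latent score; follow-up time and vital status come
    from an exponential model with log-hazard linear in age and
    ``survival_link * latent``, administratively censored at
    ``followup_horizon``; health indices are monotone Gaussian transforms of
    the latent score calibrated to the ``health_link`` Spearman targets.
    """
    rng = _rng(config, 1)
    n = config.n_participants
    f = rng.standard_normal(n)
    age = rng.uniform(*config.age_range, size=n)
    site = rng.integers(0, config.n_sites, size=n)

    label = (rng.random(n) < expit(config.label_intercept + config.label_slope * f)).astype(int)

    log_rate = (
        np.log(_GOMPERTZ_H0)
        + _GOMPERTZ_THETA * age
        + config.survival_link * f
    )
    t_death = rng.exponential(1.0, size=n) / np.exp(log_rate)
    died = (t_death <= config.followup_horizon).astype(int)
    followup = np.minimum(t_death, config.followup_horizon)
    followup = np.maximum(followup, 1e-3)  # strictly positive follow-up

    table = pd.DataFrame(
        {
            "age": age,
            "cumhazard": cumulative_hazard(age),
            "site": site,
            "alive90th": label,
            "followup_years": followup,
            "died": died,
        },
        index=pd.Index([f"S{i:04d}" for i in range(n)], name="participant_id"),
    )

    # Health indices: Gaussian copula component with Pearson rho chosen to
    # hit the Spearman target (rho = 2 sin(pi * r_s / 6)), then a monotone
    # affine transform onto a realistic scale.
    scales = {
        "self_rated_health": (4.2, 0.7),
        "sf12_pcs": (47.7, 10.8),
        "healthy_aging_index": (3.1, 1.6),
        "frailty_index": (0.0, 1.0),
    }
    for name in HEALTH_INDICES:
        target = config.health_link.get(name, 0.0)
        rho = 2.0 * np.sin(np.pi * target / 6.0)
        g = rho * f + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
        loc, scale = scales[name]
        table[name] = loc + scale * g

    table["latent"] = f
    return validate_participants(table)


def _protein_layout(config: SimulationConfig, rng: np.random.Generator):
    """Protein ids, per-protein peptide counts and block assignments."""
    n_sig = config.n_signal_proteins
    n_null = config.n_proteins - n_sig
    protein_ids = [f"P{i + 1:03d}" for i in range(config.n_proteins)]

    lo, hi = config.peptides_per_protein
    k_sig = np.clip(np.array(config.signal_peptide_counts), lo, hi)
    mean_extra = max(config.mean_null_peptides - lo, 0.5)
    k_null = lo + rng.geometric(1.0 / mean_extra, size=n_null) - 1
    k_null = np.clip(k_null, lo, hi)
    counts = np.concatenate([k_sig, k_null]).astype(int)

    blocks = np.empty(config.n_proteins, dtype=int)
    start = 0
    b = 0
    for size in config.signal_block_sizes:
        blocks[start : start + size] = b
        start += size
        b += 1
    null_sizes = np.full(config.n_null_blocks, n_null // config.n_null_blocks)
    null_sizes[: n_null % config.n_null_blocks] += 1
    for size in null_sizes:
        blocks[start : start + size] = b
        start += size
        b += 1
    return protein_ids, counts, blocks


def simulate_peptides(participants: pd.DataFrame, config: SimulationConfig) -> SimulatedStudy:
    """Simulate the complete (pre-missingness) peptide matrix with truth.

    Protein abundance = latent-factor loading (signal proteins) +
    block-correlated Gaussian + direct group effect + age trend; peptide
    abundance = protein abundance + peptide intercept + biological peptide
    noise + technical noise.  QC-pool rows are technical replicates of each
    peptide's grand intercept.
    """
    if len(participants) == 0:
        raise ConfigurationError("participants table is empty")
    rng = _rng(config, 2)
    n = len(participants)
    f = participants["latent"].to_numpy()
    label = participants["alive90th"].to_numpy()
    age_c = participants["age"].to_numpy() - float(np.mean(config.age_range))

    protein_ids, pep_counts, blocks = _protein_layout(config, rng)
    n_prot = config.n_proteins
    n_sig = config.n_signal_proteins
    sigma2 = config.protein_sd**2
    lam = np.sqrt(config.factor_share * sigma2)  # latent-factor loading (signal)
    r = config.block_correlation

    # Variance split keeps the marginal SD and the within-block correlation
    # at their configured values for signal and null proteins alike.
    block_var = np.where(np.arange(n_prot) < n_sig, (r - config.factor_share), r) * sigma2
    uniq_var = (1.0 - r) * sigma2

    effects = np.zeros(n_prot)
    effects[:n_sig] = np.asarray(config.signal_log10_effects)
    # Signal proteins load on the latent factor, which also drives the label;
    # subtracting the *realized* label-group difference in the factor makes
    # the planted group difference exactly the configured effect in this
    # cohort (conditional truth), not merely in expectation.
    kappa = float(f[label == 1].mean() - f[label == 0].mean()) if 0 < label.sum() < n else _label_shift(config)
    direct = effects.copy()
    direct[:n_sig] -= lam * kappa  # total group difference == configured effect

    n_blocks = blocks.max() + 1
    block_draw = rng.standard_normal((n, n_blocks))
    protein = block_draw[:, blocks] * np.sqrt(block_var)
    protein += np.sqrt(uniq_var) * rng.standard_normal((n, n_prot))
    protein[:, :n_sig] += lam * f[:, None]
    protein += direct * label[:, None]
    protein[:, :n_sig] += config.protein_age_slope * age_c[:, None]
    if config.proximity_slope != 0.0:
        ttd = participants["followup_years"].to_numpy()
        protein[:, :n_sig] += config.proximity_slope * ttd[:, None]

    # Peptide layer
    peptide_protein_idx = np.repeat(np.arange(n_prot), pep_counts)
    n_pep = peptide_protein_idx.size
    base_level = rng.normal(0.0, 0.5, size=n_prot)
    pep_intercept = base_level[peptide_protein_idx] + rng.uniform(-1.5, 1.5, size=n_pep)
    tech_sd = np.sqrt(np.log1p(config.technical_cv**2)) / np.log(10.0)

    values = protein[:, peptide_protein_idx] + pep_intercept
    # peptide-specific group-effect heterogeneity (digestion / ionisation
    # differences between peptides of one protein), centred within protein so
    # the protein-level group difference stays exactly the configured effect
    if config.peptide_effect_sd > 0:
        delta = rng.normal(0.0, config.peptide_effect_sd, size=n_pep)
        sums = np.bincount(peptide_protein_idx, weights=delta, minlength=n_prot)
        delta -= (sums / np.maximum(pep_counts, 1))[peptide_protein_idx]
        values += label[:, None] * delta[None, :]
    values += rng.normal(0.0, config.peptide_noise_sd, size=(n, n_pep))
    values += rng.normal(0.0, tech_sd, size=(n, n_pep))

    peptide_ids = []
    counter = np.zeros(n_prot, dtype=int)
    for j in peptide_protein_idx:
        counter[j] += 1
        peptide_ids.append(f"{protein_ids[j]}_pep{counter[j]:02d}")

    abundance = pd.DataFrame(values, index=participants.index, columns=peptide_ids)
    mapping = pd.Series(
        [protein_ids[j] for j in peptide_protein_idx], index=peptide_ids, name="protein_id"
    )
    qc = pd.DataFrame(
        pep_intercept[None, :] + rng.normal(0.0, tech_sd, size=(config.n_qc_pools, n_pep)),
        index=[f"QC{i:03d}" for i in range(config.n_qc_pools)],
        columns=peptide_ids,
    )
    imputed = pd.DataFrame(
        rng.random((n, n_pep)) < config.imputed_rate,
        index=participants.index,
        columns=peptide_ids,
    )
    dataset = PeptideDataset(
        abundance=abundance, peptide_to_protein=mapping, imputed_flag=imputed, qc_pool=qc
    )
    truth = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "true_effect": effects,
            "block": blocks,
            "is_signal": np.arange(n_prot) < n_sig,
            "n_peptides": pep_counts,
        }
    )
    return SimulatedStudy(
        participants=participants,
        peptides=dataset,
        truth=truth,
        latent=participants["latent"].rename("latent"),
    )


def apply_missingness(study: SimulatedStudy, config: SimulationConfig) -> SimulatedStudy:
    """Mask peptide cells MNAR with a probit in abundance plus sample quality.

    The retention index for cell (i, j) is

        a + b_within*(y_ij - mean_j) + b_between*(mean_j - grand mean) + c*q_i

    ``b_within > 0`` makes a peptide's low values preferentially missing
    (MNAR within peptide); ``b_between > 0`` makes low-abundance peptides
    missing more often overall (peptide-specific detection limits), so the
    empirical missing fraction still falls with abundance globally.
    ``q_i ~ N(0, 1)`` is a per-participant sample-quality factor (injection
    and column variability) scaled by ``missingness_quality_sd``; it shifts
    a whole sample's detection propensity independently of abundance, which
    is what the selection-correction instrument estimates downstream.
    QC-pool rows are never masked.  If masking would empty a peptide
    entirely, its highest-abundance cell is retained (every peptide must
    keep at least one observation).
    """
    rng = _rng(config, 3)
    data = study.peptides
    values = data.abundance.to_numpy()
    col_mean = np.nanmean(values, axis=0)
    within = values - col_mean[None, :]
    between = col_mean - np.nanmean(values)
    quality = rng.standard_normal(values.shape[0]) * config.missingness_quality_sd
    p_keep = stats.norm.cdf(
        config.missingness_intercept
        + config.missingness_slope * within
        + config.missingness_base_slope * between[None, :]
        + quality[:, None]
    )
    keep = rng.random(values.shape) < p_keep
    # never lose a peptide entirely
    dead = ~keep.any(axis=0)
    if dead.any():
        keep[np.nanargmax(values[:, dead], axis=0), np.where(dead)[0]] = True
    masked = np.where(keep, values, np.nan)
    new_data = PeptideDataset(
        abundance=pd.DataFrame(masked, index=data.abundance.index, columns=data.abundance.columns),
        peptide_to_protein=data.peptide_to_protein,
        imputed_flag=data.imputed_flag.where(pd.DataFrame(keep, index=data.abundance.index, columns=data.abundance.columns), False),
        qc_pool=data.qc_pool,
        technical_cv=data.technical_cv,
    )
    return SimulatedStudy(
        participants=study.participants, peptides=new_data, truth=study.truth, latent=study.latent
    )


def simulate_study(config: SimulationConfig, missingness: bool = True) -> SimulatedStudy:
    """Convenience: cohort -> peptides -> (optional) MNAR masking."""
    participants = simulate_cohort(config)
    study = simulate_peptides(participants, config)
    if missingness:
        study = apply_missingness(study, config)
    return study


# -- disk I/O ----------------------------------------------------------------

def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write long-format peptide TSV, phenotype TSV, QC TSV and truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "peptides": out / "peptides.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "qc_pool": out / "qc_pool.tsv",
        "truth": out / "truth.tsv",
    }
    ab = study.peptides.abundance
    long = ab.stack().rename("log10_abundance").reset_index()
    long.columns = ["participant_id", "peptide_id", "log10_abundance"]
    long["protein_id"] = study.peptides.peptide_to_protein.loc[long["peptide_id"]].to_numpy()
    flags = study.peptides.imputed_flag.stack()
    long["imputed_flag"] = flags.loc[
        pd.MultiIndex.from_frame(long[["participant_id", "peptide_id"]])
    ].astype(int).to_numpy()
    long = long[["participant_id", "peptide_id", "protein_id", "log10_abundance", "imputed_flag"]]
    long.to_csv(paths["peptides"], sep="\t", index=False, float_format="%.6f")
    study.participants.drop(columns=["latent"]).to_csv(
        paths["phenotypes"], sep="\t", float_format="%.6f"
    )
    study.peptides.qc_pool.to_csv(paths["qc_pool"], sep="\t", float_format="%.6f")
    truth = study.truth.copy()
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6f")
    return paths


def read_study(data_dir: str | Path) -> tuple[PeptideDataset, pd.DataFrame]:
    """Read the TSVs written by :func:`write_study` (truth not required)."""
    data_dir = Path(data_dir)
    long = pd.read_csv(data_dir / "peptides.tsv", sep="\t")
    abundance = long.pivot(index="participant_id", columns="peptide_id", values="log10_abundance")
    imputed = (
        long.pivot(index="participant_id", columns="peptide_id", values="imputed_flag")
        .fillna(0)
        .astype(bool)
    )
    mapping = long.drop_duplicates("peptide_id").set_index("peptide_id")["protein_id"]
    dup = long.groupby("peptide_id")["protein_id"].nunique()
    if (dup > 1).any():
        raise ConfigurationError(
            f"peptides mapped to multiple proteins: {list(dup.index[dup > 1])[:3]}"
        )
    qc_path = data_dir / "qc_pool.tsv"
    qc = pd.read_csv(qc_path, sep="\t", index_col=0) if qc_path.exists() else None
    dataset = PeptideDataset(
        abundance=abundance,
        peptide_to_protein=mapping.loc[abundance.columns],
        imputed_flag=imputed.loc[abundance.index, abundance.columns],
        qc_pool=qc,
    )
    participants = pd.read_csv(data_dir / "phenotypes.tsv", sep="\t", index_col=0)
    participants = validate_participants(participants)
    return dataset, participants
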