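"""End-to-end orchestration: simulate -> fit -> select -> score -> survive.

Every stage reads files written by earlier stages (or in-memory results of
the same run), never mutates inputs on disk, and records its parameters,
seed and row counts in a machine-readable JSON manifest.  The manifest
contains no timestamps, so identical configurations produce byte-identical
manifests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance_scores, prediction, stability_selection, survival_proximity
from .datatypes import PARTICIPANT_COLUMNS
from .peptide_regression import fit_all_peptides, flag_outliers, normalize_abundances
from .protein_meta import REPLICATE_MCMC, McmcConfig, MetaPriors, meta_all
from .synthetic_data import SimulationConfig, read_study, simulate_study, write_study

logger = logging.getLogger(__name__)


def demo_simulation_config(seed: int = 0) -> SimulationConfig:
    """A small cohort (200 participants, 30 proteins) for demos and smoke runs."""
    return SimulationConfig(
        n_participants=200,
        n_proteins=30,
        n_signal_proteins=6,
        signal_log10_effects=(-0.085, -0.075, -0.065, -0.060, -0.050, -0.042),
        signal_peptide_counts=(10, 8, 6, 5, 5, 4),
        signal_block_sizes=(4, 2),
        n_null_blocks=3,
        mean_null_peptides=6.0,
        n_qc_pools=20,
        seed=seed,
    )


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    simulate: bool = True
    data_dir: str | None = None  # read TSVs from here when simulate=False
    simulation: SimulationConfig | None = None
    heckman: bool = True
    drop_outliers: bool = True
    n_jackknife: int = 200
    mcmc_burn_in: int = 2500
    mcmc_base_samples: int = 10000
    classifier_max_subset: int = 14
    cv_folds: int = 5
    stages: tuple[str, ...] = (
        "simulate",
        "normalize",
        "fit_peptides",
        "meta",
        "select",
        "abundance",
        "cluster",
        "score",
        "classify",
        "survival",
        "proximity",
    )

    def __post_init__(self) -> None:
        if self.simulation is None and self.simulate:
            self.simulation = demo_simulation_config(self.seed)
        if self.n_jackknife <= 0 or self.cv_folds < 2:
            raise ValueError("n_jackknife must be positive and cv_folds >= 2")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def validate_inputs(data_dir: str | Path) -> list[str]:
    """Schema checks on the input TSVs; returns a list of violations."""
    data_dir = Path(data_dir)
    violations: list[str] = []
    pep_path = data_dir / "peptides.tsv"
    phe_path = data_dir / "phenotypes.tsv"
    if not pep_path.exists():
        return [f"missing file: {pep_path}"]
    if not phe_path.exists():
        return [f"missing file: {phe_path}"]
    long = pd.read_csv(pep_path, sep="\t")
    need = ["participant_id", "peptide_id", "protein_id", "log10_abundance"]
    for col in need:
        if col not in long.columns:
            violations.append(f"peptides.tsv missing column '{col}'")
    if violations:
        return violations
    multi = long.groupby("peptide_id")["protein_id"].nunique()
    for pep in multi.index[multi > 1]:
        violations.append(f"peptide '{pep}' mapped to {multi[pep]} proteins")
    dup = long.duplicated(["participant_id", "peptide_id"])
    if dup.any():
        violations.append(f"{int(dup.sum())} duplicate (participant, peptide) cells")
    if not np.isfinite(long["log10_abundance"]).all():
        violations.append("non-finite abundances present")
    pheno = pd.read_csv(phe_path, sep="\t", index_col=0)
    for col in PARTICIPANT_COLUMNS:
        if col not in pheno.columns:
            violations.append(f"phenotypes.tsv missing column '{col}'")
    unknown = set(long["participant_id"]) - set(pheno.index)
    if unknown:
        violations.append(
            f"{len(unknown)} participants in peptides.tsv absent from phenotypes.tsv"
        )
    return violations


def _write(frame: pd.DataFrame, path: Path, **kw) -> dict:
    frame.to_csv(path, sep="\t", index=kw.pop("index", False), float_format="%.6g")
    return {"path": str(path), "rows": int(len(frame))}


def run_all(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the results manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(config), "stages": {}}
    state: dict = {}

    stage_fns = {
        "simulate": _stage_simulate,
        "normalize": _stage_normalize,
        "fit_peptides": _stage_fit_peptides,
        "meta": _stage_meta,
        "select": _stage_select,
        "abundance": _stage_abundance,
        "cluster": _stage_cluster,
        "score": _stage_score,
        "classify": _stage_classify,
        "survival": _stage_survival,
        "proximity": _stage_proximity,
    }
    for stage in config.stages:
        fn = stage_fns.get(stage)
        if fn is None:
            raise StageFailure(stage, ValueError("unknown stage"))
        logger.info("stage %s: starting (seed=%d)", stage, config.seed)
        try:
            manifest["stages"][stage] = fn(config, state, out)
        except Exception as err:
            _dump_manifest(manifest, out)
            raise StageFailure(stage, err) from err
        logger.info("stage %s: done", stage)
    _dump_manifest(manifest, out)
    _write_summary(manifest, out)
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.simulation is not None:
        d["simulation"] = config.simulation.to_dict()
    d["stages"] = list(config.stages)
    return d


def _dump_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _write_summary(manifest: dict, out: Path) -> None:
    lines = ["pipeline summary", "================"]
    for stage, info in manifest["stages"].items():
        lines.append(f"[{stage}]")
        for key, val in info.items():
            if isinstance(val, dict) and "path" in val:
                lines.append(f"  {key}: {val['path']} ({val['rows']} rows)")
            else:
                lines.append(f"  {key}: {val}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")


# -- stages -----------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, state: dict, out: Path) -> dict:
    if config.simulate:
        study = simulate_study(config.simulation)
        paths = write_study(study, out / "data")
        state["data"], state["participants"] = study.peptides, study.participants
        state["truth"] = study.truth
        return {
            "seed": config.simulation.seed,
            "n_participants": len(study.participants),
            "n_peptides": study.peptides.abundance.shape[1],
            "outputs": {k: str(v) for k, v in paths.items()},
        }
    violations = validate_inputs(config.data_dir)
    if violations:
        raise ValueError("input validation failed: " + "; ".join(violations))
    data, participants = read_study(config.data_dir)
    state["data"], state["participants"] = data, participants
    return {"data_dir": str(config.data_dir), "n_participants": len(participants)}


def _stage_normalize(config: PipelineConfig, state: dict, out: Path) -> dict:
    data = normalize_abundances(state["data"], state["participants"])
    info: dict = {"n_peptides": int(data.abundance.shape[1])}
    if config.drop_outliers:
        flagged = flag_outliers(data)
        keep = data.abundance.index.difference(flagged)
        data.abundance = data.abundance.loc[keep]
        data.imputed_flag = data.imputed_flag.loc[keep]
        state["participants"] = state["participants"].loc[keep]
        info["n_outliers_removed"] = len(flagged)
    state["data"] = data
    return info


def _stage_fit_peptides(config: PipelineConfig, state: dict, out: Path) -> dict:
    effects = fit_all_peptides(state["data"], state["participants"], heckman=config.heckman)
    state["effects"] = effects
    return {
        "heckman": config.heckman,
        "effects": _write(effects, out / "peptide_effects.tsv"),
    }


def _stage_meta(config: PipelineConfig, state: dict, out: Path) -> dict:
    mcmc = McmcConfig(
        burn_in=config.mcmc_burn_in, base_samples=config.mcmc_base_samples, seed=config.seed
    )
    table, results = meta_all(state["effects"], mcmc=mcmc, keep_chains=True)
    state["meta"], state["meta_results"] = table, results
    return {"seed": config.seed, "meta": _write(table, out / "protein_meta.tsv")}


def _stage_select(config: PipelineConfig, state: dict, out: Path) -> dict:
    summaries, _ = stability_selection.jackknife_replicates(
        state["data"],
        state["participants"],
        B=config.n_jackknife,
        seed=config.seed,
        heckman=config.heckman,
        full_meta=state["meta"],
        mcmc=REPLICATE_MCMC,
    )
    ranks = stability_selection.eb_rank(state["meta_results"])
    tiers = stability_selection.tier_table(summaries, ranks)
    state["tiers"] = tiers
    state["tier1"] = stability_selection.select_tier1(summaries)
    return {
        "B": config.n_jackknife,
        "seed": config.seed,
        "n_tier1": len(state["tier1"]),
        "tiers": _write(tiers, out / "tiers.tsv"),
    }


def _stage_abundance(config: PipelineConfig, state: dict, out: Path) -> dict:
    matrix = abundance_scores.estimate_protein_abundance(state["data"])
    state["matrix"] = matrix
    return {"matrix": _write(matrix.reset_index(), out / "protein_abundance.tsv")}


def _stage_cluster(config: PipelineConfig, state: dict, out: Path) -> dict:
    assignment = abundance_scores.cluster_proteins(state["matrix"])
    state["clusters"] = assignment
    frame = assignment.labels.rename_axis("protein_id").reset_index()
    return {"k": assignment.k, "clusters": _write(frame, out / "clusters.tsv")}


def _stage_score(config: PipelineConfig, state: dict, out: Path) -> dict:
    proteins = state.get("tier1") or list(state["matrix"].columns)
    proteins = [p for p in proteins if p in state["matrix"].columns]
    if not proteins:
        proteins = list(state["matrix"].columns)
    score = abundance_scores.abundance_score(state["matrix"], proteins)
    corr = abundance_scores.health_correlations(score, state["participants"])
    state["score"] = score
    return {
        "n_proteins_in_score": len(proteins),
        "scores": _write(score.rename_axis("participant_id").reset_index(), out / "scores.tsv"),
        "health_correlations": _write(corr, out / "health_correlations.tsv"),
    }


def _stage_classify(config: PipelineConfig, state: dict, out: Path) -> dict:
    matrix, participants = state["matrix"], state["participants"]
    candidates = [p for p in (state.get("tier1") or []) if p in matrix.columns]
    if len(candidates) < 2:
        logger.warning("fewer than 2 tier-1 proteins; classifying on all proteins")
        candidates = list(matrix.columns)
    labels = participants["alive90th"].to_numpy()
    subset = prediction.mahalanobis_subset(
        matrix, labels, candidates, max_size=config.classifier_max_subset
    )
    ms = prediction.all_subsets_logistic(
        matrix, labels, subset, age=participants["age"].to_numpy()
    )
    auc, band = prediction.roc_auc(ms.averaged_probability, labels)
    cv_auc = prediction.bma_cv_auc(
        matrix, labels, subset, age=participants["age"].to_numpy(),
        n_folds=config.cv_folds, seed=config.seed,
    )
    probs = pd.DataFrame(
        {"participant_id": matrix.index, "bma_probability": ms.averaged_probability}
    )
    weights = pd.DataFrame(
        {
            "model": ["+".join(subset[i] for i in combo) for combo in ms.models],
            "bic": ms.bic,
            "weight": ms.weights,
        }
    )
    state["classifier"] = {"subset": subset, "auc": auc, "cv_auc": cv_auc}
    return {
        "subset_size": len(subset),
        "auc_in_sample": auc,
        "auc_ci": list(band),
        "auc_cv": cv_auc,
        "probabilities": _write(probs, out / "bma_probabilities.tsv"),
        "model_weights": _write(weights, out / "model_weights.tsv"),
    }


def _stage_survival(config: PipelineConfig, state: dict, out: Path) -> dict:
    proteins = [p for p in (state.get("tier1") or []) if p in state["matrix"].columns]
    matrix = state["matrix"][proteins] if proteins else state["matrix"]
    table = survival_proximity.mortality_hr_table(matrix, state["participants"])
    state["hazards"] = table
    return {"hazards": _write(table, out / "mortality_hazards.tsv")}


def _stage_proximity(config: PipelineConfig, state: dict, out: Path) -> dict:
    matrix = state["matrix"]
    tier1 = [p for p in (state.get("tier1") or []) if p in matrix.columns]
    if not tier1:
        tier1 = list(matrix.columns[: max(2, matrix.shape[1] // 2)])
    fit = survival_proximity.death_proximity_fit(matrix, state["participants"], tier1)
    result = {
        "slope": fit.slope,
        "slope_p": fit.slope_p,
        "first_stage_F": fit.first_stage_F,
        "weak_instruments": fit.weak_instruments,
        "curve": _write(fit.curve, out / "proximity_curve.tsv"),
    }
    (out / "proximity_slope.json").write_text(
        json.dumps({k: result[k] for k in ("slope", "slope_p", "first_stage_F")}, indent=2)
    )
    return result
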