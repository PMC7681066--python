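"""Delete-half jackknife stability analysis and tier-1/tier-2 selection.

Each of ``B`` replicates drops a uniformly random half of the participants
(stratified by longevity label), re-runs the peptide regressions and the
protein meta-analysis, and records every protein's replicate meta-effect
and meta-p.  The replicate median ("bootstrap") summaries feed the
selection rules:

* tier 1: bootstrap meta-p < 0.1 and |bootstrap log10 meta-effect| >= 0.041
  (a fold change of about 1.1);
* tier 2: |meta fold| > 1.05 and meta-p < 0.2 and rank in the top third of
  an empirical-Bayes ranking (posterior expected rank of |mu|), excluding
  tier-1 members.

A protein is "stable" when its full-cohort meta-effect lies inside the
replicate 2.5-97.5% band.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .datatypes import PeptideDataset, ProteinMetaEffect
from .peptide_regression import fit_all_peptides
from .protein_meta import REPLICATE_MCMC, McmcConfig, MetaPriors, meta_all, signed_fold_change

logger = logging.getLogger(__name__)

TIER1_EFFECT_THRESHOLD = 0.041  # |log10 meta-effect|; antilog ~ fold 1.10
TIER1_META_P_THRESHOLD = 0.1
TIER2_FOLD_THRESHOLD = 1.05
TIER2_META_P_THRESHOLD = 0.2


def _half_sample(
    participants: pd.DataFrame, rng: np.random.Generator, with_replacement: bool
) -> pd.Index:
    """A delete-half subsample of participant ids, stratified by label."""
    keep: list[np.ndarray] = []
    for _, grp in participants.groupby("alive90th"):
        ids = grp.index.to_numpy()
        m = len(ids) // 2
        keep.append(rng.choice(ids, size=m, replace=with_replacement))
    return pd.Index(np.concatenate(keep))


def jackknife_replicates(
    data: PeptideDataset,
    participants: pd.DataFrame,
    B: int = 200,
    seed: int = 0,
    heckman: bool = True,
    priors: MetaPriors | None = None,
    mcmc: McmcConfig | None = None,
    full_meta: pd.DataFrame | None = None,
    drop_fraction: float = 0.5,
    with_replacement: bool = False,
    summary: str = "median",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the delete-half jackknife over the whole estimation pipeline.

    Returns ``(summaries, replicate_effects)``: per-protein bootstrap
    summaries (columns ``protein_id, n_peptides, boot_effect, boot_fold,
    boot_meta_p, band_lo, band_hi, stable, n_replicates``) and the raw
    (protein x replicate) meta-effect matrix.  ``full_meta`` (the
    full-cohort meta table) is computed if not supplied.  Replicates in
    which a protein cannot be estimated (e.g. a single longevity group
    among its observed rows) are recorded as missing for that protein.

    ``drop_fraction=0.0`` keeps every participant in each replicate (used
    by equivalence checks); ``with_replacement=True`` switches to the
    resample-with-replacement reading of the scheme.
    """
    if summary not in ("median", "mean"):
        raise ValueError("summary must be 'median' or 'mean'")
    mcmc = mcmc or REPLICATE_MCMC
    priors = priors or MetaPriors()
    if full_meta is None:
        effects = fit_all_peptides(data, participants, heckman=heckman)
        full_meta, _ = meta_all(effects, priors=priors, mcmc=mcmc)
    proteins = full_meta["protein_id"].tolist()
    eff = np.full((len(proteins), B), np.nan)
    pval = np.full((len(proteins), B), np.nan)
    pos = {p: i for i, p in enumerate(proteins)}

    for r in range(B):
        rng = np.random.default_rng([seed, 101, r])
        if drop_fraction == 0.0:
            sub_ids = participants.index
        else:
            sub_ids = _half_sample(participants, rng, with_replacement)
        sub_part = participants.loc[sub_ids]
        sub_data = PeptideDataset(
            abundance=data.abundance.loc[sub_ids],
            peptide_to_protein=data.peptide_to_protein,
            imputed_flag=data.imputed_flag.loc[sub_ids],
            qc_pool=data.qc_pool,
            technical_cv=data.technical_cv,
        )
        try:
            pep = fit_all_peptides(sub_data, sub_part, heckman=heckman)
            rep_mcmc = McmcConfig(
                burn_in=mcmc.burn_in,
                base_samples=mcmc.base_samples,
                max_expansions=mcmc.max_expansions,
                geweke_threshold=mcmc.geweke_threshold,
                ess_floor=mcmc.ess_floor,
                seed=int(np.random.SeedSequence([seed, 202, r]).generate_state(1)[0] % (2**31)),
            )
            rep_meta, _ = meta_all(pep, priors=priors, mcmc=rep_mcmc)
        except Exception as err:  # a replicate may fail wholesale on tiny cohorts
            logger.warning("replicate %d failed: %s", r, err)
            continue
        for _, row in rep_meta.iterrows():
            i = pos.get(row["protein_id"])
            if i is not None:
                eff[i, r] = row["meta_effect"]
                pval[i, r] = row["meta_p"]

    agg = np.nanmedian if summary == "median" else np.nanmean
    rows = []
    for i, protein_id in enumerate(proteins):
        reps = eff[i]
        ok = np.isfinite(reps)
        full_effect = float(full_meta.loc[full_meta["protein_id"] == protein_id, "meta_effect"].iloc[0])
        if ok.sum() == 0:
            logger.warning("protein %s missing from every replicate", protein_id)
            boot_e = boot_p = band_lo = band_hi = np.nan
            stable = False
        else:
            with np.errstate(invalid="ignore"):
                boot_e = float(agg(reps))
                boot_p = float(agg(pval[i]))
            band_lo, band_hi = (float(q) for q in np.nanquantile(reps, [0.025, 0.975]))
            stable = bool(band_lo <= full_effect <= band_hi)
        rows.append(
            {
                "protein_id": protein_id,
                "n_peptides": int(full_meta.loc[full_meta["protein_id"] == protein_id, "n_peptides"].iloc[0]),
                "full_effect": full_effect,
                "boot_effect": boot_e,
                "boot_fold": signed_fold_change(boot_e) if np.isfinite(boot_e) else np.nan,
                "boot_meta_p": boot_p,
                "band_lo": band_lo,
                "band_hi": band_hi,
                "stable": stable,
                "n_replicates": int(ok.sum()),
            }
        )
    summaries = pd.DataFrame(rows)
    replicate_effects = pd.DataFrame(eff, index=pd.Index(proteins, name="protein_id"))
    return summaries, replicate_effects


# ---------------------------------------------------------------------------
# selection rules
# ---------------------------------------------------------------------------

def tier1_mask_from_folds(fold: np.ndarray, p: np.ndarray) -> np.ndarray:
    """The tier-1 rule stated on the fold scale: |fold| >= 1.1 and p < 0.1."""
    fold = np.asarray(fold, dtype=float)
    p = np.asarray(p, dtype=float)
    return (np.abs(fold) >= 10.0**TIER1_EFFECT_THRESHOLD) & (p < TIER1_META_P_THRESHOLD)


def select_tier1(
    summaries: pd.DataFrame,
    effect_col: str = "boot_effect",
    p_col: str = "boot_meta_p",
) -> list[str]:
    """Proteins with bootstrap meta-p < 0.1 and |log10 effect| >= 0.041."""
    if summaries.empty:
        raise ValueError("no summaries to select from")
    eff = summaries[effect_col].to_numpy(float)
    p = summaries[p_col].to_numpy(float)
    keep = (np.abs(eff) >= TIER1_EFFECT_THRESHOLD) & (p < TIER1_META_P_THRESHOLD)
    keep &= np.isfinite(eff) & np.isfinite(p)
    return summaries.loc[keep, "protein_id"].tolist()


def select_tier2(
    summaries: pd.DataFrame,
    ranks: pd.Series,
    effect_col: str = "boot_effect",
    p_col: str = "boot_meta_p",
) -> list[str]:
    """Second-tier proteins: |fold| > 1.05, meta-p < 0.2, top third of ranks,
    excluding tier-1 members."""
    tier1 = set(select_tier1(summaries, effect_col, p_col))
    eff = summaries[effect_col].to_numpy(float)
    p = summaries[p_col].to_numpy(float)
    cut = math.ceil(len(ranks) / 3)
    keep = (
        (np.abs(eff) > np.log10(TIER2_FOLD_THRESHOLD))
        & (p < TIER2_META_P_THRESHOLD)
        & np.isfinite(eff)
        & np.isfinite(p)
    )
    out = []
    for pid, flag in zip(summaries["protein_id"], keep):
        if flag and pid not in tier1 and pid in ranks.index and ranks[pid] <= cut:
            out.append(pid)
    return out


def eb_rank(results: dict[str, ProteinMetaEffect], meta: pd.DataFrame | None = None) -> pd.Series:
    """Empirical-Bayes ranking: posterior expected rank of |mu|.

    For each posterior draw, proteins are ranked by |mu| (rank 1 =
    largest); the expected rank over draws orders the proteins.  Final
    integer ranks break ties by meta-p, then protein id.  Requires the
    posterior chains (run the meta-analysis with ``keep_chains=True``).
    """
    ids = sorted(results)
    chains = []
    for pid in ids:
        chain = results[pid].mu_chain
        if chain is None:
            raise ValueError(f"protein {pid} has no stored chain; rerun with keep_chains=True")
        chains.append(np.abs(chain))
    n = min(len(c) for c in chains)
    mat = np.stack([c[:n] for c in chains])  # (P, n)
    # rank within each draw: largest |mu| gets rank 1
    order = np.argsort(-mat, axis=0, kind="stable")
    rank_per_draw = np.empty_like(order)
    put = np.arange(1, len(ids) + 1)[:, None] * np.ones((1, n), dtype=int)
    np.put_along_axis(rank_per_draw, order, put, axis=0)
    expected = rank_per_draw.mean(axis=1)

    meta_ps = np.array([results[pid].meta_p for pid in ids])
    frame = pd.DataFrame({"expected": expected, "meta_p": meta_ps, "protein_id": ids})
    frame = frame.sort_values(["expected", "meta_p", "protein_id"], kind="stable")
    ranks = pd.Series(np.arange(1, len(ids) + 1), index=frame["protein_id"], name="rank")
    return ranks


def tier_table(
    summaries: pd.DataFrame, ranks: pd.Series | None = None
) -> pd.DataFrame:
    """Assemble the tier assignment table (protein, tier, summaries, rank)."""
    tier1 = set(select_tier1(summaries))
    tier2 = set(select_tier2(summaries, ranks)) if ranks is not None else set()
    out = summaries.copy()
    out["tier"] = [
        "1" if p in tier1 else ("2" if p in tier2 else "none") for p in out["protein_id"]
    ]
    out["rank"] = [ranks.get(p, np.nan) if ranks is not None else np.nan for p in out["protein_id"]]
    return out
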