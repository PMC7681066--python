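"""Per-participant protein abundance, protein clustering, and summary scores.

Protein abundance for each participant is estimated from all observed
peptides of the protein with a crossed-random-effects model

    log10 abundance ~ intercept + participant effect + peptide effect + error,

fit per protein on the observed cells.  A participant's protein level is the
total prediction minus the peptide BLUP, i.e. intercept + participant BLUP;
participants with no observed peptide for a protein receive the intercept.
The mixed-model equations are solved exactly (the participant block is
diagonal, so the system reduces to a small dense solve on the peptide
block); variance components come from a method-of-moments decomposition,
with a fallback to participant means of peptide-centred values when the
participant variance component hits the boundary.

Proteins are clustered on their standardized abundance profiles: Gower
dissimilarity across participants (mean range-normalised absolute
difference), Ward agglomeration, and the Duda-Hart stopping rule scanning k
upward from 1.  The abundance summary score standardizes each protein,
sums over a protein set, and standardizes the total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .datatypes import HEALTH_INDICES, PeptideDataset


@dataclass
class ClusterAssignment:
    """Result of hierarchical protein clustering."""

    labels: pd.Series  # protein -> cluster id (1-based)
    k: int
    linkage_matrix: np.ndarray

    def members(self, cluster_id: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster_id])


# ---------------------------------------------------------------------------
# crossed random effects
# ---------------------------------------------------------------------------

def _variance_components(y: np.ndarray, row: np.ndarray, col: np.ndarray, n_rows: int, n_cols: int):
    """Method-of-moments (sigma2_participant, sigma2_peptide, sigma2_error)."""
    col_mean = np.bincount(col, weights=y, minlength=n_cols) / np.bincount(col, minlength=n_cols)
    r = y - col_mean[col]
    row_counts = np.bincount(row, minlength=n_rows)
    with np.errstate(invalid="ignore"):
        row_mean = np.bincount(row, weights=r, minlength=n_rows) / row_counts
    row_mean = np.where(row_counts > 0, row_mean, 0.0)
    resid = r - row_mean[row]
    s2e = float(np.var(resid, ddof=1)) if len(resid) > 2 else 0.0
    kbar = row_counts[row_counts > 0].mean() if (row_counts > 0).any() else 1.0
    nbar = np.bincount(col, minlength=n_cols).mean()
    s2a = float(np.var(row_mean[row_counts > 0], ddof=1) - s2e / kbar) if (row_counts > 0).sum() > 1 else 0.0
    s2c = float(np.var(col_mean, ddof=1) - s2e / nbar) if n_cols > 1 else 0.0
    return s2a, max(s2c, 1e-12), max(s2e, 1e-12)


def _blup_levels(
    y: np.ndarray, row: np.ndarray, col: np.ndarray, n_rows: int, n_cols: int
) -> np.ndarray:
    """Intercept + participant BLUP for every participant (one protein)."""
    s2a, s2c, s2e = _variance_components(y, row, col, n_rows, n_cols)
    row_counts = np.bincount(row, minlength=n_rows).astype(float)
    col_counts = np.bincount(col, minlength=n_cols).astype(float)
    row_sums = np.bincount(row, weights=y, minlength=n_rows)
    col_sums = np.bincount(col, weights=y, minlength=n_cols)

    if s2a <= 0:
        warnings.warn("participant variance component at boundary; using peptide-centred means")
        col_mean = np.where(col_counts > 0, col_sums / np.maximum(col_counts, 1), 0.0)
        r = y - col_mean[col]
        with np.errstate(invalid="ignore"):
            levels = np.bincount(row, weights=r, minlength=n_rows) / row_counts
        grand = y.mean()
        return np.where(row_counts > 0, grand + np.nan_to_num(levels), grand)

    lam_a = s2e / s2a
    lam_c = s2e / s2c
    d_a = row_counts + lam_a  # diagonal participant block

    # incidence matrix N (participants x peptides) as dense (n_cols small)
    N = np.zeros((n_rows, n_cols))
    np.add.at(N, (row, col), 1.0)

    # Schur complement onto [intercept; peptide effects]
    n_obs = float(len(y))
    top = np.empty((n_cols + 1, n_cols + 1))
    top[0, 0] = n_obs
    top[0, 1:] = col_counts
    top[1:, 0] = col_counts
    top[1:, 1:] = np.diag(col_counts + lam_c)
    rhs = np.concatenate([[y.sum()], col_sums])

    M_av = np.column_stack([row_counts, N])  # (n_rows, 1 + n_cols)
    inv_da = 1.0 / d_a
    top -= M_av.T @ (M_av * inv_da[:, None])
    rhs -= M_av.T @ (row_sums * inv_da)
    sol = np.linalg.solve(top + np.eye(n_cols + 1) * 1e-10, rhs)
    beta0, c = sol[0], sol[1:]
    a = inv_da * (row_sums - row_counts * beta0 - N @ c)
    return beta0 + a


def estimate_protein_abundance(
    data: PeptideDataset, min_peptides: int = 2
) -> pd.DataFrame:
    """Participant x protein abundance estimates (log10 scale).

    Only proteins with at least ``min_peptides`` peptides are estimated.
    The result has no missing entries: participants without observed
    peptides for a protein receive the protein's fixed intercept.
    """
    participants = data.abundance.index
    part_pos = {p: i for i, p in enumerate(participants)}
    out = {}
    for protein_id in sorted(data.proteins):
        peps = data.protein_peptides(protein_id)
        if len(peps) < min_peptides:
            continue
        block = data.abundance[peps]
        stacked = block.stack()
        if stacked.empty:
            continue
        row = np.array([part_pos[i] for i in stacked.index.get_level_values(0)])
        pep_pos = {p: j for j, p in enumerate(peps)}
        col = np.array([pep_pos[p] for p in stacked.index.get_level_values(1)])
        out[protein_id] = _blup_levels(
            stacked.to_numpy(float), row, col, len(participants), len(peps)
        )
    return pd.DataFrame(out, index=participants)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def gower_distances(profiles: np.ndarray) -> np.ndarray:
    """Condensed Gower dissimilarity between rows of ``profiles``.

    Every column (participant) is a continuous variable: the contribution
    of variable ``i`` to d(j, l) is |x_ji - x_li| / range_i, averaged over
    variables.  Equivalent to Manhattan distance on range-scaled columns
    divided by the number of variables.
    """
    ranges = profiles.max(axis=0) - profiles.min(axis=0)
    ranges[ranges == 0] = 1.0
    scaled = profiles / ranges
    return pdist(scaled, metric="cityblock") / profiles.shape[1]


def _duda_hart_critical(
    d: int, m: int, z: float = 3.2, rng: np.random.Generator | None = None, n_ref: int = 16
) -> float:
    """Critical Je(2)/Je(1) ratio below which a split is accepted.

    The classical closed form (1 - 2/(pi d) minus a z-multiple of its
    asymptotic spread) assumes many points per dimension; with m points in
    d >> m dimensions the best Ward bisection of pure noise removes far
    more than 2/(pi d) of the sum of squares, so the null ratio is
    calibrated by Monte Carlo: Ward-split ``n_ref`` reference draws of m
    iid Gaussian points in d dimensions and take mean - z * sd of their
    Je(2)/Je(1) ratios.
    """
    if m < 2:
        return 0.0
    rng = rng or np.random.default_rng(0)
    ratios = []
    for _ in range(n_ref):
        ref = rng.standard_normal((m, d))
        ratios.append(_best_split_ratio(ref))
    ratios = np.asarray(ratios)
    return float(ratios.mean() - z * max(ratios.std(ddof=1), 1e-3))


def _best_split_ratio(points: np.ndarray) -> float:
    """Je(2)/Je(1) of the top Ward bisection of a point cloud."""
    if len(points) == 2:
        return 0.0
    dist = pdist(points) / points.shape[1]
    Z = linkage(dist, method="ward")
    halves = fcluster(Z, 2, criterion="maxclust")
    total = float(((points - points.mean(axis=0)) ** 2).sum())
    if total <= 0:
        return 1.0
    within = sum(
        float(((points[halves == c] - points[halves == c].mean(axis=0)) ** 2).sum())
        for c in np.unique(halves)
    )
    return within / total


def cluster_proteins(
    matrix: pd.DataFrame, max_k: int = 50, z_crit: float = 3.2, seed: int = 0
) -> ClusterAssignment:
    """Gower + Ward hierarchical clustering with Duda-Hart stopping.

    Columns (proteins) are standardized, constant columns removed with a
    warning, Gower dissimilarities computed between protein profiles, and
    Ward's linkage built.  Scanning k upward from 1, the split of the next
    cluster is accepted while its Je(2)/Je(1) ratio falls below the
    (Monte-Carlo-calibrated) Duda-Hart critical value; the first
    non-rejected split stops the scan (ties resolve toward fewer clusters).
    """
    sd = matrix.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"removing {int(constant.sum())} constant protein columns")
        matrix = matrix.loc[:, ~constant]
        sd = sd[~constant]
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 non-constant proteins to cluster")
    z = ((matrix - matrix.mean(axis=0)) / sd).to_numpy().T  # proteins x participants
    dist = gower_distances(z)
    Z = linkage(dist, method="ward")

    # feature space for the within-cluster sums of squares of the rule
    ranges = z.max(axis=0) - z.min(axis=0)
    ranges[ranges == 0] = 1.0
    feats = z / ranges
    n_prot, d = feats.shape

    def _ss(idx: np.ndarray) -> float:
        sub = feats[idx]
        return float(((sub - sub.mean(axis=0)) ** 2).sum())

    k = 1
    labels = np.ones(n_prot, dtype=int)
    rng = np.random.default_rng([seed, 131])
    while k < min(max_k, n_prot):
        nxt = fcluster(Z, k + 1, criterion="maxclust")
        if len(np.unique(nxt)) <= k:  # ties: cannot realise k+1 clusters
            break
        # identify the parent cluster that split
        parent = None
        for lab in np.unique(labels):
            if len(np.unique(nxt[labels == lab])) > 1:
                parent = lab
                break
        if parent is None:
            break
        members = np.where(labels == parent)[0]
        je1 = _ss(members)
        children = np.unique(nxt[members])
        je2 = sum(_ss(members[nxt[members] == c]) for c in children)
        m = len(members)
        if je1 <= 0 or m < 2:
            break  # perfectly tight cluster: never split further
        if je2 / je1 >= _duda_hart_critical(d, m, z_crit, rng=rng):
            break  # split not warranted
        labels = nxt
        k += 1
    # relabel compactly, 1-based, in order of first appearance
    _, compact = np.unique(labels, return_inverse=True)
    return ClusterAssignment(
        labels=pd.Series(compact + 1, index=matrix.columns, name="cluster"),
        k=int(compact.max() + 1),
        linkage_matrix=Z,
    )


# ---------------------------------------------------------------------------
# summary scores & health correlations
# ---------------------------------------------------------------------------

def abundance_score(matrix: pd.DataFrame, protein_set: list[str]) -> pd.Series:
    """Standardize per protein, sum over ``protein_set``, standardize the sum."""
    if len(protein_set) == 0:
        raise ValueError("protein set is empty")
    missing = set(protein_set) - set(matrix.columns)
    if missing:
        raise KeyError(f"proteins not in abundance matrix: {sorted(missing)[:3]}")
    z = (matrix[protein_set] - matrix[protein_set].mean()) / matrix[protein_set].std(ddof=1)
    total = z.sum(axis=1)
    return ((total - total.mean()) / total.std(ddof=1)).rename("abundance_score")


def cluster_scores(
    matrix: pd.DataFrame, protein_set: list[str], clusters: ClusterAssignment
) -> pd.DataFrame:
    """Per-cluster subscores: mean of member z-scores within the set."""
    z = (matrix[protein_set] - matrix[protein_set].mean()) / matrix[protein_set].std(ddof=1)
    out = {}
    for cid in sorted(clusters.labels.unique()):
        members = [p for p in clusters.members(cid) if p in protein_set]
        if members:
            out[f"cluster_{cid}"] = z[members].mean(axis=1)
    return pd.DataFrame(out, index=matrix.index)


def health_correlations(score: pd.Series, participants: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlations of the abundance score with the health indices."""
    rows = []
    aligned = participants.loc[score.index]
    for name in HEALTH_INDICES:
        if name not in aligned.columns:
            continue
        x = aligned[name].to_numpy(float)
        if np.nanstd(x) == 0:
            rows.append({"index": name, "spearman_r": np.nan, "p_value": np.nan})
            continue
        r, p = stats.spearmanr(score.to_numpy(float), x, nan_policy="omit")
        rows.append({"index": name, "spearman_r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows)
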