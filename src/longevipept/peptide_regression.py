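"""Peptide-level preprocessing and longevity association models.

The association model for each peptide is an ordinary least-squares fit of

    log10 abundance ~ mu + beta1*alive90th + beta2*age + beta3*cumhazard
                      + site indicators + imputed indicator + error

on the rows where the peptide was observed; ``antilog10(beta1)`` is the fold
difference between long-lived men and those who died earlier.

Because detection in label-free proteomics depends on abundance itself
(MNAR), the naive fit is biased.  The Heckman two-step correction models
detection with a probit (the same covariates plus an exclusion variable:
the participant's mean observed abundance over the *other* peptides of the
same protein, which predicts detection but is redundant for the single
peptide's outcome equation given the covariates), then augments the outcome
regression with the inverse Mills ratio.  Standard errors account for the
estimated selection term via the usual two-step covariance.

The probit and OLS solvers here are deliberately lean numpy routines so the
delete-half jackknife can re-fit thousands of peptides hundreds of times;
they are cross-checked against statsmodels in the test suite.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .datatypes import PeptideDataset, PeptideEffect, effects_frame

MIN_OBS = 20
_FULLY_OBSERVED_FRACTION = 0.99


class NormalizationError(RuntimeError):
    pass


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# normalization & outliers
# ---------------------------------------------------------------------------

def normalize_abundances(
    data: PeptideDataset, participants: pd.DataFrame | None = None
) -> PeptideDataset:
    """Remove per-sample technical offsets estimated from pooled-QC peptides.

    The offset of each sample is the median, over the peptides detected in
    every QC replicate, of (sample value - QC mean of that peptide); it is
    subtracted from every observed value of the sample.  The per-peptide
    technical CV (from the QC replicate spread on the log10 scale) is stored
    on the returned dataset.

    When ``participants`` (with the longevity label) is supplied, the
    label-group means of the estimated offsets are equalised before
    subtraction.  Technical offsets cannot depend on a participant's future
    longevity (sample handling and run order are independent of outcome),
    so any label component in the raw offsets is absorbed biology — with
    many analytes shifted in one direction, a median offset soaks up
    roughly (signal fraction) x (effect size) of the true group difference
    and would attenuate every downstream association.
    """
    if data.qc_pool is None or data.qc_pool.empty:
        raise NormalizationError("no QC-pool replicates available")
    qc = data.qc_pool
    complete = qc.columns[qc.notna().all(axis=0)]
    if len(complete) == 0:
        raise NormalizationError("no peptide is detected in all QC replicates")
    ref = qc[complete].mean(axis=0)
    delta = data.abundance[complete] - ref
    offsets = delta.median(axis=1, skipna=True).fillna(0.0)

    if participants is not None and "alive90th" in participants.columns:
        labels = participants.loc[offsets.index, "alive90th"]
        grand = offsets.mean()
        group_means = offsets.groupby(labels).transform("mean")
        offsets = offsets - group_means + grand

    log10_sd = qc.std(axis=0, ddof=1)
    cv = np.sqrt(np.expm1((log10_sd * np.log(10.0)) ** 2))

    out = data.copy()
    out.abundance = data.abundance.sub(offsets, axis=0)
    out.technical_cv = pd.Series(cv, index=qc.columns, name="technical_cv")
    return out


def participant_profiles(data: PeptideDataset) -> pd.DataFrame:
    """Per-participant, per-protein means of observed peptide abundances,
    missing entries completed by the column median."""
    protein_of = data.peptide_to_protein
    profile = data.abundance.T.groupby(protein_of).mean().T
    return profile.fillna(profile.median(axis=0))


def flag_outliers(data: PeptideDataset, quantile: float = 0.999) -> list[str]:
    """Participants whose robust multivariate distance on the per-protein
    profile exceeds the chi-square ``quantile`` critical value."""
    profile = participant_profiles(data)
    n, p = profile.shape
    if n < 10:
        raise FitError(f"need at least 10 participants to flag outliers, got {n}")
    x = profile.to_numpy()
    try:
        from sklearn.covariance import MinCovDet

        if n <= p + 1:
            raise np.linalg.LinAlgError("more columns than rows")
        mcd = MinCovDet(random_state=0).fit(x)
        d2 = mcd.mahalanobis(x)
    except (np.linalg.LinAlgError, ValueError) as err:
        warnings.warn(f"robust covariance degenerate ({err}); using diagonal fallback")
        med = np.median(x, axis=0)
        mad = stats.median_abs_deviation(x, axis=0, scale="normal")
        mad[mad == 0] = 1.0
        d2 = (((x - med) / mad) ** 2).sum(axis=1)
    cut = stats.chi2.ppf(quantile, df=p)
    return list(profile.index[d2 > cut])


# ---------------------------------------------------------------------------
# design matrices and lean solvers
# ---------------------------------------------------------------------------

def base_design(participants: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept, alive90th, age, cumhazard and site indicator columns."""
    sites = pd.get_dummies(participants["site"].astype("category"), prefix="site", drop_first=True)
    X = np.column_stack(
        [
            np.ones(len(participants)),
            participants["alive90th"].to_numpy(float),
            participants["age"].to_numpy(float),
            participants["cumhazard"].to_numpy(float),
            sites.to_numpy(float),
        ]
    )
    names = ["const", "alive90th", "age", "cumhazard", *sites.columns]
    return X, names


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int]:
    """OLS via the normal equations, rank-deficiency safe.

    Returns (beta, cov, sigma2, rank).  The common full-rank case is a
    single LAPACK solve; aliased designs fall back to the pseudo-inverse
    (minimum-norm solution).
    """
    XtX = X.T @ X
    Xty = X.T @ y
    p = X.shape[1]
    try:
        XtX_inv = np.linalg.inv(XtX)
        # near-singular designs sneak past inv(); detect via reconstruction
        if not np.allclose(XtX @ XtX_inv[:, 0], np.eye(p)[:, 0], atol=1e-6):
            raise np.linalg.LinAlgError
        rank = p
    except np.linalg.LinAlgError:
        XtX_inv = np.linalg.pinv(XtX, hermitian=True)
        rank = int(np.linalg.matrix_rank(XtX))
    beta = XtX_inv @ Xty
    resid = y - X @ beta
    dof = max(len(y) - rank, 1)
    sigma2 = float(resid @ resid) / dof
    return beta, sigma2 * XtX_inv, sigma2, rank


_SQRT2PI = np.sqrt(2.0 * np.pi)


def _norm_pdf(x: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * x * x) / _SQRT2PI


def _probit_mle(
    X: np.ndarray,
    D: np.ndarray,
    extra: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Probit MLE by Fisher scoring for one or many response vectors.

    ``X`` is the shared (n, p0) design; ``D`` is (n,) or (n, k) of 0/1
    detection indicators; ``extra`` (optional, (n, k)) supplies one
    response-specific trailing column (the selection instrument), so the
    full design for response ``j`` is ``[X, extra[:, j]]``.  Returns
    (gamma (p, k), Fisher information inverse (k, p, p), converged (k,)).
    """
    D = np.atleast_2d(D.T).T  # (n, k)
    n, p0 = X.shape
    k = D.shape[1]
    if extra is not None:
        extra = np.atleast_2d(extra.T).T
    p = p0 + (0 if extra is None else 1)
    gamma = np.zeros((p, k))
    # start from the intercept-only solution
    pbar = np.clip(D.mean(axis=0), 1e-4, 1 - 1e-4)
    gamma[0] = stats.norm.ppf(pbar)
    converged = np.zeros(k, dtype=bool)
    eps = 1e-10

    def _eval(gamma_a: np.ndarray, D_a: np.ndarray, extra_a: np.ndarray | None):
        """Gradient and Fisher information for the active columns only."""
        ka = gamma_a.shape[1]
        eta = X @ gamma_a[:p0]
        if extra_a is not None:
            eta = eta + extra_a * gamma_a[p0]
        cdf = np.clip(ndtr(eta), eps, 1 - eps)
        pdf = _norm_pdf(eta)
        denom = cdf * (1 - cdf)
        weight = pdf**2 / denom
        score_resid = (D_a - cdf) * pdf / denom
        info = np.empty((ka, p, p))
        info[:, :p0, :p0] = np.einsum("np,nk,nq->kpq", X, weight, X)
        grad = np.empty((p, ka))
        grad[:p0] = X.T @ score_resid
        if extra_a is not None:
            wz = weight * extra_a
            info[:, :p0, p0] = (X.T @ wz).T
            info[:, p0, :p0] = info[:, :p0, p0]
            info[:, p0, p0] = (wz * extra_a).sum(axis=0)
            grad[p0] = (score_resid * extra_a).sum(axis=0)
        info += np.eye(p)[None] * 1e-10
        return grad, info

    for _ in range(max_iter):
        active = np.where(~converged)[0]
        if active.size == 0:
            break
        extra_a = None if extra is None else extra[:, active]
        grad, info = _eval(gamma[:, active], D[:, active], extra_a)
        step = np.linalg.solve(info, grad.T[..., None])[..., 0].T  # (p, ka)
        gamma[:, active] = gamma[:, active] + step
        converged[active] = np.abs(step).max(axis=0) < tol
    _, info = _eval(gamma, D, extra)
    info_inv = np.linalg.inv(info)
    finite = np.isfinite(gamma).all(axis=0)
    return gamma, info_inv, converged & finite


# ---------------------------------------------------------------------------
# per-peptide fits
# ---------------------------------------------------------------------------

def _peptide_design(
    X_base: np.ndarray, imputed_col: np.ndarray, obs: np.ndarray
) -> np.ndarray:
    cols = [X_base[obs]]
    if imputed_col[obs].any() and not imputed_col[obs].all():
        cols.append(imputed_col[obs, None].astype(float))
    return np.hstack(cols)


def _effect_from_fit(
    peptide_id: str,
    protein_id: str,
    beta: np.ndarray,
    cov: np.ndarray,
    n_obs: int,
    lambda_coef: float = np.nan,
    converged: bool = True,
) -> PeptideEffect:
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    return PeptideEffect(
        peptide_id=peptide_id,
        protein_id=protein_id,
        beta1=float(beta[1]),
        se=se,
        n_obs=int(n_obs),
        heckman_lambda_coef=lambda_coef,
        converged=bool(converged and se > 0),
    )


def fit_peptide_model(
    data: PeptideDataset, participants: pd.DataFrame, peptide_id: str
) -> PeptideEffect:
    """Uncorrected OLS association fit for a single peptide."""
    X_base, _ = base_design(participants)
    y_full = data.abundance[peptide_id].to_numpy(float)
    obs = ~np.isnan(y_full)
    protein_id = str(data.peptide_to_protein[peptide_id])
    n_obs = int(obs.sum())
    if n_obs < MIN_OBS:
        raise FitError(f"peptide {peptide_id}: {n_obs} observed values (< {MIN_OBS})")
    labels = participants["alive90th"].to_numpy()[obs]
    if labels.min() == labels.max():
        raise FitError(f"peptide {peptide_id}: only one longevity group observed")
    y = y_full[obs]
    if np.ptp(y) == 0.0:
        return PeptideEffect(peptide_id, protein_id, 0.0, 0.0, n_obs, converged=False)
    imputed_col = data.imputed_flag[peptide_id].to_numpy(bool)
    X = _peptide_design(X_base, imputed_col, obs)
    beta, cov, _, rank = _ols(X, y)
    if rank < X.shape[1]:
        warnings.warn(f"peptide {peptide_id}: rank-deficient design, aliased columns dropped")
    return _effect_from_fit(peptide_id, protein_id, beta, cov, n_obs)


def _block_mean_instrument(data: PeptideDataset, peptide_id: str) -> np.ndarray:
    """Participant mean observed abundance over the protein's *other* peptides
    (the protein-block-mean exclusion-variable dialect).

    It predicts detection strongly, but shares the protein-level biological
    variance with the target peptide's outcome error, so corrections based
    on it inherit that endogeneity; preferred default is
    :func:`_detection_propensity_instrument`.
    """
    protein_id = str(data.peptide_to_protein[peptide_id])
    peps = [p for p in data.protein_peptides(protein_id) if p != peptide_id]
    overall = data.abundance.mean(axis=1, skipna=True)
    if not peps:
        return overall.to_numpy(float)
    mean = data.abundance[peps].mean(axis=1, skipna=True)
    return mean.fillna(overall).to_numpy(float)


def _propensity_from_counts(obs_count: np.ndarray, total: np.ndarray) -> np.ndarray:
    """Probit-scale detection propensity from per-participant counts."""
    total = np.maximum(total, 1)
    frac = np.clip(obs_count / total, 1.0 / (total + 2), 1.0 - 1.0 / (total + 2))
    return stats.norm.ppf(frac)


def _detection_propensity_instrument(data: PeptideDataset, peptide_id: str) -> np.ndarray:
    """Participant detection propensity over peptides of *other* proteins.

    The probit of each participant's observed fraction across all peptides
    outside the target peptide's protein: it tracks sample-level detection
    quality (hence the selection probability of every peptide) while being
    exogenous to the target peptide's outcome error.
    """
    protein_id = str(data.peptide_to_protein[peptide_id])
    own = set(data.protein_peptides(protein_id))
    others = [p for p in data.abundance.columns if p not in own]
    if not others:  # single-protein dataset: leave out only the peptide itself
        others = [p for p in data.abundance.columns if p != peptide_id]
    block = data.abundance[others].notna().to_numpy()
    return _propensity_from_counts(block.sum(axis=1), np.full(len(block), block.shape[1]))


_INSTRUMENTS = {
    "detection_propensity": _detection_propensity_instrument,
    "protein_block_mean": _block_mean_instrument,
}


def heckman_correct(
    data: PeptideDataset,
    participants: pd.DataFrame,
    peptide_id: str,
    instrument: str = "detection_propensity",
) -> PeptideEffect:
    """Two-step Heckman selection-corrected association fit for one peptide.

    Step 1 fits a probit of the detection indicator on the outcome-model
    covariates plus an exclusion variable (``instrument``: the participant's
    detection propensity over other proteins' peptides by default, or the
    protein-block mean abundance dialect); step 2 augments the outcome OLS
    with the inverse Mills ratio and reports a standard error corrected for
    the estimated selection term.  Peptides at least 99% observed are
    returned uncorrected (nothing to correct), and a non-convergent probit
    falls back to the uncorrected fit with ``converged=False``.
    """
    y_full = data.abundance[peptide_id].to_numpy(float)
    obs = ~np.isnan(y_full)
    if obs.mean() >= _FULLY_OBSERVED_FRACTION:
        return fit_peptide_model(data, participants, peptide_id)
    n_obs = int(obs.sum())
    if n_obs < MIN_OBS:
        raise FitError(f"peptide {peptide_id}: {n_obs} observed values (< {MIN_OBS})")

    protein_id = str(data.peptide_to_protein[peptide_id])
    X_base, _ = base_design(participants)
    excl = _INSTRUMENTS[instrument](data, peptide_id)
    W = np.column_stack([X_base, excl])
    gamma, vgamma, ok = _probit_mle(X_base, obs.astype(float), extra=excl)
    base_fit = fit_peptide_model(data, participants, peptide_id)
    if not ok[0]:
        base_fit.converged = False
        return base_fit

    eta = W @ gamma[:, 0]
    mills = _norm_pdf(eta) / np.clip(ndtr(eta), 1e-10, None)
    imputed_col = data.imputed_flag[peptide_id].to_numpy(bool)
    X = _peptide_design(X_base, imputed_col, obs)
    Xs = np.hstack([X, mills[obs, None]])
    y = y_full[obs]
    beta, _, _, rank = _ols(Xs, y)
    cov = _heckman_cov(Xs, y, beta, eta[obs], mills[obs], W[obs], vgamma[0])
    return _effect_from_fit(
        peptide_id, protein_id, beta, cov, n_obs, lambda_coef=float(beta[-1]),
        converged=rank == Xs.shape[1],
    )


def _heckman_cov(
    Xs: np.ndarray,
    y: np.ndarray,
    beta: np.ndarray,
    eta_obs: np.ndarray,
    mills_obs: np.ndarray,
    W_obs: np.ndarray,
    vgamma: np.ndarray,
) -> np.ndarray:
    """Two-step covariance for the Mills-augmented outcome regression."""
    n1 = len(y)
    resid = y - Xs @ beta
    b_lambda = beta[-1]
    delta = mills_obs * (mills_obs + eta_obs)
    sigma2 = float(resid @ resid) / n1 + float(delta.mean()) * b_lambda**2
    rho2 = np.clip(b_lambda**2 / sigma2 if sigma2 > 0 else 0.0, 0.0, 1.0)
    A_inv = np.linalg.pinv(Xs.T @ Xs, hermitian=True)
    XdX = Xs.T @ (Xs * (delta * rho2)[:, None])
    XdW = Xs.T @ (W_obs * delta[:, None])
    Q = rho2 * XdW @ vgamma @ XdW.T
    V = sigma2 * A_inv @ (Xs.T @ Xs - XdX + Q) @ A_inv
    return V


# ---------------------------------------------------------------------------
# cohort-level batch fitting
# ---------------------------------------------------------------------------

def fit_all_peptides(
    data: PeptideDataset,
    participants: pd.DataFrame,
    heckman: bool = True,
    min_obs: int = MIN_OBS,
    instrument: str = "detection_propensity",
) -> pd.DataFrame:
    """Fit every eligible peptide, returning the peptide-effects table.

    The probit step is batched per protein (all its peptides share the same
    selection design), which is what makes the delete-half jackknife
    affordable.  Peptides with fewer than ``min_obs`` observations or a
    single longevity group among observed rows are skipped.
    """
    X_base, _ = base_design(participants)
    n = len(participants)
    labels = participants["alive90th"].to_numpy()
    values = data.abundance.to_numpy(float)
    observed = ~np.isnan(values)
    imputed = data.imputed_flag.to_numpy(bool)
    peptides = list(data.abundance.columns)
    col_of = {p: i for i, p in enumerate(peptides)}

    effects: list[PeptideEffect] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # participants with no data
        overall_mean = np.nan_to_num(np.nanmean(values, axis=1))
    total_obs_per_row = observed.sum(axis=1)

    for protein_id, group in data.peptide_to_protein.groupby(data.peptide_to_protein):
        peps = [p for p in group.index if p in col_of]
        idx = np.array([col_of[p] for p in peps])
        vals = values[:, idx]
        obs = observed[:, idx]
        n_obs = obs.sum(axis=0)
        frac = n_obs / n

        eligible = n_obs >= min_obs
        for j in np.where(eligible)[0]:
            lab = labels[obs[:, j]]
            if lab.min() == lab.max():
                eligible[j] = False

        needs_heckman = heckman & eligible & (frac < _FULLY_OBSERVED_FRACTION)
        mills = {}
        vgam = {}
        eta_all = {}
        inst = {}
        hk_idx = np.where(needs_heckman)[0]
        if hk_idx.size:
            if instrument == "protein_block_mean":
                # leave-one-out protein-block mean as the selection instrument
                sums = np.where(obs, vals, 0.0).sum(axis=1)
                counts = obs.sum(axis=1)
                loo_num = sums[:, None] - np.where(obs[:, hk_idx], vals[:, hk_idx], 0.0)
                loo_den = counts[:, None] - obs[:, hk_idx]
                with np.errstate(invalid="ignore", divide="ignore"):
                    loo = loo_num / loo_den
                loo = np.where(loo_den > 0, loo, overall_mean[:, None])
                loo = np.where(np.isfinite(loo), loo, 0.0)
            else:
                # detection propensity over peptides of other proteins
                other_obs = total_obs_per_row - obs.sum(axis=1)
                other_total = np.full(n, observed.shape[1] - obs.shape[1])
                if observed.shape[1] == obs.shape[1]:  # single-protein dataset
                    other_obs = total_obs_per_row[:, None] - obs[:, hk_idx]
                    other_total = np.full((n, 1), observed.shape[1] - 1)
                    loo = _propensity_from_counts(other_obs, other_total)
                else:
                    prop = _propensity_from_counts(other_obs, other_total)
                    loo = np.tile(prop[:, None], (1, hk_idx.size))
            gam, vg, ok = _probit_mle(X_base, obs[:, hk_idx].astype(float), extra=loo)
            p0 = X_base.shape[1]
            for pos, j in enumerate(hk_idx):
                if not ok[pos]:
                    needs_heckman[j] = False
                    continue
                eta = X_base @ gam[:p0, pos] + loo[:, pos] * gam[p0, pos]
                mills[j] = _norm_pdf(eta) / np.clip(ndtr(eta), 1e-10, None)
                vgam[j] = vg[pos]
                eta_all[j] = eta
                inst[j] = loo[:, pos]
        for j in np.where(eligible)[0]:
            o = obs[:, j]
            y = vals[o, j]
            if np.ptp(y) == 0.0:
                effects.append(
                    PeptideEffect(peps[j], str(protein_id), 0.0, 0.0, int(n_obs[j]), converged=False)
                )
                continue
            X = _peptide_design(X_base, imputed[:, idx[j]], o)
            if needs_heckman[j] and j in mills:
                Xs = np.hstack([X, mills[j][o, None]])
                beta, _, _, rank = _ols(Xs, y)
                W_full = np.column_stack([X_base, inst[j]])
                cov = _heckman_cov(
                    Xs, y, beta, eta_all[j][o], mills[j][o], W_full[o], vgam[j]
                )
                effects.append(
                    _effect_from_fit(
                        peps[j], str(protein_id), beta, cov, n_obs[j],
                        lambda_coef=float(beta[-1]), converged=rank == Xs.shape[1],
                    )
                )
            else:
                beta, cov, _, rank = _ols(X, y)
                conv = rank == X.shape[1]
                if heckman and frac[j] < _FULLY_OBSERVED_FRACTION and not needs_heckman[j]:
                    conv = False  # probit fallback
                effects.append(
                    _effect_from_fit(peps[j], str(protein_id), beta, cov, n_obs[j], converged=conv)
                )
    frame = effects_frame(effects)
    if not frame.empty:
        frame = frame.set_index("peptide_id", drop=False)
        frame = frame.loc[[p for p in peptides if p in frame.index]].reset_index(drop=True)
    return frame
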