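"""Mortality hazard ratios and death-proximity analysis of protein scores.

Per-protein mortality association: a Cox proportional-hazards fit of the
standardized protein abundance, adjusted for baseline age through a
restricted cubic spline (3 knots), reported as the hazard ratio per 1 SD of
abundance.  Tertile analysis interacts top/bottom abundance tertile
indicators with the age spline and evaluates tertile-vs-middle hazard
ratios on an age grid with delta-method bands.

Death proximity: a staged structural model.  A one-factor measurement model
summarises the protein set into factor scores; the structural equation
regresses the score on baseline age and time to death, instrumenting time
to death with health status (SF-12 physical component) and the population
cumulative hazard at age (two-stage least squares), since observed time to
death is endogenous to the score.  Model-predicted scores are then smoothed
along the time-to-death axis with an Epanechnikov-kernel local-linear
regression, and the association is summarised as the average time
derivative of the smooth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats


class SurvivalFitError(RuntimeError):
    pass


def restricted_cubic_spline(x: np.ndarray, knots: np.ndarray | None = None) -> np.ndarray:
    """Natural (restricted) cubic spline basis with 3 knots: 2 columns."""
    x = np.asarray(x, dtype=float)
    if knots is None:
        knots = np.quantile(x, [0.1, 0.5, 0.9])
    t1, t2, t3 = knots
    if not (t1 < t2 < t3):
        raise ValueError("knots must be strictly increasing")

    def pos3(u):
        return np.clip(u, 0, None) ** 3

    nl = (
        pos3(x - t1)
        - pos3(x - t2) * (t3 - t1) / (t3 - t2)
        + pos3(x - t3) * (t2 - t1) / (t3 - t2)
    ) / (t3 - t1) ** 2
    return np.column_stack([x, nl])


@dataclass
class HazardResult:
    protein_id: str
    hr_per_sd: float
    ci95: tuple[float, float]
    p_value: float
    n_deaths: int


def protein_mortality_hr(
    abundance: pd.Series, participants: pd.DataFrame, min_deaths: int = 20
) -> HazardResult:
    """Age-adjusted hazard ratio of mortality per 1 SD of protein abundance."""
    aligned = participants.loc[abundance.index]
    deaths = int(aligned["died"].sum())
    if deaths < min_deaths:
        raise SurvivalFitError(f"only {deaths} deaths (< {min_deaths})")
    sd = abundance.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise SurvivalFitError("zero-variance protein abundance")
    spline = restricted_cubic_spline(aligned["age"].to_numpy())
    df = pd.DataFrame(
        {
            "duration": aligned["followup_years"].to_numpy(),
            "event": aligned["died"].to_numpy(),
            "z": (abundance - abundance.mean()).to_numpy() / sd,
            "age_s1": spline[:, 0],
            "age_s2": spline[:, 1],
        }
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="duration", event_col="event",
            fit_options={"precision": 1e-10, "r_precision": 1e-14})
    beta = float(cph.params_["z"])
    se = float(cph.standard_errors_["z"])
    z = stats.norm.ppf(0.975)
    name = str(abundance.name) if abundance.name is not None else "protein"
    return HazardResult(
        protein_id=name,
        hr_per_sd=float(np.exp(beta)),
        ci95=(float(np.exp(beta - z * se)), float(np.exp(beta + z * se))),
        p_value=float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else np.nan,
        n_deaths=deaths,
    )


def mortality_hr_table(matrix: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    """Hazard-ratio table over all proteins of an abundance matrix."""
    rows = []
    for protein_id in matrix.columns:
        try:
            r = protein_mortality_hr(matrix[protein_id], participants)
        except SurvivalFitError as err:
            warnings.warn(f"{protein_id}: {err}")
            continue
        rows.append(
            {
                "protein_id": protein_id,
                "hazard_ratio": r.hr_per_sd,
                "ci_lo": r.ci95[0],
                "ci_hi": r.ci95[1],
                "p_value": r.p_value,
            }
        )
    return pd.DataFrame(rows)


def tertile_hr_by_age(
    abundance: pd.Series,
    participants: pd.DataFrame,
    age_grid: np.ndarray | None = None,
    n_age_bins: int = 4,
) -> pd.DataFrame:
    """Hazard ratios of the top and bottom abundance tertile versus the
    middle tertile, as functions of baseline age.

    Tertile indicators are interacted with the age spline basis; HRs are
    evaluated on ``age_grid`` with delta-method 95% bands.  Grid points
    falling in an age bin where a tertile is empty are reported missing.
    """
    aligned = participants.loc[abundance.index]
    tert = pd.qcut(abundance, 3, labels=[0, 1, 2]).astype(int)
    ages = aligned["age"].to_numpy()
    knots = np.quantile(ages, [0.1, 0.5, 0.9])
    spline = restricted_cubic_spline(ages, knots)
    spline_c = spline - spline.mean(axis=0)
    low = (tert == 0).to_numpy(float)
    high = (tert == 2).to_numpy(float)
    df = pd.DataFrame(
        {
            "duration": aligned["followup_years"].to_numpy(),
            "event": aligned["died"].to_numpy(),
            "low": low,
            "high": high,
            "s1": spline_c[:, 0],
            "s2": spline_c[:, 1],
            "low_s1": low * spline_c[:, 0],
            "low_s2": low * spline_c[:, 1],
            "high_s1": high * spline_c[:, 0],
            "high_s2": high * spline_c[:, 1],
        }
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="duration", event_col="event",
            fit_options={"precision": 1e-10, "r_precision": 1e-14})
    params = cph.params_
    cov = cph.variance_matrix_

    if age_grid is None:
        age_grid = np.linspace(np.quantile(ages, 0.05), np.quantile(ages, 0.95), 12)
    bins = np.quantile(ages, np.linspace(0, 1, n_age_bins + 1))
    rows = []
    z = stats.norm.ppf(0.975)
    for age in age_grid:
        b = np.searchsorted(bins[1:-1], age)
        in_bin = (ages >= bins[b]) & (ages <= bins[b + 1])
        sp = restricted_cubic_spline(np.array([age]), knots)[0] - spline.mean(axis=0)
        for name, ind in (("low", low), ("high", high)):
            if not (ind[in_bin] > 0).any() or not ((tert == 1).to_numpy()[in_bin]).any():
                rows.append({"age": age, "tertile": name, "hr": np.nan, "lo": np.nan, "hi": np.nan})
                continue
            vec = pd.Series(0.0, index=params.index)
            vec[name] = 1.0
            vec[f"{name}_s1"] = sp[0]
            vec[f"{name}_s2"] = sp[1]
            est = float(vec @ params)
            se = float(np.sqrt(vec @ cov @ vec))
            rows.append(
                {
                    "age": age,
                    "tertile": name,
                    "hr": np.exp(est),
                    "lo": np.exp(est - z * se),
                    "hi": np.exp(est + z * se),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# death proximity
# ---------------------------------------------------------------------------

def one_factor_scores(matrix: pd.DataFrame) -> tuple[pd.Series, np.ndarray]:
    """Maximum-likelihood one-factor scores of a standardized protein set.

    The factor sign is aligned so the average loading is positive.  A
    single-protein set returns the standardized protein itself.  Heywood
    cases (vanishing uniqueness) are clamped with a warning.
    """
    z = (matrix - matrix.mean()) / matrix.std(ddof=1)
    if z.shape[1] == 1:
        return z.iloc[:, 0].rename("factor_score"), np.array([1.0])
    from sklearn.decomposition import FactorAnalysis

    fa = FactorAnalysis(n_components=1, random_state=0)
    scores = fa.fit_transform(z.to_numpy())[:, 0]
    loadings = fa.components_[0]
    if np.any(fa.noise_variance_ < 1e-6):
        warnings.warn("Heywood case: uniqueness clamped at the variance floor")
    if loadings.mean() < 0:
        loadings, scores = -loadings, -scores
    scores = (scores - scores.mean()) / (scores.std(ddof=1) or 1.0)
    return pd.Series(scores, index=matrix.index, name="factor_score"), loadings


def epanechnikov_local_linear(
    x: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    bandwidth: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Local-linear regression with the Epanechnikov kernel.

    Returns (fitted values, local slopes) on ``grid``.  With an effectively
    infinite bandwidth every point gets full weight and the smooth
    collapses to the ordinary least-squares line.
    """
    fit = np.full(len(grid), np.nan)
    slope = np.full(len(grid), np.nan)
    for i, g in enumerate(grid):
        u = (x - g) / bandwidth
        w = np.where(np.abs(u) < 1, 0.75 * (1 - u**2), 0.0)
        if w.sum() <= 0 or (w > 0).sum() < 3:
            continue
        xc = x - g
        sw, swx, swx2 = w.sum(), (w * xc).sum(), (w * xc**2).sum()
        swy, swxy = (w * y).sum(), (w * xc * y).sum()
        det = sw * swx2 - swx**2
        if det <= 0:
            continue
        fit[i] = (swx2 * swy - swx * swxy) / det
        slope[i] = (sw * swxy - swx * swy) / det
    return fit, slope


def rule_of_thumb_bandwidth(x: np.ndarray, multiplier: float = 3.0) -> float:
    """Silverman-type bandwidth, widened for local-linear regression."""
    x = np.asarray(x, dtype=float)
    spread = min(x.std(ddof=1), stats.iqr(x) / 1.34) or x.std(ddof=1) or 1.0
    return multiplier * 0.9 * spread * len(x) ** (-0.2)


@dataclass
class ProximityFit:
    factor_scores: pd.Series
    loadings: np.ndarray
    coefficients: dict  # structural: intercept, age, time_to_death
    slope: float  # average time derivative of the smoothed prediction
    slope_p: float  # p-value of the structural time-to-death coefficient
    first_stage_F: float
    weak_instruments: bool
    curve: pd.DataFrame = field(repr=False, default=None)


def _two_stage_least_squares(
    y: np.ndarray, exog: np.ndarray, endog: np.ndarray, instruments: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """2SLS of y on [exog, endog], instrumenting endog.

    Returns (beta for [exog cols..., endog], covariance, first-stage F for
    the excluded instruments).
    """
    Z = np.hstack([exog, instruments])
    g, *_ = np.linalg.lstsq(Z, endog, rcond=None)
    endog_hat = Z @ g
    resid1 = endog - endog_hat
    # first-stage F of the excluded instruments
    g0, *_ = np.linalg.lstsq(exog, endog, rcond=None)
    rss0 = float(((endog - exog @ g0) ** 2).sum())
    rss1 = float((resid1**2).sum())
    q = instruments.shape[1]
    dof = len(y) - Z.shape[1]
    F = ((rss0 - rss1) / q) / (rss1 / dof) if rss1 > 0 and dof > 0 else np.inf

    Xhat = np.hstack([exog, endog_hat[:, None]])
    XtX_inv = np.linalg.pinv(Xhat.T @ Xhat, hermitian=True)
    beta = XtX_inv @ Xhat.T @ y
    X_actual = np.hstack([exog, endog[:, None]])
    resid = y - X_actual @ beta
    sigma2 = float(resid @ resid) / max(len(y) - Xhat.shape[1], 1)
    return beta, sigma2 * XtX_inv, float(F)


def death_proximity_fit(
    matrix: pd.DataFrame,
    participants: pd.DataFrame,
    protein_set: list[str],
    bandwidth: float | None = None,
    include_censored: bool = False,
) -> ProximityFit:
    """Staged SEM: factor scores, 2SLS structural fit, kernel smoothing.

    The structural model regresses the factor score on baseline age and
    time to death (decedents only unless ``include_censored``, in which
    case censored participants enter at the follow-up horizon), with SF-12
    PCS and the cumulative-hazard covariate as instruments for time to
    death.  The smoothed curve is evaluated over the observed time-to-death
    range only, and the slope is the mean derivative of the smooth.
    """
    if len(protein_set) == 0:
        raise ValueError("protein set is empty")
    scores, loadings = one_factor_scores(matrix[protein_set])
    aligned = participants.loc[scores.index]
    mask = (aligned["died"] == 1).to_numpy()
    if include_censored:
        mask = np.ones(len(aligned), dtype=bool)
    if mask.sum() < 10:
        raise SurvivalFitError("too few decedents for the structural fit")
    ttd = aligned["followup_years"].to_numpy()[mask]
    y = scores.to_numpy()[mask]
    age = aligned["age"].to_numpy()[mask]
    exog = np.column_stack([np.ones(mask.sum()), age - age.mean()])
    instruments = np.column_stack(
        [aligned["sf12_pcs"].to_numpy()[mask], aligned["cumhazard"].to_numpy()[mask]]
    )
    beta, cov, F = _two_stage_least_squares(y, exog, ttd, instruments)
    b_ttd = float(beta[-1])
    se_ttd = float(np.sqrt(max(cov[-1, -1], 0.0)))
    slope_p = float(2 * stats.norm.sf(abs(b_ttd / se_ttd))) if se_ttd > 0 else np.nan
    weak = F < 10
    if weak:
        warnings.warn(f"weak instruments: first-stage F = {F:.2f} < 10")

    # model-predicted score along time to death, at the mean age
    pred = beta[0] + b_ttd * ttd
    h = bandwidth if bandwidth is not None else rule_of_thumb_bandwidth(ttd)
    grid = np.linspace(ttd.min(), ttd.max(), 40)
    fitted, slopes = epanechnikov_local_linear(ttd, pred, grid, h)
    slope = float(np.nanmean(slopes))
    curve = pd.DataFrame({"time_to_death": grid, "predicted_score": fitted, "local_slope": slopes})
    return ProximityFit(
        factor_scores=scores,
        loadings=loadings,
        coefficients={"intercept": float(beta[0]), "age": float(beta[1]), "time_to_death": b_ttd},
        slope=slope,
        slope_p=slope_p,
        first_stage_F=F,
        weak_instruments=bool(weak),
        curve=curve,
    )
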