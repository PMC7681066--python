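"""Mortality hazard models and the death-proximity analysis."""

import numpy as np
import pandas as pd
import pytest

from longevipept.survival_proximity import (
    SurvivalFitError,
    death_proximity_fit,
    epanechnikov_local_linear,
    one_factor_scores,
    protein_mortality_hr,
    restricted_cubic_spline,
    rule_of_thumb_bandwidth,
    tertile_hr_by_age,
)


def survival_cohort(n=800, log_hr=0.0, seed=0, age_interaction=0.0):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    age = rng.uniform(70.0, 88.0, size=n)
    beta = log_hr + age_interaction * (age - 79.0)
    rate = 0.05 * np.exp(0.07 * (age - 79.0) + beta * z)
    t = rng.exponential(1.0 / rate)
    participants = pd.DataFrame(
        {
            "age": age,
            "followup_years": np.maximum(np.minimum(t, 15.0), 1e-3),
            "died": (t <= 15.0).astype(int),
        },
        index=pd.Index([f"S{i:04d}" for i in range(n)], name="participant_id"),
    )
    return pd.Series(z, index=participants.index, name="prot"), participants


def cox_partial_likelihood_newton(times, events, X, n_iter=200):
    """Independent textbook Newton-Raphson on the Cox partial likelihood
    (no ties in the fixture), used as an oracle."""
    order = np.argsort(times)
    times, events, X = times[order], events[order], X[order]
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        w = np.exp(eta)
        # reverse cumulative sums over the risk sets
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
        grad = np.zeros_like(beta)
        hess = np.zeros((len(beta), len(beta)))
        for i in np.where(events == 1)[0]:
            xbar = s1[i] / s0[i]
            grad += X[i] - xbar
            s2 = np.zeros((len(beta), len(beta)))
            wi = w[i:]
            Xi = X[i:]
            s2 = (wi[:, None, None] * Xi[:, :, None] * Xi[:, None, :]).sum(axis=0)
            hess -= s2 / s0[i] - np.outer(xbar, xbar)
        step = np.linalg.solve(hess, grad)
        beta = beta - step
        if np.abs(step).max() < 1e-12:
            break
    return beta


def test_cox_fit_matches_independent_partial_likelihood():
    rng = np.random.default_rng(20)
    z, participants = survival_cohort(n=20, log_hr=0.4, seed=20)
    res = protein_mortality_hr(z, participants, min_deaths=1)
    spline = restricted_cubic_spline(participants["age"].to_numpy())
    X = np.column_stack([(z - z.mean()).to_numpy() / z.std(ddof=1), spline])
    beta = cox_partial_likelihood_newton(
        participants["followup_years"].to_numpy(),
        participants["died"].to_numpy(),
        X,
    )
    assert np.log(res.hr_per_sd) == pytest.approx(beta[0], abs=1e-6)


def test_null_protein_covers_hr_one():
    hits = 0
    for seed in range(30):
        z, participants = survival_cohort(n=500, log_hr=0.0, seed=seed)
        res = protein_mortality_hr(z, participants)
        if res.ci95[0] <= 1.0 <= res.ci95[1]:
            hits += 1
    assert hits >= 25  # ~95% nominal coverage


def test_hr_is_invariant_to_rescaling():
    z, participants = survival_cohort(n=600, log_hr=0.3, seed=2)
    a = protein_mortality_hr(z, participants)
    b = protein_mortality_hr(z * 10.0, participants)
    assert a.hr_per_sd == pytest.approx(b.hr_per_sd, rel=1e-8)


def test_degenerate_inputs_raise():
    z, participants = survival_cohort(n=300, seed=3)
    with pytest.raises(SurvivalFitError):
        protein_mortality_hr(pd.Series(1.0, index=z.index), participants)
    alive = participants.copy()
    alive["died"] = 0
    with pytest.raises(SurvivalFitError):
        protein_mortality_hr(z, alive)


def test_tertile_curves_flat_under_the_null():
    z, participants = survival_cohort(n=1500, log_hr=0.0, seed=4)
    curves = tertile_hr_by_age(z, participants)
    ok = curves.dropna()
    covers = (ok["lo"] <= 1.0) & (1.0 <= ok["hi"])
    assert covers.mean() > 0.8


def test_attenuating_effect_declines_with_age_and_symmetry():
    z, participants = survival_cohort(n=4000, log_hr=0.5, seed=5, age_interaction=-0.04)
    curves = tertile_hr_by_age(z, participants)
    top = curves[curves["tertile"] == "high"].dropna()
    bottom = curves[curves["tertile"] == "low"].dropna()
    young = top[top["age"] < top["age"].median()]["hr"].mean()
    old = top[top["age"] >= top["age"].median()]["hr"].mean()
    assert young > old  # planted attenuation recovered
    # symmetric effect: bottom-tertile curve ~ reciprocal of top-tertile
    merged = top.merge(bottom, on="age", suffixes=("_hi", "_lo"))
    ratio = merged["hr_hi"] * merged["hr_lo"]
    assert np.median(np.abs(np.log(ratio))) < 0.35


def test_infinite_bandwidth_recovers_the_ols_line():
    rng = np.random.default_rng(6)
    x = rng.uniform(0, 10, 300)
    y = 1.5 - 0.3 * x + rng.standard_normal(300)
    grid = np.linspace(1, 9, 15)
    fit, slope = epanechnikov_local_linear(x, y, grid, bandwidth=1e9)
    coef = np.polyfit(x, y, 1)
    np.testing.assert_allclose(slope, coef[0], atol=1e-8)
    np.testing.assert_allclose(fit, coef[0] * grid + coef[1], atol=1e-6)


def test_bandwidth_rule_is_positive_and_scales():
    rng = np.random.default_rng(7)
    x = rng.uniform(0, 15, 500)
    h = rule_of_thumb_bandwidth(x)
    assert h > 0
    assert rule_of_thumb_bandwidth(2 * x) == pytest.approx(2 * h, rel=1e-9)


def test_single_protein_factor_is_the_standardized_protein():
    rng = np.random.default_rng(8)
    matrix = pd.DataFrame({"A": rng.standard_normal(100) * 3 + 1})
    scores, loadings = one_factor_scores(matrix)
    z = (matrix["A"] - matrix["A"].mean()) / matrix["A"].std(ddof=1)
    np.testing.assert_allclose(scores.to_numpy(), z.to_numpy(), atol=1e-12)


def test_factor_scores_invariant_to_protein_order():
    rng = np.random.default_rng(9)
    f = rng.standard_normal(200)
    matrix = pd.DataFrame({f"P{j}": 0.8 * f + 0.5 * rng.standard_normal(200) for j in range(5)})
    a, _ = one_factor_scores(matrix)
    b, _ = one_factor_scores(matrix[list(matrix.columns[::-1])])
    np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-8)


def test_proximity_null_and_planted_slopes():
    from longevipept.benchmarks import proximity_experiment

    result = proximity_experiment(seed=1)
    assert result["relative_error"] < 0.2
    assert result["signal_p"] < 0.05
    assert result["null_p"] > 0.1
    assert result["first_stage_F"] > 10
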