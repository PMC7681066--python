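"""Normalization, outlier flagging and the association/selection models."""

import numpy as np
import pandas as pd
import pytest

from longevipept.datatypes import PeptideDataset
from longevipept.peptide_regression import (
    FitError,
    NormalizationError,
    _probit_mle,
    base_design,
    fit_all_peptides,
    fit_peptide_model,
    flag_outliers,
    heckman_correct,
    normalize_abundances,
)
from longevipept.synthetic_data import SimulationConfig, simulate_cohort, simulate_peptides


def test_planted_sample_shift_is_removed(demo_study):
    data = demo_study.peptides.copy()
    victim = data.abundance.index[3]
    data.abundance.loc[victim] = data.abundance.loc[victim] + 0.3
    out = normalize_abundances(data)
    ref = normalize_abundances(demo_study.peptides)
    shifted = out.abundance.loc[victim].dropna()
    np.testing.assert_allclose(
        shifted.to_numpy(), ref.abundance.loc[victim].dropna().to_numpy(), atol=1e-6
    )


def test_technical_cv_recovered_from_qc_replicates():
    rng = np.random.default_rng(2)
    n_rep, cv = 40, 0.10
    sd_log10 = np.sqrt(np.log1p(cv**2)) / np.log(10.0)
    qc = pd.DataFrame(rng.normal(0.0, sd_log10, size=(n_rep, 30)),
                      columns=[f"pep{i}" for i in range(30)])
    data = PeptideDataset(
        abundance=pd.DataFrame(rng.normal(0, 0.2, (50, 30)), columns=qc.columns),
        peptide_to_protein=pd.Series("P1", index=qc.columns),
        qc_pool=qc,
    )
    out = normalize_abundances(data)
    assert abs(out.technical_cv.mean() - cv) < 0.02


def test_normalization_requires_qc_complete_peptides(demo_study):
    data = demo_study.peptides.copy()
    data.qc_pool = data.qc_pool.where(np.zeros_like(data.qc_pool, dtype=bool), np.nan)
    with pytest.raises(NormalizationError):
        normalize_abundances(data)


def test_label_balanced_offsets_do_not_absorb_group_differences(demo_study):
    out = normalize_abundances(demo_study.peptides, demo_study.participants)
    offsets = (demo_study.peptides.abundance - out.abundance).median(axis=1, skipna=True)
    groups = offsets.groupby(demo_study.participants["alive90th"]).mean()
    assert abs(groups.iloc[0] - groups.iloc[1]) < 1e-9


def test_planted_outlier_is_flagged(demo_study):
    data = demo_study.peptides.copy()
    victim = data.abundance.index[7]
    data.abundance.loc[victim] = data.abundance.loc[victim] + 5 * data.abundance.std().mean()
    flags = flag_outliers(data)
    assert victim in flags


def test_outlier_flagging_needs_ten_participants(demo_study):
    data = demo_study.peptides.copy()
    keep = data.abundance.index[:5]
    data.abundance = data.abundance.loc[keep]
    data.imputed_flag = data.imputed_flag.loc[keep]
    with pytest.raises(FitError):
        flag_outliers(data)


def test_ols_fit_matches_statsmodels(midsize_study):
    import statsmodels.api as sm

    data = midsize_study.peptides
    participants = midsize_study.participants
    peptide = data.abundance.columns[0]
    ours = fit_peptide_model(data, participants, peptide)

    y = data.abundance[peptide]
    obs = y.notna()
    X, _ = base_design(participants)
    cols = [X[obs.to_numpy()]]
    imp = data.imputed_flag[peptide].to_numpy()[obs.to_numpy()]
    if imp.any() and not imp.all():
        cols.append(imp[:, None].astype(float))
    fit = sm.OLS(y[obs].to_numpy(), np.hstack(cols)).fit()
    assert ours.beta1 == pytest.approx(fit.params[1], abs=1e-8)
    assert ours.se == pytest.approx(fit.bse[1], rel=1e-6)


def test_probit_matches_statsmodels(midsize_study):
    import statsmodels.api as sm

    participants = midsize_study.participants
    X, _ = base_design(participants)
    rng = np.random.default_rng(3)
    z = rng.standard_normal(len(participants))
    eta = 0.5 + 0.8 * z - 0.3 * participants["alive90th"].to_numpy()
    d = (rng.random(len(participants)) < sm.families.links.Probit().inverse(eta)).astype(float)
    gamma, _, ok = _probit_mle(X, d, extra=z)
    ref = sm.Probit(d, np.column_stack([X, z])).fit(disp=0)
    assert ok[0]
    np.testing.assert_allclose(gamma[:, 0], ref.params, atol=1e-5)


def test_permuted_labels_center_estimates_at_zero(midsize_study):
    participants = midsize_study.participants.copy()
    rng = np.random.default_rng(8)
    participants["alive90th"] = rng.permutation(participants["alive90th"].to_numpy())
    effects = fit_all_peptides(midsize_study.peptides, participants, heckman=False)
    t = effects["beta1"] / effects["se"]
    assert abs(t.mean()) < 0.3


def test_constant_abundance_is_flagged_nonconverged(midsize_study):
    data = midsize_study.peptides.copy()
    peptide = data.abundance.columns[0]
    data.abundance[peptide] = 1.0
    eff = fit_peptide_model(data, midsize_study.participants, peptide)
    assert eff.beta1 == 0.0 and eff.se == 0.0 and not eff.converged


def test_effect_invariant_to_constant_shift_and_row_order(midsize_study):
    data = midsize_study.peptides
    participants = midsize_study.participants
    peptide = data.abundance.columns[1]
    base = fit_peptide_model(data, participants, peptide)

    shifted = data.copy()
    shifted.abundance[peptide] = shifted.abundance[peptide] + 2.5
    assert fit_peptide_model(shifted, participants, peptide).beta1 == pytest.approx(
        base.beta1, abs=1e-10
    )

    order = np.random.default_rng(0).permutation(len(participants))
    reordered = data.copy()
    reordered.abundance = reordered.abundance.iloc[order]
    reordered.imputed_flag = reordered.imputed_flag.iloc[order]
    eff = fit_peptide_model(reordered, participants.iloc[order], peptide)
    assert eff.beta1 == pytest.approx(base.beta1, abs=1e-8)


def test_fully_observed_peptide_bypasses_heckman(midsize_study):
    data = midsize_study.peptides.copy()
    participants = midsize_study.participants
    peptide = data.abundance.columns[0]
    col = data.abundance[peptide]
    data.abundance[peptide] = col.fillna(col.mean())  # force full observation
    plain = fit_peptide_model(data, participants, peptide)
    heck = heckman_correct(data, participants, peptide)
    assert heck.beta1 == plain.beta1 and heck.se == plain.se
    assert np.isnan(heck.heckman_lambda_coef)


def test_batch_fit_agrees_with_single_peptide_fits(demo_study):
    data = normalize_abundances(demo_study.peptides)
    participants = demo_study.participants
    table = fit_all_peptides(data, participants, heckman=True).set_index("peptide_id")
    rng = np.random.default_rng(4)
    for peptide in rng.choice(table.index.to_numpy(), size=6, replace=False):
        frac = data.abundance[peptide].notna().mean()
        single = (
            heckman_correct(data, participants, peptide)
            if frac < 0.99
            else fit_peptide_model(data, participants, peptide)
        )
        assert table.loc[peptide, "beta1"] == pytest.approx(single.beta1, abs=1e-8)
        assert table.loc[peptide, "se"] == pytest.approx(single.se, rel=1e-6)


def test_heckman_type_one_error_under_mcar_null():
    # null effects, MCAR missingness: the correction must not reject more
    # often than the uncorrected fit (peptides of one protein share the
    # protein-level draw, so rates are compared pairwise on the same data)
    config = SimulationConfig(
        n_participants=400,
        n_proteins=30,
        n_signal_proteins=1,
        signal_log10_effects=(0.0,),
        signal_peptide_counts=(5,),
        signal_block_sizes=(1,),
        n_null_blocks=5,
        mean_null_peptides=5.0,
        n_qc_pools=10,
        missingness_intercept=0.8,
        missingness_slope=0.0,
        missingness_base_slope=0.0,
        peptide_effect_sd=0.0,
        seed=21,
    )
    from longevipept.synthetic_data import apply_missingness

    study = apply_missingness(simulate_peptides(simulate_cohort(config), config), config)
    rates = {}
    for heckman in (True, False):
        effects = fit_all_peptides(study.peptides, study.participants, heckman=heckman)
        effects = effects[effects["converged"]]
        rates[heckman] = float((np.abs(effects["beta1"] / effects["se"]) > 1.96).mean())
    assert rates[True] <= rates[False] + 0.02
    assert rates[True] <= 0.15
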