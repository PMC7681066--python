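"""Jackknife stability, tier rules and empirical-Bayes ranking."""

import numpy as np
import pandas as pd
import pytest

from longevipept.peptide_regression import fit_all_peptides
from longevipept.protein_meta import McmcConfig, meta_all
from longevipept.reference_tables import tier1_table
from longevipept.stability_selection import (
    eb_rank,
    jackknife_replicates,
    select_tier1,
    select_tier2,
    tier1_mask_from_folds,
    tier_table,
)
from tests.conftest import make_effects


def summaries_frame(rows):
    return pd.DataFrame(rows, columns=["protein_id", "boot_effect", "boot_meta_p"])


def test_published_rows_all_pass_the_tier1_rule():
    table = tier1_table()
    keep = tier1_mask_from_folds(table["meta_fold"], table["meta_p"])
    assert keep.sum() == 25


@pytest.mark.parametrize(
    "fold,p,expected",
    [(-1.09, 0.01, False), (-1.15, 0.11, False), (-1.15, 0.05, True), (1.10, 0.099, True)],
)
def test_tier1_rule_boundaries(fold, p, expected):
    assert bool(tier1_mask_from_folds(np.array([fold]), np.array([p]))[0]) == expected


def test_tier1_monotone_in_effect_size():
    base = summaries_frame([("A", -0.042, 0.05), ("B", -0.030, 0.05)])
    assert select_tier1(base) == ["A"]
    stronger = summaries_frame([("A", -0.09, 0.05), ("B", -0.030, 0.05)])
    assert "A" in select_tier1(stronger)


def test_tier2_rules_and_disjointness():
    rows = summaries_frame(
        [
            ("T1", -0.05, 0.01),     # tier 1
            ("T2", np.log10(1.07), 0.15),  # tier 2 if ranked high
            ("LOW", np.log10(1.07), 0.15),  # same stats, ranked low
            ("BADP", np.log10(1.07), 0.25),
            ("SMALL", np.log10(1.03), 0.05),
            ("X1", 0.001, 0.4),
        ]
    )
    ranks = pd.Series([1, 2, 6, 3, 4, 5], index=["T1", "T2", "LOW", "BADP", "SMALL", "X1"])
    tier2 = select_tier2(rows, ranks)
    assert tier2 == ["T2"]
    assert "T1" not in tier2
    table = tier_table(rows, ranks)
    assert table.loc[table["protein_id"] == "T1", "tier"].iloc[0] == "1"
    assert table.loc[table["protein_id"] == "LOW", "tier"].iloc[0] == "none"


def test_eb_rank_orders_by_posterior_magnitude():
    effs = pd.concat(
        [
            make_effects("STRONG", [-0.09, -0.08, -0.085], [0.01] * 3),
            make_effects("WEAK", [-0.02, -0.015, -0.025], [0.01] * 3),
            make_effects("NULL", [0.001, -0.002, 0.0015], [0.01] * 3),
        ]
    )
    _, results = meta_all(effs, mcmc=McmcConfig(seed=3), keep_chains=True)
    ranks = eb_rank(results)
    assert ranks["STRONG"] < ranks["WEAK"] < ranks["NULL"]


def test_eb_rank_recovers_graded_magnitudes():
    rng = np.random.default_rng(29)
    true = np.linspace(0.0, 0.1, 30)
    frames = [
        make_effects(f"G{i:02d}", t + rng.normal(0, 0.008, 4), [0.008] * 4)
        for i, t in enumerate(true)
    ]
    _, results = meta_all(
        pd.concat(frames),
        mcmc=McmcConfig(burn_in=500, base_samples=2000, max_expansions=0, seed=1),
        keep_chains=True,
    )
    ranks = eb_rank(results)
    from scipy.stats import spearmanr

    rho, _ = spearmanr([ranks[f"G{i:02d}"] for i in range(30)], true)
    assert rho < -0.8


def test_eb_rank_needs_chains():
    effs = make_effects("P", [-0.05, -0.04], [0.02, 0.02])
    _, results = meta_all(effs, mcmc=McmcConfig(seed=1), keep_chains=False)
    with pytest.raises(ValueError):
        eb_rank(results)


def test_drop_none_replicate_reproduces_full_cohort(demo_study):
    data = demo_study.peptides
    participants = demo_study.participants
    effects = fit_all_peptides(data, participants, heckman=False)
    mcmc = McmcConfig(burn_in=2000, base_samples=8000, max_expansions=0, seed=0)
    full, _ = meta_all(effects, mcmc=mcmc)
    summaries, reps = jackknife_replicates(
        data, participants, B=1, seed=0, heckman=False, full_meta=full,
        drop_fraction=0.0, mcmc=mcmc,
    )
    # identical data; only Monte Carlo noise between the chains (heavy
    # tau-mixture tails make the posterior-mean MC error a few 1e-3)
    np.testing.assert_allclose(
        summaries["boot_effect"].to_numpy(), summaries["full_effect"].to_numpy(), atol=1.2e-2
    )


def test_jackknife_is_deterministic_and_stratified(demo_study):
    data = demo_study.peptides
    participants = demo_study.participants
    effects = fit_all_peptides(data, participants, heckman=False)
    mcmc = McmcConfig(burn_in=300, base_samples=1000, max_expansions=0, seed=0)
    full, _ = meta_all(effects, mcmc=mcmc)
    a, ra = jackknife_replicates(data, participants, B=3, seed=4, heckman=False,
                                 full_meta=full, mcmc=mcmc)
    b, rb = jackknife_replicates(data, participants, B=3, seed=4, heckman=False,
                                 full_meta=full, mcmc=mcmc)
    pd.testing.assert_frame_equal(a, b)
    pd.testing.assert_frame_equal(ra, rb)
    assert (a["n_replicates"] >= 1).all()


def test_discordant_two_peptide_protein_has_wider_band_than_concordant(midsize_study):
    # paired comparison built directly on replicate meta-effect dispersion
    rng = np.random.default_rng(31)
    n_rep = 60
    concordant, discordant = [], []
    for r in range(n_rep):
        big = make_effects("BIG", -0.08 + rng.normal(0, 0.005, 20), [0.005] * 20)
        two = make_effects("TWO", [-0.02 + rng.normal(0, 0.02), -0.14 + rng.normal(0, 0.02)],
                           [0.02, 0.02])
        mcmc = McmcConfig(burn_in=200, base_samples=600, max_expansions=0, seed=r)
        table, _ = meta_all(pd.concat([big, two]), mcmc=mcmc)
        table = table.set_index("protein_id")
        concordant.append(table.loc["BIG", "meta_effect"])
        discordant.append(table.loc["TWO", "meta_effect"])
    assert np.std(discordant) > np.std(concordant)
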