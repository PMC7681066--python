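"""Protein abundance BLUPs, clustering, scores and health correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform

from longevipept.abundance_scores import (
    abundance_score,
    cluster_proteins,
    cluster_scores,
    estimate_protein_abundance,
    gower_distances,
    health_correlations,
)
from longevipept.datatypes import PeptideDataset


def crossed_dataset(n=80, k=5, part_sd=0.1, noise_sd=0.05, seed=0, missing=0.0):
    rng = np.random.default_rng(seed)
    levels = rng.normal(0, part_sd, size=n)
    pep_fx = rng.normal(0, 0.8, size=k)
    values = levels[:, None] + pep_fx[None, :] + rng.normal(0, noise_sd, (n, k))
    if missing:
        values = np.where(rng.random((n, k)) < missing, np.nan, values)
    cols = [f"P1_pep{j}" for j in range(k)]
    data = PeptideDataset(
        abundance=pd.DataFrame(values, columns=cols,
                               index=[f"S{i:03d}" for i in range(n)]),
        peptide_to_protein=pd.Series("P1", index=cols),
    )
    return data, levels


def test_balanced_complete_estimates_track_participant_means():
    data, levels = crossed_dataset()
    est = estimate_protein_abundance(data)["P1"]
    centred = data.abundance - data.abundance.mean(axis=0)
    means = centred.mean(axis=1)
    # shrinkage preserves order and near-proportionality
    assert np.corrcoef(est, means)[0, 1] > 0.999


def test_peptide_shift_leaves_participant_contrasts_unchanged():
    # a constant shift of one peptide is absorbed by the peptide effect (up
    # to the non-identifiable intercept/peptide-mean split): participant
    # CONTRASTS, which every downstream stage consumes, are untouched
    data, _ = crossed_dataset(missing=0.15, seed=3)
    shifted = data.copy()
    shifted.abundance.iloc[:, 0] = shifted.abundance.iloc[:, 0] + 3.0
    a = estimate_protein_abundance(data)["P1"]
    b = estimate_protein_abundance(shifted)["P1"]
    diff = (b - a).to_numpy()
    # variance components re-estimated from shifted data move shrinkage a hair
    assert diff.std() < 1e-3
    np.testing.assert_allclose((a - a.mean()).to_numpy(), (b - b.mean()).to_numpy(), atol=1e-3)


def test_protein_shift_equivariance():
    data, _ = crossed_dataset(missing=0.1, seed=4)
    shifted = data.copy()
    shifted.abundance = shifted.abundance + 0.7
    a = estimate_protein_abundance(data)["P1"]
    b = estimate_protein_abundance(shifted)["P1"]
    np.testing.assert_allclose((b - a).to_numpy(), 0.7, atol=1e-6)


def test_true_participant_levels_recovered():
    data, levels = crossed_dataset(n=200, k=10, part_sd=0.1, seed=5, missing=0.1)
    est = estimate_protein_abundance(data)["P1"]
    assert np.corrcoef(est.to_numpy(), levels)[0, 1] > 0.9


def test_blup_agrees_with_statsmodels_mixedlm():
    import statsmodels.formula.api as smf

    data, _ = crossed_dataset(n=40, k=3, seed=6, missing=0.1)
    est = estimate_protein_abundance(data)["P1"]
    stacked = data.abundance.stack().rename("y").reset_index()
    stacked.columns = ["part", "pep", "y"]
    stacked["g"] = 1
    model = smf.mixedlm(
        "y ~ 1", stacked, groups="g",
        vc_formula={"part": "0 + C(part)", "pep": "0 + C(pep)"},
    ).fit()
    re = model.random_effects[1]
    import re as _re

    part_re = pd.Series(
        {_re.search(r"\[(S\d+)\]\]$", n).group(1): v for n, v in re.items() if n.startswith("part")}
    )
    ours = est - est.mean()
    theirs = part_re.reindex(ours.index).fillna(0.0)
    assert np.corrcoef(ours.to_numpy(), theirs.to_numpy())[0, 1] > 0.99


def test_gower_equals_direct_double_loop():
    rng = np.random.default_rng(7)
    profiles = rng.standard_normal((6, 15))
    condensed = gower_distances(profiles)
    mat = squareform(condensed)
    ranges = profiles.max(axis=0) - profiles.min(axis=0)
    for i in range(6):
        for j in range(6):
            direct = np.mean(np.abs(profiles[i] - profiles[j]) / ranges)
            assert mat[i, j] == pytest.approx(direct, abs=1e-12)


def test_duplicate_columns_merge_first():
    rng = np.random.default_rng(8)
    base = rng.standard_normal((100, 4))
    matrix = pd.DataFrame(
        np.column_stack([base, base[:, 0]]), columns=["A", "B", "C", "D", "A2"]
    )
    assignment = cluster_proteins(matrix)
    Z = assignment.linkage_matrix
    first = {int(Z[0, 0]), int(Z[0, 1])}
    assert first == {0, 4}  # the identical pair merges at height ~0
    assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)


def test_clustering_invariant_to_order_and_affine_rescale():
    rng = np.random.default_rng(9)
    f1, f2 = rng.standard_normal((2, 200))
    cols = {}
    for j in range(4):
        cols[f"A{j}"] = f1 + 0.4 * rng.standard_normal(200)
    for j in range(4):
        cols[f"B{j}"] = f2 + 0.4 * rng.standard_normal(200)
    matrix = pd.DataFrame(cols)
    base = cluster_proteins(matrix)
    scrambled = matrix[list(matrix.columns[::-1])].copy()
    scrambled["A1"] = scrambled["A1"] * 7.0 - 3.0
    again = cluster_proteins(scrambled)
    assert base.k == again.k
    from sklearn.metrics import adjusted_rand_score

    joined = pd.concat([base.labels.rename("a"), again.labels.rename("b")], axis=1)
    assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0


def test_unstructured_proteins_stay_in_few_clusters():
    rng = np.random.default_rng(10)
    matrix = pd.DataFrame(rng.standard_normal((300, 12)),
                          columns=[f"P{i}" for i in range(12)])
    assignment = cluster_proteins(matrix)
    assert assignment.k <= 3


def test_constant_column_removed_with_warning():
    rng = np.random.default_rng(11)
    matrix = pd.DataFrame(rng.standard_normal((50, 5)), columns=list("ABCDE"))
    matrix["E"] = 1.0
    with pytest.warns(UserWarning):
        assignment = cluster_proteins(matrix)
    assert "E" not in assignment.labels.index


def test_abundance_score_properties():
    rng = np.random.default_rng(12)
    matrix = pd.DataFrame(
        rng.standard_normal((150, 4)) * [1.0, 2.0, 0.5, 3.0], columns=list("ABCD")
    )
    score = abundance_score(matrix, ["A"])
    zA = (matrix["A"] - matrix["A"].mean()) / matrix["A"].std(ddof=1)
    np.testing.assert_allclose(score.to_numpy(), zA.to_numpy(), atol=1e-12)

    full = abundance_score(matrix, list("ABCD"))
    assert full.mean() == pytest.approx(0.0, abs=1e-12)
    assert full.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    matrix["A_dup"] = matrix["A"] * 4.0 + 1.0  # perfectly correlated twin
    one = abundance_score(matrix, ["A"])
    two = abundance_score(matrix, ["A", "A_dup"])
    assert (one.rank() == two.rank()).all()

    with pytest.raises(ValueError):
        abundance_score(matrix, [])


def test_health_correlations_ranks_and_missing(demo_study):
    rng = np.random.default_rng(13)
    participants = demo_study.participants.copy()
    score = pd.Series(rng.standard_normal(len(participants)), index=participants.index)
    table = health_correlations(score, participants).set_index("index")
    assert (table["spearman_r"].abs() < 0.2).all()

    transformed = np.exp(score)  # monotone transform: identical Spearman
    again = health_correlations(transformed, participants).set_index("index")
    np.testing.assert_allclose(
        table["spearman_r"].to_numpy(), again["spearman_r"].to_numpy(), atol=1e-12
    )

    participants["frailty_index"] = 1.0
    broken = health_correlations(score, participants).set_index("index")
    assert np.isnan(broken.loc["frailty_index", "spearman_r"])
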