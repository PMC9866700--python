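"""Morphometric generator, group statistics, subset selection and LDA."""

import numpy as np
import pandas as pd
import pytest

from chemopheno import morpho as M


def test_default_table_shape(morpho_table):
    assert len(morpho_table) == 75
    assert morpho_table["species"].value_counts().eq(15).all()
    assert list(morpho_table.columns) == ["species"] + M.CHARACTERS
    for c in M.COUNT_CHARACTERS:
        assert (morpho_table[c] >= 1).all()
        assert (morpho_table[c] == morpho_table[c].astype(int)).all()


def test_zero_sd_reproduces_means():
    prof = M.default_profiles()[0]
    frozen = M.SpeciesProfile(prof.species, prof.mean, np.zeros(12), prof.correlation)
    table = M.generate_morphometrics([frozen], n_per_species=4, seed=1, discretize=False)
    np.testing.assert_allclose(table[M.CHARACTERS].to_numpy(), np.tile(prof.mean, (4, 1)))


def test_large_sample_recovers_profile_correlations():
    """Law-of-large-numbers check on the continuous draws."""
    table = M.generate_morphometrics(n_per_species=5000, seed=3, discretize=False)
    one = table[table["species"] == "S_ovatus"]
    corr, _p, _s = M.correlation_matrix(one)
    np.testing.assert_allclose(corr.to_numpy(), M.default_correlation(), atol=0.05)


def test_descriptive_stats_and_cv_regimes():
    # population CVs resolve cleanly at larger n: X12 noisy, the rest tight
    table = M.generate_morphometrics(n_per_species=200, seed=5)
    stats = M.descriptive_stats(table)
    piv = stats.pivot(index="character", columns="species", values="cv_percent")
    assert (piv.loc["X12"] > 40).all()
    assert (piv.drop("X12").median() < 20).all()
    # closed-form check on a toy column
    toy = pd.DataFrame({"species": ["s"] * 3, **{c: [1.0, 2.0, 3.0] for c in M.CHARACTERS}})
    row = M.descriptive_stats(toy).iloc[0]
    assert row["mean"] == pytest.approx(2.0)
    assert row["sd"] == pytest.approx(1.0)
    assert row["cv_percent"] == pytest.approx(50.0)


def test_correlation_signs_follow_design(morpho_table):
    corr, _p, _sig = M.correlation_matrix(morpho_table)
    assert (np.diag(corr) == 1).all()
    assert corr.loc["X6", "X8"] > 0
    assert corr.loc["X8", "X10"] > 0
    assert corr.loc["X2", "X8"] < 0
    assert corr.loc["X2", "X6"] < 0


def test_group_tests_identical_groups():
    """No separation: Wilks' lambda = 1 and Kruskal-Wallis H = 0."""
    rng = np.random.default_rng(7)
    # block must have more rows than characters so the pooled within-group
    # scatter stays full rank when the block is replicated across groups
    block = pd.DataFrame(rng.normal(10, 1, size=(20, 12)), columns=M.CHARACTERS)
    table = pd.concat(
        [block.assign(species=s) for s in ("g1", "g2", "g3")], ignore_index=True
    )
    res = M.group_tests(table)
    assert res.manova["wilks_lambda"] == pytest.approx(1.0, abs=1e-9)
    assert (res.per_character["H"].abs() < 1e-9).all()
    assert ((res.per_character["wilks_lambda"] - 1.0).abs() < 1e-9).all()


def test_wilks_matches_statsmodels(morpho_table):
    """Independent oracle for the hand-computed MANOVA statistic."""
    from statsmodels.multivariate.manova import MANOVA

    mv = MANOVA.from_formula(
        " + ".join(M.CHARACTERS) + " ~ species", data=morpho_table
    )
    sm_res = mv.mv_test().results["species"]["stat"]
    lam = float(sm_res.loc["Wilks' lambda", "Value"])
    ours = M.group_tests(morpho_table).manova["wilks_lambda"]
    assert ours == pytest.approx(lam, rel=1e-6)


def test_two_group_kruskal_reduces_to_rank_sum():
    from scipy import stats as sps

    rng = np.random.default_rng(2)
    a = rng.normal(0, 1, 12)
    b = rng.normal(0.5, 1, 12)
    H, p_kw = sps.kruskal(a, b)
    p_mw = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                            use_continuity=False).pvalue
    assert p_kw == pytest.approx(p_mw, rel=1e-6)


def test_posthoc_bonferroni_separates_planted_groups():
    rng = np.random.default_rng(4)
    frames = []
    for i, s in enumerate(["a", "b", "c"]):
        X = rng.normal(10 + 5 * i, 0.5, size=(12, 12))
        frames.append(pd.DataFrame(X, columns=M.CHARACTERS).assign(species=s))
    res = M.group_tests(pd.concat(frames, ignore_index=True))
    for c in M.CHARACTERS:
        mat = res.posthoc[c]
        off = mat.where(~np.eye(3, dtype=bool)).stack()
        assert (off < 0.05).all()


def test_best_subset_structure(morpho_table):
    res = M.best_subset(morpho_table)
    assert len(res.table) == 2**12 - 1
    # full model has minimal RSS and Cp = p + 1
    full = res.table[res.table["size"] == 12].iloc[0]
    assert full["rss"] == res.table["rss"].min()
    assert full["cp"] == pytest.approx(13.0)
    # best-RSS subsets are nested-monotone in size
    best_rss = [
        res.table[res.table["size"] == k]["rss"].min() for k in range(1, 13)
    ]
    assert all(a >= b - 1e-9 for a, b in zip(best_rss, best_rss[1:]))
    assert 1 <= len(res.chosen) <= 12


def test_best_subset_finds_planted_predictor():
    rng = np.random.default_rng(9)
    n = 40
    X = pd.DataFrame(rng.normal(size=(n, 12)), columns=M.CHARACTERS)
    labels = np.repeat(["u", "v"], n // 2)
    X["X5"] = np.where(labels == "u", 0.0, 8.0) + rng.normal(0, 0.3, n)
    table = X.assign(species=labels)
    res = M.best_subset(table)
    for size, best in res.best_per_size["rss"].items():
        assert "X5" in best
    assert "X5" in res.chosen


def test_lda_two_class_midpoint_boundary():
    rng = np.random.default_rng(1)
    a = rng.normal(0.0, 1.0, 200)
    b = rng.normal(6.0, 1.0, 200)
    table = pd.DataFrame({
        "species": ["a"] * 200 + ["b"] * 200,
        "X1": np.concatenate([a, b]),
    })
    model = M.lda_fit(table, ["X1"])
    mid = float(model.class_means.values.mean())
    eps = 0.05
    below = pd.DataFrame({"X1": [mid - eps]})
    above = pd.DataFrame({"X1": [mid + eps]})
    assert M.lda_predict(model, below) == ["a"]
    assert M.lda_predict(model, above) == ["b"]


def test_lda_direction_count_and_confusion(morpho_table):
    model = M.lda_fit(morpho_table)
    assert model.n_components == 4  # 5 classes -> at most 4 directions
    pred = M.lda_predict(model, morpho_table)
    cm = M.confusion_matrix(morpho_table["species"], pred, model.classes)
    assert (cm.sum(axis=1) == 15).all()
    # scalings are orthonormal in the within-class metric
    G = model.scalings.T @ model.pooled_cov @ model.scalings
    np.testing.assert_allclose(G, np.eye(model.n_components), atol=1e-8)


def test_lda_affine_invariance(morpho_table):
    model = M.lda_fit(morpho_table)
    pred = M.lda_predict(model, morpho_table)
    scores = M.lda_project(model, morpho_table).to_numpy()

    scaled = morpho_table.copy()
    scaled["X2"] = scaled["X2"] * 37.0 + 5.0
    scaled["X7"] = scaled["X7"] * 0.01
    model2 = M.lda_fit(scaled, model.variables)
    assert M.lda_predict(model2, scaled) == pred
    scores2 = M.lda_project(model2, scaled).to_numpy()
    for m in range(scores.shape[1]):
        sign = np.sign(scores[:, m] @ scores2[:, m])
        np.testing.assert_allclose(scores2[:, m] * sign, scores[:, m], atol=1e-6)


def test_lda_singular_covariance_names_collinear_variables(morpho_table):
    table = morpho_table.copy()
    table["X3"] = 2.0 * table["X2"]
    with pytest.raises(np.linalg.LinAlgError, match="X2|X3"):
        M.lda_fit(table)


def test_lda_class_mean_recovery_at_large_n():
    """Estimated class means converge to the profile means (<2%)."""
    table = M.generate_morphometrics(n_per_species=2000, seed=8, discretize=False)
    model = M.lda_fit(table)
    for prof in M.default_profiles():
        est = model.class_means.loc[prof.species].to_numpy()
        rel = np.abs(est - prof.mean) / prof.mean
        assert rel.max() < 0.02


def test_split_evaluation_accuracy(morpho_table):
    accs = M.evaluate_splits(morpho_table, M.CHARACTERS, n_splits=20, seed=1)
    assert len(accs) == 20
    assert np.median(accs) >= 13 / 15
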