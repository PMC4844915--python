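"""Embedding, Wald-Wolfowitz dissimilarity, k-NN and comparison stats."""
import numpy as np
import pytest

import dynpac as dp
from dynpac.group import (SubjectFeatures, TrajectoryKNN, cross_validate,
                          knn_classify)


# ------------------------------------------------------------ embedding

def test_delay_embed_shapes():
    x = np.arange(10.0)
    assert np.array_equal(dp.delay_embed(x, 1, 1), x[:, None])
    pts = dp.delay_embed(x, 3, 2)
    assert pts.shape == (6, 3)
    assert np.array_equal(pts[0], [0, 2, 4])
    with pytest.raises(ValueError):
        dp.delay_embed(x, 6, 2)


def test_delay_embed_sine_traces_circle():
    t = np.arange(400)
    x = np.sin(2 * np.pi * t / 40)
    pts = dp.delay_embed(x, 2, 10)          # quarter-period delay
    radii = np.linalg.norm(pts, axis=1)
    assert radii.std() / radii.mean() < 0.05


# ----------------------------------------------------- WW dissimilarity

def test_ww_separated_clouds(rng):
    a = rng.standard_normal((30, 2))
    b = rng.standard_normal((30, 2)) + 20.0
    res = dp.ww_dissimilarity(a, b)
    assert res.runs == 2                    # single cross edge
    assert res.w > 5.0


def test_ww_null_is_standardized(rng):
    ws = []
    for _ in range(200):
        pooled = rng.standard_normal((40, 3))
        ws.append(dp.ww_dissimilarity(pooled[:20], pooled[20:]).w)
    assert abs(np.mean(ws)) < 0.25
    assert 0.7 < np.std(ws) < 1.3


def test_ww_runs_match_networkx_mst(rng):
    """Oracle: cross-edge count on an independently built MST."""
    import networkx as nx
    pts = rng.standard_normal((9, 2))
    labels = np.r_[np.zeros(5, int), np.ones(4, int)]
    res = dp.ww_dissimilarity(pts[:5], pts[5:])
    G = nx.Graph()
    for i in range(9):
        for j in range(i + 1, 9):
            G.add_edge(i, j, weight=float(np.linalg.norm(pts[i] - pts[j])))
    T = nx.minimum_spanning_tree(G)
    cross = sum(labels[u] != labels[v] for u, v in T.edges)
    assert res.runs == cross + 1


def test_ww_friedman_rafsky_moments(rng):
    """E[R] under label permutation matches 2mn/N + 1."""
    pts = rng.standard_normal((24, 2))
    runs = []
    for _ in range(300):
        idx = rng.permutation(24)
        runs.append(dp.ww_dissimilarity(pts[idx[:12]], pts[idx[12:]]).runs)
    assert np.mean(runs) == pytest.approx(2 * 12 * 12 / 24 + 1, rel=0.06)


def test_ww_input_validation(rng):
    with pytest.raises(ValueError):
        dp.ww_dissimilarity(np.zeros((0, 2)), rng.standard_normal((3, 2)))
    with pytest.raises(ValueError):
        dp.ww_dissimilarity(rng.standard_normal((3, 2)),
                            rng.standard_normal((3, 3)))
    # duplicate points are resolved by the documented jitter, not an error
    a = np.zeros((4, 2))
    b = np.ones((4, 2))
    assert dp.ww_dissimilarity(a, b).runs >= 2


# ----------------------------------------------------------------- k-NN

def test_knn_memorizes_training_point(rng):
    X = rng.standard_normal((10, 3))
    y = np.array(["a"] * 5 + ["b"] * 5)
    assert knn_classify(X, y, X[7], k=1) == "b"


def test_knn_separated_clusters(rng):
    X = np.vstack([rng.standard_normal((8, 2)),
                   rng.standard_normal((8, 2)) + 15.0])
    y = np.array([0] * 8 + [1] * 8)
    clf = TrajectoryKNN(k=5).fit(X, y)
    assert clf.score(X + 0.1, y) == 1.0
    with pytest.raises(ValueError):
        TrajectoryKNN(k=20).fit(X, y)


def test_knn_tie_breaks_toward_nearer_class():
    X = np.array([[0.0], [0.2], [10.0], [10.2]])
    y = np.array(["near", "near", "far", "far"])
    # k=4: two votes each; the summed distance favours "near"
    assert knn_classify(X, y, np.array([1.0]), k=4) == "near"


def test_knn_is_sklearn_compatible(rng):
    from sklearn.base import clone
    clf = TrajectoryKNN(k=3, metric="euclidean")
    params = clf.get_params()
    assert params["k"] == 3
    clone(clf)  # must not raise
    X = rng.standard_normal((8, 40))
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    clf.fit(X, y).predict(X[:2])


def test_ww_trajectory_metric_scale_invariant(rng):
    base = np.cumsum(rng.standard_normal((10, 60)), axis=1)
    y = np.array([0] * 5 + [1] * 5)
    y_groups = base.copy()
    y_groups[5:] += 30.0
    clf = TrajectoryKNN(k=3, metric="ww_trajectory", embed_m=2, embed_tau=1)
    p1 = clf.fit(y_groups, y).predict(y_groups)
    p2 = clf.fit(y_groups * 7.3, y).predict(y_groups * 7.3)
    assert np.array_equal(p1, p2)


# -------------------------------------------------------- cross-validate

def _feature_sets(rng, separated=True):
    feats = []
    labels = []
    for g, mu in enumerate([0.0, 8.0 if separated else 0.0]):
        for _ in range(6):
            v = rng.standard_normal(12) + mu
            series = np.cumsum(rng.standard_normal(60)) + mu * 10
            feats.append(SubjectFeatures(series, series, v, v / 10,
                                         label=str(g)))
            labels.append(str(g))
    return feats, np.array(labels)


def test_cross_validate_chance_level_when_identical(rng):
    feats, labels = _feature_sets(rng, separated=False)
    acc, _ = cross_validate(feats, labels, feature="tr", scheme="loo", k=3)
    assert acc <= 0.8    # no skill beyond chance fluctuation


def test_cross_validate_perfect_separation_all_schemes(rng):
    feats, labels = _feature_sets(rng, separated=True)
    halves = [(f, f) for f in feats]    # stationary halves
    for scheme in ("loo", "twofold", "split_loo", "split_twofold"):
        acc, _ = cross_validate(feats, labels, feature="tr", scheme=scheme,
                                k=3, repetitions=10, seed=1,
                                half_features=halves)
        assert acc >= 0.95, scheme


def test_cross_validate_validation_errors(rng):
    feats, labels = _feature_sets(rng)
    with pytest.raises(ValueError):
        cross_validate(feats[:3], labels[:3].repeat(1), feature="tr")
    with pytest.raises(ValueError):
        cross_validate(feats, labels, scheme="split_loo")   # needs halves


# ------------------------------------------------------------ statistics

def test_ranksum_identical_and_extreme():
    stat, p = dp.ranksum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == pytest.approx(1.0)
    stat, p = dp.ranksum_test([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
    assert p == pytest.approx(0.1)          # exact over the 20 arrangements
    assert stat == pytest.approx(6.0)       # minimal rank sum 1+2+3


def test_ranksum_power(rng):
    rejections = sum(
        dp.ranksum_test(rng.standard_normal(100) + 2,
                        rng.standard_normal(100))[1] < 1e-3
        for _ in range(20))
    assert rejections == 20


def test_partial_correlation_reduces_to_pearson(rng):
    from scipy.stats import pearsonr
    x, y = rng.standard_normal((2, 80))
    r, p = dp.partial_correlation(x, y)
    rr, pp = pearsonr(x, y)
    assert r == pytest.approx(rr) and p == pytest.approx(pp)


def test_partial_correlation_removes_shared_covariate(rng):
    age = rng.uniform(7, 14, 500)
    x = age + 0.3 * rng.standard_normal(500)
    y = 2 * age + 0.3 * rng.standard_normal(500)
    raw, _ = dp.partial_correlation(x, y)
    part, _ = dp.partial_correlation(x, y, covariates=age)
    assert raw > 0.9
    assert abs(part) < 0.1
    same, _ = dp.partial_correlation(x, age, covariates=age)
    assert abs(same) < 0.1


def test_partial_correlation_matches_pingouin(rng):
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd
    x = rng.standard_normal(60)
    z = rng.standard_normal(60)
    y = 0.5 * x + 0.8 * z + 0.3 * rng.standard_normal(60)
    r, p = dp.partial_correlation(x, y, covariates=z)
    ref = pingouin.partial_corr(
        pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z")
    assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
    assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)


def test_partial_correlation_validation():
    with pytest.raises(ValueError):
        dp.partial_correlation(np.ones(10), np.arange(10.0))
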