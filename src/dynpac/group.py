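"""Group-level analysis: trajectory dissimilarity, k-NN classification
under four validation schemes, and the comparison statistics.

Scalar index series (dIER, wdIER) are compared as dynamic trajectories:
each series is time-delay embedded and two embedded clouds are scored
with the Wald-Wolfowitz / Friedman-Rafsky dissimilarity -- the
standardized deficit of label runs on the Euclidean minimum spanning
tree of the pooled points.  TR matrices and PD vectors are compared with
plain Euclidean distance.  The classifier is a k-nearest-neighbour vote
packaged as a scikit-learn estimator.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin

from .dynamics import TVPACResult, dier_series, wdier_series, pd_pac, tr_matrix

__all__ = [
    "delay_embed", "DissimilarityResult", "ww_dissimilarity",
    "TrajectoryKNN", "knn_classify", "SubjectFeatures", "extract_features",
    "cross_validate", "ranksum_test", "partial_correlation",
]


def delay_embed(series: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Time-delay embedding: point i = (x_i, x_{i+tau}, ..., x_{i+(m-1)tau}).

    Returns an array of shape (L - (m-1)*tau, m).
    """
    x = np.asarray(series, float)
    if m < 1 or tau < 1:
        raise ValueError("m and tau must be >= 1")
    npts = x.size - (m - 1) * tau
    if npts <= m:
        raise ValueError("series too short for this embedding")
    if m == 1:
        return x[:, None].copy()
    return np.lib.stride_tricks.sliding_window_view(
        x, (m - 1) * tau + 1)[:, ::tau][:npts].copy()


@dataclass
class DissimilarityResult:
    w: float          # standardized dissimilarity (larger = more dissimilar)
    runs: int         # observed label runs R on the pooled MST
    n_a: int
    n_b: int


def _mst_edges(points: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    d = cdist(points, points)
    # duplicate points make the MST ambiguous; documented epsilon jitter
    iu = np.triu_indices(len(points), k=1)
    if np.any(d[iu] == 0):
        scale = points.std() or 1.0
        points = points + rng.normal(0, 1e-9 * scale, points.shape)
        d = cdist(points, points)
    mst = minimum_spanning_tree(d).tocoo()
    return np.column_stack([mst.row, mst.col])


def ww_dissimilarity(cloud_a: np.ndarray, cloud_b: np.ndarray,
                     seed: int = 0) -> DissimilarityResult:
    """Friedman-Rafsky multivariate Wald-Wolfowitz dissimilarity.

    Builds the Euclidean MST on the pooled points; R = cross-sample edges
    + 1 (the number of label-pure subtrees after deleting cross edges).
    w = -(R - E[R]) / sqrt(Var[R]) with the Friedman-Rafsky null moments,
    so well-separated samples give large positive w.
    """
    A = np.atleast_2d(np.asarray(cloud_a, float))
    B = np.atleast_2d(np.asarray(cloud_b, float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("clouds must share dimensionality")
    m, n = len(A), len(B)
    if m == 0 or n == 0:
        raise ValueError("clouds must be non-empty")
    N = m + n
    pooled = np.vstack([A, B])
    labels = np.r_[np.zeros(m, int), np.ones(n, int)]
    edges = _mst_edges(pooled, np.random.default_rng(seed))
    cross = int((labels[edges[:, 0]] != labels[edges[:, 1]]).sum())
    R = cross + 1
    deg = np.bincount(edges.ravel(), minlength=N)
    C = float((deg * (deg - 1)).sum()) / 2.0
    ER = 2.0 * m * n / N + 1.0
    var = (2.0 * m * n / (N * (N - 1.0))) * (
        (2.0 * m * n - N) / N
        + (C - N + 2.0) / ((N - 2.0) * (N - 3.0))
        * (N * (N - 1.0) - 4.0 * m * n + 2.0)
    )
    w = -(R - ER) / np.sqrt(var) if var > 0 else 0.0
    return DissimilarityResult(float(w), R, m, n)


class TrajectoryKNN(BaseEstimator, ClassifierMixin):
    """k-nearest-neighbour classifier over feature vectors or trajectories.

    Parameters
    ----------
    k : odd neighbour count (the robust range in this setting is 7-11).
    metric : "euclidean" for plain feature vectors, or "ww_trajectory" to
        treat each row as a scalar time series, delay-embed it and use the
        Wald-Wolfowitz dissimilarity (floored at zero) as the distance.
    embed_m, embed_tau : embedding parameters for the trajectory metric.
    """

    def __init__(self, k: int = 9, metric: str = "euclidean",
                 embed_m: int = 3, embed_tau: int = 1, seed: int = 0):
        self.k = k
        self.metric = metric
        self.embed_m = embed_m
        self.embed_tau = embed_tau
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        if self.k > len(X):
            raise ValueError("k exceeds the training-set size")
        if self.metric not in ("euclidean", "ww_trajectory"):
            raise ValueError("unknown metric")
        self.X_ = X
        self.y_ = y
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        return self

    def _dist_row(self, x) -> np.ndarray:
        if self.metric == "euclidean":
            return np.linalg.norm(self.X_ - x[None, :], axis=1)
        ex = delay_embed(x, self.embed_m, self.embed_tau)
        out = np.empty(len(self.X_))
        for i, row in enumerate(self.X_):
            er = delay_embed(row, self.embed_m, self.embed_tau)
            out[i] = max(ww_dissimilarity(ex, er, seed=self.seed).w, 0.0)
        return out

    def predict(self, X):
        X = np.asarray(X, float)
        out = []
        for x in X:
            d = self._dist_row(x)
            nn = np.argsort(d, kind="stable")[:self.k]
            votes = {}
            for idx in nn:
                lab = self.y_[idx]
                cnt, s = votes.get(lab, (0, 0.0))
                votes[lab] = (cnt + 1, s + d[idx])
            # majority vote; ties toward the smaller summed distance
            out.append(max(votes.items(), key=lambda kv: (kv[1][0], -kv[1][1]))[0])
        return np.array(out)

    def score(self, X, y):
        return float((self.predict(X) == np.asarray(y)).mean())


def knn_classify(train_X, train_y, test_x, k: int = 9,
                 distance: str = "euclidean"):
    """Label of a single test feature under k-NN majority vote."""
    clf = TrajectoryKNN(k=k, metric=distance).fit(train_X, train_y)
    return clf.predict(np.atleast_2d(test_x))[0]


@dataclass
class SubjectFeatures:
    """Feature vectors derived from one subject's prominent-mode series."""

    dier: np.ndarray
    wdier: np.ndarray
    tr: np.ndarray
    pd: np.ndarray
    label: str | None = None


def extract_features(result: TVPACResult, label: str | None = None,
                     half: int | None = None) -> SubjectFeatures:
    """dIER/wdIER series, flattened TR matrix and PD vector for a subject.

    ``half`` of 0 or 1 recomputes everything on the corresponding half of
    the window series (for the split-reliability validation schemes).
    """
    if half is not None:
        nw = result.n_windows
        sl = slice(0, nw // 2) if half == 0 else slice(nw // 2, nw)
        result = TVPACResult(
            {p: s[sl] for p, s in result.modes.items()},
            result.window_times[sl], result.windowing, result.grid,
            result.rate_hz)
    tr = np.array([v for v in tr_matrix(result).values()])
    pd_vec = pd_pac(result).vector
    return SubjectFeatures(dier_series(result), wdier_series(result),
                           tr, pd_vec, label)


_FEATURE_METRIC = {"dier": "ww_trajectory", "wdier": "ww_trajectory",
                   "tr": "euclidean", "pd": "euclidean"}


def _feature_matrix(feats: list[SubjectFeatures], feature: str) -> np.ndarray:
    return np.vstack([np.asarray(getattr(f, feature), float) for f in feats])


def cross_validate(features, labels, feature: str = "tr",
                   scheme: str = "loo", k: int = 9, repetitions: int = 200,
                   seed: int = 0,
                   half_features=None) -> tuple[float, float]:
    """Classification accuracy under one of four validation schemes.

    ``features`` is a list of SubjectFeatures (or a 2-D matrix); for the
    split schemes ``half_features`` supplies the per-subject (half A,
    half B) feature pairs.  Returns (mean accuracy, dispersion over
    repetitions); leave-one-out schemes are deterministic and return
    dispersion 0.
    """
    y = np.asarray(labels)
    metric = _FEATURE_METRIC.get(feature, "euclidean")
    if isinstance(features, np.ndarray):
        X = features
    else:
        X = _feature_matrix(features, feature)
    n = len(y)
    classes, inverse = np.unique(y, return_inverse=True)
    if len(classes) < 2 or min(np.bincount(inverse)) < 2:
        raise ValueError("need at least 2 subjects per class")
    rng = np.random.default_rng(seed)

    def stratified_half(labels_idx, size):
        chosen = []
        for c in range(len(classes)):
            members = np.nonzero(labels_idx == c)[0]
            members = rng.permutation(members)
            chosen.append(members[:max(len(members) // 2, 1)])
        return np.concatenate(chosen)

    def acc_split(train_idx, test_idx, XX, yy):
        if len(np.unique(yy[train_idx])) < 2:
            return None
        clf = TrajectoryKNN(k=min(k, len(train_idx)), metric=metric)
        clf.fit(XX[train_idx], yy[train_idx])
        return clf.score(XX[test_idx], yy[test_idx])

    if scheme == "loo":
        correct = [acc_split(np.delete(np.arange(n), i), [i], X, y)
                   for i in range(n)]
        return float(np.mean([c for c in correct if c is not None])), 0.0

    if scheme == "twofold":
        accs = []
        for _ in range(repetitions):
            tr_idx = stratified_half(inverse, n // 2)
            te_idx = np.setdiff1d(np.arange(n), tr_idx)
            a = acc_split(tr_idx, te_idx, X, y)
            if a is not None:
                accs.append(a)
        return float(np.mean(accs)), float(np.std(accs))

    # split-half schemes: items are the 2n half-series features
    if half_features is None:
        raise ValueError("split schemes need half_features")
    Xh = np.vstack([
        np.vstack([np.asarray(getattr(h, feature), float) for h in pair])
        for pair in half_features])
    yh = np.repeat(y, 2)
    subj = np.repeat(np.arange(n), 2)

    if scheme == "split_loo":
        correct = []
        for i in range(n):
            tr_idx = np.nonzero(subj != i)[0]
            te_idx = np.nonzero(subj == i)[0]
            a = acc_split(tr_idx, te_idx, Xh, yh)
            if a is not None:
                correct.append(a)
        return float(np.mean(correct)), 0.0

    if scheme == "split_twofold":
        accs = []
        _, inv_h = np.unique(yh, return_inverse=True)
        for _ in range(repetitions):
            tr_idx = stratified_half(inv_h, n)
            te_idx = np.setdiff1d(np.arange(2 * n), tr_idx)
            a = acc_split(tr_idx, te_idx, Xh, yh)
            if a is not None:
                accs.append(a)
        return float(np.mean(accs)), float(np.std(accs))

    raise ValueError(f"unknown scheme {scheme!r}")


def ranksum_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact for small tie-free samples, otherwise the normal approximation
    with tie correction.  Returns (rank-sum statistic of sample A, p).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    res = spstats.mannwhitneyu(a, b, alternative="two-sided",
                               use_continuity=False)
    W = float(res.statistic + a.size * (a.size + 1) / 2.0)
    return W, float(res.pvalue)


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing out covariates.

    Residuals are taken against an intercept plus the covariate columns;
    the p-value uses a t reference with n - 2 - n_covariates degrees of
    freedom.  With no covariates this reduces to the plain Pearson r.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    if covariates is None:
        r, p = spstats.pearsonr(x, y)
        return float(r), float(p)
    Z = np.atleast_2d(np.asarray(covariates, float))
    if Z.shape[0] != x.size:
        Z = Z.T
    c = Z.shape[1]
    n = x.size
    if n <= c + 2:
        raise ValueError("need n > n_covariates + 2")
    design = np.column_stack([np.ones(n), Z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - c
    r = np.clip(r, -0.9999999, 0.9999999)
    t = r * np.sqrt(df / (1 - r * r))
    p = 2 * spstats.t.sf(abs(t), df)
    return float(r), float(p)
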