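"""Ecopopulation analysis: LDA assignment accuracy, k-means clustering,
and gap-statistic selection of cluster number.

An "ecopopulation" is a set of occurrence points grouped purely by
environment; comparing environmental clusters with taxonomy asks whether
described taxa are ecologically distinct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.utils.validation import check_array, check_is_fitted


@dataclass
class ConfusionMatrix:
    """Row-percent confusion of true taxon (rows) vs predicted (columns)."""

    labels: list[str]
    percent: np.ndarray  # (g, g), each row sums to 100

    def accuracy(self, label: str) -> float:
        i = self.labels.index(label)
        return float(self.percent[i, i])


@dataclass
class GapStatResult:
    k_values: np.ndarray
    gap: np.ndarray
    se: np.ndarray
    k_best: int
    log_wk: np.ndarray


def lda_confusion(values: np.ndarray, labels: list[str],
                  uniform_priors: bool = False,
                  shrinkage: float | str | None = None) -> ConfusionMatrix:
    """Resubstitution LDA confusion matrix in row percentages.

    The discriminant is fit on all labeled rows and the same rows are
    predicted back (matching how assignment accuracy is usually reported
    for ecopopulation analyses); priors default to group proportions.
    Groups smaller than the dimension trigger covariance shrinkage
    (``shrinkage='auto'``) automatically.
    """
    X = check_array(np.asarray(values, dtype=float))
    y = np.asarray(labels)
    groups = list(dict.fromkeys(labels))  # first-seen order
    counts = {g: int((y == g).sum()) for g in groups}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if min(counts.values()) < 2:
        raise ValueError("every group needs at least 2 rows")
    solver = "svd"
    if shrinkage is None and min(counts.values()) <= X.shape[1]:
        shrinkage = "auto"
    if shrinkage is not None:
        solver = "lsqr"
    priors = None
    if uniform_priors:
        priors = np.full(len(groups), 1.0 / len(groups))
    lda = LinearDiscriminantAnalysis(solver=solver, shrinkage=shrinkage,
                                     priors=priors)
    lda.fit(X, y)
    pred = lda.predict(X)
    g = len(groups)
    mat = np.zeros((g, g))
    gi = {name: i for i, name in enumerate(groups)}
    for t, p in zip(y, pred):
        mat[gi[t], gi[p]] += 1
    percent = 100.0 * mat / mat.sum(axis=1, keepdims=True)
    return ConfusionMatrix(groups, percent)


def kmeans_assign(values: np.ndarray, k: int, seed: int = 0,
                  n_init: int = 25) -> tuple[np.ndarray, float]:
    """Seeded k-means; returns (cluster ids, within-cluster SS W_k)."""
    X = check_array(np.asarray(values, dtype=float))
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds n={X.shape[0]}")
    if k == 1:
        center = X.mean(axis=0)
        w = float(((X - center) ** 2).sum())
        return np.zeros(X.shape[0], dtype=int), w
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    ids = km.fit_predict(X)
    return ids, float(km.inertia_)


class GapStatisticSelector(BaseEstimator):
    """Select the number of k-means clusters by the gap statistic.

    For each k in 1..k_max, Gap(k) = E*[log W_k] - log W_k, where the
    expectation is over B reference data sets drawn uniformly over each
    feature's observed range, and W_k is the within-cluster sum of
    squares. The selected k is the smallest k with
    Gap(k) >= Gap(k+1) - se(k+1), with se(k) = sd_b(log W_k^(b)) *
    sqrt(1 + 1/B) (the one-standard-error rule).

    Parameters
    ----------
    k_max : int, default=10
        Largest cluster count considered.
    n_refs : int, default=100
        Number of uniform reference data sets B.
    n_init : int, default=25
        k-means restarts per fit.
    random_state : int, default=0
        Seed for the reference draws and every k-means fit.

    Attributes
    ----------
    k_best_ : int
        Selected number of clusters.
    result_ : GapStatResult
        Per-k gap values, standard errors and log W_k.
    labels_ : ndarray
        k-means assignment of the training rows at ``k_best_``.
    """

    def __init__(self, k_max: int = 10, n_refs: int = 100, n_init: int = 25,
                 random_state: int = 0):
        self.k_max = k_max
        self.n_refs = n_refs
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(np.asarray(X, dtype=float))
        n = X.shape[0]
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if n <= self.k_max:
            raise ValueError("need more rows than k_max")
        if np.allclose(X, X[0]):
            raise ValueError("degenerate data: all rows identical")
        rng = np.random.default_rng(self.random_state)
        ks = np.arange(1, self.k_max + 1)
        log_wk = np.empty(len(ks))
        for i, k in enumerate(ks):
            _, w = kmeans_assign(X, int(k), seed=int(rng.integers(2**31)),
                                 n_init=self.n_init)
            log_wk[i] = np.log(max(w, 1e-300))
        lo, hi = X.min(axis=0), X.max(axis=0)
        log_wk_ref = np.empty((self.n_refs, len(ks)))
        for b in range(self.n_refs):
            ref = rng.uniform(lo, hi, size=X.shape)
            for i, k in enumerate(ks):
                _, w = kmeans_assign(ref, int(k), seed=int(rng.integers(2**31)),
                                     n_init=self.n_init)
                log_wk_ref[b, i] = np.log(max(w, 1e-300))
        gap = log_wk_ref.mean(axis=0) - log_wk
        se = log_wk_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / self.n_refs)
        k_best = int(ks[-1])
        for i in range(len(ks) - 1):
            if gap[i] >= gap[i + 1] - se[i + 1]:
                k_best = int(ks[i])
                break
        self.result_ = GapStatResult(ks, gap, se, k_best, log_wk)
        self.k_best_ = k_best
        self.labels_, _ = kmeans_assign(X, k_best, seed=self.random_state,
                                        n_init=self.n_init)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def gap_statistic(values: np.ndarray, k_max: int = 10, n_refs: int = 100,
                  seed: int = 0, n_init: int = 25) -> GapStatResult:
    """Functional wrapper over :class:`GapStatisticSelector`."""
    sel = GapStatisticSelector(k_max=k_max, n_refs=n_refs, n_init=n_init,
                               random_state=seed)
    sel.fit(values)
    return sel.result_
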