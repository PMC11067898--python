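"""Minimum-volume-ellipsoid (MVE) niche models.

The fundamental niche of a taxon is estimated as the smallest-volume
ellipsoid in environmental space that contains a stated fraction
(default 90%) of its occurrence points — the classic robust
location/shape estimator, fit by Rousseeuw-style subset resampling.
Suitability surfaces are Mahalanobis-distance based: distance is
measured in units of the ellipsoid (boundary = 1), and suitability is
the Gaussian kernel exp(-d^2/2), which is monotone in distance, 1 at
the center, and bounded in (0, 1].
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .io import EnvStack

logger = logging.getLogger(__name__)

DEFAULT_QUANTILES = (0.75, 0.85, 0.90, 0.95, 0.99)


@dataclass
class EllipsoidModel:
    """A fitted ellipsoid niche: center c and SPD shape matrix S.

    The niche boundary is the set {x : (x-c)' S^-1 (x-c) = 1}; at least
    ceil(inclusion * n_fit) of the calibration points lie inside it.
    """

    taxon: str
    center: np.ndarray
    shape: np.ndarray
    inclusion: float
    variables: list[str]
    n_fit: int
    seed: int

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.shape = np.asarray(self.shape, dtype=float)
        eig = np.linalg.eigvalsh(self.shape)
        if eig.min() <= 0:
            raise ValueError("shape matrix must be symmetric positive definite")

    @property
    def d(self) -> int:
        return self.center.size

    def volume(self) -> float:
        """Euclidean volume of the ellipsoid in environmental units."""
        d = self.d
        unit_ball = math.pi ** (d / 2) / math.gamma(d / 2 + 1)
        return unit_ball * math.sqrt(np.linalg.det(self.shape))

    def mahalanobis(self, X: np.ndarray) -> np.ndarray:
        """Scaled Mahalanobis distance of rows of X (boundary = 1)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        delta = X - self.center
        inv = np.linalg.inv(self.shape)
        md2 = np.einsum("nd,de,ne->n", delta, inv, delta)
        return np.sqrt(np.maximum(md2, 0.0))

    def suitability(self, X: np.ndarray) -> np.ndarray:
        return suitability_from_distance(self.mahalanobis(X))

    def to_dict(self) -> dict:
        return {
            "taxon": self.taxon,
            "center": self.center.tolist(),
            "shape": self.shape.tolist(),
            "inclusion": self.inclusion,
            "variables": list(self.variables),
            "n_fit": self.n_fit,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EllipsoidModel":
        return cls(d["taxon"], np.array(d["center"]), np.array(d["shape"]),
                   d["inclusion"], list(d["variables"]), d["n_fit"], d["seed"])


def suitability_from_distance(d: np.ndarray, kind: str = "gaussian",
                              d_max: float | None = None) -> np.ndarray:
    """Map Mahalanobis distance to suitability.

    ``gaussian`` (default): exp(-d^2/2), in (0, 1], equal to a
    multivariate-normal density up to normalization. ``linear``:
    max(0, 1 - d/d_max).
    """
    d = np.asarray(d, dtype=float)
    if kind == "gaussian":
        return np.exp(-0.5 * d ** 2)
    if kind == "linear":
        if d_max is None:
            raise ValueError("linear suitability needs d_max")
        return np.maximum(0.0, 1.0 - d / d_max)
    raise ValueError(f"unknown suitability kind {kind!r}")


def _candidate_subsets(n: int, d: int, n_subsets: int,
                       rng: np.random.Generator) -> np.ndarray:
    """(B, d+1) index array: all (d+1)-subsets when few enough, else a
    random sample of them."""
    total = math.comb(n, d + 1)
    if total <= n_subsets:
        return np.array(list(itertools.combinations(range(n), d + 1)))
    # rank-based sampling without replacement within each subset
    keys = rng.random((n_subsets, n))
    return np.argpartition(keys, d + 1, axis=1)[:, :d + 1]


def fit_mve(values: np.ndarray, inclusion: float = 0.90,
            n_subsets: int = 5000, seed: int = 0, taxon: str = "",
            variables: list[str] | None = None) -> EllipsoidModel:
    """Fit a minimum volume ellipsoid by subset resampling.

    Draws ``n_subsets`` random (d+1)-point subsets (or enumerates all of
    them when there are no more than ``n_subsets``); for each, takes the
    subset mean m and covariance C, scales C by the h-th smallest squared
    Mahalanobis distance s of all points (h = ceil(inclusion * n)), and
    keeps the candidate of minimum volume, proportional to
    sqrt(det(s * C)). Deterministic given ``seed``.
    """
    X = np.asarray(values, dtype=float)
    X = X[np.all(np.isfinite(X), axis=1)]
    if X.ndim != 2:
        raise ValueError("values must be a 2-D matrix")
    n, d = X.shape
    if not 0 < inclusion <= 1:
        raise ValueError("inclusion must be in (0, 1]")
    if n <= d:
        raise ValueError(f"need at least d+1={d + 1} points, got {n}")
    if np.allclose(X, X[0]):
        raise ValueError("all points identical; ellipsoid undefined")
    h = int(math.ceil(inclusion * n))
    rng = np.random.default_rng(seed)
    idx = _candidate_subsets(n, d, n_subsets, rng)

    sub = X[idx]                                   # (B, d+1, d)
    means = sub.mean(axis=1)                       # (B, d)
    cen = sub - means[:, None, :]
    covs = np.einsum("bkd,bke->bde", cen, cen) / d  # ddof=1 over d+1 points
    dets = np.linalg.det(covs)
    scale = float(np.prod(np.var(X, axis=0)))
    valid = np.isfinite(dets) & (dets > max(scale, 1e-300) * 1e-12)
    if not valid.any():
        raise ValueError("all candidate subsets are degenerate (collinear data)")
    means_v, covs_v, dets_v = means[valid], covs[valid], dets[valid]
    inv = np.linalg.inv(covs_v)
    delta = X[None, :, :] - means_v[:, None, :]     # (B, n, d)
    md2 = np.einsum("bnd,bde,bne->bn", delta, inv, delta)
    s = np.partition(md2, h - 1, axis=1)[:, h - 1]  # h-th smallest
    ok = s > 0
    if not ok.any():
        raise ValueError("degenerate fit: h-th distance is zero everywhere")
    # log-volume^2 of candidate ellipsoid = d*log(s) + log(det C) + const
    crit = np.where(ok, d * np.log(np.where(ok, s, 1.0)) + np.log(dets_v), np.inf)
    best = int(np.argmin(crit))
    center = means_v[best]
    shape = s[best] * covs_v[best]
    shape = 0.5 * (shape + shape.T)
    model = EllipsoidModel(taxon, center, shape, inclusion,
                           list(variables or [f"v{i}" for i in range(d)]),
                           n_fit=n, seed=seed)
    return model


class EllipsoidNicheModel(BaseEstimator):
    """Scikit-learn-style estimator around the MVE niche fit.

    ``fit(X)`` estimates the minimum volume ellipsoid containing
    ``inclusion`` of the rows of X; ``mahalanobis(X)`` returns scaled
    distances (ellipsoid boundary = 1); ``score_samples(X)`` returns
    suitabilities in (0, 1]; ``predict(X)`` returns 1 inside the
    ellipsoid, 0 outside.

    Parameters
    ----------
    inclusion : float, default=0.90
        Fraction of calibration points the ellipsoid must contain.
    n_subsets : int, default=5000
        Resampling budget (all subsets are enumerated when cheaper).
    random_state : int, default=0
        Seed for subset sampling.

    Attributes
    ----------
    center_ : ndarray of shape (d,)
    shape_ : ndarray of shape (d, d)
    model_ : EllipsoidModel
    n_features_in_ : int
    """

    def __init__(self, inclusion: float = 0.90, n_subsets: int = 5000,
                 random_state: int = 0, taxon: str = "",
                 variables: list[str] | None = None):
        self.inclusion = inclusion
        self.n_subsets = n_subsets
        self.random_state = random_state
        self.taxon = taxon
        self.variables = variables

    def fit(self, X, y=None):
        X = check_array(X)
        self.model_ = fit_mve(X, inclusion=self.inclusion,
                              n_subsets=self.n_subsets,
                              seed=self.random_state, taxon=self.taxon,
                              variables=self.variables)
        self.center_ = self.model_.center
        self.shape_ = self.model_.shape
        self.n_features_in_ = X.shape[1]
        return self

    def mahalanobis(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.mahalanobis(check_array(X))

    def score_samples(self, X) -> np.ndarray:
        return suitability_from_distance(self.mahalanobis(X))

    def predict(self, X) -> np.ndarray:
        return (self.mahalanobis(X) <= 1.0).astype(int)


# ---------------------------------------------------------------------------
# suitability rasters and thresholds


@dataclass
class SuitabilityRaster:
    """Per-cell Mahalanobis distance and suitability on an EnvStack grid."""

    origin: tuple[float, float]
    cell_size: float
    distance: np.ndarray
    suitability: np.ndarray


def mahalanobis_raster(model: EllipsoidModel, stack: EnvStack,
                       mask: np.ndarray | None = None) -> SuitabilityRaster:
    """Distance and suitability of every (non-NA) cell to the niche
    ellipsoid; cells outside ``mask`` (if given) and NA cells stay NaN."""
    missing = [v for v in model.variables if v not in stack.layers]
    if missing:
        raise KeyError(f"stack lacks model variables: {missing}")
    sub = stack.select(model.variables) if model.variables else stack
    use = ~sub.na_mask if mask is None else (mask & ~sub.na_mask)
    V = sub.values_matrix(use)
    dist = np.full(sub.shape, np.nan)
    suit = np.full(sub.shape, np.nan)
    if V.shape[0]:
        dvals = model.mahalanobis(V)
        dist[use] = dvals
        suit[use] = suitability_from_distance(dvals)
    return SuitabilityRaster(sub.origin, sub.cell_size, dist, suit)


@dataclass
class ThresholdSet:
    """Gamma fit to occurrence distances plus inverse-CDF cutoffs."""

    gamma_shape: float
    gamma_rate: float
    quantile_thresholds: dict[float, float]

    def __post_init__(self) -> None:
        qs = sorted(self.quantile_thresholds)
        cuts = [self.quantile_thresholds[q] for q in qs]
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cutoffs must strictly increase with quantile")


def gamma_thresholds(model: EllipsoidModel, occ_values: np.ndarray,
                     quantiles: tuple[float, ...] = DEFAULT_QUANTILES
                     ) -> ThresholdSet:
    """Fit a Gamma distribution to occurrence Mahalanobis distances and
    derive data-inclusion distance cutoffs.

    Occurrence-to-ellipsoid distances are right-skewed, so a Gamma is an
    appropriate parametric summary; cutoffs are the Gamma inverse CDF at
    the requested inclusion levels. Zero distances are jittered up by
    machine epsilon (logged).
    """
    dists = model.mahalanobis(np.asarray(occ_values, dtype=float))
    if dists.size < 5:
        raise ValueError("need at least 5 occurrence distances for a Gamma fit")
    if np.ptp(dists) == 0:
        raise ValueError("constant distances; Gamma fit is degenerate")
    n_zero = int((dists == 0).sum())
    if n_zero:
        logger.info("gamma_thresholds: jittered %d zero distances", n_zero)
        dists = np.where(dists == 0, np.finfo(float).eps, dists)
    shape, _, scale = stats.gamma.fit(dists, floc=0.0)
    cuts = {float(q): float(stats.gamma.ppf(q, shape, scale=scale))
            for q in quantiles}
    return ThresholdSet(float(shape), 1.0 / float(scale), cuts)


def binary_map(sr: SuitabilityRaster, ts: ThresholdSet, q: float) -> np.ndarray:
    """Binary presence map: 1 where distance <= cutoff(q), 0 elsewhere,
    NaN preserved."""
    if q not in ts.quantile_thresholds:
        raise KeyError(f"no threshold fitted for quantile {q}")
    cut = ts.quantile_thresholds[q]
    out = np.where(sr.distance <= cut, 1.0, 0.0)
    out[~np.isfinite(sr.distance)] = np.nan
    return out
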