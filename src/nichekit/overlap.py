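"""Pairwise niche-equivalency testing by background similarity.

For a pair of taxa, the observed Schoener's D between their suitability
surfaces is compared against two null distributions, each built by
fitting ellipsoid models to random points drawn within the *other*
taxon's accessible area (M). Two-tailed at alpha = 0.05, a comparison is
scored on a -2..+2 scale: -2 (p < 0.025 against both nulls, niche
divergence), -1 (one of two), 0 (random variation), +1 (p > 0.975 for
one), +2 (both, extreme conservatism).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .ellipsoid import EllipsoidModel, fit_mve, suitability_from_distance
from .io import AccessibleArea, EnvStack

logger = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    taxon_a: str
    taxon_b: str
    d_obs: float
    null_from_ma: np.ndarray  # D of model_b vs random models from M_a
    null_from_mb: np.ndarray  # D of model_a vs random models from M_b
    p_a: float                # rank of d_obs in null_from_mb (model_a fixed)
    p_b: float                # rank of d_obs in null_from_ma (model_b fixed)
    score: int
    conflict_flag: bool


@dataclass
class ScoreMatrix:
    """Lower-triangular pairwise score table (one score per unordered pair)."""

    taxa: list[str]
    scores: dict[frozenset, int] = field(default_factory=dict)

    def get(self, a: str, b: str) -> int | None:
        return self.scores.get(frozenset((a, b)))

    def to_dataframe(self):
        import pandas as pd
        n = len(self.taxa)
        mat = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(i):
                s = self.get(self.taxa[i], self.taxa[j])
                if s is not None:
                    mat[i, j] = s
        return pd.DataFrame(mat, index=self.taxa, columns=self.taxa)

    def class_counts(self) -> dict[int, int]:
        counts = {s: 0 for s in (-2, -1, 0, 1, 2)}
        for s in self.scores.values():
            counts[s] += 1
        return counts


def _normalize(values: np.ndarray) -> np.ndarray:
    v = np.where(np.isfinite(values), values, 0.0)
    total = v.sum()
    if total <= 0:
        raise ValueError("surface sums to zero over the comparison extent")
    return v / total


def schoeners_d(sa: np.ndarray, sb: np.ndarray) -> float:
    """Schoener's D between two suitability surfaces on a shared extent.

    Each surface is normalized to sum to 1 over the extent (NA cells
    contribute 0); D = 1 - 0.5 * sum |p_a - p_b|, so identical surfaces
    give D = 1 and surfaces with disjoint support give D = 0.
    """
    sa = np.asarray(sa, dtype=float).ravel()
    sb = np.asarray(sb, dtype=float).ravel()
    if sa.shape != sb.shape:
        raise ValueError("surfaces must share a grid/extent")
    pa, pb = _normalize(sa), _normalize(sb)
    return float(1.0 - 0.5 * np.abs(pa - pb).sum())


def pvalue(d_obs: float, null: np.ndarray) -> float:
    """Rank p-value with add-one correction: (1 + #{null <= d_obs}) / (N+1).

    Small p means the observed overlap is lower than the background
    expectation (divergence); large p means higher (conservatism). Ties
    count fully into the lower tail, which is conservative for
    divergence claims.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + np.sum(null <= d_obs)) / (null.size + 1))


def score_comparison(p_a: float, p_b: float, alpha: float = 0.05
                     ) -> tuple[int, bool]:
    """Map a pair of background-test p-values to the -2..+2 scale.

    Two-tailed at ``alpha``: cut points are alpha/2 and 1 - alpha/2.
    Returns (score, conflict_flag); the flag marks the contradictory case
    of one p in the lower tail and the other in the upper (scored 0).
    """
    lo, hi = alpha / 2.0, 1.0 - alpha / 2.0
    low_a, low_b = p_a < lo, p_b < lo
    high_a, high_b = p_a > hi, p_b > hi
    conflict = (low_a and high_b) or (low_b and high_a)
    if conflict:
        return 0, True
    if low_a and low_b:
        return -2, False
    if high_a and high_b:
        return 2, False
    if low_a or low_b:
        return -1, False
    if high_a or high_b:
        return 1, False
    return 0, False


def background_null(model_fixed: EllipsoidModel, m_random: AccessibleArea,
                    stack: EnvStack, n_points: int, n_reps: int = 100,
                    seed: int = 0, extent_mask: np.ndarray | None = None,
                    n_subsets: int = 500, max_retries: int = 10
                    ) -> np.ndarray:
    """Null D distribution for one direction of a background test.

    Each replicate samples ``n_points`` cells uniformly without
    replacement from the non-NA cells of ``m_random``, fits an ellipsoid
    model to their environmental values, and computes Schoener's D
    between that random model's suitability surface and the fixed
    model's surface over the comparison extent. Fully seeded.
    """
    sub = stack.select(model_fixed.variables)
    m_mask = sub.mask_for_area(m_random)
    n_cells = int(m_mask.sum())
    d = len(model_fixed.variables)
    if n_points < d + 1:
        raise ValueError("n_points must be at least d+1")
    if n_cells < n_points:
        raise ValueError(
            f"accessible area has {n_cells} valid cells < n_points={n_points}")
    if extent_mask is None:
        extent_mask = ~sub.na_mask
    V_extent = sub.values_matrix(extent_mask & ~sub.na_mask)
    fixed_surface = model_fixed.suitability(V_extent)
    V_m = sub.values_matrix(m_mask)
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for rep in range(n_reps):
        for attempt in range(max_retries):
            pick = rng.choice(n_cells, size=n_points, replace=False)
            try:
                rm = fit_mve(V_m[pick], inclusion=model_fixed.inclusion,
                             n_subsets=n_subsets,
                             seed=int(rng.integers(2**31)))
                break
            except ValueError:
                continue
        else:
            raise ValueError(f"replicate {rep}: {max_retries} singular fits")
        out[rep] = schoeners_d(fixed_surface, rm.suitability(V_extent))
    return out


def compare_pair(model_a: EllipsoidModel, model_b: EllipsoidModel,
                 area_a: AccessibleArea, area_b: AccessibleArea,
                 stack: EnvStack, n_points_a: int, n_points_b: int,
                 n_reps: int = 100, alpha: float = 0.05, seed: int = 0,
                 n_subsets: int = 500) -> ComparisonResult:
    """Full background-similarity test for one taxon pair.

    The comparison extent is the union of the two accessible areas'
    non-NA cells; ``n_points_a`` is the number of random points drawn per
    replicate within taxon a's M (conventionally a's own thinned
    occurrence count), and likewise for b.
    """
    if model_a.variables != model_b.variables:
        raise ValueError("models were fitted on different variable sets")
    sub = stack.select(model_a.variables)
    extent = sub.mask_for_area(area_a) | sub.mask_for_area(area_b)
    if not extent.any():
        raise ValueError("empty comparison extent")
    V = sub.values_matrix(extent)
    d_obs = schoeners_d(model_a.suitability(V), model_b.suitability(V))
    rng = np.random.default_rng(seed)
    null_b = background_null(model_a, area_b, sub, n_points_b, n_reps,
                             seed=int(rng.integers(2**31)),
                             extent_mask=extent, n_subsets=n_subsets)
    null_a = background_null(model_b, area_a, sub, n_points_a, n_reps,
                             seed=int(rng.integers(2**31)),
                             extent_mask=extent, n_subsets=n_subsets)
    p_a = pvalue(d_obs, null_b)
    p_b = pvalue(d_obs, null_a)
    score, conflict = score_comparison(p_a, p_b, alpha)
    return ComparisonResult(model_a.taxon, model_b.taxon, d_obs,
                            null_a, null_b, p_a, p_b, score, conflict)


def pairwise_matrix(models: dict[str, EllipsoidModel],
                    areas: dict[str, AccessibleArea],
                    n_occurrences: dict[str, int],
                    stack: EnvStack, n_reps: int = 100, alpha: float = 0.05,
                    seed: int = 0, n_subsets: int = 500
                    ) -> tuple[ScoreMatrix, list[ComparisonResult]]:
    """Run the background test for every unordered pair of taxa.

    Null-model point counts default to each taxon's own (thinned)
    occurrence count, matching equal-sampling-effort convention.
    """
    taxa = list(models)
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    rng = np.random.default_rng(seed)
    matrix = ScoreMatrix(taxa)
    results = []
    for a, b in itertools.combinations(taxa, 2):
        res = compare_pair(models[a], models[b], areas[a], areas[b], stack,
                           n_occurrences[a], n_occurrences[b], n_reps,
                           alpha, seed=int(rng.integers(2**31)),
                           n_subsets=n_subsets)
        matrix.scores[frozenset((a, b))] = res.score
        results.append(res)
    return matrix, results
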