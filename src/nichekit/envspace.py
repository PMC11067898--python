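"""Environmental data matrices at occurrence points and PCA variable
importance.

Importance of a variable on a component is reported as its percent
contribution, 100 * loading^2 / sum of squared loadings for that
component — the form in which climatic-variable importance is usually
quoted (e.g. "annual evapotranspiration, 70.3% of PC1").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .io import EnvStack, OccurrenceRecord

logger = logging.getLogger(__name__)


@dataclass
class EnvMatrix:
    """Environmental values at a taxon's occurrence points (no NA rows)."""

    taxon: str
    points: list[tuple[float, float]]
    values: np.ndarray  # (n, d)
    variables: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.variables):
            raise ValueError("values shape inconsistent with variables")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("EnvMatrix must not contain NA rows")


@dataclass
class PCAResult:
    loadings: np.ndarray            # (d, d): columns are components
    explained_fraction: np.ndarray  # (d,)
    top_contributors: list[list[tuple[str, float]]]
    variables: list[str]

    def contributions(self) -> np.ndarray:
        """Percent contribution of each variable (rows) per component."""
        sq = self.loadings ** 2
        return 100.0 * sq / sq.sum(axis=0, keepdims=True)


def extract_values(stack: EnvStack,
                   points: list[tuple[float, float]] | list[OccurrenceRecord],
                   taxon: str = "") -> EnvMatrix:
    """Nearest-cell-center lookup of stack values at lon/lat points.

    Points falling on NA cells (or off the grid) are dropped and counted
    in the log; an error is raised if nothing remains.
    """
    coords = [(p.lon, p.lat) if isinstance(p, OccurrenceRecord) else tuple(p)
              for p in points]
    kept_pts, rows = [], []
    n_dropped = 0
    for lon, lat in coords:
        r, c = stack.index_of(lon, lat)
        if stack.in_bounds(r, c) and not stack.na_mask[r, c]:
            kept_pts.append((lon, lat))
            rows.append(stack.values_at(r, c))
        else:
            n_dropped += 1
    if not rows:
        raise ValueError("all points fall on NA cells or outside the grid")
    if n_dropped:
        logger.info("extract_values: dropped %d of %d points on NA cells",
                    n_dropped, len(coords))
    return EnvMatrix(taxon, kept_pts, np.array(rows), stack.variables)


def pca_importance(values: np.ndarray, variables: list[str],
                   scale: bool = True, n_top: int = 2) -> PCAResult:
    """PCA of an environmental data matrix with per-component variable
    contributions.

    Data are centered and (by default) scaled to unit variance, i.e.
    correlation-matrix PCA — appropriate when variables carry
    incommensurate units. Zero-variance columns are dropped (logged).
    Contribution of variable v to component c is 100 * loading(v,c)^2 /
    sum_v loading(v,c)^2.
    """
    X = np.asarray(values, dtype=float)
    n, d = X.shape
    if n <= d:
        raise ValueError(f"need more rows ({n}) than variables ({d}) for PCA")
    sd = X.std(axis=0, ddof=1)
    usable = sd > 0
    if not np.all(usable):
        dropped = [v for v, u in zip(variables, usable) if not u]
        logger.info("pca_importance: dropping zero-variance columns %s", dropped)
        X = X[:, usable]
        variables = [v for v, u in zip(variables, usable) if u]
        sd = sd[usable]
    if X.shape[1] < 2:
        raise ValueError("fewer than 2 usable columns")
    Xc = X - X.mean(axis=0)
    if scale:
        Xc = Xc / sd
    pca = PCA(n_components=Xc.shape[1], svd_solver="full")
    pca.fit(Xc)
    loadings = pca.components_.T  # (d, k) orthonormal columns
    frac = pca.explained_variance_ratio_
    contrib = 100.0 * loadings ** 2 / (loadings ** 2).sum(axis=0, keepdims=True)
    top = []
    for c in range(contrib.shape[1]):
        idx = np.argsort(contrib[:, c])[::-1][:n_top]
        top.append([(variables[i], float(contrib[i, c])) for i in idx])
    return PCAResult(loadings, frac, top, list(variables))


def select_variables(stack: EnvStack, keep: list[str]) -> EnvStack:
    """Sub-stack with the requested variables in the requested order."""
    return stack.select(keep)
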