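"""Occurrence cleaning: uncertainty filter, dedupe, breeding-season
windows, accessible-area clipping, and spatial thinning.

The canonical step order is uncertainty -> dedupe -> dates -> M-clip ->
thin; ``prepare`` applies it and records per-step counts in a prep log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import AccessibleArea, OccurrenceRecord

EARTH_RADIUS_KM = 6371.0

#: Default breeding months: April-July north of the equator, October-January
#: (wrapping the year boundary) south of it.
NORTHERN_MONTHS = (4, 5, 6, 7)
SOUTHERN_MONTHS = (10, 11, 12, 1)


@dataclass
class OccurrenceSet:
    """A taxon's records plus an ordered log of (step, n_before, n_after)."""

    taxon: str
    records: list[OccurrenceRecord]
    prep_log: list[tuple[str, int, int]] = field(default_factory=list)

    def log(self, step: str, n_before: int, n_after: int) -> None:
        if n_after > n_before:
            raise ValueError("a filter step cannot add records")
        self.prep_log.append((step, n_before, n_after))


def filter_uncertainty(recs: list[OccurrenceRecord], max_km: float = 10.0,
                       keep_missing: bool = True) -> list[OccurrenceRecord]:
    """Drop records with coordinate uncertainty strictly above ``max_km``.

    The boundary is kept (a record at exactly ``max_km`` passes); records
    with no stated uncertainty are retained by default.
    """
    if max_km <= 0:
        raise ValueError("max_km must be positive")
    out = []
    for r in recs:
        if r.uncertainty_m is None:
            if keep_missing:
                out.append(r)
        elif r.uncertainty_m <= max_km * 1000.0:
            out.append(r)
    return out


def dedupe_localities(recs: list[OccurrenceRecord],
                      precision: float = 1e-4) -> list[OccurrenceRecord]:
    """One record per unique (taxon, lon, lat) site.

    Coordinates are rounded to ``precision`` degrees before comparison;
    the earliest-dated record at each site is kept (dateless records sort
    last). First-seen order of sites is preserved.
    """
    ndig = max(0, int(round(-math.log10(precision))))
    best: dict[tuple, OccurrenceRecord] = {}
    order: list[tuple] = []
    for r in recs:
        key = (r.taxon, round(r.lon, ndig), round(r.lat, ndig))
        if key not in best:
            best[key] = r
            order.append(key)
        else:
            cur = best[key]
            if r.event_date is not None and (
                    cur.event_date is None or r.event_date < cur.event_date):
                best[key] = r
    return [best[k] for k in order]


def filter_breeding_window(recs: list[OccurrenceRecord],
                           windows: dict[str, object],
                           keep_dateless_residents: bool = True
                           ) -> list[OccurrenceRecord]:
    """Keep records whose month falls in the taxon's breeding window.

    ``windows`` maps taxon -> either the string ``"resident"`` (no date
    filter), ``"north"`` / ``"south"`` (the default hemisphere windows),
    or an explicit list of months (which may wrap the year boundary).
    Dateless records are dropped for migratory taxa and kept for
    residents.
    """
    out = []
    for r in recs:
        if r.taxon not in windows:
            raise KeyError(f"no breeding window assigned for taxon {r.taxon!r}")
        w = windows[r.taxon]
        if w == "resident":
            if r.event_date is not None or keep_dateless_residents:
                out.append(r)
            continue
        if w == "north":
            months = NORTHERN_MONTHS
        elif w == "south":
            months = SOUTHERN_MONTHS
        else:
            months = tuple(int(m) for m in w)  # type: ignore[arg-type]
        if r.event_date is not None and r.event_date.month in months:
            out.append(r)
    return out


def clip_to_m(recs: list[OccurrenceRecord],
              area: AccessibleArea) -> list[OccurrenceRecord]:
    """Drop records outside the taxon's accessible area (closed polygons:
    boundary points are kept)."""
    return [r for r in recs if area.contains(r.lon, r.lat)]


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (Earth radius 6371 km); broadcasts."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def thin_spatial(recs: list[OccurrenceRecord], min_km: float,
                 seed: int = 0) -> list[OccurrenceRecord]:
    """Greedy spatial thinning to a minimum great-circle separation.

    Records are visited in a seed-shuffled order; each is accepted iff it
    lies at least ``min_km`` from every already-accepted record. The
    retained set therefore always satisfies the pairwise constraint and
    is deterministic for a given seed.
    """
    if min_km <= 0:
        raise ValueError("min_km must be positive")
    if not recs:
        return []
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(recs))
    kept_idx: list[int] = []
    lons = np.array([r.lon for r in recs])
    lats = np.array([r.lat for r in recs])
    for i in order:
        if not kept_idx:
            kept_idx.append(i)
            continue
        d = haversine_km(lons[i], lats[i], lons[kept_idx], lats[kept_idx])
        if np.all(d >= min_km):
            kept_idx.append(i)
    kept_idx.sort()
    return [recs[i] for i in kept_idx]


def prepare(taxon: str, recs: list[OccurrenceRecord], *,
            max_uncertainty_km: float = 10.0,
            windows: dict[str, object] | None = None,
            area: AccessibleArea | None = None,
            thin_km: float | None = 20.0,
            seed: int = 0) -> OccurrenceSet:
    """Run the canonical cleaning pipeline for one taxon.

    Steps (each optional where its inputs are None): uncertainty filter,
    locality dedupe, breeding-window date filter, M clip, spatial thin.
    """
    recs = [r for r in recs if r.taxon == taxon]
    out = OccurrenceSet(taxon, recs)

    n = len(recs)
    recs = filter_uncertainty(recs, max_uncertainty_km)
    out.log("uncertainty", n, len(recs))

    n = len(recs)
    recs = dedupe_localities(recs)
    out.log("dedupe", n, len(recs))

    if windows is not None:
        n = len(recs)
        recs = filter_breeding_window(recs, windows)
        out.log("breeding_window", n, len(recs))

    if area is not None:
        n = len(recs)
        recs = clip_to_m(recs, area)
        out.log("m_clip", n, len(recs))

    if thin_km is not None:
        n = len(recs)
        recs = thin_spatial(recs, thin_km, seed=seed)
        out.log("thin", n, len(recs))

    out.records = recs
    return out
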