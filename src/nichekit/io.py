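"""Readers and writers for the external formats the pipeline touches.

Occurrence tables are Darwin-Core-like CSV, environmental layers are
co-registered single-band ESRI ASCII grids in geographic (WGS84 lon/lat)
coordinates, accessible areas (Ms) are GeoJSON multi-polygons, and
phylogenies are Newick with branch lengths.

Grid convention: cells are addressed by their centers, row 0 is the
northernmost row, and NA propagates by union across layers — a cell that
is NA in any layer is NA in every layer, so every non-NA cell carries a
complete environmental vector.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from datetime import date

import dendropy
import numpy as np
from shapely.geometry import Point, mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

logger = logging.getLogger(__name__)

#: Default Darwin-Core column names for occurrence CSVs.
DWC_COLUMNS = {
    "taxon": "species",
    "lon": "decimalLongitude",
    "lat": "decimalLatitude",
    "uncertainty_m": "coordinateUncertaintyInMeters",
    "event_date": "eventDate",
}


@dataclass(frozen=True)
class OccurrenceRecord:
    """A single georeferenced occurrence of a taxon (WGS84 degrees)."""

    taxon: str
    lon: float
    lat: float
    uncertainty_m: float | None = None
    event_date: date | None = None

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        if self.uncertainty_m is not None and self.uncertainty_m < 0:
            raise ValueError(f"negative coordinate uncertainty: {self.uncertainty_m}")


@dataclass
class AccessibleArea:
    """The accessible biogeographic area (M) of a taxon.

    M delimits both niche-model calibration and null-model point sampling:
    it is the region the taxon could plausibly have reached over relevant
    time, typically hand-drawn along major dispersal barriers.
    """

    taxon: str
    polygons: BaseGeometry

    def __post_init__(self) -> None:
        if self.polygons is None or self.polygons.is_empty:
            raise ValueError(f"empty accessible area for {self.taxon!r}")
        if not self.polygons.is_valid:
            self.polygons = make_valid(self.polygons)
            logger.info("repaired invalid accessible-area geometry for %s", self.taxon)

    def contains(self, lon: float, lat: float) -> bool:
        """Closed-polygon membership: boundary points count as inside."""
        p = Point(lon, lat)
        return bool(self.polygons.contains(p) or self.polygons.touches(p))


class EnvStack:
    """A set of co-registered environmental raster layers on one grid.

    Parameters
    ----------
    layers : dict of str -> 2D float array
        Ordered mapping of variable name to value grid; NA encoded as NaN.
    origin : (float, float)
        Lon/lat of the *center* of cell (0, 0), the northwest cell.
    cell_size : float
        Cell edge length in degrees (> 0); square cells.
    """

    def __init__(self, layers: dict[str, np.ndarray], origin: tuple[float, float],
                 cell_size: float):
        if cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not layers:
            raise ValueError("EnvStack needs at least one layer")
        arrays = {}
        shp = None
        for name, arr in layers.items():
            a = np.asarray(arr, dtype=float)
            if a.ndim != 2:
                raise ValueError(f"layer {name!r} is not 2-D")
            if shp is None:
                shp = a.shape
            elif a.shape != shp:
                raise ValueError(f"layer {name!r} shape {a.shape} != {shp}")
            arrays[name] = a.copy()
        # union NA mask: NA anywhere is NA everywhere
        na = np.zeros(shp, dtype=bool)
        for a in arrays.values():
            na |= ~np.isfinite(a)
        for a in arrays.values():
            a[na] = np.nan
        self.layers = arrays
        self.origin = (float(origin[0]), float(origin[1]))
        self.cell_size = float(cell_size)
        self.na_mask = na

    # -- grid geometry -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def n_rows(self) -> int:
        return self.shape[0]

    @property
    def n_cols(self) -> int:
        return self.shape[1]

    @property
    def variables(self) -> list[str]:
        return list(self.layers)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon0, lat0 = self.origin
        return (lon0 + col * self.cell_size, lat0 - row * self.cell_size)

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Nearest-cell-center index; may fall outside the grid."""
        lon0, lat0 = self.origin
        col = int(round((lon - lon0) / self.cell_size))
        row = int(round((lat0 - lat) / self.cell_size))
        return (row, col)

    def in_bounds(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Lon and lat arrays of all cell centers, each shaped like a layer."""
        lon0, lat0 = self.origin
        cols = lon0 + np.arange(self.n_cols) * self.cell_size
        rows = lat0 - np.arange(self.n_rows) * self.cell_size
        return np.meshgrid(cols, rows)

    # -- values --------------------------------------------------------

    def values_at(self, row: int, col: int) -> np.ndarray:
        return np.array([self.layers[v][row, col] for v in self.layers])

    def values_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Stack layer values into an (n_cells, d) matrix.

        ``mask`` selects cells (boolean grid); defaults to all non-NA cells.
        """
        if mask is None:
            mask = ~self.na_mask
        return np.column_stack([self.layers[v][mask] for v in self.layers])

    def select(self, keep: list[str]) -> "EnvStack":
        """Sub-stack with the named layers, in the requested order."""
        missing = [v for v in keep if v not in self.layers]
        if missing:
            raise KeyError(f"unknown variables: {missing}")
        return EnvStack({v: self.layers[v] for v in keep}, self.origin, self.cell_size)

    def mask_for_area(self, area: AccessibleArea) -> np.ndarray:
        """Boolean grid of non-NA cells whose centers fall inside ``area``."""
        from shapely import intersects_xy

        lon, lat = self.cell_centers()
        # intersects (not contains) so boundary cell centers count as inside
        inside = intersects_xy(area.polygons, lon.ravel(), lat.ravel())
        return inside.reshape(lon.shape) & ~self.na_mask


# ---------------------------------------------------------------------------
# occurrence CSV


def _parse_float(s: str) -> float | None:
    s = (s or "").strip()
    if not s or s.upper() in {"NA", "NAN", "NULL"}:
        return None
    return float(s)


def _parse_date(s: str) -> date | None:
    s = (s or "").strip()
    if not s:
        return None
    # accept ISO dates, possibly with a time suffix or truncated precision
    core = s.split("T")[0].split(" ")[0]
    parts = core.split("-")
    try:
        if len(parts) >= 3:
            return date(int(parts[0]), int(parts[1]), int(parts[2]))
        if len(parts) == 2:
            return date(int(parts[0]), int(parts[1]), 1)
    except ValueError:
        return None
    return None


def read_occurrences(path, column_map: dict[str, str] | None = None
                     ) -> list[OccurrenceRecord]:
    """Read a Darwin-Core-like occurrence CSV.

    Rows with unparseable or out-of-range coordinates are rejected and
    reported (logged with their row index); missing uncertainty and dates
    are preserved as missing.
    """
    cols = dict(DWC_COLUMNS)
    if column_map:
        cols.update(column_map)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError("empty table")
        for key in ("taxon", "lon", "lat"):
            if cols[key] not in reader.fieldnames:
                raise KeyError(f"missing mapped column {cols[key]!r}")
        records: list[OccurrenceRecord] = []
        n_rejected = 0
        for i, row in enumerate(reader):
            try:
                lon = _parse_float(row[cols["lon"]])
                lat = _parse_float(row[cols["lat"]])
                if lon is None or lat is None:
                    raise ValueError("missing coordinates")
                unc = None
                if cols["uncertainty_m"] in row:
                    unc = _parse_float(row.get(cols["uncertainty_m"], ""))
                ev = _parse_date(row.get(cols["event_date"], "")) \
                    if cols["event_date"] in row else None
                records.append(OccurrenceRecord(
                    taxon=row[cols["taxon"]].strip(), lon=lon, lat=lat,
                    uncertainty_m=unc, event_date=ev))
            except (ValueError, KeyError) as exc:
                n_rejected += 1
                logger.warning("rejected occurrence row %d: %s", i, exc)
        if not records and n_rejected == 0:
            raise ValueError("empty table")
    if n_rejected:
        logger.info("rejected %d of %d rows", n_rejected, n_rejected + len(records))
    return records


def write_occurrences(records: list[OccurrenceRecord], path,
                      column_map: dict[str, str] | None = None) -> None:
    cols = dict(DWC_COLUMNS)
    if column_map:
        cols.update(column_map)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow([cols["taxon"], cols["lon"], cols["lat"],
                    cols["uncertainty_m"], cols["event_date"]])
        for r in records:
            w.writerow([
                r.taxon, repr(float(r.lon)), repr(float(r.lat)),
                "" if r.uncertainty_m is None else repr(float(r.uncertainty_m)),
                "" if r.event_date is None else r.event_date.isoformat(),
            ])


# ---------------------------------------------------------------------------
# ASCII-grid rasters

_NODATA = -9999.0


def read_ascii_grid(path) -> tuple[np.ndarray, tuple[float, float], float]:
    """Read one ESRI ASCII grid; returns (array, origin, cell_size).

    ``origin`` is the lon/lat of the center of the top-left cell.
    """
    header: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise ValueError(f"truncated ASCII grid: {path}")
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value"}:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if req not in header:
                raise ValueError(f"ASCII grid missing header field {req!r}")
        data = np.loadtxt(fh, dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nrows, ncols)
    nodata = header.get("nodata_value", _NODATA)
    data[data == nodata] = np.nan
    cs = header["cellsize"]
    origin = (header["xllcorner"] + cs / 2.0,
              header["yllcorner"] + cs * (nrows - 0.5))
    return data, origin, cs


def write_ascii_grid(arr: np.ndarray, origin: tuple[float, float],
                     cell_size: float, path) -> None:
    arr = np.asarray(arr, dtype=float)
    nrows, ncols = arr.shape
    xll = origin[0] - cell_size / 2.0
    yll = origin[1] - cell_size * (nrows - 0.5)
    out = np.where(np.isfinite(arr), arr, _NODATA)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xll!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {cell_size!r}\n")
        fh.write(f"NODATA_value {_NODATA}\n")
        np.savetxt(fh, out, fmt="%.17g")


def read_env_stack(paths: list, names: list[str] | None = None) -> EnvStack:
    """Stack single-band ASCII-grid rasters onto a shared grid.

    All rasters must share the cell size and sit on the same lattice
    (origins offset by whole cells); extents are cropped to the common
    overlap. The union NA mask is applied across layers.
    """
    if not paths:
        raise ValueError("no raster paths given")
    if names is None:
        import os
        names = [os.path.splitext(os.path.basename(str(p)))[0] for p in paths]
    if len(set(names)) != len(names):
        raise ValueError("duplicate layer names")
    grids = [read_ascii_grid(p) for p in paths]
    cs = grids[0][2]
    for (_, _, c), p in zip(grids, paths):
        if abs(c - cs) > 1e-9 * max(cs, 1.0):
            raise ValueError(f"cell size mismatch in {p}")
    # integer offsets of each grid's origin from the first, in cells
    ox, oy = grids[0][1]
    offsets = []
    for arr, (gx, gy), _ in grids:
        dc = (gx - ox) / cs
        dr = (oy - gy) / cs
        if abs(dc - round(dc)) > 1e-6 or abs(dr - round(dr)) > 1e-6:
            raise ValueError("rasters are not on a shared lattice")
        offsets.append((int(round(dr)), int(round(dc))))
    # overlap window in the first grid's row/col coordinates: grid g with
    # offset (dr, dc) covers rows [dr, dr + nrows) there
    r0 = max(dr for dr, _ in offsets)
    c0 = max(dc for _, dc in offsets)
    r1 = min(dr + arr.shape[0] for (arr, _, _), (dr, _) in zip(grids, offsets))
    c1 = min(dc + arr.shape[1] for (arr, _, _), (_, dc) in zip(grids, offsets))
    if r1 <= r0 or c1 <= c0:
        raise ValueError("rasters have no overlapping extent")
    layers = {}
    for name, (arr, _, _), (dr, dc) in zip(names, grids, offsets):
        layers[name] = arr[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
    origin = (ox + c0 * cs, oy - r0 * cs)
    return EnvStack(layers, origin, cs)


def write_env_stack(stack: EnvStack, directory) -> list[str]:
    """Write one .asc file per layer; returns the written paths."""
    import os
    os.makedirs(directory, exist_ok=True)
    paths = []
    for name in stack.variables:
        p = os.path.join(directory, f"{name}.asc")
        write_ascii_grid(stack.layers[name], stack.origin, stack.cell_size, p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# accessible-area polygons (GeoJSON)


def read_polygons(path, taxon_property: str = "taxon") -> list[AccessibleArea]:
    """Read accessible areas from a GeoJSON FeatureCollection.

    Each feature must carry a taxon name property and a non-null geometry;
    invalid rings are repaired (logged) by ``AccessibleArea``.
    """
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    feats = gj.get("features", [gj] if gj.get("type") == "Feature" else [])
    if not feats:
        raise ValueError("no features in GeoJSON")
    areas = []
    for f in feats:
        props = f.get("properties") or {}
        if taxon_property not in props:
            raise KeyError(f"feature missing {taxon_property!r} property")
        if f.get("geometry") is None:
            raise ValueError(f"null geometry for {props[taxon_property]!r}")
        areas.append(AccessibleArea(props[taxon_property], shape(f["geometry"])))
    return areas


def write_polygons(areas: list[AccessibleArea], path,
                   taxon_property: str = "taxon") -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature",
             "properties": {taxon_property: a.taxon},
             "geometry": mapping(a.polygons)}
            for a in areas
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(fc, fh)


# ---------------------------------------------------------------------------
# Newick trees


def _check_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("branch lengths required")
        if edge.length < 0:
            raise ValueError("negative branch length")
    return tree


def read_newick(path=None, data: str | None = None) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths (dendropy.Tree)."""
    kwargs = dict(schema="newick", suppress_internal_node_taxa=True,
                  rooting="force-rooted")
    try:
        if data is not None:
            tree = dendropy.Tree.get(data=data, **kwargs)
        else:
            tree = dendropy.Tree.get(path=str(path), **kwargs)
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"duplicate tips or malformed newick: {exc}") from exc
    return _check_tree(tree)


def write_newick(tree: dendropy.Tree, path=None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(s)
    return s
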