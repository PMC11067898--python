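"""Virtual-species worlds with known ground truth.

Generates smooth multi-layer environmental rasters, a phylogeny, true
ellipsoid niches evolved on that tree under one of three scenarios —
*partitioning* (descendants split the ancestral niche), *conservatism*
(descendants inherit it unchanged), *divergence* (one descendant shifts
to a novel niche) — plus disjoint accessible areas and occurrence
samples drawn from within each taxon's true niche. Every stage of the
pipeline can thus be tested against known truth without any downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import ndimage, stats
from shapely.geometry import box

from .ellipsoid import EllipsoidModel
from .io import AccessibleArea, EnvStack, OccurrenceRecord
from .prep import OccurrenceSet

SCENARIOS = ("partitioning", "conservatism", "divergence")


@dataclass
class ScenarioConfig:
    """Study conditions for one simulated world.

    Defaults describe a two-taxon allopatric world: a 100 x 100 raster of
    three smooth standardized environmental layers, niches of width 0.5
    standard deviations, 100 occurrences per taxon, and (for the
    divergence scenario) a center offset of 4 Mahalanobis units — more
    than twice the scaled ellipsoid radius, so the true niches do not
    intersect.
    """

    scenario: str = "conservatism"
    n_taxa: int = 2
    n_occurrences: int = 100
    raster_size: tuple[int, int] = (100, 100)
    n_variables: int = 3
    niche_width: float = 0.5
    offset: float = 4.0
    step_sd: float = 0.0
    smoothness: float = 5.0
    inclusion: float = 0.90
    cutoff_quantile: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.offset < 0:
            raise ValueError("offset must be nonnegative")
        if self.n_occurrences < self.n_variables + 1:
            raise ValueError("need at least d+1 occurrences per taxon")


@dataclass
class SyntheticWorld:
    stack: EnvStack
    tree: dendropy.Tree
    true_models: dict[str, EllipsoidModel]
    areas: dict[str, AccessibleArea]
    occurrences: dict[str, OccurrenceSet]
    truth_log: dict = field(default_factory=dict)


def simulate_env(size: tuple[int, int], n_vars: int, smoothness: float,
                 seed: int = 0, lat_gradient: float = 0.0,
                 origin: tuple[float, float] = (-50.0, 10.0),
                 cell_size: float = 0.05) -> EnvStack:
    """Smooth standardized environmental layers.

    Each layer is seeded white noise convolved with a Gaussian kernel of
    radius ``smoothness`` cells, plus an optional north-south gradient,
    then standardized to mean 0 and SD 1 over non-NA cells.
    """
    rows, cols = size
    if rows < 20 or cols < 20:
        raise ValueError("raster must be at least 20 x 20")
    if n_vars < 2:
        raise ValueError("need at least 2 environmental variables")
    if smoothness >= min(rows, cols) / 2:
        raise ValueError("kernel radius too large for the raster")
    rng = np.random.default_rng(seed)
    layers = {}
    lat = np.linspace(1.0, -1.0, rows)[:, None]
    for i in range(n_vars):
        z = rng.standard_normal((rows, cols))
        if smoothness > 0:
            z = ndimage.gaussian_filter(z, sigma=smoothness, mode="reflect")
        if lat_gradient:
            z = z + lat_gradient * lat * z.std()
        z = (z - z.mean()) / z.std()
        layers[f"env{i + 1}"] = z
    return EnvStack(layers, origin, cell_size)


def _sqrtm_spd(S: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(S)
    return V @ np.diag(np.sqrt(np.maximum(w, 0.0))) @ V.T


def _random_unit(d: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(d)
    return v / np.linalg.norm(v)


def evolve_niches(tree: dendropy.Tree, root_model: EllipsoidModel,
                  step_sd: float, scenario: str, offset: float = 4.0,
                  seed: int = 0) -> dict[str, EllipsoidModel]:
    """Evolve true ellipsoid niches down a tree under one scenario.

    conservatism: every tip inherits the root ellipsoid unchanged.
    partitioning: at each split the parent ellipsoid is divided into two
    disjoint half-sized sub-ellipsoids (constructed in the parent's
    whitened space as balls of radius 1/2 centered at +/- u/2 along a
    random direction u), so every descendant niche is contained in the
    ancestral one and sisters sit on opposite sides of the split plane.
    divergence: the first tip's center is displaced by ``offset``
    Mahalanobis units along a random direction; all others inherit.
    Optional Brownian jitter of centers (``step_sd`` per unit branch
    length, in Mahalanobis units) applies on every branch.
    """
    rng = np.random.default_rng(seed)
    d = root_model.d
    A_root = _sqrtm_spd(root_model.shape)

    node_model: dict = {tree.seed_node: (root_model.center.copy(),
                                         root_model.shape.copy())}
    if scenario == "partitioning":
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            children = node.child_nodes()
            if len(children) != 2:
                raise ValueError("partitioning scenario needs a binary tree")
            c, S = node_model[node]
            A = _sqrtm_spd(S)
            u = _random_unit(d, rng)
            for child, sign in zip(children, (+1.0, -1.0)):
                node_model[child] = (c + sign * 0.5 * (A @ u), S / 4.0)
    else:
        leaves = list(tree.leaf_node_iter())
        shifted = leaves[0] if scenario == "divergence" else None
        u = _random_unit(d, rng)
        for leaf in leaves:
            c = root_model.center.copy()
            if leaf is shifted:
                c = c + offset * (A_root @ u)
            node_model[leaf] = (c, root_model.shape.copy())

    models = {}
    for leaf in tree.leaf_node_iter():
        c, S = node_model[leaf]
        if step_sd > 0:
            depth = leaf.distance_from_root()
            c = c + _sqrtm_spd(S) @ rng.standard_normal(d) * step_sd * math.sqrt(depth)
        label = leaf.taxon.label
        models[label] = EllipsoidModel(label, c, S, root_model.inclusion,
                                       list(root_model.variables),
                                       n_fit=0, seed=seed)
    return models


def sample_occurrences(model: EllipsoidModel, area: AccessibleArea,
                       stack: EnvStack, n: int,
                       cutoff_quantile: float = 0.95,
                       seed: int = 0) -> tuple[OccurrenceSet, np.ndarray]:
    """Sample occurrences uniformly from suitable cells inside M.

    Eligible cells are the non-NA cells of ``area`` whose true scaled
    Mahalanobis distance is at most a cutoff radius; the cutoff maps
    ``cutoff_quantile`` through the chi-square quantile ratio against the
    model's inclusion level (0.95 vs 0.90 gives a radius slightly above
    the ellipsoid boundary). Occurrences get sub-cell uniform jitter;
    true distances are returned alongside.
    """
    d = model.d
    radius = math.sqrt(stats.chi2.ppf(cutoff_quantile, d)
                       / stats.chi2.ppf(model.inclusion, d))
    sub = stack.select(model.variables)
    m_mask = sub.mask_for_area(area)
    if not m_mask.any():
        raise ValueError("accessible area contains no valid cells")
    V = sub.values_matrix(m_mask)
    dist = model.mahalanobis(V)
    eligible = dist <= radius
    frac = eligible.mean()
    if frac < 1e-4:
        raise ValueError(
            f"acceptance probability {frac:.2e} too low: niche/M mismatch")
    if eligible.sum() < 3 * (d + 1):
        raise ValueError(
            f"only {int(eligible.sum())} suitable cells in M: niche/M mismatch")
    rows, cols = np.nonzero(m_mask)
    rows, cols = rows[eligible], cols[eligible]
    dist = dist[eligible]
    rng = np.random.default_rng(seed)
    pick = rng.integers(rows.size, size=n)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2)) * sub.cell_size
    records = []
    for k, i in enumerate(pick):
        lon, lat = sub.cell_center(int(rows[i]), int(cols[i]))
        records.append(OccurrenceRecord(model.taxon, lon + jitter[k, 0],
                                        lat + jitter[k, 1]))
    occ = OccurrenceSet(model.taxon, records)
    occ.log("simulated", n, n)
    return occ, dist[pick]


def _default_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Balanced-ish random binary tree with unit-depth tips."""
    if n_taxa == 2:
        newick = "(t1:1.0,t2:1.0):0.0;"
        return dendropy.Tree.get(data=newick, schema="newick",
                                 rooting="force-rooted")
    import random

    from dendropy.simulate import treesim
    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_taxa)])
    return treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        taxon_namespace=taxa, rng=random.Random(seed))


def make_world(config: ScenarioConfig,
               tree: dendropy.Tree | None = None) -> SyntheticWorld:
    """Compose a full synthetic world from a scenario configuration.

    Environmental layers, a tree (random binary if not supplied), true
    niches per the scenario, disjoint rectangular Ms (vertical strips,
    mirroring allopatric breeding ranges), and occurrence samples. Fully
    deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(2**31)) for k in
             ("env", "tree", "niches", "occ")}
    rows, cols = config.raster_size
    stack = simulate_env((rows, cols), config.n_variables,
                         config.smoothness, seed=seeds["env"])
    if tree is None:
        tree = _default_tree(config.n_taxa, seeds["tree"])
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    d = config.n_variables
    root = EllipsoidModel("ancestor", np.zeros(d),
                          np.eye(d) * config.niche_width ** 2,
                          config.inclusion, stack.variables, n_fit=0,
                          seed=config.seed)

    # disjoint vertical strips as accessible areas, with a one-cell gap
    lon0, lat0 = stack.origin
    cs = stack.cell_size
    west = lon0 - cs / 2
    north = lat0 + cs / 2
    south = north - rows * cs
    strip = cols * cs / len(taxa)
    areas = {}
    for i, t in enumerate(taxa):
        x0 = west + i * strip
        x1 = west + (i + 1) * strip - (cs if i < len(taxa) - 1 else 0.0)
        areas[t] = AccessibleArea(t, box(x0, south, x1, north))

    # a taxon whose true niche has (almost) no suitable accessible cells
    # cannot exist there: redraw the niche-evolution directions, bounded
    # and deterministic
    max_attempts = 20
    for attempt in range(max_attempts):
        true_models = evolve_niches(tree, root, config.step_sd,
                                    config.scenario, offset=config.offset,
                                    seed=seeds["niches"] + attempt)
        occurrences = {}
        truth_dists = {}
        occ_rng = np.random.default_rng(seeds["occ"])
        try:
            for t in taxa:
                occ, dists = sample_occurrences(
                    true_models[t], areas[t], stack, config.n_occurrences,
                    cutoff_quantile=config.cutoff_quantile,
                    seed=int(occ_rng.integers(2**31)))
                occurrences[t] = occ
                truth_dists[t] = dists
        except ValueError:
            continue
        break
    else:
        raise ValueError(
            f"no habitable niche configuration in {max_attempts} attempts")
    seeds["niches"] += attempt
    truth_log = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
        "stage_seeds": seeds,
        "taxa": taxa,
        "true_models": {t: true_models[t].to_dict() for t in taxa},
        "true_distances": {t: truth_dists[t].tolist() for t in taxa},
    }
    return SyntheticWorld(stack, tree, true_models, areas, occurrences,
                          truth_log)


def write_world(world: SyntheticWorld, directory) -> None:
    """Persist a world in the standard pipeline formats."""
    import json
    import os

    from .io import write_env_stack, write_newick, write_occurrences, \
        write_polygons

    os.makedirs(directory, exist_ok=True)
    write_env_stack(world.stack, os.path.join(directory, "env"))
    write_newick(world.tree, os.path.join(directory, "tree.nwk"))
    write_polygons(list(world.areas.values()),
                   os.path.join(directory, "areas.geojson"))
    recs = [r for occ in world.occurrences.values() for r in occ.records]
    write_occurrences(recs, os.path.join(directory, "occurrences.csv"))
    with open(os.path.join(directory, "truth_log.json"), "w") as fh:
        json.dump(world.truth_log, fh, indent=1)
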