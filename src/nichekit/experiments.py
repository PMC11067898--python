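"""Simulation studies over synthetic worlds.

Two canned experiments back the package's statistical claims: the error
calibration of the background-similarity test (its false-divergence rate
under niche conservatism and its power under true divergence), and the
consistency of the MVE center estimate as occurrence numbers grow. Both
run entirely on simulated worlds with known truth and are fully seeded.
"""

from __future__ import annotations

import numpy as np

from .ellipsoid import fit_mve
from .envspace import extract_values
from .overlap import compare_pair
from .synthetic import ScenarioConfig, make_world


def scenario_score_rates(scenario: str, n_pairs: int = 50, n_reps: int = 50,
                         n_occurrences: int = 100, seed: int = 0,
                         **config_kw) -> dict:
    """Score distribution of the equivalency test over simulated pairs.

    Builds ``n_pairs`` independent two-taxon worlds under ``scenario``,
    fits an ellipsoid model per taxon, runs the dual background test with
    ``n_reps`` null models per direction, and tallies the -2..+2 scores.
    Under conservatism (identical true niches, disjoint Ms) the -2 rate
    estimates the test's false-divergence (type-I) rate; under divergence
    (non-intersecting true niches) it estimates power.
    """
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(n_pairs):
        world_seed = int(rng.integers(2**31))
        w = make_world(ScenarioConfig(scenario=scenario,
                                      n_occurrences=n_occurrences,
                                      seed=world_seed, **config_kw))
        models, counts = {}, {}
        for t, occ in w.occurrences.items():
            mat = extract_values(w.stack, occ.records, taxon=t)
            models[t] = fit_mve(mat.values, seed=world_seed, taxon=t,
                                variables=mat.variables)
            counts[t] = len(occ.records)
        ta, tb = list(models)
        res = compare_pair(models[ta], models[tb], w.areas[ta], w.areas[tb],
                           w.stack, counts[ta], counts[tb], n_reps=n_reps,
                           seed=int(rng.integers(2**31)))
        scores.append(res.score)
    scores = np.array(scores)
    return {
        "scores": scores,
        "minus2_rate": float((scores == -2).mean()),
        "plus2_rate": float((scores == 2).mean()),
    }


def center_recovery_errors(n_values: tuple[int, ...] = (25, 100, 400),
                           n_seeds: int = 30, seed: int = 0,
                           raster_size: tuple[int, int] = (160, 160),
                           subsets_per_point: int = 50) -> dict[int, float]:
    """Mean MVE center error (environmental units) versus occurrence count.

    For each n, builds ``n_seeds`` conservatism worlds on a large
    landscape (so the pool of suitable cells does not limit the
    estimate), fits the ellipsoid model to each first taxon's sample with
    a resampling budget proportional to n (as robust-covariance
    implementations conventionally scale their subset counts), and
    averages the Euclidean error to the true niche center. Consistency of
    the estimator shows as errors decreasing with n. The same worlds
    (paired seeds) are reused across the n values.
    """
    rng = np.random.default_rng(seed)
    base = int(rng.integers(2**30))
    out = {}
    for n in n_values:
        errs = []
        for k in range(n_seeds):
            w = make_world(ScenarioConfig(n_occurrences=n,
                                          raster_size=raster_size,
                                          seed=base + k))
            t = next(iter(w.occurrences))
            mat = extract_values(w.stack, w.occurrences[t].records, taxon=t)
            fit = fit_mve(mat.values, seed=0, n_subsets=subsets_per_point * n)
            errs.append(float(np.linalg.norm(fit.center
                                             - w.true_models[t].center)))
        out[n] = float(np.mean(errs))
    return out
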