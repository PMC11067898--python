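import itertools
import math

import numpy as np
import pytest
from scipy import stats

from nichekit import EllipsoidNicheModel, binary_map, fit_mve, \
    gamma_thresholds, mahalanobis_raster
from nichekit.ellipsoid import suitability_from_distance
from nichekit.io import EnvStack


from oracles import mve_oracle_2d


class TestFitMVE:
    def test_coverage_invariant(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            X = rng.standard_normal((40, 3))
            m = fit_mve(X, inclusion=0.9, seed=seed)
            inside = (m.mahalanobis(X) <= 1.0 + 1e-12).sum()
            assert inside >= math.ceil(0.9 * 40)

    def test_1d_interval_matches_exhaustive_search(self):
        X = np.arange(10, dtype=float).reshape(-1, 1)
        m = fit_mve(X, inclusion=0.9, seed=0)
        d = m.mahalanobis(X)
        assert (d <= 1 + 1e-12).sum() >= 9
        half_width = math.sqrt(m.shape[0, 0])
        # oracle: best 9-point window over the sorted values
        xs = np.sort(X[:, 0])
        best = min((xs[i + 8] - xs[i]) / 2 for i in range(2))
        assert half_width <= best + 1e-9

    def test_circle_inclusion_1_recovers_center(self):
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        X = np.column_stack([3 + 2 * np.cos(theta), -1 + 2 * np.sin(theta)])
        m = fit_mve(X, inclusion=1.0, seed=0)
        assert np.allclose(m.center, [3, -1], atol=1e-6)
        assert np.allclose(m.mahalanobis(X), 1.0, atol=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_volume_equals_subset_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        X = rng.standard_normal((n, 2))
        m = fit_mve(X, inclusion=0.9, seed=seed)
        got = np.sqrt(np.linalg.det(m.shape))
        assert got == pytest.approx(mve_oracle_2d(X, 0.9), rel=1e-9)

    def test_volume_nondecreasing_in_inclusion(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 2))
        vols = [fit_mve(X, inclusion=q, seed=3).volume()
                for q in (0.75, 0.90, 1.0)]
        assert vols[0] <= vols[1] <= vols[2]

    def test_affine_invariance_of_distances(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 2))
        A = np.array([[2.0, 0.5], [0.0, 1.5]])
        b = np.array([10.0, -4.0])
        m1 = fit_mve(X, seed=5)
        m2 = fit_mve(X @ A.T + b, seed=5)
        assert np.allclose(m1.mahalanobis(X),
                           m2.mahalanobis(X @ A.T + b), atol=1e-8)

    def test_singular_input_errors(self):
        with pytest.raises(ValueError):
            fit_mve(np.ones((10, 2)))
        with pytest.raises(ValueError):
            fit_mve(np.zeros((2, 2)))

    def test_estimator_api(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 2))
        est = EllipsoidNicheModel(inclusion=0.9, random_state=1).fit(X)
        assert est.center_.shape == (2,)
        assert est.predict(X).sum() >= 45
        s = est.score_samples(X)
        assert np.all((s > 0) & (s <= 1))
        assert est.get_params()["inclusion"] == 0.9


class TestMahalanobisRaster:
    def make_stack(self, values):
        # values: (rows, cols, d)
        layers = {f"v{i}": values[:, :, i] for i in range(values.shape[2])}
        return EnvStack(layers, (0.0, 10.0), 1.0)

    def test_center_cell_distance_zero_suitability_one(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 2))
        m = fit_mve(X, seed=0)
        vals = np.zeros((1, 1, 2))
        vals[0, 0] = m.center
        sr = mahalanobis_raster(m, self.make_stack(vals))
        assert sr.distance[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert sr.suitability[0, 0] == pytest.approx(1.0)

    def test_identity_shape_unit_offset(self):
        from nichekit import EllipsoidModel
        m = EllipsoidModel("t", np.zeros(2), np.eye(2), 0.9, ["v0", "v1"], 5, 0)
        vals = np.zeros((1, 1, 2))
        vals[0, 0] = [1.0, 0.0]
        sr = mahalanobis_raster(m, self.make_stack(vals))
        assert sr.distance[0, 0] == pytest.approx(1.0)
        assert sr.suitability[0, 0] == pytest.approx(math.exp(-0.5))

    def test_matches_per_cell_loop_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((25, 2))
        m = fit_mve(X, seed=2)
        vals = rng.standard_normal((5, 5, 2))
        stack = self.make_stack(vals)
        sr = mahalanobis_raster(m, stack)
        inv = np.linalg.inv(m.shape)
        for r in range(5):
            for c in range(5):
                delta = vals[r, c] - m.center
                expect = math.sqrt(delta @ inv @ delta)
                assert sr.distance[r, c] == pytest.approx(expect, abs=1e-10)

    def test_na_cells_stay_na(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((25, 2))
        m = fit_mve(X, seed=2)
        vals = rng.standard_normal((4, 4, 2))
        vals[1, 2, 0] = np.nan
        sr = mahalanobis_raster(m, self.make_stack(vals))
        assert np.isnan(sr.distance[1, 2]) and np.isnan(sr.suitability[1, 2])

    def test_suitability_monotone_in_distance(self):
        d = np.linspace(0, 5, 50)
        s = suitability_from_distance(d)
        assert np.all(np.diff(s) < 0)
        assert s[0] == 1.0


class TestGammaThresholds:
    def make_identity_model(self):
        from nichekit import EllipsoidModel
        return EllipsoidModel("t", np.zeros(1), np.eye(1), 0.9, ["v0"], 5, 0)

    def test_exponential_distances_recover_unit_shape(self):
        # distances ~ Exponential(1) = Gamma(shape 1, rate 1)
        rng = np.random.default_rng(0)
        m = self.make_identity_model()
        x = rng.exponential(1.0, size=10000).reshape(-1, 1)
        ts = gamma_thresholds(m, x)
        assert ts.gamma_shape == pytest.approx(1.0, abs=0.05)
        assert ts.quantile_thresholds[0.75] == pytest.approx(-math.log(0.25),
                                                             abs=0.05)

    def test_constant_distances_error(self):
        m = self.make_identity_model()
        with pytest.raises(ValueError, match="degenerate|constant"):
            gamma_thresholds(m, np.full((10, 1), 2.0))

    def test_cutoffs_strictly_increase(self):
        rng = np.random.default_rng(1)
        m = self.make_identity_model()
        ts = gamma_thresholds(m, rng.gamma(2.0, 1.0, 500).reshape(-1, 1))
        cuts = [ts.quantile_thresholds[q]
                for q in sorted(ts.quantile_thresholds)]
        assert np.all(np.diff(cuts) > 0)

    def test_too_few_distances_error(self):
        m = self.make_identity_model()
        with pytest.raises(ValueError, match="at least 5"):
            gamma_thresholds(m, np.array([[1.0], [2.0]]))


class TestBinaryMap:
    def setup_method(self):
        from nichekit.ellipsoid import SuitabilityRaster, ThresholdSet
        dist = np.array([[0.5, 1.5, 3.0]])
        self.sr = SuitabilityRaster((0, 0), 1.0, dist,
                                    suitability_from_distance(dist))
        self.ts = ThresholdSet(1.0, 1.0, {0.75: 1.386, 0.95: 2.996})

    def test_thresholds_nest(self):
        lo = binary_map(self.sr, self.ts, 0.75)
        hi = binary_map(self.sr, self.ts, 0.95)
        assert np.all(hi[lo == 1] == 1)

    def test_exponential_cutoff_toy_counts(self):
        # cutoff -ln(0.25) ~= 1.386 keeps exactly the 0.5-distance cell
        assert binary_map(self.sr, self.ts, 0.75).sum() == 1
        assert binary_map(self.sr, self.ts, 0.95).sum() == 2

    def test_zero_distance_raster_all_suitable(self):
        from nichekit.ellipsoid import SuitabilityRaster
        sr = SuitabilityRaster((0, 0), 1.0, np.zeros((2, 2)), np.ones((2, 2)))
        assert binary_map(sr, self.ts, 0.75).sum() == 4

    def test_unknown_quantile_errors(self):
        with pytest.raises(KeyError):
            binary_map(self.sr, self.ts, 0.5)

    def test_na_preserved(self):
        self.sr.distance[0, 1] = np.nan
        out = binary_map(self.sr, self.ts, 0.75)
        assert np.isnan(out[0, 1])
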