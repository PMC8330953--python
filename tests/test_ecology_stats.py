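import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
import skbio.stats.distance as skbio_distance

from pitfoam.ecology_stats import (
    bray_curtis,
    fit_env_surface,
    nmds,
    permanova,
)
from oracles import bray_curtis_brute, permanova_exact_p_brute, permanova_f_brute


def _euclidean_dm(points, ids=None):
    ids = ids or [str(i) for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        X = np.array([[1.0, 1.0], [2.0, 2.0]])
        assert np.asarray(bray_curtis(X).data)[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert np.asarray(bray_curtis(X).data)[0, 1] == 1.0

    def test_direct_formula(self):
        X = np.array([[2.0, 1.0], [2.0, 3.0]])
        assert np.asarray(bray_curtis(X).data)[0, 1] == pytest.approx(0.25)

    def test_matches_brute_force_oracle(self, rng):
        X = rng.random((7, 9))
        D = np.asarray(bray_curtis(X).data)
        np.testing.assert_allclose(D, bray_curtis_brute(X), atol=1e-12)

    def test_scale_invariance_on_relative_abundances(self, rng):
        # a common rescaling leaves BC unchanged; per-sample scalings do
        # too once samples are renormalized to relative abundance
        X = rng.random((6, 5)) + 0.1
        a = np.asarray(bray_curtis(X).data)
        np.testing.assert_allclose(
            a, np.asarray(bray_curtis(3.7 * X).data), atol=1e-12
        )
        rel = X / X.sum(axis=0)
        scales = rng.uniform(0.5, 5.0, 5)
        scaled_rel = (X * scales) / (X * scales).sum(axis=0)
        np.testing.assert_allclose(
            np.asarray(bray_curtis(rel).data),
            np.asarray(bray_curtis(scaled_rel).data),
            atol=1e-12,
        )

    def test_all_zero_sample_is_error(self):
        with pytest.raises(ValueError):
            bray_curtis(np.array([[1.0, 0.0], [1.0, 0.0]]))


class TestPermanova:
    def test_matches_skbio_statistic(self, rng):
        pts = rng.normal(0, 1, (15, 3))
        dm = _euclidean_dm(pts)
        groups = np.array(["a"] * 7 + ["b"] * 8)
        mine = permanova(dm, groups, n_perm=99, seed=0)
        ref = skbio_distance.permanova(dm, groups, permutations=99)
        assert mine.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-12)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        pts = rng.normal(0, 1, (6, 2))
        pts[3:] += 1.5
        dm = _euclidean_dm(pts)
        groups = ["x", "x", "x", "y", "y", "y"]
        res = permanova(dm, np.array(groups), method="exact")
        expected = permanova_exact_p_brute(np.asarray(dm.data), groups)
        assert res.p_value == pytest.approx(expected, abs=0)
        assert res.pseudo_F == pytest.approx(
            permanova_f_brute(np.asarray(dm.data), groups), rel=1e-12
        )

    def test_separated_clouds_r2_near_one(self, rng):
        cloud = rng.normal(0, 0.01, (8, 2))
        pts = np.vstack([cloud, cloud + 100.0])
        dm = _euclidean_dm(pts)
        groups = np.array(["a"] * 8 + ["b"] * 8)
        res = permanova(dm, groups, n_perm=199, seed=1)
        assert res.R2 > 0.999
        assert res.p_value == pytest.approx(1 / 200)

    def test_r2_invariant_to_permutation_count(self, rng):
        pts = rng.normal(0, 1, (12, 2))
        dm = _euclidean_dm(pts)
        groups = np.array(["a"] * 6 + ["b"] * 6)
        r1 = permanova(dm, groups, n_perm=9, seed=0).R2
        r2 = permanova(dm, groups, n_perm=199, seed=5).R2
        assert r1 == pytest.approx(r2, abs=0)

    def test_reproducible_under_seed(self, rng):
        pts = rng.normal(0, 1, (12, 2))
        dm = _euclidean_dm(pts)
        groups = np.array(["a"] * 6 + ["b"] * 6)
        p1 = permanova(dm, groups, n_perm=99, seed=42).p_value
        p2 = permanova(dm, groups, n_perm=99, seed=42).p_value
        assert p1 == p2

    def test_stratified_guard_against_pseudoreplication(self, rng):
        """Texture constant within farms + farm strata -> p == 1."""
        pts = rng.normal(0, 1, (12, 2))
        pts[6:] += 5  # texture difference confounded with farm
        dm = _euclidean_dm(pts)
        texture = np.array(["foam"] * 6 + ["no-foam"] * 6)
        farm = np.array(["f1"] * 3 + ["f2"] * 3 + ["f3"] * 3 + ["f4"] * 3)
        res = permanova(dm, texture, n_perm=99, strata=farm, seed=0)
        assert res.p_value == 1.0

    def test_single_group_is_error(self, rng):
        dm = _euclidean_dm(rng.normal(0, 1, (4, 2)))
        with pytest.raises(ValueError):
            permanova(dm, np.array(["a"] * 4))


class TestNmds:
    def test_recovers_planar_configuration(self, rng):
        pts = rng.normal(0, 1, (10, 2))
        res = nmds(_euclidean_dm(pts), k=2, n_restarts=2, seed=0)
        assert res.stress <= 0.01

    def test_stress_monotone_in_dimensions(self, rng):
        pts = rng.normal(0, 1, (9, 5))
        dm = _euclidean_dm(pts)
        s2 = nmds(dm, k=2, n_restarts=2, seed=0).stress
        s8 = nmds(dm, k=8, n_restarts=2, seed=0).stress
        assert s8 <= s2 + 1e-9

    def test_deterministic_under_seed(self, rng):
        pts = rng.normal(0, 1, (8, 4))
        dm = _euclidean_dm(pts)
        a = nmds(dm, k=2, n_restarts=3, seed=7)
        b = nmds(dm, k=2, n_restarts=3, seed=7)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_stress_history_non_increasing(self, rng):
        pts = rng.normal(0, 1, (12, 6))
        res = nmds(_euclidean_dm(pts), k=2, n_restarts=1, seed=0)
        hist = res.stress_history
        assert (np.diff(hist) <= 1e-12).all()

    def test_stress_invariant_to_rotation(self, rng):
        pts = rng.normal(0, 1, (10, 4))
        dm = _euclidean_dm(pts)
        res = nmds(dm, k=2, n_restarts=2, seed=0)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        from pitfoam.ecology_stats import _condensed, _config_distances
        from scipy.optimize import isotonic_regression

        def stress_of(X):
            delta = _condensed(np.asarray(dm.data))
            d = _config_distances(X)
            order = np.lexsort((np.arange(len(delta)), delta))
            dhat = np.empty_like(d)
            dhat[order] = isotonic_regression(d[order]).x
            dhat *= np.sqrt((d**2).sum() / (dhat**2).sum())
            return np.sqrt(((d - dhat) ** 2).sum() / (d**2).sum())

        assert stress_of(res.coordinates @ R) == pytest.approx(
            stress_of(res.coordinates), abs=1e-9
        )

    def test_k_too_large_is_error(self, rng):
        dm = _euclidean_dm(rng.normal(0, 1, (5, 2)))
        with pytest.raises(ValueError):
            nmds(dm, k=5)


class TestEnvSurface:
    def test_exact_quadratic_recovered(self, rng):
        coords = rng.normal(0, 1, (40, 2))
        env = 1 + 2 * coords[:, 0] - 0.5 * coords[:, 1] ** 2 + coords[:, 0] * coords[:, 1]
        fit = fit_env_surface(coords, env)
        assert fit.R2 == pytest.approx(1.0, abs=1e-9)

    def test_independent_env_low_r2(self, rng):
        coords = rng.normal(0, 1, (500, 2))
        env = rng.normal(0, 1, 500)
        assert fit_env_surface(coords, env).R2 < 0.05

    def test_constant_env_r2_zero(self, rng):
        coords = rng.normal(0, 1, (30, 2))
        assert fit_env_surface(coords, np.full(30, 3.7)).R2 == 0.0

    def test_missing_env_rows_dropped(self, rng):
        coords = rng.normal(0, 1, (30, 2))
        env = 1 + coords[:, 0]
        env[:5] = np.nan
        fit = fit_env_surface(coords, env)
        assert np.isnan(fit.fitted[:5]).all()
        assert fit.R2 == pytest.approx(1.0, abs=1e-9)

    def test_too_few_samples_is_error(self, rng):
        with pytest.raises(ValueError):
            fit_env_surface(rng.normal(0, 1, (4, 2)), np.arange(4.0))
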