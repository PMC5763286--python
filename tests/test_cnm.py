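"""Cluster Newton solver: sampling, SSR, affine surrogate, update, loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbpkcnm.cnm import (
    CNMConfig,
    Cluster,
    ConstraintMask,
    cnm_update,
    fit_linear_map,
    run_cnm,
    sample_initial_cluster,
    ssr,
)
from pbpkcnm.parameters import BoundBox


def toy_bounds(n, lo=1e-3, hi=1e3):
    return BoundBox(np.full(n, lo), np.full(n, hi))


def affine_forward(A, b):
    def forward(x):
        return A @ x + b
    return forward


def evaluated_cluster(points, forward, target, config):
    from pbpkcnm.cnm import _evaluate

    return _evaluate(forward, points, target, config, iteration=0)


class TestSampling:
    def test_samples_respect_bounds_and_mask(self):
        bounds = BoundBox(np.full(10, 0.1), np.full(10, 10.0))
        mask = ConstraintMask(np.array([3]), np.array([1.7]))
        cfg = CNMConfig(n_points=500, seed=7)
        pts = sample_initial_cluster(bounds, mask, cfg)
        assert pts.shape == (500, 10)
        assert bounds.contains(pts).all()
        assert np.all(pts[:, 3] == 1.7)

    def test_log_uniform_median_near_geometric_mean(self):
        # on [0.1, 10] the log-uniform median is the geometric mean 1.0
        bounds = BoundBox(np.array([0.1]), np.array([10.0]))
        cfg = CNMConfig(n_points=10_000, seed=3)
        pts = sample_initial_cluster(bounds, ConstraintMask.empty(), cfg)
        assert 0.8 <= np.median(pts) <= 1.25

    def test_reproducible_under_seed(self):
        bounds = toy_bounds(5)
        cfg = CNMConfig(n_points=50, seed=11)
        a = sample_initial_cluster(bounds, ConstraintMask.empty(), cfg)
        b = sample_initial_cluster(bounds, ConstraintMask.empty(), cfg)
        np.testing.assert_array_equal(a, b)

    def test_all_fixed_mask_rejected(self):
        bounds = toy_bounds(3)
        mask = ConstraintMask(np.arange(3), np.ones(3))
        with pytest.raises(ValueError):
            sample_initial_cluster(bounds, mask, CNMConfig(n_points=5))


class TestSSR:
    def test_exact_match_is_zero(self):
        t = np.array([2.0, 3.0, 4.0])
        assert ssr(t, t) == 0.0

    def test_hand_computed_relative_residuals(self):
        assert ssr(np.array([1.1, 0.9]), np.array([1.0, 1.0])) == pytest.approx(0.02)

    def test_scale_invariance_of_relative_mode(self):
        calc = np.array([1.2, 0.7, 5.0])
        tgt = np.array([1.0, 1.0, 4.0])
        assert ssr(calc, tgt) == pytest.approx(ssr(10 * calc, 10 * tgt))

    def test_zero_target_rejected(self):
        with pytest.raises(ValueError):
            ssr(np.ones(2), np.array([1.0, 0.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssr(np.ones(3), np.ones(2))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.1, 100), min_size=1, max_size=13),
           st.floats(0.5, 2.0))
    def test_relative_ssr_invariant_under_joint_scaling(self, target, factor):
        tgt = np.asarray(target)
        calc = tgt * 1.1
        assert ssr(factor * calc, factor * tgt) == pytest.approx(ssr(calc, tgt))


class TestAffineSurrogate:
    def _exact_instance(self, rng, n_points=40, n_free=4, n_obs=3):
        A = rng.normal(size=(n_obs, n_free))
        b = rng.normal(size=n_obs)
        pts = rng.uniform(1.0, 5.0, size=(n_points, n_free))
        obs = pts @ A.T + b
        cfg = CNMConfig(n_points=n_points, sampling="linear", residual="absolute")
        cluster = Cluster(points=pts, observables=obs,
                          ssr=np.zeros(n_points), ok=np.ones(n_points, bool))
        return A, b, cluster, cfg

    def test_exact_affine_map_recovered(self, rng):
        A, b, cluster, cfg = self._exact_instance(rng)
        A_fit, b_fit = fit_linear_map(cluster, np.arange(4), cfg)
        np.testing.assert_allclose(A_fit, A, atol=1e-8)
        np.testing.assert_allclose(b_fit, b, atol=1e-8)

    def test_constant_observables_give_zero_slope(self, rng):
        _, _, cluster, cfg = self._exact_instance(rng)
        cluster.observables[:] = np.array([4.0, 5.0, 6.0])
        A_fit, b_fit = fit_linear_map(cluster, np.arange(4), cfg)
        np.testing.assert_allclose(A_fit, 0.0, atol=1e-10)
        np.testing.assert_allclose(b_fit, [4.0, 5.0, 6.0])

    def test_matches_normal_equations_oracle(self, rng):
        # independent solve of the normal equations on a tiny instance
        n_points, n_free, n_obs = 5, 2, 2
        pts = rng.uniform(1.0, 3.0, size=(n_points, n_free))
        obs = rng.normal(size=(n_points, n_obs))
        cfg = CNMConfig(n_points=n_points, sampling="linear", residual="absolute")
        cluster = Cluster(points=pts, observables=obs,
                          ssr=np.zeros(n_points), ok=np.ones(n_points, bool))
        A_fit, b_fit = fit_linear_map(cluster, np.arange(n_free), cfg)
        X = np.column_stack([pts, np.ones(n_points)])
        beta = np.linalg.solve(X.T @ X, X.T @ obs)
        np.testing.assert_allclose(A_fit, beta[:-1].T, atol=1e-8)
        np.testing.assert_allclose(b_fit, beta[-1], atol=1e-8)

    def test_too_few_points_rejected(self, rng):
        A, b, cluster, cfg = self._exact_instance(rng, n_points=3, n_free=4)
        with pytest.raises(ValueError, match="successful points"):
            fit_linear_map(cluster, np.arange(4), cfg)


class TestUpdate:
    def _setup(self, rng, ds, eta=0.0, n_free=6, n_obs=3, cutoff=1e-10):
        A = rng.normal(size=(n_obs, n_free))
        b = rng.normal(size=n_obs)
        forward = affine_forward(A, b)
        bounds = BoundBox(np.full(n_free, 1e-6), np.full(n_free, 1e6))
        cfg = CNMConfig(n_points=30, ds=ds, eta=eta, sampling="linear",
                        residual="absolute", svd_cutoff=cutoff, seed=5)
        # points and target centred well inside the box so the min-norm
        # Newton displacement never reaches a bound (no clipping at play)
        pts = rng.uniform(100.0, 110.0, size=(30, n_free))
        target = forward(rng.uniform(102.0, 108.0, size=n_free))
        cluster = evaluated_cluster(pts, forward, target, cfg)
        return A, b, cluster, target, cfg, bounds

    def test_one_step_solves_affine_problem(self, rng):
        # pseudoinverse identity: with a full-row-rank affine map, eta=0 and
        # dS=0 the post-update predicted residual vanishes
        A, b, cluster, target, cfg, bounds = self._setup(rng, ds=0.0)
        new = cnm_update(cluster, A, b, target, cfg, ConstraintMask.empty(),
                         bounds, np.random.default_rng(0))
        resid = new @ A.T + b - target
        assert np.abs(resid).max() < 1e-6

    def test_matches_pseudoinverse_oracle(self, rng):
        A, b, cluster, target, cfg, bounds = self._setup(rng, ds=0.0)
        new = cnm_update(cluster, A, b, target, cfg, ConstraintMask.empty(),
                         bounds, np.random.default_rng(0))
        oracle = cluster.points + (target - cluster.observables) @ np.linalg.pinv(A).T
        np.testing.assert_allclose(new, oracle, rtol=1e-8)

    def test_ds_one_freezes_cluster(self, rng):
        A, b, cluster, target, cfg, bounds = self._setup(rng, ds=1.0)
        new = cnm_update(cluster, A, b, target, cfg, ConstraintMask.empty(),
                         bounds, np.random.default_rng(0))
        np.testing.assert_array_equal(new, cluster.points)

    def test_ds_damps_displacement_linearly(self, rng):
        # dS = 0.2 moves every coordinate 0.8x the full Newton displacement
        A, b, cluster, target, cfg, bounds = self._setup(rng, ds=0.0)
        full = cnm_update(cluster, A, b, target, cfg, ConstraintMask.empty(),
                          bounds, np.random.default_rng(0))
        import dataclasses

        cfg_damped = dataclasses.replace(cfg, ds=0.2)
        damped = cnm_update(cluster, A, b, target, cfg_damped,
                            ConstraintMask.empty(), bounds,
                            np.random.default_rng(0))
        np.testing.assert_allclose(damped - cluster.points,
                                   0.8 * (full - cluster.points), rtol=1e-10)

    def test_fixed_coordinates_never_move(self, rng):
        A, b, cluster, target, cfg, bounds = self._setup(rng, ds=0.0)
        mask = ConstraintMask(np.array([1, 4]), np.array([102.5, 103.5]))
        cluster.points[:, [1, 4]] = [102.5, 103.5]
        A_free = A[:, mask.free_indices(6)]  # surrogate fit spans free coords
        new = cnm_update(cluster, A_free, b, target, cfg, mask, bounds,
                         np.random.default_rng(0))
        assert np.all(new[:, 1] == 102.5)
        assert np.all(new[:, 4] == 103.5)

    def test_update_clips_to_bounds(self, rng):
        A, b, cluster, target, cfg, bounds = self._setup(rng, ds=0.0)
        tight = BoundBox(np.full(6, 0.5), np.full(6, 2.0))
        new = cnm_update(cluster, A, b, target, cfg, ConstraintMask.empty(),
                         tight, np.random.default_rng(0))
        assert tight.contains(new).all()


class TestRunCNM:
    def test_linear_toy_collapses_in_three_iterations(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        b = np.array([0.5, -0.3])
        truth = np.array([3.0, 4.0])
        target = A @ truth + b
        bounds = BoundBox(np.full(2, 1e-3), np.full(2, 1e3))
        cfg = CNMConfig(n_points=50, iterations=3, ds=0.0, eta=0.0,
                        sampling="linear", residual="absolute",
                        svd_cutoff=1e-12, seed=9)
        history = run_cnm(affine_forward(A, b), target, bounds, config=cfg)
        assert history[-1].median_ssr() < 1e-4 * history[0].median_ssr()

    def test_bounds_hold_at_every_iteration(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(2, 3))
        bounds = BoundBox(np.full(3, 0.5), np.full(3, 5.0))
        cfg = CNMConfig(n_points=30, iterations=4, ds=0.2, sampling="linear",
                        residual="absolute", seed=2)
        history = run_cnm(affine_forward(A, np.zeros(2)),
                          np.array([10.0, -3.0]), bounds, config=cfg)
        for cluster in history:
            assert bounds.contains(cluster.points).all()

    def test_mask_columns_constant_across_iterations(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(2, 4))
        bounds = toy_bounds(4, 0.1, 10.0)
        mask = ConstraintMask(np.array([0, 2]), np.array([1.3, 0.7]))
        cfg = CNMConfig(n_points=25, iterations=3, ds=0.2, sampling="linear",
                        residual="absolute", seed=2)
        history = run_cnm(affine_forward(A, np.zeros(2)), np.array([2.0, 1.0]),
                          bounds, mask, cfg)
        for cluster in history:
            assert np.all(cluster.points[:, 0] == 1.3)
            assert np.all(cluster.points[:, 2] == 0.7)

    def test_bitwise_reproducible_under_seed(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(3, 4))
        bounds = toy_bounds(4, 0.1, 10.0)
        cfg = CNMConfig(n_points=20, iterations=3, seed=77, sampling="log")
        target = np.abs(A @ np.ones(4)) + 1.0
        h1 = run_cnm(affine_forward(A, np.zeros(3)), target, bounds, config=cfg)
        h2 = run_cnm(affine_forward(A, np.zeros(3)), target, bounds, config=cfg)
        np.testing.assert_array_equal(h1[-1].points, h2[-1].points)
        np.testing.assert_array_equal(h1[-1].ssr, h2[-1].ssr)

    def test_failed_points_resampled_within_bounds(self):
        rng = np.random.default_rng(12)
        A = rng.normal(size=(2, 3))
        bounds = toy_bounds(3, 0.1, 10.0)

        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            if calls["n"] % 5 == 0:
                return None
            return A @ x

        cfg = CNMConfig(n_points=20, iterations=2, sampling="log", seed=1)
        history = run_cnm(flaky, np.array([2.0, 1.0]), bounds, config=cfg)
        for cluster in history:
            assert bounds.contains(cluster.points).all()
            assert cluster.n_ok >= 10

    def test_median_ssr_decreases_on_nonlinear_toy(self):
        # mildly nonlinear positive forward map, ten independent seeds
        def forward(x):
            return np.array([x[0] * x[1] ** 0.5, x[0] ** 0.7 + x[1],
                             3.0 * x[1] / x[0] ** 0.3])

        bounds = toy_bounds(2, 0.1, 10.0)
        target = forward(np.array([2.0, 0.8]))
        for seed in range(10):
            cfg = CNMConfig(n_points=40, iterations=5, ds=0.2, seed=seed)
            history = run_cnm(forward, target, bounds, config=cfg)
            assert history[-1].median_ssr() < history[0].median_ssr()
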