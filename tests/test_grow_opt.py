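"""Growth rule, perpendicular-descent optimizers, smoothing, budget ledger."""

import math

import numpy as np
import pytest

from mfepath import fixtures as fx
from mfepath.cv_model import CVSpace
from mfepath.exceptions import DegenerateDirectionError
from mfepath.grow_opt import (GrowConfig, OptimizeConfig, QuasiNewtonOptimizer,
                              bend_objective_value, budget, grow_path,
                              grow_step, growth_direction, optimize_path,
                              perp_component, sd_sweep, sigma_perp,
                              sigma_perp_from_components, smooth_path,
                              variable_step_controller, _evaluate_gradients)
from mfepath.path_model import Path, interpolate_linear
from mfepath.surfaces import AnalyticSurface

EUCLID2 = CVSpace.euclidean(2)


class FlatSurface:
    has_value = True
    n = 2

    def value(self, chi):
        return 0.0

    def gradient(self, chi):
        return np.zeros(2)


class TestGrowthDirection:
    def test_zero_gradient_points_at_product(self):
        d = growth_direction(np.zeros(2), np.array([0.0, 0.0]),
                             np.array([0.0, 2.0]), w=3.0, space=EUCLID2)
        np.testing.assert_allclose(d, [0.0, 1.0], atol=1e-12)

    def test_hand_evaluated_blend(self):
        d = growth_direction(np.array([0.0, 1.0]), np.array([0.0, 0.0]),
                             np.array([1.0, 0.0]), w=1.0, space=EUCLID2)
        np.testing.assert_allclose(d, [0.70711, -0.70711], atol=1e-5)
        raw = growth_direction(np.array([0.0, 1.0]), np.array([0.0, 0.0]),
                               np.array([1.0, 0.0]), w=1.0, space=EUCLID2, raw=True)
        np.testing.assert_allclose(raw, [1.0, -1.0], atol=1e-12)

    def test_angle_to_product_shrinks_monotonically_in_w(self):
        grad = np.array([1.0, 2.0])
        end, prod = np.array([0.0, 0.0]), np.array([1.0, 0.0])
        angles = []
        for w in (0.5, 1.0, 2.0, 5.0, 20.0, 100.0):
            d = growth_direction(grad, end, prod, w, space=EUCLID2)
            angles.append(math.acos(np.clip(np.dot(d, [1.0, 0.0]), -1, 1)))
        assert all(a > b for a, b in zip(angles, angles[1:]))

    def test_exact_cancellation_raises(self):
        # gradient equals w * unit pull -> zero resultant
        with pytest.raises(DegenerateDirectionError):
            growth_direction(np.array([2.0, 0.0]), np.array([0.0, 0.0]),
                             np.array([1.0, 0.0]), w=2.0, space=EUCLID2)


class TestGrowStep:
    def test_product_appended_when_within_step(self):
        path = Path(np.array([[0.0, 0.0], [0.5, 0.0]]), EUCLID2, complete=False)
        cfg = GrowConfig(s_g=0.6, w=1.0, sweeps=0)
        newpath, finished, _ = grow_step(path, FlatSurface(), cfg,
                                         np.array([1.0, 0.0]))
        assert finished
        np.testing.assert_allclose(newpath.points[-1], [1.0, 0.0])
        assert newpath.complete

    def test_flat_surface_growth_is_straight_and_counts_steps(self):
        reactant = np.array([0.0, 0.0])
        product = np.array([1.0, 0.75])   # distance 1.25, not a multiple of s_g
        cfg = GrowConfig(s_g=0.2, w=5.0, sweeps=2, s_op=0.01)
        res = grow_path(reactant, product, FlatSurface(), cfg, space=EUCLID2)
        dist = np.linalg.norm(product - reactant)
        expected_appends = math.ceil(dist / cfg.s_g)
        assert res.path.m == expected_appends + 1
        # collinearity: every snapshot on the straight segment
        t = res.path.points @ (product / dist)
        off = res.path.points - np.outer(t, product / dist)
        assert np.max(np.abs(off)) < 1e-10

    def test_grown_path_avoids_the_barrier(self, ala_scenario, straight_path_40):
        surf = ala_scenario.surface
        cfg = GrowConfig(s_g=0.102, w=10.0, sweeps=2, s_op=0.002)
        res = grow_path(ala_scenario.reactant, ala_scenario.product, surf,
                        cfg, space=ala_scenario.space)
        grown_max = max(surf.value(p) for p in res.path.points)
        straight_max = max(surf.value(p) for p in straight_path_40.points)
        assert grown_max < straight_max


class TestPerpComponent:
    def test_parallel_gradient_vanishes(self):
        s = np.array([1.0, 0.0])
        np.testing.assert_allclose(perp_component(3.0 * s, s), 0.0, atol=1e-12)

    def test_orthogonal_gradient_reversed(self):
        p = perp_component(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        np.testing.assert_allclose(p, [-1.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_orthogonality_for_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.normal(size=4)
        t = rng.normal(size=4)
        t /= np.linalg.norm(t)
        assert abs(np.dot(perp_component(g, t), t)) < 1e-12

    def test_non_unit_tangent_rejected(self):
        with pytest.raises(ValueError):
            perp_component(np.ones(2), np.array([1.0, 1.0]))


class TestSdSweep:
    def test_stationary_on_a_descent_line(self):
        # straight path along the gradient line of a harmonic bowl
        surf = AnalyticSurface("harmonic", k=2.0, center=[0.0, 0.0])
        path = interpolate_linear(np.array([-1.0, 0.0]), np.array([1.0, 0.0]),
                                  9, space=EUCLID2)
        out = sd_sweep(path, surf, s_op=0.01)
        assert np.max(np.linalg.norm(out.points - path.points, axis=1)) < 1e-10

    def test_saddle_symmetry_keeps_snapshots_on_axis(self):
        scen = fx.saddle_quadratic()
        path = interpolate_linear(scen.reactant, scen.product, 11, space=scen.space)
        out = sd_sweep(path, scen.surface, s_op=0.01)
        assert np.max(np.abs(out.points[:, 1])) < 1e-12

    def test_one_sweep_lowers_total_free_energy(self, ala_scenario, straight_path_40):
        surf = ala_scenario.surface
        before = sum(surf.value(p) for p in straight_path_40.points)
        out = sd_sweep(straight_path_40, surf, s_op=0.002)
        after = sum(surf.value(p) for p in out.points)
        assert after < before

    def test_anchors_never_move(self, ala_scenario, straight_path_40):
        out = sd_sweep(straight_path_40, ala_scenario.surface, s_op=0.01)
        np.testing.assert_array_equal(out.points[0], straight_path_40.points[0])
        np.testing.assert_array_equal(out.points[-1], straight_path_40.points[-1])


class TestVariableStep:
    def test_halved_on_improvement_as_published(self):
        assert variable_step_controller([10.0, 9.0], 0.004, 0.004) == 0.002

    def test_reset_on_worsening_as_published(self):
        assert variable_step_controller([9.0, 10.0], 0.001, 0.004) == 0.004

    def test_no_history_keeps_step(self):
        assert variable_step_controller([10.0], 0.003, 0.004) == 0.003

    def test_inverted_flag_applies_conventional_rule(self):
        assert variable_step_controller([10.0, 9.0], 0.004, 0.004,
                                        inverted=True) == 0.004
        assert variable_step_controller([9.0, 10.0], 0.004, 0.004,
                                        inverted=True) == 0.002


class TestQuasiNewton:
    def test_first_iteration_reduces_to_sd_step(self, ala_scenario, straight_path_40):
        surf = ala_scenario.surface
        cfg = OptimizeConfig(method="quasi_newton", s_step=1.0, smooth_steps=0)
        qn = QuasiNewtonOptimizer(cfg)
        grads = _evaluate_gradients(straight_path_40, surf)
        out_qn = qn.sweep(straight_path_40, surf, grads=grads)
        out_sd = sd_sweep(straight_path_40, surf, s_op=1.0, grads=grads)
        np.testing.assert_allclose(out_qn.points, out_sd.points, atol=1e-10)

    def test_converges_faster_than_fixed_sd(self, ala_scenario, straight_path_40):
        surf = ala_scenario.surface
        res_qn = optimize_path(straight_path_40, surf,
                               OptimizeConfig(method="quasi_newton", s_step=0.2,
                                              max_iter=50, sigma_rel_threshold=None))
        res_sd = optimize_path(straight_path_40, surf,
                               OptimizeConfig(method="sd_fixed", s_op=0.002,
                                              max_iter=50, sigma_rel_threshold=None))
        assert res_qn.sigma_trace[-1] < res_sd.sigma_trace[-1]


class TestSmoothing:
    def test_straight_path_is_a_fixed_point(self):
        path = interpolate_linear(np.zeros(2), np.array([2.0, 0.0]), 6,
                                  space=EUCLID2)
        assert bend_objective_value(path) == 0.0
        out = smooth_path(path, steps=50)
        np.testing.assert_allclose(out.points, path.points, atol=1e-12)

    def test_right_angle_elbow_objective_and_descent(self):
        path = Path(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]]), EUCLID2)
        f0 = bend_objective_value(path)
        assert f0 == pytest.approx((np.pi / 2) ** 2, abs=1e-12)
        out = smooth_path(path, steps=200, step_size=1e-3)
        assert bend_objective_value(out) < f0

    @pytest.mark.parametrize("seed", range(3))
    def test_objective_never_increases(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.uniform(0.05, 0.4, size=(12, 2)), axis=0)
        path = Path(pts, EUCLID2)
        f0 = bend_objective_value(path)
        out = smooth_path(path, steps=500, step_size=1e-3)
        assert bend_objective_value(out) <= f0

    def test_anchors_fixed(self):
        path = Path(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]]), EUCLID2)
        out = smooth_path(path, steps=100, step_size=1e-3)
        np.testing.assert_array_equal(out.points[0], path.points[0])
        np.testing.assert_array_equal(out.points[-1], path.points[-1])


class TestSigmaPerp:
    def test_zero_components(self):
        assert sigma_perp_from_components(np.zeros((4, 2)), 2, 4) == 0.0

    def test_single_snapshot_hand_value(self):
        val = sigma_perp_from_components(np.array([[3.0, 4.0]]), 2, 1)
        assert val == pytest.approx(np.sqrt(25.0 / 2.0), abs=1e-12)
        assert val == pytest.approx(3.5355, abs=1e-4)

    def test_squared_reading_available(self):
        val = sigma_perp_from_components(np.array([[3.0, 4.0]]), 2, 1, squared=True)
        assert val == pytest.approx(12.5)

    def test_declines_to_small_fraction_on_fixture(self, ala_scenario,
                                                   straight_path_40):
        surf = ala_scenario.surface
        res = optimize_path(straight_path_40, surf,
                            OptimizeConfig(method="sd_fixed", s_op=0.002,
                                           max_iter=1500,
                                           sigma_rel_threshold=0.05))
        assert res.converged
        assert res.sigma_trace[-1] < 0.05 * res.sigma_trace[0]


class TestBudget:
    def test_full_path_protocol_matches_published_accounting(self):
        led = budget(40, protocol="full_path", iterations=200, sampling_ps=3)
        assert led.simulations == 8000
        assert float(led.total_ns) == 24.0
        assert float(led.steps_per_snapshot) == 6.0e5

    def test_growing_protocol_matches_published_accounting(self):
        led = budget(40, protocol="growing", sweeps=2, sampling_ps=3)
        assert led.simulations == 1640  # 2 x (40 + 40*39/2)
        assert float(led.total_ns) == 4.92
        assert float(led.steps_per_snapshot) == 1.23e5

    def test_single_snapshot_growth_degenerate(self):
        led = budget(1, protocol="growing", sweeps=2, sampling_ps=3)
        assert led.simulations == 2  # the lone growth event's sweeps

    def test_counts_are_exact_integers(self):
        led = budget(33, protocol="growing", sweeps=3, sampling_ps=0.7,
                     timestep_fs=0.5)
        assert isinstance(led.simulations, int)
        assert led.simulations == 3 * 33 * 34 // 2
        # totals are rational arithmetic, no float drift
        assert led.total_ns * 1000 == led.simulations * led.sampling_ps

    def test_actual_grow_driver_matches_ledger_scale(self):
        # the driver's gradient evaluations track the k * sum(i) accounting
        reactant = np.array([0.0, 0.0])
        product = np.array([2.0, 0.0])
        cfg = GrowConfig(s_g=0.21, w=5.0, sweeps=2, s_op=0.01)
        res = grow_path(reactant, product, FlatSurface(), cfg, space=EUCLID2)
        m = res.path.m
        led = budget(m, protocol="growing", sweeps=2, sampling_ps=3)
        # exact up to the lone reactant-gradient evaluation that seeds growth
        assert abs(res.gradient_evaluations - led.simulations) <= cfg.sweeps + 1
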