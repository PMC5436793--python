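"""Constrained dynamics: SHAKE, Z matrix, mean-force estimator, corrections."""

import numpy as np
import pytest

from mfepath import fixtures as fx
from mfepath.constants import KB
from mfepath.cv_model import CVSpec, CVVector
from mfepath.toy_md import (HarmonicWell, LambdaEstimate, MDConfig, ToySystem,
                            endpoint_correction, mean_force_field,
                            relax_to_constraints, run_constrained,
                            shake_correct, z_matrix)

K = fx.HARMONIC_TOY_K
CENTER = fx.HARMONIC_TOY_CENTER


@pytest.fixture(scope="module")
def harmonic_system():
    return fx.harmonic_particle_2cv()


class TestZMatrix:
    def test_coordinate_cvs_give_inverse_mass_identity(self, harmonic_system):
        zm = z_matrix(harmonic_system, harmonic_system.initial_coords)
        np.testing.assert_allclose(zm.matrix, np.eye(2) / 12.0, atol=1e-15)
        assert zm.determinant == pytest.approx(1.0 / 144.0)
        assert not zm.singular

    def test_distance_cv_reduced_mass(self):
        system = fx.two_atom_distance_system()
        zm = z_matrix(system, system.initial_coords)
        assert zm.matrix.shape == (1, 1)
        assert zm.matrix[0, 0] == pytest.approx(1 / 12.0 + 1 / 16.0)

    def test_duplicated_cv_specs_flagged_singular(self):
        spec = CVSpec("coordinate", ((0,),), axis=0)
        system = ToySystem(masses=np.array([12.0]),
                           potential=HarmonicWell(1.0, np.zeros((1, 3))),
                           cv_specs=(spec, spec))
        zm = z_matrix(system, system.initial_coords)
        assert zm.determinant == pytest.approx(0.0, abs=1e-15)
        assert zm.singular


class TestShake:
    def test_already_satisfied_constraints_noop(self, harmonic_system):
        cfg = MDConfig()
        coords = harmonic_system.initial_coords.copy()
        targets = harmonic_system.cv_values(coords)
        out, lam = shake_correct(harmonic_system, coords, coords, targets, cfg)
        np.testing.assert_array_equal(out, coords)
        np.testing.assert_array_equal(lam, 0.0)

    def test_linear_constraint_solved_in_one_pass(self):
        spec = CVSpec("coordinate", ((0,),), axis=0)
        system = ToySystem(masses=np.array([1.0]),
                           potential=HarmonicWell(0.0, np.zeros((1, 3))),
                           cv_specs=(spec,))
        cfg = MDConfig()
        drifted = np.array([[0.1, 0.0, 0.0]])
        out, lam = shake_correct(system, drifted, np.zeros((1, 3)),
                                 np.array([0.0]), cfg)
        assert abs(out[0, 0]) <= cfg.shake_tol
        assert lam[0] != 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_residuals_within_tolerance_after_random_perturbations(self, seed):
        system = fx.two_atom_distance_system()
        cfg = MDConfig()
        rng = np.random.default_rng(seed)
        ref = relax_to_constraints(system, np.array([2.0]), cfg)
        perturbed = ref + rng.normal(scale=0.05, size=ref.shape)
        out, _ = shake_correct(system, perturbed, ref, np.array([2.0]), cfg)
        resid = system.cv_values(out) - 2.0
        assert np.max(np.abs(resid)) <= 1e-8


class TestRunConstrained:
    def test_harmonic_mean_force_closed_form(self, harmonic_system):
        cfg = MDConfig(production_steps=2000, seed=11)
        target = np.array([1.1, -0.8])
        est = run_constrained(harmonic_system, target, cfg)
        expected = K * (target - CENTER[0, :2])
        # the separable harmonic multiplier is exact and temperature-free
        np.testing.assert_allclose(est.lambda_mean, expected,
                                   atol=3 * np.max(est.lambda_se) + 1e-9)
        assert est.n_samples == 2000

    def test_ignorable_coordinate_has_zero_mean_force(self):
        # potential independent of y; constrain y anyway
        k = np.array([[2.0, 0.0, 2.0]])
        specs = (CVSpec("coordinate", ((0,),), axis=0),
                 CVSpec("coordinate", ((0,),), axis=1))
        system = ToySystem(masses=np.array([12.0]),
                           potential=HarmonicWell(k, np.zeros((1, 3))),
                           cv_specs=specs)
        cfg = MDConfig(production_steps=1500, seed=4)
        est = run_constrained(system, np.array([0.3, 0.7]), cfg)
        assert abs(est.lambda_mean[1]) <= 3 * est.lambda_se[1] + 1e-9

    def test_same_seed_bit_identical(self, harmonic_system):
        cfg = MDConfig(production_steps=500, seed=21)
        a = run_constrained(harmonic_system, np.array([0.9, 0.1]), cfg)
        b = run_constrained(harmonic_system, np.array([0.9, 0.1]), cfg)
        np.testing.assert_array_equal(a.lambda_mean, b.lambda_mean)
        np.testing.assert_array_equal(a.lambda_se, b.lambda_se)
        assert a.z_inv_sqrt_mean == b.z_inv_sqrt_mean

    def test_velocity_verlet_agrees_on_harmonic_mean(self, harmonic_system):
        target = np.array([0.7, 0.2])
        expected = K * (target - CENTER[0, :2])
        cfg = MDConfig(production_steps=1000, seed=5, integrator="velocity_verlet")
        est = run_constrained(harmonic_system, target, cfg)
        np.testing.assert_allclose(est.lambda_mean, expected, atol=1e-9)


class TestMeanForceField:
    def test_gradient_matches_harmonic_closed_form(self, harmonic_system):
        cfg = MDConfig(production_steps=1000, seed=7)
        field = mean_force_field(harmonic_system, cfg)
        chi = np.array([0.8, -0.1])
        g = field.gradient(chi)
        np.testing.assert_allclose(g, K * (chi - CENTER[0, :2]), atol=1e-9)
        assert field.has_value is False

    def test_zero_gradient_at_the_minimum(self, harmonic_system):
        cfg = MDConfig(production_steps=800, seed=8)
        field = mean_force_field(harmonic_system, cfg)
        g = field.gradient(CENTER[0, :2])
        np.testing.assert_allclose(g, 0.0, atol=1e-9)

    def test_distinct_seeds_differ_but_pool_to_closed_form(self):
        # anharmonically coupled toy: the multiplier genuinely fluctuates
        system = fx.coupled_particle_2cv()
        target = np.array([0.4, -0.2])
        closed = fx.coupled_lambda_x_closed_form(0.4)
        samples = []
        for seed in range(8):
            cfg = MDConfig(production_steps=4000, seed=300 + seed)
            samples.append(run_constrained(system, target, cfg).lambda_mean[0])
        samples = np.array(samples)
        assert np.unique(samples).size == samples.size
        pooled_se = samples.std(ddof=1) / np.sqrt(samples.size)
        assert abs(samples.mean() - closed) <= 3 * pooled_se


class TestThermodynamicIntegration:
    def test_straight_segment_recovers_harmonic_delta_f(self, harmonic_system):
        # trapezoid TI of <lambda> along a straight segment; the integrand is
        # linear in chi so the quadrature is exact up to sampling noise
        a = np.array([0.2, -0.1])
        b = np.array([1.4, 0.6])
        npts = 5
        chis = np.linspace(0, 1, npts)[:, None] * (b - a)[None, :] + a[None, :]
        lams = []
        for i, chi in enumerate(chis):
            cfg = MDConfig(production_steps=800, seed=50 + i)
            lams.append(run_constrained(harmonic_system, chi, cfg).lambda_mean)
        lams = np.array(lams)
        seg = (b - a) / (npts - 1)
        ti = sum(0.5 * np.dot(lams[i] + lams[i + 1], seg) for i in range(npts - 1))
        c = CENTER[0, :2]
        exact = 0.5 * K * (np.sum((b - c) ** 2) - np.sum((a - c) ** 2))
        assert ti == pytest.approx(exact, abs=1e-8)

    def test_correction_term_much_smaller_than_mean_force_term(self, harmonic_system):
        a = np.array([0.2, -0.1])
        b = np.array([1.4, 0.6])
        cfg_a = MDConfig(production_steps=500, seed=60)
        cfg_b = MDConfig(production_steps=500, seed=61)
        est_a = run_constrained(harmonic_system, a, cfg_a)
        est_b = run_constrained(harmonic_system, b, cfg_b)
        term2 = endpoint_correction(est_b, 298.0) - endpoint_correction(est_a, 298.0)
        c = CENTER[0, :2]
        term1 = 0.5 * K * (np.sum((b - c) ** 2) - np.sum((a - c) ** 2))
        assert abs(term2) < abs(term1)


class TestEndpointCorrection:
    def _estimate(self, zmean):
        space_vec = CVVector(np.zeros(2),
                             fx.harmonic_particle_2cv().space)
        return LambdaEstimate(lambda_mean=np.zeros(2), lambda_se=np.zeros(2),
                              n_samples=1, z_inv_sqrt_mean=zmean,
                              target=space_vec)

    def test_unit_mean_gives_zero(self):
        assert endpoint_correction(self._estimate(1.0), 298.0) == 0.0

    def test_mean_e_gives_minus_kbt(self):
        corr = endpoint_correction(self._estimate(np.e), 298.0)
        assert corr == pytest.approx(-KB * 298.0)
        assert corr == pytest.approx(-0.5922, abs=5e-4)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            endpoint_correction(self._estimate(0.0), 298.0)
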