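"""Reduced-polynomial hyperelasticity: closed form, fitting, pre-stretch."""

import numpy as np
import pytest

from tetherdic.materials import (PrestretchSpec, ReducedPolynomialModel,
                                 apply_prestretch, fit_reduced_polynomial,
                                 lamina_curve, uniaxial_nominal_stress)
from tetherdic.tensile import StressStrainCurve


@pytest.fixture(scope="module")
def two_term_model():
    return ReducedPolynomialModel(2, [0.3, 1.0], "posterior")


class TestUniaxialStress:
    def test_zero_strain_zero_stress(self, two_term_model):
        assert uniaxial_nominal_stress(two_term_model, 0.0) == pytest.approx(0.0)

    def test_neo_hookean_closed_form(self):
        m = ReducedPolynomialModel(1, [0.5])
        lam = 1.1
        expected = 2 * 0.5 * (lam - lam ** -2)
        assert uniaxial_nominal_stress(m, lam - 1) == pytest.approx(expected, rel=1e-12)

    def test_matches_symbolic_energy_derivative(self, two_term_model):
        """P(lambda) equals dW/dlambda of the incompressible strain energy
        (independent sympy oracle)."""
        import sympy as sp

        lam = sp.symbols("lam", positive=True)
        C1, C2 = two_term_model.coefficients
        i1 = lam ** 2 + 2 / lam
        W = C1 * (i1 - 3) + C2 * (i1 - 3) ** 2
        dW = sp.lambdify(lam, sp.diff(W, lam), "numpy")
        for lv in (1.01, 1.05, 1.1, 1.2, 1.5):
            ours = uniaxial_nominal_stress(two_term_model, lv - 1.0)
            assert ours == pytest.approx(float(dW(lv)), rel=1e-8)

    def test_small_strain_limit_six_c10(self):
        m = ReducedPolynomialModel(1, [0.5])
        h = 1e-7
        slope = (uniaxial_nominal_stress(m, h) - uniaxial_nominal_stress(m, -h)) / (2 * h)
        assert slope == pytest.approx(6 * 0.5, rel=1e-5)


class TestFit:
    def test_noiseless_coefficients_recovered(self, two_term_model):
        eps = np.linspace(0.0, 0.12, 80)
        c = StressStrainCurve(eps, uniaxial_nominal_stress(two_term_model, eps))
        m = fit_reduced_polynomial(c, order=2)
        assert np.allclose(m.coefficients, [0.3, 1.0], atol=1e-6)
        assert m.r2 > 1 - 1e-12

    def test_fit_predict_roundtrip(self, two_term_model):
        eps = np.linspace(0.0, 0.1, 50)
        sig = uniaxial_nominal_stress(two_term_model, eps)
        m = fit_reduced_polynomial(StressStrainCurve(eps, sig), order=2)
        assert np.allclose(uniaxial_nominal_stress(m, eps), sig, atol=1e-9)

    def test_linear_small_strain_gives_e_over_six(self):
        E = 3.0
        eps = np.linspace(0.0, 0.01, 60)
        m = fit_reduced_polynomial(StressStrainCurve(eps, E * eps), order=1)
        assert m.c10 == pytest.approx(E / 6.0, rel=0.01)

    def test_noisy_recovery_median_bias(self, two_term_model):
        """2% multiplicative noise, 100 seeds: median coefficient bias < 5%."""
        eps = np.linspace(0.005, 0.12, 80)
        sig0 = uniaxial_nominal_stress(two_term_model, eps)
        coefs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            sig = sig0 * (1 + rng.normal(0, 0.02, len(sig0)))
            coefs.append(fit_reduced_polynomial(
                StressStrainCurve(eps, sig), order=2).coefficients)
        med = np.median(coefs, axis=0)
        assert np.all(np.abs(med / [0.3, 1.0] - 1.0) < 0.05)

    def test_negative_c10_raises(self):
        eps = np.linspace(0.0, 0.1, 40)
        with pytest.raises(ValueError, match="C_10"):
            fit_reduced_polynomial(StressStrainCurve(eps, -2.0 * eps), order=1)

    def test_model_json_roundtrip(self, two_term_model):
        m = ReducedPolynomialModel.from_json(two_term_model.to_json())
        assert m.order == 2 and np.allclose(m.coefficients, [0.3, 1.0])


class TestPrestretch:
    def test_zero_shift_identity(self):
        c = StressStrainCurve(np.linspace(0, 0.1, 20), np.linspace(0, 1, 20))
        out = apply_prestretch(c, PrestretchSpec(0.0))
        assert np.array_equal(out.strain, c.strain)
        assert np.array_equal(out.stress_mpa, c.stress_mpa)

    def test_five_percent_translation(self):
        c = StressStrainCurve(np.linspace(0, 0.1, 20), np.linspace(0, 1, 20))
        out = apply_prestretch(c, 0.05)
        assert np.allclose(out.strain, c.strain + 0.05)
        assert np.array_equal(out.stress_mpa, c.stress_mpa)

    def test_additivity(self):
        c = StressStrainCurve(np.linspace(0, 0.1, 20), np.linspace(0, 1, 20))
        twice = apply_prestretch(apply_prestretch(c, 0.025), 0.025)
        once = apply_prestretch(c, 0.05)
        assert np.allclose(twice.strain, once.strain)

    def test_negative_shift_raises(self):
        with pytest.raises(ValueError):
            PrestretchSpec(-0.01)


class TestLaminaCurve:
    def test_identical_inputs_identity(self):
        c = StressStrainCurve(np.linspace(0.0, 0.1, 30), np.linspace(0, 2, 30), "ON")
        out = lamina_curve(c, c)
        assert np.allclose(np.interp(c.strain, out.strain, out.stress_mpa),
                           c.stress_mpa, atol=1e-9)
        assert out.region_label == "lamina_cribrosa"

    def test_linear_average(self):
        eps = np.linspace(0.0, 0.1, 30)
        out = lamina_curve(StressStrainCurve(eps, 2 * eps, "ON"),
                           StressStrainCurve(eps, 4 * eps, "peripapillary"))
        assert np.allclose(out.stress_mpa, 3 * out.strain, atol=1e-12)

    def test_bounded_by_inputs(self):
        eps = np.linspace(0.001, 0.1, 50)
        on = StressStrainCurve(eps, 0.5 * eps ** 1.2, "ON")
        pps = StressStrainCurve(eps, 3.0 * eps ** 1.05, "peripapillary")
        out = lamina_curve(on, pps)
        lo = np.minimum(np.interp(out.strain, on.strain, on.stress_mpa),
                        np.interp(out.strain, pps.strain, pps.stress_mpa))
        hi = np.maximum(np.interp(out.strain, on.strain, on.stress_mpa),
                        np.interp(out.strain, pps.strain, pps.stress_mpa))
        assert np.all(out.stress_mpa >= lo - 1e-12)
        assert np.all(out.stress_mpa <= hi + 1e-12)

    def test_disjoint_ranges_raise(self):
        a = StressStrainCurve(np.linspace(0, 0.05, 10), np.linspace(0, 1, 10))
        b = StressStrainCurve(np.linspace(0.06, 0.1, 10), np.linspace(0, 1, 10))
        with pytest.raises(ValueError):
            lamina_curve(a, b)
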