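"""Linear-response layer: chi_a, step responses and the bilobed chi_b."""

import numpy as np
import pytest

from blswitch.model_core import ModelParams
from blswitch.response import (ResponseModel, chi_a_laplace, chi_a_time,
                               chi_b_numeric, chi_b_time,
                               nonlinear_step_response, response_table,
                               step_response)
from conftest import random_stable_params


@pytest.fixture
def fig10_model():
    # low-ligand operating point of the bilobed-response figure
    params = ModelParams(A0=13.6, R0=0.224).with_ell(0.2)
    return ResponseModel.from_params(params, lambda_Y=30.0, H=20.0,
                                     Pcw_star=0.5)


class TestRateConstants:
    def test_root_identities(self, rng):
        # A+B = -tr(beta), A*B = det(beta)
        for _ in range(10):
            p = random_stable_params(rng)
            m = ResponseModel.from_params(p)
            A, B = m.rates_AB
            tr = m.beta[0, 0] + m.beta[1, 1]
            det = np.linalg.det(m.beta)
            assert A + B == pytest.approx(-tr, rel=1e-12)
            assert A * B == pytest.approx(det, rel=1e-10)
            assert A.real > 0 and B.real > 0

    def test_rates_are_negated_eigenvalues(self, fig10_model):
        A, B = fig10_model.rates_AB
        eig = np.sort_complex(-np.linalg.eigvals(fig10_model.beta))
        np.testing.assert_allclose(sorted([A, B], key=abs),
                                   np.sort(eig)[::1], rtol=1e-10)


class TestChiALaplace:
    def test_zero_area_perfect_adaptation(self, rng):
        # chi_a~(0) = 0 for any stable operating point
        for _ in range(20):
            p = random_stable_params(rng)
            m = ResponseModel.from_params(p)
            assert abs(chi_a_laplace(0.0, m)) < 1e-8

    def test_high_frequency_limit(self, fig10_model):
        m = fig10_model
        p = m.params
        expected = -p.KL * m.fp.xi.xi1 / (p.L + p.KL) ** 2
        assert chi_a_laplace(1e9, m) == pytest.approx(expected, rel=1e-6)

    def test_pole_rejected(self, fig10_model):
        A, _ = fig10_model.rates_AB
        with pytest.raises(ZeroDivisionError):
            chi_a_laplace(-A, fig10_model)

    def test_matches_transform_of_time_domain(self, fig10_model):
        # quadrature Laplace transform of chi_a(t) (continuous part plus
        # the instantaneous term) matches the closed form
        m = fig10_model
        t = np.linspace(0.0, 4000.0, 400_001)
        chi = chi_a_time(m, t)
        _, _, cd = m._ligation_weights
        for s in (0.1, 1.0, 10.0):
            quad = np.trapezoid(chi * np.exp(-s * t), t) - cd
            assert quad == pytest.approx(chi_a_laplace(s, m), rel=1e-4,
                                         abs=1e-9)


class TestStepResponse:
    def test_zero_step_is_flat(self, fig10_model):
        t = np.linspace(0, 50, 20)
        assert np.all(step_response(fig10_model, 0.0, t) == 0.0)

    def test_adaptation_returns_to_baseline(self, fig10_model):
        # the slowest relaxation rate here is ~2e-3 1/s, so by t = 1e4 s
        # the activity has recovered to a tiny fraction of the initial dip
        m = fig10_model
        dL = 1e-3 * (m.params.L + m.params.KL)
        resp = step_response(m, dL, [0.5, 5.0, 1e4])
        assert abs(resp[-1]) < 1e-6 * abs(resp[0])

    def test_immediate_response_is_deligation_term(self, fig10_model):
        m = fig10_model
        dL = 1e-4
        r0 = step_response(m, dL, [1e-9])[0]
        _, _, cd = m._ligation_weights
        assert r0 == pytest.approx(-cd * dL, rel=1e-6)

    def test_matches_nonlinear_ode(self, fig10_model):
        m = fig10_model
        dL = 1e-3 * (m.params.L + m.params.KL)
        t = np.linspace(0.0, 400.0, 60)[1:]
        lin = step_response(m, dL, t)
        nonlin = nonlinear_step_response(m.params, dL, t)
        scale = np.abs(nonlin).max()
        np.testing.assert_allclose(lin, nonlin, atol=1e-2 * scale)


class TestChiB:
    def test_closed_form_matches_numerical_convolution(self, rng):
        for _ in range(10):
            p = random_stable_params(rng)
            m = ResponseModel.from_params(p)
            t = np.linspace(0.0, 120.0, 600)
            closed = chi_b_time(m, t)
            numeric = chi_b_numeric(m, t)
            scale = np.abs(closed).max()
            np.testing.assert_allclose(closed, numeric, atol=1e-4 * scale)

    def test_zero_area(self, rng):
        # adaptation survives the motor cascade: integral of chi_b is 0
        for _ in range(20):
            p = random_stable_params(rng)
            m = ResponseModel.from_params(p)
            (X0, X2), (Y0, Y2), (Z0, Z2) = m.chi_b_coefficients()
            c0, c2, cd = m._ligation_weights
            A, B = m.rates_AB
            area = m.prefactor * ((-c0 * X0 + c2 * X2 - cd) / m.lambda_Y
                                  + (-c0 * Y0 + c2 * Y2) / A
                                  + (-c0 * Z0 + c2 * Z2) / B)
            assert abs(area) < 1e-8
        # adaptive quadrature cross-check on one operating point
        from scipy.integrate import quad

        m = ResponseModel.from_params(ModelParams(A0=13.6, R0=0.2,
                                                  L=0.02))
        A, B = m.rates_AB
        total, _ = quad(lambda s: chi_b_time(m, np.array([s]))[0],
                        0.0, 40.0 / min(A.real, B.real),
                        points=[1.0 / m.lambda_Y, 1.0 / A.real,
                                1.0 / B.real],
                        limit=400)
        lobe = abs(chi_b_time(m, np.array([2.0 / B.real]))[0]) / B.real
        assert abs(total) < 1e-6 * max(lobe, 1e-30)

    def test_bilobed_shape_and_ligand_dependence(self):
        # an attractant increase suppresses activity, so the clockwise
        # bias drops immediately (negative early lobe); methylation
        # adaptation overshoots into a compensating lobe of opposite
        # sign whose depth shrinks as the ligand level grows, while the
        # methylation time scales (set by the Jacobian) stay put
        base = ModelParams(A0=13.6, R0=0.224)
        t = np.linspace(0.0, 2000.0, 8001)
        depths, rates = [], []
        for ell in (0.2, 2.0, 20.0):
            m = ResponseModel.from_params(base.with_ell(ell))
            chi = chi_b_time(m, t)
            assert chi[0] < 0          # immediate tumble suppression
            assert chi.max() > 0       # compensating adaptive lobe
            i_neg_end = np.argmax(chi > 0)
            assert 0 < i_neg_end < len(t) - 1
            depths.append(chi.max())
            rates.append([r.real for r in m.rates_AB])
        # the adaptive lobe gets shallower at higher ligand levels
        assert depths[0] > depths[1] > depths[2]
        # each decay rate moves by < 2x across the same ligand span over
        # which the lobe depth changes by more than 100x
        rates = np.sort(np.array(rates), axis=1)
        spread = rates.max(axis=0) / rates.min(axis=0)
        assert (spread < 2.0).all()
        assert depths[0] / depths[2] > 100.0

    def test_response_table_csv_columns(self, fig10_model):
        df = response_table(fig10_model, np.linspace(0, 10, 11))
        assert list(df.columns) == ["t", "chi_a", "chi_b"]
        assert len(df) == 11
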