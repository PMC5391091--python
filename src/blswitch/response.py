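"""Linear response of receptor activity and motor bias to ligand changes.

A weak time-dependent attractant perturbation L -> L + dL(t) displaces
the mean level populations according to the linearized mean dynamics

    d/dt d_xi_m = sum_n beta_mn d_xi_n + gamma_m dL(t),    m, n in {0, 2},

and the mean activity through both the level shift and the
instantaneous re-ligation of the intermediate level.  The activity
response function chi_a(t) (defined by d_xi_a(t) = int chi_a(t-t')
dL(t') dt') therefore has a delta spike at t = 0 plus a two-exponential
relaxation with the decay rates of the Jacobian.  Feeding chi_a through
the CheY phosphorylation cascade (first-order, rate lambda_Y) and the
steep Hill response of the flagellar motor yields the bilobed
chemotactic response function chi_b(t) for the fractional clockwise
bias.  Perfect adaptation forces both response curves to enclose zero
area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .model_core import ModelParams
from .lna import beta_matrix, gamma_vector
from .qssa import FixedPoint, StateFractions, drift, solve_fixed_point

__all__ = ["ResponseModel", "chi_a_laplace", "step_response", "chi_a_time",
           "chi_b_time", "chi_b_numeric", "response_table"]


@dataclass(frozen=True)
class ResponseModel:
    """Operating point and coefficients of the linear response theory.

    ``A`` and ``B`` are the two (positive) decay rates of the
    methylation dynamics, the negatives of the Jacobian eigenvalues;
    the X/Y/Z coefficient pairs are the partial-fraction weights of the
    three exponentials (lambda_Y, A, B) in chi_b(t).  They may be
    complex conjugates when the Jacobian has complex eigenvalues; the
    time-domain responses are then the real parts.
    """

    params: ModelParams
    fp: FixedPoint
    beta: np.ndarray
    gamma: np.ndarray
    lambda_Y: float = 30.0    # CheYp dephosphorylation rate, 1/s
    H: float = 20.0           # motor Hill coefficient (non-adapted)
    Pcw_star: float = 0.5     # clockwise bias at the operating point

    @classmethod
    def from_params(cls, params: ModelParams, lambda_Y: float = 30.0,
                    H: float = 20.0, Pcw_star: float = 0.5,
                    simplified: bool = True) -> "ResponseModel":
        fp = solve_fixed_point(params, linearized=simplified)
        return cls(params=params, fp=fp,
                   beta=beta_matrix(fp, params, simplified=simplified),
                   gamma=gamma_vector(fp, params, simplified=simplified),
                   lambda_Y=lambda_Y, H=H, Pcw_star=Pcw_star)

    @property
    def rates_AB(self) -> tuple[complex, complex]:
        """Decay rates (A, B): roots of s^2 + tr*s + det with sign flip.

        A + B = -tr(beta) and A*B = det(beta); both have positive real
        part at a stable fixed point.
        """
        b = self.beta
        tr = b[0, 0] + b[1, 1]
        disc = np.lib.scimath.sqrt((b[0, 0] - b[1, 1]) ** 2
                                   + 4.0 * b[0, 1] * b[1, 0])
        A = -0.5 * (tr + disc)
        B = -0.5 * (tr - disc)
        return complex(A), complex(B)

    @property
    def _ligation_weights(self) -> tuple[float, float, float]:
        """(c0, c2, c_delta): weights of d_xi_0, d_xi_2 and dL in d_xi_a."""
        p = self.params
        c0 = p.KL / (p.L + p.KL)
        c2 = p.L / (p.L + p.KL)
        cd = p.KL * self.fp.xi.xi1 / (p.L + p.KL) ** 2
        return c0, c2, cd

    def _chi_m_numerators(self, s: complex) -> tuple[complex, complex]:
        b, g = self.beta, self.gamma
        n0 = (s - b[1, 1]) * g[0] + b[0, 1] * g[1]
        n2 = b[1, 0] * g[0] + (s - b[0, 0]) * g[1]
        return n0, n2

    @property
    def prefactor(self) -> float:
        """H * lambda_Y * (1 - P_CW*) / xi_a*: converts chi_a to chi_b."""
        return self.H * self.lambda_Y * (1.0 - self.Pcw_star) / self.fp.xi_a

    def chi_b_coefficients(self):
        """Partial-fraction weights of chi_b(t)/prefactor.

        Returns ((X0, X2), (Y0, Y2), (Z0, Z2)) multiplying
        exp(-lambda_Y t), exp(-A t) and exp(-B t); obtained by residue
        evaluation of chi_m(s)/(s + lambda_Y) at its three poles.
        """
        A, B = self.rates_AB
        lY = self.lambda_Y
        if A == B or lY in (A, B):
            raise ArithmeticError("degenerate decay rates; use the "
                                  "numerical convolution")
        n0A, n2A = self._chi_m_numerators(-A)
        n0B, n2B = self._chi_m_numerators(-B)
        n0Y, n2Y = self._chi_m_numerators(-lY)
        dX = (A - lY) * (B - lY)
        dY = (B - A) * (lY - A)
        dZ = (A - B) * (lY - B)
        return ((n0Y / dX, n2Y / dX), (n0A / dY, n2A / dY),
                (n0B / dZ, n2B / dZ))


def chi_a_laplace(s, model: ResponseModel) -> complex | float:
    """Laplace transform of the activity response function chi_a(t).

    chi_a~(s) = -c0*chi_0~(s) + c2*chi_2~(s) - c_delta, with
    chi_m~(s) = [(s I - beta)^-1 gamma]_m.  Perfect adaptation gives
    chi_a~(0) = 0; s -> infinity leaves only the instantaneous
    re-ligation term -c_delta.
    """
    A, B = model.rates_AB
    c0, c2, cd = model._ligation_weights
    n0, n2 = model._chi_m_numerators(s)
    d = (s + A) * (s + B)
    if abs(d) < 1e-300 or min(abs(s + A), abs(s + B)) < 1e-12 * max(
            abs(A), abs(B)):
        raise ZeroDivisionError(f"s = {s} is (numerically) a pole of the "
                                "response")
    val = -c0 * n0 / d + c2 * n2 / d - cd
    return val.real if abs(val.imag) < 1e-14 * (1 + abs(val)) else val


def step_response(model: ResponseModel, dL_s: float,
                  t_grid: np.ndarray) -> np.ndarray:
    """Mean activity shift d_xi_a(t) after a ligand step of size dL_s (uM).

    Solves the linear level dynamics with the matrix exponential:
    d_xi(t) = beta^-1 (e^{beta t} - 1) gamma dL_s, then adds the
    instantaneous re-ligation term.  Valid while |dL_s| << L + KL.
    """
    p = model.params
    if abs(dL_s) > 0.1 * (p.L + p.KL):
        import warnings

        warnings.warn("step size is not small versus L + KL; the linear "
                      "response is inaccurate", stacklevel=2)
    c0, c2, cd = model._ligation_weights
    binv_g = np.linalg.solve(model.beta, model.gamma)
    out = np.empty(len(t_grid))
    for i, t in enumerate(np.asarray(t_grid, dtype=float)):
        if t <= 0:
            out[i] = 0.0
            continue
        dxi = (expm(model.beta * t) - np.eye(2)) @ binv_g * dL_s
        out[i] = -c0 * dxi[0] + c2 * dxi[1] - cd * dL_s
    return out


def chi_a_time(model: ResponseModel, t_grid: np.ndarray) -> np.ndarray:
    """Continuous part of chi_a(t): chi_a(t) = -c_delta*delta(t) + this.

    Equal to -c0*[e^{beta t} gamma]_0 + c2*[e^{beta t} gamma]_2 for
    t > 0 (the derivative of the step response).
    """
    c0, c2, _ = model._ligation_weights
    out = np.empty(len(t_grid))
    for i, t in enumerate(np.asarray(t_grid, dtype=float)):
        v = expm(model.beta * t) @ model.gamma
        out[i] = -c0 * v[0] + c2 * v[1]
    return out


def chi_b_time(model: ResponseModel, t_grid: np.ndarray) -> np.ndarray:
    """Chemotactic (clockwise-bias) response function chi_b(t).

    Three-exponential closed form; falls back to the numerical
    convolution when the decay rates degenerate.  The curve is bilobed:
    an immediate lobe from the instantaneous de-activation by ligand,
    and a delayed opposite lobe from methylation adaptation, with equal
    areas.
    """
    t = np.asarray(t_grid, dtype=float)
    c0, c2, cd = model._ligation_weights
    lY = model.lambda_Y
    try:
        (X0, X2), (Y0, Y2), (Z0, Z2) = model.chi_b_coefficients()
    except ArithmeticError:
        import warnings

        warnings.warn("degenerate response rates; evaluating chi_b by "
                      "numerical convolution", stacklevel=2)
        return chi_b_numeric(model, t)
    A, B = model.rates_AB
    val = (np.exp(-lY * t) * (-c0 * X0 + c2 * X2 - cd)
           + np.exp(-A * t) * (-c0 * Y0 + c2 * Y2)
           + np.exp(-B * t) * (-c0 * Z0 + c2 * Z2))
    return model.prefactor * val.real


def chi_b_numeric(model: ResponseModel, t_grid: np.ndarray) -> np.ndarray:
    """chi_b(t) by direct integration of the cascade ODEs.

    Independent of the partial-fraction algebra: propagates
    z' = beta z (z(0) = gamma) together with the exponentially
    filtered activity response w' = -lambda_Y w + chi_a_cont(t),
    w(0) = -c_delta (the filtered delta spike).
    """
    c0, c2, cd = model._ligation_weights
    lY = model.lambda_Y
    beta, gamma = model.beta, model.gamma

    def rhs(_t, y):
        z0, z2, w = y
        dz = beta @ np.array([z0, z2])
        chi_cont = -c0 * z0 + c2 * z2
        return [dz[0], dz[1], -lY * w + chi_cont]

    t = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(rhs, (0.0, float(t[-1])), [gamma[0], gamma[1], -cd],
                    t_eval=t, method="LSODA", rtol=1e-10, atol=1e-14)
    return model.prefactor * sol.y[2]


def nonlinear_step_response(params: ModelParams, dL_s: float,
                            t_grid: np.ndarray,
                            linearized: bool = True) -> np.ndarray:
    """Activity shift from the full (nonlinear) mean dynamics.

    Integrates the mean equations at L + dL_s starting from the
    pre-stimulus fixed point; oracle for :func:`step_response`.
    """
    from .qssa import active_fraction

    fp = solve_fixed_point(params, linearized=linearized)
    p2 = params.replace(L=params.L + dL_s)
    xa0 = fp.xi_a

    def rhs(_t, y):
        return drift(StateFractions(*np.clip(y, 0.0, 1.0)), p2,
                     linearized=linearized)

    t = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(rhs, (0.0, float(t[-1])), [fp.xi.xi0, fp.xi.xi2],
                    t_eval=t, method="LSODA", rtol=1e-11, atol=1e-14)
    out = np.empty(len(t))
    for i in range(len(t)):
        xi = StateFractions(*np.clip(sol.y[:, i], 0.0, 1.0))
        out[i] = active_fraction(xi, p2) - xa0
    return out


def response_table(model: ResponseModel, t_grid: np.ndarray):
    """(t, chi_a, chi_b) DataFrame for CSV export."""
    import pandas as pd

    return pd.DataFrame(dict(t=np.asarray(t_grid, dtype=float),
                             chi_a=chi_a_time(model, t_grid),
                             chi_b=chi_b_time(model, t_grid)))
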