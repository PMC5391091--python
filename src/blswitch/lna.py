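"""Linear noise approximation around the deterministic fixed point.

Expanding the slow (xi_0, xi_2) Fokker-Planck dynamics to linear order
about the fixed point gives an Ornstein-Uhlenbeck process whose
stationary covariance solves the Lyapunov equation

    beta @ sigma + sigma @ beta.T + 2 D = 0,

with beta the drift Jacobian and D the (diagonal) diffusion matrix at
the fixed point.  The activity variance follows by propagating the
(xi_0, xi_2) covariance through the active-fraction map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import ModelParams, critical_R0
from .qssa import FixedPoint, StateFractions, diffusion, solve_fixed_point

__all__ = [
    "LNAResult",
    "beta_matrix",
    "gamma_vector",
    "stationary_covariance",
    "activity_variance",
    "lna_at",
    "variance_profile",
    "peak_activity_variance",
]


class StabilityError(ArithmeticError):
    """The drift Jacobian is not Hurwitz; no stationary covariance exists."""


@dataclass(frozen=True)
class LNAResult:
    """Jacobian, ligand sensitivity, noise and covariance at a fixed point."""

    fp: FixedPoint
    beta: np.ndarray      # 2x2 drift Jacobian, 1/s
    gamma: np.ndarray     # 2-vector d(drift)/dL, 1/(s uM)
    Dstar: np.ndarray     # 2-vector diffusion at the fixed point, 1/s
    sigma: np.ndarray     # 2x2 stationary covariance of (xi0', xi2')
    sigma_a2: float       # stationary variance of the active fraction


def _enzyme_partials(xi: StateFractions, p: ModelParams):
    """Exact partial derivatives of the free-enzyme map wrt xi0, xi2, L."""
    LKL = p.L + p.KL
    denR = p.Kr * LKL + p.A0 * (p.KL * xi.xi0 + p.L * (1.0 - xi.xi2))
    denB = p.Kb * LKL + p.A0 * (p.KL * (1.0 - xi.xi0) + p.L * xi.xi2)
    dRf = np.array([-p.R0 * p.Kr * LKL * p.A0 * p.KL,
                    +p.R0 * p.Kr * LKL * p.A0 * p.L]) / denR**2
    dBf = np.array([+p.B0 * p.Kb * LKL * p.A0 * p.KL,
                    -p.B0 * p.Kb * LKL * p.A0 * p.L]) / denB**2
    xi1 = xi.xi1
    dRf_dL = -p.R0 * p.Kr * p.A0 * p.KL * xi1 / denR**2
    dBf_dL = +p.B0 * p.Kb * p.A0 * p.KL * xi1 / denB**2
    return dRf, dBf, dRf_dL, dBf_dL


def _drift_partials(fp: FixedPoint, p: ModelParams, simplified: bool):
    """Partials of (v0, v2) wrt (xi0, xi2), (Rf, Bf) and L at the fixed point.

    ``simplified=True`` uses the Rf << Kr, Bf << Kb forms in which the
    per-receptor rates are nu_r*Rf/Kr and nu_b*Bf/Kb; otherwise the full
    Michaelis factors are differentiated.
    """
    xi, Rf, Bf = fp.xi, fp.Rf, fp.Bf
    c0 = p.KL / (p.L + p.KL)
    c2 = p.L / (p.L + p.KL)
    xi1 = xi.xi1
    if simplified:
        r, b = p.nu_r * Rf / p.Kr, p.nu_b * Bf / p.Kb
        dr_dRf = p.nu_r / p.Kr
        db_dBf = p.nu_b / p.Kb
    else:
        r = p.nu_r * Rf / (Rf + p.Kr)
        b = p.nu_b * Bf / (Bf + p.Kb)
        dr_dRf = p.nu_r * p.Kr / (Rf + p.Kr) ** 2
        db_dBf = p.nu_b * p.Kb / (Bf + p.Kb) ** 2
    # v0 = b*c0*xi1 - r*xi0 ; v2 = r*c2*xi1 - b*xi2
    dv_dxi = np.array([[-(b * c0 + r), -b * c0],
                       [-r * c2, -(r * c2 + b)]])
    dv_dRf = np.array([-dr_dRf * xi.xi0, dr_dRf * c2 * xi1])
    dv_dBf = np.array([db_dBf * c0 * xi1, -db_dBf * xi.xi2])
    # direct L dependence through the ligation weights c0, c2
    dc0 = -p.KL / (p.L + p.KL) ** 2
    dc2 = +p.KL / (p.L + p.KL) ** 2
    dv_dL = np.array([b * dc0 * xi1, r * dc2 * xi1])
    return dv_dxi, dv_dRf, dv_dBf, dv_dL


def beta_matrix(fp: FixedPoint, params: ModelParams,
                simplified: bool = True) -> np.ndarray:
    """Drift Jacobian beta_mn = d v_m / d xi_n at the fixed point (1/s).

    Includes the indirect dependence through the free-enzyme
    sequestration, beta_mn = dv_m/dxi_n + (dv_m/dRf)(dRf/dxi_n)
    + (dv_m/dBf)(dBf/dxi_n).
    """
    dv_dxi, dv_dRf, dv_dBf, _ = _drift_partials(fp, params, simplified)
    dRf, dBf, _, _ = _enzyme_partials(fp.xi, params)
    return dv_dxi + np.outer(dv_dRf, dRf) + np.outer(dv_dBf, dBf)


def gamma_vector(fp: FixedPoint, params: ModelParams,
                 simplified: bool = True) -> np.ndarray:
    """Total ligand sensitivity gamma_m = d v_m / dL at the fixed point."""
    _, dv_dRf, dv_dBf, dv_dL = _drift_partials(fp, params, simplified)
    _, _, dRf_dL, dBf_dL = _enzyme_partials(fp.xi, params)
    return dv_dL + dv_dRf * dRf_dL + dv_dBf * dBf_dL


def stationary_covariance(beta: np.ndarray, Dstar: np.ndarray) -> np.ndarray:
    """Closed-form solution of beta@sigma + sigma@beta.T + 2D = 0 (2x2).

    Requires beta Hurwitz (both eigenvalues with negative real part).
    """
    beta = np.asarray(beta, dtype=float)
    D0, D2 = np.asarray(Dstar, dtype=float)
    b00, b02 = beta[0]
    b20, b22 = beta[1]
    tr = b00 + b22
    det = b00 * b22 - b02 * b20
    if not (tr < 0 and det > 0):
        raise StabilityError(
            f"Jacobian is not Hurwitz (tr={tr:.3g}, det={det:.3g})")
    den = tr * det
    s00 = -((b22 * tr - b02 * b20) * D0 + b02**2 * D2) / den
    s22 = -(b20**2 * D0 + (b00 * tr - b02 * b20) * D2) / den
    s02 = (b20 * b22 * D0 + b00 * b02 * D2) / den
    return np.array([[s00, s02], [s02, s22]])


def activity_variance(sigma: np.ndarray, params: ModelParams) -> float:
    """Variance of the active fraction from the (xi0, xi2) covariance.

    xi_a depends on (xi0, xi2) through (-xi0 + l*xi2)/(1+l), hence
    sigma_a^2 = (sigma00 + l^2 sigma22 - 2 l sigma02)/(1+l)^2.
    """
    ell = params.ell
    s = np.asarray(sigma)
    return float((s[0, 0] + ell**2 * s[1, 1] - 2.0 * ell * s[0, 1])
                 / (1.0 + ell) ** 2)


def lna_at(params: ModelParams, simplified: bool = True,
           linearized_fp: bool | None = None) -> LNAResult:
    """Fixed point plus full LNA summary for one parameter set.

    By default the fixed point is solved in the kinetics regime matching
    the Jacobian mode (linearized enzyme kinetics for the simplified
    analytical coefficients), so that beta is exactly the Jacobian of
    the drift whose zero defines the fixed point.
    """
    if linearized_fp is None:
        linearized_fp = simplified
    fp = solve_fixed_point(params, linearized=linearized_fp)
    beta = beta_matrix(fp, params, simplified=simplified)
    gamma = gamma_vector(fp, params, simplified=simplified)
    Dstar = diffusion(fp.xi, params, linearized=linearized_fp)
    sigma = stationary_covariance(beta, Dstar)
    return LNAResult(fp=fp, beta=beta, gamma=gamma, Dstar=Dstar, sigma=sigma,
                     sigma_a2=activity_variance(sigma, params))


def variance_profile(params: ModelParams, R0_grid, ell_grid,
                     simplified: bool = True):
    """sigma_a^2 (and covariance entries) over an (R0, ell) grid.

    Returns a DataFrame with columns (A0, R0, ell, sigma00, sigma22,
    sigma02, sigma_a2, xi_a); solver failures are recorded as NaN rows.
    """
    import pandas as pd

    rows = []
    for ell in np.atleast_1d(ell_grid):
        for R0 in np.atleast_1d(R0_grid):
            p = params.replace(R0=float(R0)).with_ell(float(ell))
            row = dict(A0=p.A0, R0=float(R0), ell=float(ell))
            try:
                res = lna_at(p, simplified=simplified)
                row.update(sigma00=res.sigma[0, 0], sigma22=res.sigma[1, 1],
                           sigma02=res.sigma[0, 1], sigma_a2=res.sigma_a2,
                           xi_a=res.fp.xi_a)
            except (ArithmeticError, RuntimeError):
                row.update(sigma00=np.nan, sigma22=np.nan, sigma02=np.nan,
                           sigma_a2=np.nan, xi_a=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def peak_activity_variance(params: ModelParams, ell: float,
                           simplified: bool = True,
                           refine: bool = True) -> tuple[float, float]:
    """(R0_peak, peak sigma_a^2) over CheR concentration at fixed ell.

    Scans a grid of R0 around the critical concentration and optionally
    refines the maximum by golden-section search.
    """
    from scipy.optimize import minimize_scalar

    p_ell = params.with_ell(ell)
    Rc = critical_R0(params)

    def f(R0: float) -> float:
        return lna_at(p_ell.replace(R0=float(R0)),
                      simplified=simplified).sigma_a2

    grid = Rc * np.linspace(0.5, 1.5, 41)
    vals = np.array([f(R0) for R0 in grid])
    i = int(np.argmax(vals))
    if not refine:
        return float(grid[i]), float(vals[i])
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(lambda x: -f(x), bounds=(lo, hi), method="bounded",
                          options={"xatol": Rc * 1e-6})
    return float(res.x), float(-res.fun)
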