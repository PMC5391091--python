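"""Quasi-steady-state reduction of the M = 2 receptor model.

Fast processes (enzyme and ligand binding, conformational switching) are
integrated out, leaving the slow methylation-level fractions
xi = (xi_0, xi_2) as the only coordinates.  This module provides the
drift and diffusion coefficients of the resulting Fokker-Planck
description, the free-enzyme self-consistency, the deterministic fixed
point, the ligand-independent (perfect-adaptation) closed form for the
steady-state activity, and the zero-order-ultrasensitivity limits.

Two variants of the enzyme kinetics are supported throughout:

* ``linearized=False`` (default): full Michaelis factors
  Rf/(Rf+Kr), Bf/(Bf+Kb) in the methylation/demethylation fluxes;
* ``linearized=True``: the Rf << Kr, Bf << Kb regime (factors Rf/Kr,
  Bf/Kb), which is the regime in which the analytical formulas for the
  fixed point and the noise coefficients are derived.

In both variants the free-enzyme concentrations use the linear
sequestration balance (free + substrate-bound = total with bound
fractions proportional to Rf resp. Bf), which is what makes them a
closed function of xi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model_core import ModelParams

__all__ = [
    "StateFractions",
    "FixedPoint",
    "free_enzymes",
    "drift",
    "diffusion",
    "active_fraction",
    "solve_fixed_point",
    "solve_fixed_point_ode",
    "perfect_adaptation_xa",
    "adaptation_quadratic_coeffs",
    "zou_limits",
    "fixed_point_sweep",
]


@dataclass(frozen=True)
class StateFractions:
    """Receptor fractions in the bottom (xi0) and top (xi2) levels."""

    xi0: float
    xi2: float

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.xi0 <= 1 + 1e-12
                and -1e-12 <= self.xi2 <= 1 + 1e-12):
            raise ValueError(f"fractions outside [0,1]: {self}")
        if self.xi0 + self.xi2 > 1 + 1e-9:
            raise ValueError(f"xi0 + xi2 > 1: {self}")

    @property
    def xi1(self) -> float:
        """Intermediate-level fraction (by normalization)."""
        return 1.0 - self.xi0 - self.xi2

    def as_array(self) -> np.ndarray:
        return np.array([self.xi0, self.xi2])


@dataclass(frozen=True)
class FixedPoint:
    """Self-consistent steady state of the mean dynamics."""

    xi: StateFractions
    Rf: float      # free CheR, uM
    Bf: float      # free CheB, uM
    xi_a: float    # active fraction
    linearized: bool = False


def free_enzymes(xi: StateFractions, params: ModelParams,
                 ) -> tuple[float, float]:
    """Free CheR and CheB concentrations (uM) at receptor state ``xi``.

    Sequestration balance: CheR is bound to inactive receptors (level 0
    plus the ligated part of the intermediate), CheB to active ones
    (level 2 plus the unligated part of the intermediate).
    """
    p = params
    LKL = p.L + p.KL
    Rf = p.R0 * p.Kr * LKL / (
        p.Kr * LKL + p.A0 * (p.KL * xi.xi0 + p.L * (1.0 - xi.xi2)))
    Bf = p.B0 * p.Kb * LKL / (
        p.Kb * LKL + p.A0 * (p.KL * (1.0 - xi.xi0) + p.L * xi.xi2))
    return Rf, Bf


def _fluxes(xi: StateFractions, params: ModelParams, linearized: bool,
            ) -> tuple[float, float, float, float]:
    """Return the four one-way methylation-level fluxes (1/s).

    Order: (demeth 1->0, meth 0->1, meth 1->2, demeth 2->1); the first
    pair feeds xi0, the second pair feeds xi2.
    """
    p = params
    Rf, Bf = free_enzymes(xi, params)
    if linearized:
        r = p.nu_r * Rf / p.Kr
        b = p.nu_b * Bf / p.Kb
    else:
        r = p.nu_r * Rf / (Rf + p.Kr)
        b = p.nu_b * Bf / (Bf + p.Kb)
    c0 = p.KL / (p.L + p.KL)      # unligated (active) weight of level 1
    c2 = p.L / (p.L + p.KL)       # ligated (inactive) weight of level 1
    xi1 = xi.xi1
    return b * c0 * xi1, r * xi.xi0, r * c2 * xi1, b * xi.xi2


def drift(xi: StateFractions, params: ModelParams,
          linearized: bool = False) -> np.ndarray:
    """Drift vector (v0, v2) of the slow dynamics, in 1/s."""
    w10, w01, w12, w21 = _fluxes(xi, params, linearized)
    return np.array([w10 - w01, w12 - w21])


def diffusion(xi: StateFractions, params: ModelParams,
              linearized: bool = False) -> np.ndarray:
    """Diffusion coefficients (D0, D2) of the slow dynamics, in 1/s.

    Each coordinate's diffusion is 1/(2N) times the sum of the two
    opposing fluxes feeding it, the finite-N shot noise of the
    methylation steps.
    """
    w10, w01, w12, w21 = _fluxes(xi, params, linearized)
    return np.array([w10 + w01, w12 + w21]) / (2.0 * params.N)


def active_fraction(xi: StateFractions, params: ModelParams) -> float:
    """Active receptor fraction xi_a = (1-xi0)/(1+l) + l*xi2/(1+l)."""
    ell = params.ell
    return (1.0 - xi.xi0) / (1.0 + ell) + ell * xi.xi2 / (1.0 + ell)


def _free_R_of_xa(xa: float, p: ModelParams) -> float:
    """Free CheR at active fraction xa (inactive substrate = 1 - xa).

    Same linear sequestration balance as :func:`free_enzymes`; the
    ligand drops out because KL*xi0 + L*(1-xi2) = (L+KL)*(1-xi_a).
    """
    return p.R0 * p.Kr / (p.Kr + p.A0 * (1.0 - xa))


def _free_B_of_xa(xa: float, p: ModelParams) -> float:
    return p.B0 * p.Kb / (p.Kb + p.A0 * xa)


def _rates_at_xa(xa: float, p: ModelParams, linearized: bool,
                 ) -> tuple[float, float, float, float]:
    Rf = _free_R_of_xa(xa, p)
    Bf = _free_B_of_xa(xa, p)
    if linearized:
        return p.nu_r * Rf / p.Kr, p.nu_b * Bf / p.Kb, Rf, Bf
    return p.nu_r * Rf / (Rf + p.Kr), p.nu_b * Bf / (Bf + p.Kb), Rf, Bf


class FixedPointError(RuntimeError):
    """Raised when the steady-state solver fails; carries the last iterate."""

    def __init__(self, msg: str, last: StateFractions | None = None):
        super().__init__(msg)
        self.last = last


def solve_fixed_point(params: ModelParams, linearized: bool = False,
                      tol: float = 1e-14) -> FixedPoint:
    """Solve for the self-consistent steady state of the mean dynamics.

    Perfect adaptation makes the problem one-dimensional: summing the
    two flux-balance conditions eliminates the ligand entirely, leaving
    a scalar equation r(xi_a)*(1 - xi_a) = b(xi_a)*xi_a for the active
    fraction, where r and b are the per-receptor methylation and
    demethylation rates at the sequestration-consistent free-enzyme
    levels.  The bracket endpoints have opposite signs, so Brent's
    method is guaranteed to converge; the level populations are then
    reconstructed from the detailed flux balances.  Falls back to direct
    time integration of the mean equations if the residual check fails.
    """
    p = params

    def h(xa: float) -> float:
        r, b, _, _ = _rates_at_xa(xa, p, linearized)
        return r * (1.0 - xa) - b * xa

    if p.R0 == 0.0 or h(0.0) <= 0.0:
        xa = 0.0
    elif h(1.0) >= 0.0:
        xa = 1.0
    else:
        xa = brentq(h, 0.0, 1.0, xtol=tol, rtol=8.9e-16, maxiter=200)

    r, b, Rf, Bf = _rates_at_xa(xa, p, linearized)
    ell = p.ell
    if r == 0.0:
        xi = StateFractions(1.0, 0.0)
    elif b == 0.0:
        xi = StateFractions(0.0, 1.0)
    else:
        q = r / b
        xi0 = 1.0 / (1.0 + (1.0 + ell) * q + ell * q * q)
        xi = StateFractions(xi0, ell * q * q * xi0)
    fp = FixedPoint(xi=xi, Rf=Rf, Bf=Bf, xi_a=active_fraction(xi, p),
                    linearized=linearized)
    resid = np.abs(drift(xi, p, linearized=linearized)).max()
    if resid > 1e-10:
        return solve_fixed_point_ode(params, linearized=linearized)
    return fp


def solve_fixed_point_ode(params: ModelParams, linearized: bool = False,
                          t_max: float = 1e6, resid_tol: float = 1e-10,
                          ) -> FixedPoint:
    """Steady state by long time integration of d(xi)/dt = v(xi).

    Used as an independent cross-check of :func:`solve_fixed_point` and
    as its fall-back.
    """
    p = params

    def rhs(_t, y):
        return drift(StateFractions(*np.clip(y, 0.0, 1.0)), p,
                     linearized=linearized)

    sol = solve_ivp(rhs, (0.0, t_max), [1.0, 0.0], method="LSODA",
                    rtol=1e-12, atol=1e-13)
    xi = StateFractions(*np.clip(sol.y[:, -1], 0.0, 1.0))
    resid = np.abs(drift(xi, p, linearized=linearized)).max()
    if resid > resid_tol:
        raise FixedPointError(
            f"steady state not reached: |v| = {resid:.3g} 1/s", xi)
    Rf, Bf = free_enzymes(xi, p)
    return FixedPoint(xi=xi, Rf=Rf, Bf=Bf, xi_a=active_fraction(xi, p),
                      linearized=linearized)


def adaptation_quadratic_coeffs(params: ModelParams,
                                ) -> tuple[float, float, float]:
    """Coefficients (a, b, c) of the ligand-free quadratic for xi_a*.

    Derived from the summed flux balance nu_r*(Rf/Kr)*(1-xi_a) =
    nu_b*(Bf/Kb)*xi_a with the linear sequestration expressions for Rf
    and Bf:

        a = A0*(nu_b*B0 - nu_r*R0)
        b = nu_r*R0*(A0 - Kb) - nu_b*B0*(Kr + A0)
        c = nu_r*R0*Kb
    """
    p = params
    a = p.A0 * (p.nu_b * p.B0 - p.nu_r * p.R0)
    b = p.nu_r * p.R0 * (p.A0 - p.Kb) - p.nu_b * p.B0 * (p.Kr + p.A0)
    c = p.nu_r * p.R0 * p.Kb
    return a, b, c


def perfect_adaptation_xa(params: ModelParams, warn_tol: float = 0.05,
                          ) -> float:
    """Closed-form steady-state active fraction (ligand independent).

    Root in [0, 1] of the adaptation quadratic; valid in the
    Rf << Kr, Bf << Kb regime (checked post hoc, warning otherwise).
    """
    import warnings

    a, b, c = adaptation_quadratic_coeffs(params)
    if params.R0 == 0.0:
        return 0.0
    if a == 0.0:    # alpha = 1: linear equation
        roots = [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise ArithmeticError("adaptation quadratic has no real root")
        sq = np.sqrt(disc)
        roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    good = [x for x in roots if -1e-12 <= x <= 1 + 1e-12]
    if not good:
        raise ArithmeticError(
            f"no adaptation root in [0,1]: roots = {roots}")
    xa = float(min(good, key=lambda x: abs(x - 0.5)))
    Rf = _free_R_of_xa(xa, params)
    Bf = _free_B_of_xa(xa, params)
    if Rf > warn_tol * params.Kr or Bf > warn_tol * params.Kb:
        warnings.warn(
            "free enzymes are not small versus their dissociation "
            "constants; the closed-form activity is approximate",
            stacklevel=2)
    return min(max(xa, 0.0), 1.0)


def zou_limits(params: ModelParams, regime: str) -> tuple | None:
    """Limiting level populations (xi0, xi1, xi2) for A0 -> infinity.

    In the low-ligand limit the top level empties and (xi0, xi1) form a
    Goldbeter-Koshland two-state switch at alpha = 1; in the high-ligand
    limit the bottom level empties and (xi1, xi2) do.  Returns ``None``
    at the critical point alpha = 1 (populations indeterminate).
    """
    from .model_core import alpha as _alpha

    if regime not in ("low_ligand", "high_ligand"):
        raise ValueError("regime must be 'low_ligand' or 'high_ligand'")
    a = _alpha(params)
    if a == 1.0:
        return None
    if regime == "low_ligand":
        return (1.0, 0.0, 0.0) if a < 1 else (0.0, 1.0, 0.0)
    return (0.0, 1.0, 0.0) if a < 1 else (0.0, 0.0, 1.0)


def fixed_point_sweep(params: ModelParams, R0_grid, ell_grid,
                      linearized: bool = False):
    """Fixed points over an (R0, ell) grid as a pandas DataFrame.

    Columns: R0, ell, A0, xi0, xi1, xi2, xi_a, Rf, Bf.
    """
    import pandas as pd

    rows = []
    for R0 in np.atleast_1d(R0_grid):
        for ell in np.atleast_1d(ell_grid):
            p = params.replace(R0=float(R0)).with_ell(float(ell))
            fp = solve_fixed_point(p, linearized=linearized)
            rows.append(dict(R0=float(R0), ell=float(ell), A0=p.A0,
                             xi0=fp.xi.xi0, xi1=fp.xi.xi1, xi2=fp.xi.xi2,
                             xi_a=fp.xi_a, Rf=fp.Rf, Bf=fp.Bf))
    return pd.DataFrame(rows)
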