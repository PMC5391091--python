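"""Linear noise approximation built directly on the reaction network.

The two-variable analytical layer (:mod:`blswitch.lna`) rests on the
quasi-steady-state reduction, whose enzyme-binding treatment (linear
sequestration, equilibrium dissociation constants) is accurate only for
deep time-scale separation.  This module provides the reference that
needs no reduction at all: the deterministic steady state of the full
mass-action network and the stationary covariance from the network-level
Lyapunov equation, with every elementary reaction contributing its own
shot noise.  It is the analytical counterpart the exact stochastic
simulation should agree with, up to genuine finite-copy-number effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve_continuous_lyapunov

from .model_core import (BIND_B, BIND_L, BIND_R, KineticRates, ModelParams,
                         ReactionNetwork, build_network)

__all__ = ["NetworkLNA", "network_lna"]


@dataclass(frozen=True)
class NetworkLNA:
    """Steady state and fluctuations of the full network."""

    network: ReactionNetwork
    conc: np.ndarray          # steady-state species concentrations, uM
    Rf: float                 # free CheR, uM
    Bf: float                 # free CheB, uM
    xi_a: float               # active receptor fraction
    cov: np.ndarray           # species covariance (fraction units)
    sigma_a2: float           # variance of the active fraction

    @property
    def level_fractions(self) -> np.ndarray:
        lev = np.array(self.network.level_of)
        A0 = self.conc.sum()
        return np.array([self.conc[lev == m].sum() / A0
                         for m in range(self.network.M + 1)])


def _fluxes(net: ReactionNetwork, conc, Rf, Bf, L):
    out = np.empty(len(net.reactions))
    for j, r in enumerate(net.reactions):
        if r.kind == BIND_R:
            f = Rf
        elif r.kind == BIND_B:
            f = Bf
        elif r.kind == BIND_L:
            f = L
        else:
            f = 1.0
        out[j] = r.rate * conc[r.reactant] * f
    return out


def _steady_state(net: ReactionNetwork, p: ModelParams, t_max: float = 5e5):
    n = net.n_species
    boundR = np.array([s.endswith(".R") for s in net.species])
    boundB = np.array([s.endswith(".B") for s in net.species])

    def rhs(_t, c):
        Rf = p.R0 - c[boundR].sum()
        Bf = p.B0 - c[boundB].sum()
        dc = np.zeros(n)
        fl = _fluxes(net, c, Rf, Bf, p.L)
        for j, r in enumerate(net.reactions):
            dc[r.reactant] -= fl[j]
            dc[r.product] += fl[j]
        return dc

    c0 = np.zeros(n)
    c0[net.index("m0")] = p.A0
    sol = solve_ivp(rhs, (0.0, t_max), c0, method="LSODA", rtol=1e-12,
                    atol=1e-14)
    c = np.clip(sol.y[:, -1], 0.0, None)
    resid = np.abs(rhs(0.0, c)).max()
    if resid > 1e-9:
        raise RuntimeError(f"network steady state not reached "
                           f"(|dc/dt| = {resid:.2g} uM/s)")
    return c, float(p.R0 - c[boundR].sum()), float(p.B0 - c[boundB].sum())


def network_lna(params: ModelParams, rates: KineticRates | None = None,
                network: ReactionNetwork | None = None) -> NetworkLNA:
    """Full-network steady state, covariance and activity variance.

    Solves the mass-action mean equations to stationarity, builds the
    Jacobian (including free-enzyme feedback through the conservation
    laws) and the reaction shot-noise matrix, eliminates the receptor
    conservation direction, and solves the Lyapunov equation in the
    reduced space.  Covariances are reported in receptor-fraction units.
    """
    p = params
    net = network if network is not None else build_network(p, rates)
    n = net.n_species
    conc, Rf, Bf = _steady_state(net, p)
    boundR = np.array([s.endswith(".R") for s in net.species])
    boundB = np.array([s.endswith(".B") for s in net.species])

    # stoichiometry and flux derivatives in concentration units
    n_rx = len(net.reactions)
    S = np.zeros((n, n_rx))
    dfdc = np.zeros((n_rx, n))
    fl = _fluxes(net, conc, Rf, Bf, p.L)
    for j, r in enumerate(net.reactions):
        S[r.reactant, j] -= 1.0
        S[r.product, j] += 1.0
        if r.kind == BIND_R:
            dfdc[j, r.reactant] += r.rate * Rf
            dfdc[j, boundR] -= r.rate * conc[r.reactant]   # dRf/dc = -1
        elif r.kind == BIND_B:
            dfdc[j, r.reactant] += r.rate * Bf
            dfdc[j, boundB] -= r.rate * conc[r.reactant]
        elif r.kind == BIND_L:
            dfdc[j, r.reactant] += r.rate * p.L
        else:
            dfdc[j, r.reactant] += r.rate
    A = S @ dfdc                       # Jacobian, 1/s
    Q = (S * fl) @ S.T / p.conversion  # shot noise, uM^2/s

    # eliminate the receptor-conservation direction (all reactions
    # conserve total receptor, so both A and Q are singular along 1)
    drop = net.index("m0")
    keep = [i for i in range(n) if i != drop]
    T = np.zeros((n, n - 1))           # full <- reduced
    for row, i in enumerate(keep):
        T[i, row] = 1.0
    T[drop, :] = -1.0                  # c_drop = A0 - sum(others)
    P = np.zeros((n - 1, n))           # reduced <- full
    for row, i in enumerate(keep):
        P[row, i] = 1.0
    A_red = P @ A @ T
    Q_red = P @ Q @ P.T
    if np.linalg.eigvals(A_red).real.max() >= 0:
        raise ArithmeticError("network Jacobian is not Hurwitz")
    C_red = solve_continuous_lyapunov(A_red, -Q_red)

    w_full = np.array(net.active_mask, dtype=float) / p.A0
    w_red = T.T @ w_full
    sigma_a2 = float(w_red @ C_red @ w_red)
    cov_full = T @ C_red @ T.T / p.A0**2
    return NetworkLNA(network=net, conc=conc, Rf=Rf, Bf=Bf,
                      xi_a=float(conc[np.array(net.active_mask)].sum()
                                 / p.A0),
                      cov=cov_full, sigma_a2=sigma_a2)
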