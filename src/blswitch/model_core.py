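"""Core definitions of the stochastic Barkai-Leibler receptor model.

A chemotaxis receptor complex (receptor + CheW + CheA) carries ``M``
methylation sites and is either kinase-*active* or *inactive*.  The
methyltransferase CheR binds inactive receptors and adds methyl groups;
the methylesterase CheB binds active receptors and removes them.  Ligand
(attractant) binding inactivates receptors in the intermediate
methylation levels; the lowest level is always inactive and the highest
always active.  This module holds the parameter containers, the
activity-probability function a_m(L), the zero-order-ultrasensitivity
control parameter alpha = R0*nu_r/(B0*nu_b), and the builder for the
full stochastic reaction network used by the Gillespie simulator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields, replace

__all__ = [
    "ModelParams",
    "KineticRates",
    "Reaction",
    "ReactionNetwork",
    "ECOLI_DEFAULTS",
    "LITERATURE_SETS",
    "literature_params",
    "activity_probability",
    "alpha",
    "critical_R0",
    "build_network",
    "load_params",
]

#: Table of baseline kinetic/concentration values for E. coli chemotaxis
#: receptor (de)methylation.  R0 and A0 are the quantities varied in the
#: ultrasensitivity study; their defaults put the system at the critical
#: enzyme ratio (alpha = 1) with an intermediate receptor abundance.
ECOLI_DEFAULTS = dict(
    V=1e-15,          # cell volume, litres
    conversion=602.3,  # particles per uM at V = 1e-15 L
    B0=0.28,          # total CheB, uM
    Kr=0.39,          # CheR dissociation constant, uM
    Kb=0.54,          # CheB dissociation constant, uM
    KL=0.1,           # ligand dissociation constant (intermediate levels), uM
    nu_r=0.75,        # methylation catalytic rate, 1/s
    nu_b=0.6,         # demethylation catalytic rate, 1/s
)

#: Literature parameter sets for the downstream CheY/motor estimates.
#: Keys a_Y (uM^-1 s^-1), lambda_Y (1/s) and Y0 (uM) belong to the
#: phosphorylation cascade; the rest override ModelParams fields.
LITERATURE_SETS = {
    "morton-firth": dict(a_Y=3.0, lambda_Y=14.15, Y0=18.0, A0=5.0,
                         R0=0.235, B0=2.27, nu_r=0.819, nu_b=0.155),
    "rao": dict(a_Y=100.0, lambda_Y=30.1, Y0=17.9, A0=5.0,
                R0=0.3, B0=2.0, nu_r=0.255, nu_b=0.5),
    "kollmann": dict(a_Y=100.0, lambda_Y=30.1, Y0=9.7, A0=5.3,
                     R0=0.16, B0=0.28, nu_r=0.39, nu_b=6.3),
}


@dataclass(frozen=True)
class ModelParams:
    """All concentrations (uM), rates (1/s) and counts of the receptor model.

    ``conversion`` is the particles-per-uM factor for the cell volume
    (602.3 at V = 1e-15 L); the receptor copy number is
    ``N = round(A0 * conversion)``.
    """

    M: int = 2
    A0: float = 13.6
    R0: float = 0.224
    B0: float = ECOLI_DEFAULTS["B0"]
    Kr: float = ECOLI_DEFAULTS["Kr"]
    Kb: float = ECOLI_DEFAULTS["Kb"]
    KL: float = ECOLI_DEFAULTS["KL"]
    nu_r: float = ECOLI_DEFAULTS["nu_r"]
    nu_b: float = ECOLI_DEFAULTS["nu_b"]
    L: float = 2.0
    V: float = ECOLI_DEFAULTS["V"]
    conversion: float = ECOLI_DEFAULTS["conversion"]

    def __post_init__(self) -> None:
        if not (isinstance(self.M, int) and self.M >= 1):
            raise ValueError(f"M must be an integer >= 1, got {self.M!r}")
        if self.L < 0:
            raise ValueError("ligand concentration L must be >= 0")
        for name in ("A0", "B0", "Kr", "Kb", "KL", "nu_r", "nu_b", "V",
                     "conversion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.R0 < 0:
            raise ValueError("R0 must be >= 0")
        if self.N < 1:
            raise ValueError("derived receptor number N must be >= 1")

    @property
    def N(self) -> int:
        """Total receptor copy number in the cell."""
        return int(round(self.A0 * self.conversion))

    @property
    def ell(self) -> float:
        """Dimensionless ligand concentration l = L/KL."""
        return self.L / self.KL

    def with_ell(self, ell: float) -> "ModelParams":
        """Return a copy at ligand level ``ell`` (L = ell*KL)."""
        return replace(self, L=ell * self.KL)

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


def literature_params(name: str, **overrides) -> tuple[ModelParams, dict]:
    """Return (ModelParams, cascade-constants dict) for a literature set.

    ``name`` is one of 'morton-firth', 'rao', 'kollmann'.  The second
    element holds a_Y, lambda_Y and Y0 for :mod:`blswitch.motor`.
    """
    try:
        vals = dict(LITERATURE_SETS[name.lower()])
    except KeyError:
        raise KeyError(f"unknown literature set {name!r}; choose from "
                       f"{sorted(LITERATURE_SETS)}") from None
    cascade = {k: vals.pop(k) for k in ("a_Y", "lambda_Y", "Y0")}
    vals.update(overrides)
    return ModelParams(**vals), cascade


@dataclass(frozen=True)
class KineticRates:
    """Individual binding/unbinding rates behind the dissociation constants.

    Only the ratios are constrained by the steady-state theory
    (Kr = k_minus/k_plus, Kb = k_minus_p/k_plus_p, KL = k_d/k_a); the
    absolute magnitudes set the time-scale separation between binding
    and catalysis in the stochastic simulation.
    """

    k_plus: float      # CheR binding, uM^-1 s^-1
    k_minus: float     # CheR unbinding, 1/s
    k_plus_p: float    # CheB binding, uM^-1 s^-1
    k_minus_p: float   # CheB unbinding, 1/s
    k_a: float         # ligand binding, uM^-1 s^-1
    k_d: float         # ligand unbinding, 1/s

    @classmethod
    def from_params(cls, params: ModelParams, k_minus: float = 10.0,
                    k_minus_p: float = 10.0, k_d: float = 100.0,
                    ) -> "KineticRates":
        """Derive on-rates from the dissociation constants.

        Default unbinding rates (10, 10, 100 s^-1) keep binding at least
        an order of magnitude faster than the catalytic rates nu_r, nu_b,
        which is the regime the quasi-steady-state reduction assumes.
        """
        rates = cls(k_plus=k_minus / params.Kr, k_minus=k_minus,
                    k_plus_p=k_minus_p / params.Kb, k_minus_p=k_minus_p,
                    k_a=k_d / params.KL, k_d=k_d)
        rates.validate(params)
        return rates

    def validate(self, params: ModelParams, rtol: float = 1e-12) -> None:
        for ratio, K, lab in ((self.k_minus / self.k_plus, params.Kr, "Kr"),
                              (self.k_minus_p / self.k_plus_p, params.Kb, "Kb"),
                              (self.k_d / self.k_a, params.KL, "KL")):
            if abs(ratio - K) > rtol * K:
                raise ValueError(f"rate ratio {ratio} != {lab} = {K}")
        floor = 10.0 * max(params.nu_r, params.nu_b)
        if min(self.k_minus, self.k_minus_p, self.k_d) < floor:
            warnings.warn(
                "unbinding rates are not >= 10x the catalytic rates; the "
                "time-scale separation behind the QSSA analysis is weak",
                stacklevel=2)


# reaction rate-law kinds
FIRST_ORDER = "first_order"
BIND_R = "bind_R"      # propensity = k * count * [free CheR]
BIND_B = "bind_B"      # propensity = k * count * [free CheB]
BIND_L = "bind_L"      # propensity = k * count * L (external ligand)


@dataclass(frozen=True)
class Reaction:
    """One elementary step acting on a single receptor species.

    ``dR``/``dB`` are the changes in the free CheR/CheB pools (+1 on
    release, -1 on binding).  ``pair`` groups the two directions of a
    reversible pair; irreversible steps have ``pair = -1``.
    """

    name: str
    reactant: int
    product: int
    rate: float
    kind: str
    dR: int = 0
    dB: int = 0
    pair: int = -1


@dataclass(frozen=True)
class ReactionNetwork:
    """Species labels and elementary reactions of the full receptor model."""

    M: int
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    active_mask: tuple[bool, ...]      # kinase-active conformations
    level_of: tuple[int, ...]          # methylation level per species

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reversible(self) -> int:
        return len({r.pair for r in self.reactions if r.pair >= 0})

    @property
    def n_irreversible(self) -> int:
        return sum(1 for r in self.reactions if r.pair < 0)

    @property
    def n_reactions(self) -> int:
        """Distinct reactions, counting each reversible pair once."""
        return self.n_reversible + self.n_irreversible

    def index(self, label: str) -> int:
        return self.species.index(label)

    def to_text(self) -> str:
        """Plain-text reaction listing (one line per elementary step)."""
        lines = [f"# BL reaction network, M={self.M}: "
                 f"{self.n_species} species, {self.n_reactions} reactions "
                 f"({self.n_reversible} reversible pairs, "
                 f"{self.n_irreversible} irreversible)"]
        for r in self.reactions:
            extra = []
            if r.dR:
                extra.append(f"CheR{'+' if r.dR > 0 else '-'}")
            if r.dB:
                extra.append(f"CheB{'+' if r.dB > 0 else '-'}")
            tag = f" [{','.join(extra)}]" if extra else ""
            lines.append(f"{r.name}: {self.species[r.reactant]} -> "
                         f"{self.species[r.product]}{tag}  k={r.rate:g} "
                         f"({r.kind})")
        return "\n".join(lines)


def activity_probability(m: int, params: ModelParams,
                         Km: float | None = None) -> float:
    """Probability a_m(L) that a level-``m`` receptor is active.

    a_m(L) = a_m(0) * K_m / (L + K_m) with a_m(0) = m/M, using the ideal
    conventions K_0 = 0 (level 0 always inactive) and K_M = infinity
    (level M always active).  Intermediate levels default to K_m = KL.
    """
    if not 0 <= m <= params.M:
        raise ValueError(f"methylation level m={m} outside [0, {params.M}]")
    if m == 0:
        return 0.0
    if m == params.M:
        return 1.0
    if Km is None:
        Km = params.KL
    if Km < 0:
        raise ValueError("Km must be >= 0")
    if math.isinf(Km):
        return m / params.M
    return (m / params.M) * Km / (params.L + Km)


def alpha(params: ModelParams) -> float:
    """ZOU control parameter alpha = R0*nu_r / (B0*nu_b).

    The mean activity switches ultrasensitively as alpha crosses 1 in
    the saturating-receptor limit A0 -> infinity.
    """
    return params.R0 * params.nu_r / (params.B0 * params.nu_b)


def critical_R0(params: ModelParams) -> float:
    """CheR concentration at which alpha = 1 (the GK point), in uM."""
    return params.B0 * params.nu_b / params.nu_r


def _intermediate_flip_rates(m: int, M: int, base: float) -> tuple[float, float]:
    # equilibrium P(active | unligated) = m/M for the spontaneous-flip mode
    p = m / M
    return base * p, base * (1.0 - p)   # (inactive->active, active->inactive)


def build_network(params: ModelParams, rates: KineticRates | None = None,
                  spontaneous_flip: bool = False,
                  flip_rate: float = 1000.0) -> ReactionNetwork:
    """Build the full stochastic reaction network for any M >= 1.

    Species per level: the always-inactive bottom level and always-active
    top level each have a free and an enzyme-bound form; every
    intermediate level has an active unligated, an inactive ligated, a
    CheB-bound (active) and a CheR-bound (inactive, ligated) form -- 4M
    species and 5M-1 distinct reactions in total for M >= 2.

    With ``spontaneous_flip=True`` each intermediate level gains an
    unligated *inactive* conformation exchanging with the active one at
    fast rates tuned so the unligated-active equilibrium weight is m/M
    (the a_m(0) = m/M convention); this breaks the 4M species count and
    is off by default.
    """
    if rates is None:
        rates = KineticRates.from_params(params)
    M = params.M
    if M == 1 and params.L > 0:
        warnings.warn("ligand plays no role for M = 1; the intermediate "
                      "levels it binds to do not exist", stacklevel=2)

    species: list[str] = []
    active: list[bool] = []
    level: list[int] = []

    def add(label: str, is_active: bool, m: int) -> int:
        species.append(label)
        active.append(is_active)
        level.append(m)
        return len(species) - 1

    idx: dict[str, int] = {}
    idx["m0"] = add("m0", False, 0)
    idx["m0.R"] = add("m0.R", False, 0)
    for m in range(1, M):
        idx[f"m{m}a"] = add(f"m{m}a", True, m)
        idx[f"m{m}i"] = add(f"m{m}i", False, m)
        idx[f"m{m}a.B"] = add(f"m{m}a.B", True, m)
        idx[f"m{m}i.R"] = add(f"m{m}i.R", False, m)
        if spontaneous_flip:
            idx[f"m{m}x"] = add(f"m{m}x", False, m)
    idx[f"m{M}"] = add(f"m{M}", True, M)
    idx[f"m{M}.B"] = add(f"m{M}.B", True, M)

    rxns: list[Reaction] = []
    pair = 0

    def reversible(nf, rf, pf, kf, kindf, nb, kb, kindb, dRf=0, dBf=0):
        nonlocal pair
        rxns.append(Reaction(nf, rf, pf, kf, kindf, dR=dRf, dB=dBf, pair=pair))
        rxns.append(Reaction(nb, pf, rf, kb, kindb, dR=-dRf, dB=-dBf,
                             pair=pair))
        pair += 1

    def dest_label(m: int) -> str:
        # catalytic products enter the unligated sub-state of level m;
        # for intermediates that is the active conformation (ligand and
        # enzymes re-equilibrate on the fast time scale)
        if m == 0:
            return "m0"
        if m == M:
            return f"m{M}"
        return f"m{m}a"

    # level 0: CheR binding + methylation
    reversible("R_bind_m0", idx["m0"], idx["m0.R"], rates.k_plus, BIND_R,
               "R_unbind_m0", rates.k_minus, FIRST_ORDER, dRf=-1)
    rxns.append(Reaction("methylate_m0", idx["m0.R"], idx[dest_label(1)],
                         params.nu_r, FIRST_ORDER, dR=+1))

    for m in range(1, M):
        # ligand binding inactivates the intermediate level
        reversible(f"L_bind_m{m}", idx[f"m{m}a"], idx[f"m{m}i"],
                   rates.k_a, BIND_L,
                   f"L_unbind_m{m}", rates.k_d, FIRST_ORDER)
        # CheB binds the active conformation; demethylation
        reversible(f"B_bind_m{m}", idx[f"m{m}a"], idx[f"m{m}a.B"],
                   rates.k_plus_p, BIND_B,
                   f"B_unbind_m{m}", rates.k_minus_p, FIRST_ORDER, dBf=-1)
        rxns.append(Reaction(f"demethylate_m{m}", idx[f"m{m}a.B"],
                             idx[dest_label(m - 1)], params.nu_b,
                             FIRST_ORDER, dB=+1))
        # CheR binds the inactive (ligated) conformation; methylation
        reversible(f"R_bind_m{m}", idx[f"m{m}i"], idx[f"m{m}i.R"],
                   rates.k_plus, BIND_R,
                   f"R_unbind_m{m}", rates.k_minus, FIRST_ORDER, dRf=-1)
        rxns.append(Reaction(f"methylate_m{m}", idx[f"m{m}i.R"],
                             idx[dest_label(m + 1)], params.nu_r,
                             FIRST_ORDER, dR=+1))
        if spontaneous_flip:
            k_ia, k_ai = _intermediate_flip_rates(m, M, flip_rate)
            reversible(f"flip_m{m}", idx[f"m{m}x"], idx[f"m{m}a"],
                       k_ia, FIRST_ORDER,
                       f"unflip_m{m}", k_ai, FIRST_ORDER)

    # level M: CheB binding + demethylation
    reversible(f"B_bind_m{M}", idx[f"m{M}"], idx[f"m{M}.B"],
               rates.k_plus_p, BIND_B,
               f"B_unbind_m{M}", rates.k_minus_p, FIRST_ORDER, dBf=-1)
    rxns.append(Reaction(f"demethylate_m{M}", idx[f"m{M}.B"],
                         idx[dest_label(M - 1)], params.nu_b,
                         FIRST_ORDER, dB=+1))

    return ReactionNetwork(M=M, species=tuple(species), reactions=tuple(rxns),
                           active_mask=tuple(active), level_of=tuple(level))


def load_params(path, **overrides) -> ModelParams:
    """Read a flat key/value YAML parameter file into ModelParams.

    Keys are ModelParams field names; ``overrides`` win over file values.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key/value mapping")
    known = {f.name for f in fields(ModelParams)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown parameter(s) {sorted(unknown)}")
    data.update(overrides)
    if "M" in data:
        data["M"] = int(data["M"])
    return ModelParams(**data)
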