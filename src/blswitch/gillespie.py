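"""Exact stochastic simulation of the receptor reaction network.

Direct-method Gillespie dynamics over the discrete conformational
states, with free CheR/CheB molecule pools and the ligand treated as a
constant external concentration.  The hot loop is compiled with numba;
for the copy numbers of interest (N ~ 3e3 - 2e4 receptors, ~10^2
enzymes) exactness is affordable and no leaping approximation is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model_core import (BIND_B, BIND_L, BIND_R, KineticRates, ModelParams,
                         ReactionNetwork, build_network)

__all__ = ["SimConfig", "Trajectory", "TrajectorySummary", "simulate",
           "summarize", "sweep", "simulate_summary"]

_KIND_CODE = {"first_order": 0, BIND_R: 1, BIND_B: 2, BIND_L: 3}


@dataclass(frozen=True)
class SimConfig:
    """Run-length and sampling choices for one stochastic realization.

    Defaults give ~2e4 samples over a 1e4 s steady-state window, long
    against the slowest methylation relaxation times (hundreds of
    seconds near the ultrasensitive transition).
    """

    seed: int = 1
    t_burn: float = 500.0
    t_total: float = 10500.0
    sample_dt: float = 0.5
    initial_state: str = "lowest"   # "lowest": all unmethylated & unbound;
    #                                 "fixed_point": warm start (M = 2)

    def __post_init__(self) -> None:
        if not (self.t_total > self.t_burn >= 0):
            raise ValueError("need t_total > t_burn >= 0")
        if self.sample_dt <= 0:
            raise ValueError("sample_dt must be > 0")
        if self.initial_state not in ("lowest", "fixed_point"):
            raise ValueError(f"unknown initial_state {self.initial_state!r}")


@dataclass(frozen=True)
class Trajectory:
    """Sampled species counts from one stochastic realization."""

    network: ReactionNetwork
    params: ModelParams
    config: SimConfig
    times: np.ndarray         # (n_samples,)
    counts: np.ndarray        # (n_samples, n_species) int64
    free_R: np.ndarray        # (n_samples,) free CheR molecules
    free_B: np.ndarray        # (n_samples,)
    absorbed: bool = False    # total propensity hit zero

    @property
    def xi_a(self) -> np.ndarray:
        """Active receptor fraction per sample."""
        mask = np.array(self.network.active_mask)
        return self.counts[:, mask].sum(axis=1) / self.params.N

    def level_fractions(self) -> np.ndarray:
        """(n_samples, M+1) receptor fraction per methylation level."""
        lev = np.array(self.network.level_of)
        out = np.zeros((self.counts.shape[0], self.network.M + 1))
        for m in range(self.network.M + 1):
            out[:, m] = self.counts[:, lev == m].sum(axis=1)
        return out / self.params.N

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.counts, columns=list(self.network.species))
        df.insert(0, "time", self.times)
        df["free_R"] = self.free_R
        df["free_B"] = self.free_B
        df["xi_a"] = self.xi_a
        return df


@dataclass(frozen=True)
class TrajectorySummary:
    """Steady-state statistics of one trajectory (post burn-in)."""

    mean_xi_a: float
    var_xi_a: float
    se_mean_xi_a: float
    se_var_xi_a: float
    mean_levels: np.ndarray
    se_mean_levels: np.ndarray
    autocorr_rate: float       # lambda_xi, 1/s (nan if not resolvable)
    n_samples: int
    n_blocks: int
    config: SimConfig = field(repr=False, default=None)

    def to_dict(self) -> dict:
        d = dict(mean_xi_a=self.mean_xi_a, var_xi_a=self.var_xi_a,
                 se_mean_xi_a=self.se_mean_xi_a,
                 se_var_xi_a=self.se_var_xi_a,
                 mean_levels=list(map(float, self.mean_levels)),
                 se_mean_levels=list(map(float, self.se_mean_levels)),
                 autocorr_rate=self.autocorr_rate,
                 n_samples=self.n_samples, n_blocks=self.n_blocks)
        if self.config is not None:
            d["config"] = dict(seed=self.config.seed,
                               t_burn=self.config.t_burn,
                               t_total=self.config.t_total,
                               sample_dt=self.config.sample_dt)
        return d


@njit(cache=True, fastmath=True)
def _ssa_kernel(counts0, nR0, nB0, react, prod, dR, dB, rate, kind,
                upd_ptr, upd_idx, conv, L, sample_times,
                seed):  # pragma: no cover - jitted
    # xorshift64* PRNG, seeded through one splitmix64 scramble; fast,
    # full-period and deterministic for a given integer seed
    rng = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    rng = (rng ^ (rng >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    rng = (rng ^ (rng >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    rng = rng ^ (rng >> np.uint64(31))
    if rng == np.uint64(0):
        rng = np.uint64(0x106689D45497FDB5)
    counts = counts0.copy()
    n_rxn = rate.shape[0]
    n_samp = sample_times.shape[0]
    n_sp = counts.shape[0]
    out = np.zeros((n_samp, n_sp), dtype=np.int64)
    outR = np.zeros(n_samp, dtype=np.int64)
    outB = np.zeros(n_samp, dtype=np.int64)
    props = np.zeros(n_rxn)
    nR = nR0
    nB = nB0
    t = 0.0
    isamp = 0
    absorbed = False
    total = 0.0
    for j in range(n_rxn):
        k = kind[j]
        if k == 1:
            f = nR / conv
        elif k == 2:
            f = nB / conv
        elif k == 3:
            f = L
        else:
            f = 1.0
        props[j] = rate[j] * counts[react[j]] * f
        total += props[j]
    refresh = 0
    while isamp < n_samp:
        if refresh >= 262144:
            # control floating-point drift of the running total
            total = 0.0
            for j in range(n_rxn):
                total += props[j]
            refresh = 0
        if total <= 1e-300:
            absorbed = True
            while isamp < n_samp:
                out[isamp] = counts
                outR[isamp] = nR
                outB[isamp] = nB
                isamp += 1
            break
        rng ^= rng >> np.uint64(12)
        rng ^= rng << np.uint64(25)
        rng ^= rng >> np.uint64(27)
        u1 = np.float64(rng * np.uint64(0x2545F4914F6CDD1D)
                        >> np.uint64(11)) * 1.1102230246251565e-16
        t_next = t - np.log(1.0 - u1) / total
        while isamp < n_samp and sample_times[isamp] < t_next:
            out[isamp] = counts
            outR[isamp] = nR
            outB[isamp] = nB
            isamp += 1
        if isamp >= n_samp:
            break
        rng ^= rng >> np.uint64(12)
        rng ^= rng << np.uint64(25)
        rng ^= rng >> np.uint64(27)
        u = np.float64(rng * np.uint64(0x2545F4914F6CDD1D)
                       >> np.uint64(11)) * 1.1102230246251565e-16 * total
        acc = 0.0
        jsel = -1
        for j in range(n_rxn):
            acc += props[j]
            if u <= acc:
                jsel = j
                break
        if jsel < 0:      # rounding pushed u past the accumulated sum
            for j in range(n_rxn - 1, -1, -1):
                if props[j] > 0.0:
                    jsel = j
                    break
        counts[react[jsel]] -= 1
        counts[prod[jsel]] += 1
        nR += dR[jsel]
        nB += dB[jsel]
        # refresh only the propensities the firing could have changed
        for q in range(upd_ptr[jsel], upd_ptr[jsel + 1]):
            j = upd_idx[q]
            k = kind[j]
            if k == 1:
                f = nR / conv
            elif k == 2:
                f = nB / conv
            elif k == 3:
                f = L
            else:
                f = 1.0
            pnew = rate[j] * counts[react[j]] * f
            total += pnew - props[j]
            props[j] = pnew
        t = t_next
        refresh += 1
    return out, outR, outB, absorbed


def _dependency_graph(react, prod, dR, dB, kind):
    """CSR arrays: reactions whose propensity may change after each firing."""
    n = react.size
    ptr = [0]
    idx: list[int] = []
    for j in range(n):
        touched = {react[j], prod[j]}
        deps = [i for i in range(n)
                if react[i] in touched
                or (dR[j] != 0 and kind[i] == 1)
                or (dB[j] != 0 and kind[i] == 2)]
        idx.extend(deps)
        ptr.append(len(idx))
    return (np.array(ptr, dtype=np.int64), np.array(idx, dtype=np.int64))


def _compile_network(network: ReactionNetwork):
    react = np.array([r.reactant for r in network.reactions], dtype=np.int64)
    prod = np.array([r.product for r in network.reactions], dtype=np.int64)
    dR = np.array([r.dR for r in network.reactions], dtype=np.int64)
    dB = np.array([r.dB for r in network.reactions], dtype=np.int64)
    rate = np.array([r.rate for r in network.reactions], dtype=np.float64)
    kind = np.array([_KIND_CODE[r.kind] for r in network.reactions],
                    dtype=np.int64)
    return react, prod, dR, dB, rate, kind


def _warm_start(network: ReactionNetwork, params: ModelParams,
                nR_tot: int, nB_tot: int):
    """Initial counts near the deterministic steady state (M = 2 only).

    Deterministic rounding of the QSSA fixed-point occupancies of the 8
    conformational states; removes the long cold-start transient when
    only stationary statistics are wanted.
    """
    from .qssa import solve_fixed_point

    if network.M != 2:
        raise ValueError("fixed_point initialization exists for M = 2 only")
    fp = solve_fixed_point(params)
    p = params
    ell = p.ell
    fR = fp.Rf / (fp.Rf + p.Kr)      # CheR-bound fraction of its substrates
    fB = fp.Bf / (fp.Bf + p.Kb)
    xi1 = fp.xi.xi1
    frac = {
        "m0": fp.xi.xi0 * (1 - fR), "m0.R": fp.xi.xi0 * fR,
        "m1a": xi1 / (1 + ell) * (1 - fB), "m1a.B": xi1 / (1 + ell) * fB,
        "m1i": xi1 * ell / (1 + ell) * (1 - fR),
        "m1i.R": xi1 * ell / (1 + ell) * fR,
        "m2": fp.xi.xi2 * (1 - fB), "m2.B": fp.xi.xi2 * fB,
    }
    counts = np.zeros(network.n_species, dtype=np.int64)
    for label, f in frac.items():
        counts[network.index(label)] = int(round(f * p.N))
    # absorb the rounding remainder into the largest unbound bucket, then
    # respect
    # the finite enzyme pools
    labels_unbound = ["m0", "m1a", "m1i", "m2"]
    big = max(labels_unbound, key=lambda s: counts[network.index(s)])
    counts[network.index(big)] += p.N - counts.sum()
    for bound, free_pool, partner in (("R", nR_tot, ("m0.R", "m1i.R")),
                                      ("B", nB_tot, ("m1a.B", "m2.B"))):
        used = sum(counts[network.index(s)] for s in partner)
        if used > free_pool:
            excess = used - free_pool
            for s in partner:
                take = min(excess, counts[network.index(s)])
                counts[network.index(s)] -= take
                counts[network.index(s[: s.index(".")])] += take
                excess -= take
    nR0 = nR_tot - (counts[network.index("m0.R")]
                    + counts[network.index("m1i.R")])
    nB0 = nB_tot - (counts[network.index("m1a.B")]
                    + counts[network.index("m2.B")])
    assert counts.sum() == p.N and nR0 >= 0 and nB0 >= 0
    return counts, int(nR0), int(nB0)


def _enzyme_count(conc: float, conversion: float, label: str) -> int:
    n = int(round(conc * conversion))
    if conc > 0 and n == 0:
        warnings.warn(f"{label} concentration below one molecule per cell; "
                      "using a single molecule", stacklevel=3)
        n = 1
    return n


def simulate(network: ReactionNetwork, params: ModelParams,
             config: SimConfig) -> Trajectory:
    """Run one exact SSA realization; reproducible for a given seed.

    All receptors start in the unmethylated, unbound (inactive) state;
    sampling records the state on a uniform time grid from t = 0 (the
    burn-in is discarded later, by :func:`summarize`).
    """
    if network.M != params.M:
        raise ValueError("network and params disagree on M")
    react, prod, dR, dB, rate, kind = _compile_network(network)
    nR_tot = _enzyme_count(params.R0, params.conversion, "CheR")
    nB_tot = _enzyme_count(params.B0, params.conversion, "CheB")
    if config.initial_state == "fixed_point":
        counts0, nR0, nB0 = _warm_start(network, params, nR_tot, nB_tot)
    else:
        counts0 = np.zeros(network.n_species, dtype=np.int64)
        counts0[network.index("m0")] = params.N
        nR0, nB0 = nR_tot, nB_tot
    n_samp = int(np.floor(config.t_total / config.sample_dt)) + 1
    sample_times = np.arange(n_samp) * config.sample_dt
    upd_ptr, upd_idx = _dependency_graph(react, prod, dR, dB, kind)
    out, outR, outB, absorbed = _ssa_kernel(
        counts0, nR0, nB0, react, prod, dR, dB, rate, kind,
        upd_ptr, upd_idx, params.conversion, params.L, sample_times,
        int(config.seed) % 2**32)
    return Trajectory(network=network, params=params, config=config,
                      times=sample_times, counts=out, free_R=outR,
                      free_B=outB, absorbed=bool(absorbed))


def _autocorr_rate(x: np.ndarray, dt: float, max_lag_frac: float = 0.1,
                   ) -> float:
    """Exponential decay rate of the autocorrelation of ``x`` (1/s).

    Fits log acf ~ -lambda * lag over the lags where the acf stays
    above 0.05; returns nan when the signal carries no resolvable
    correlation (e.g. a frozen trajectory).
    """
    x = x - x.mean()
    v = np.dot(x, x) / x.size
    if v <= 0:
        return np.nan
    n = x.size
    max_lag = max(int(n * max_lag_frac), 10)
    lags = np.arange(1, max_lag)
    acf = np.empty(lags.size)
    for i, k in enumerate(lags):
        acf[i] = np.dot(x[:-k], x[k:]) / ((n - k) * v)
    keep = acf > 0.05
    if keep.any():
        stop = int(np.argmin(keep)) if not keep.all() else lags.size
    else:
        stop = 0
    if stop < 3:
        return np.nan
    sel = slice(0, stop)
    lam = -np.polyfit(lags[sel] * dt, np.log(acf[sel]), 1)[0]
    return float(lam) if lam > 0 else np.nan


def summarize(traj: Trajectory, config: SimConfig | None = None,
              ) -> TrajectorySummary:
    """Steady-state mean/variance of the activity with blocked errors.

    Discards the burn-in, estimates the activity autocorrelation decay
    rate lambda_xi, and uses blocks of length >= 20/lambda_xi so block
    averages are nearly independent; standard errors are the empirical
    scatter of the block statistics.
    """
    cfg = config or traj.config
    keep = traj.times >= cfg.t_burn
    xa = traj.xi_a[keep]
    levels = traj.level_fractions()[keep]
    n = xa.size
    if n < 100:
        warnings.warn(f"only {n} post-burn-in samples; estimates are "
                      "imprecise", stacklevel=2)
    lam = _autocorr_rate(xa, cfg.sample_dt)
    if np.isfinite(lam):
        block_len = int(np.ceil(20.0 / (lam * cfg.sample_dt)))
    else:
        block_len = max(n // 20, 1)
    block_len = int(np.clip(block_len, 1, max(n // 4, 1)))
    nb = n // block_len
    trimmed = xa[:nb * block_len].reshape(nb, block_len)
    bmeans = trimmed.mean(axis=1)
    bvars = trimmed.var(axis=1)
    mean = float(xa.mean())
    var = float(xa.var())
    se_mean = float(bmeans.std(ddof=1) / np.sqrt(nb)) if nb > 1 else np.inf
    se_var = float(bvars.std(ddof=1) / np.sqrt(nb)) if nb > 1 else np.inf
    lev_trim = levels[:nb * block_len].reshape(nb, block_len, -1)
    lev_bmeans = lev_trim.mean(axis=1)
    se_levels = (lev_bmeans.std(axis=0, ddof=1) / np.sqrt(nb)
                 if nb > 1 else np.full(levels.shape[1], np.inf))
    return TrajectorySummary(
        mean_xi_a=mean, var_xi_a=var, se_mean_xi_a=se_mean,
        se_var_xi_a=se_var, mean_levels=levels.mean(axis=0),
        se_mean_levels=se_levels, autocorr_rate=lam, n_samples=n,
        n_blocks=nb, config=cfg)


def simulate_summary(params: ModelParams, config: SimConfig,
                     rates: KineticRates | None = None) -> TrajectorySummary:
    """Convenience: build the network, simulate, summarize."""
    net = build_network(params, rates)
    return summarize(simulate(net, params, config))


def point_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-point seeds derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % np.uint32(2**31)]


def sweep(params: ModelParams, vary: str, grid, config: SimConfig,
          rates: KineticRates | None = None):
    """Run one SSA summary per grid value of ``vary`` (R0, ell, A0 or M).

    Per-point seeds derive deterministically from ``config.seed``;
    per-point failures are recorded (column ``error``) and the sweep
    continues.  Returns a pandas DataFrame.
    """
    import dataclasses

    import pandas as pd

    if vary not in ("R0", "ell", "A0", "M"):
        raise ValueError(f"cannot sweep over {vary!r}")
    grid = list(np.atleast_1d(grid))
    seeds = point_seeds(config.seed, len(grid))
    rows = []
    for val, seed in zip(grid, seeds):
        if vary == "ell":
            p = params.with_ell(float(val))
        elif vary == "M":
            p = params.replace(M=int(val))
        else:
            p = params.replace(**{vary: float(val)})
        cfg = dataclasses.replace(config, seed=seed)
        row = {vary: val, "seed": seed}
        try:
            s = simulate_summary(p, cfg, rates)
            row.update(mean_xi_a=s.mean_xi_a, var_xi_a=s.var_xi_a,
                       se_mean_xi_a=s.se_mean_xi_a, se_var_xi_a=s.se_var_xi_a,
                       autocorr_rate=s.autocorr_rate, n_samples=s.n_samples,
                       error="")
            for m, (mu, se) in enumerate(zip(s.mean_levels,
                                             s.se_mean_levels)):
                row[f"mean_xi{m}"] = mu
                row[f"se_mean_xi{m}"] = se
        except Exception as exc:   # per-point failures must not kill a sweep
            row.update(error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)
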