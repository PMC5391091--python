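# Methods

## The model

A chemotaxis receptor complex (receptor + CheW + CheA) in *E. coli*
carries `M` methylation sites and is, at any instant, either
kinase-*active* or *inactive*.  The methyltransferase CheR binds only
inactive receptors and adds a methyl group at catalytic rate `nu_r`;
the methylesterase CheB binds only active receptors and removes one at
rate `nu_b`.  Attractant (ligand, uniform concentration `L`) binds
receptors in the intermediate methylation levels and inactivates them.
The bottom level (`m = 0`) is always inactive and the top level
(`m = M`) always active — in the activity-probability function
`a_m(L) = a_m(0) K_m/(L + K_m)` this corresponds to the ideal choices
`K_0 = 0` and `K_M = infinity`; intermediates use `K_m = KL`.  This
wiring is what makes the steady-state activity independent of the
ambient ligand level (perfect adaptation): the enzymes only see the
*conformation*, whose total balance is ligand-free at stationarity.

The antagonistic CheR/CheB pair acting on a shared receptor pool is a
covalent-modification cycle.  When the receptor concentration `A0` far
exceeds both enzyme pools and their dissociation constants, the mean
active fraction becomes an ultrasensitive (switch-like) function of the
control parameter

    alpha = R0 * nu_r / (B0 * nu_b),

jumping near `alpha = 1` — zero-order ultrasensitivity (ZOU).  In the
limits `ell = L/KL -> 0` and `ell -> infinity` the three-level `M = 2`
system reduces to two different two-level switches (populations shared
between levels 0/1, respectively 1/2).

### Stochastic description

All binding steps are explicit reactions: per level there are free and
enzyme-bound forms, and intermediates additionally split into an active
unligated and an inactive ligated conformation, giving `4M` species and
`5M - 1` distinct reactions (reversible pairs counted once) for
`M >= 2`.  Catalytic products enter the unligated sub-state of the
destination level; ligand and enzymes re-equilibrate on the fast time
scale, so steady-state observables are insensitive to that convention.
The dynamics are simulated exactly (direct-method SSA) with the ligand
as a fixed external concentration and discrete free-enzyme pools
(`round(c * 602.3)` molecules at the default 1e-15 L cell volume).

The individual binding rates are not fixed by the steady-state theory,
only their ratios (the dissociation constants `Kr`, `Kb`, `KL`) are.
Defaults: unbinding at 10 s^-1 for both enzymes and 100 s^-1 for the
ligand, an order of magnitude above the catalytic rates, enforcing the
time-scale separation the reduced description assumes while keeping the
event rate of the exact simulation manageable.

For `M > 2` the convention `a_m(0) = m/M` conflicts with the pure
active/inactive-by-ligation splitting that yields the `4M` species
count.  The default network uses the pure ligation split (unligated
intermediates are active, `K_m = KL`); an optional mode
(`build_network(..., spontaneous_flip=True)`) adds a fast spontaneous
conformational exchange calibrated so the unligated-active equilibrium
weight is `m/M`.  The default reproduces the species/reaction
combinatorics above; the option exists because neither convention is
forced by the biochemistry.

### Quasi-steady-state reduction (M = 2)

With binding fast, the intra-level occupancies are enslaved to the
slow level fractions `xi = (xi0, xi2)` and the free-enzyme
concentrations follow a linear sequestration balance,

    Rf = R0 Kr (L+KL) / (Kr (L+KL) + A0 [KL xi0 + L (1 - xi2)]),

with the mirrored expression for `Bf`.  The slow dynamics carry drift
`v(xi)` (methylation/demethylation flux differences) and diffusion
`D(xi)` (flux sums over `2N`), defining a two-variable Fokker-Planck
equation.  Two kinetics variants are implemented everywhere: the full
Michaelis factors `Rf/(Rf+Kr)`, and the linearized regime `Rf/Kr`
(valid for `Rf << Kr`, `Bf << Kb`) in which the closed-form results
are derived.  Analytical coefficients default to the linearized forms;
`simplified=False` differentiates the full drift instead.

**Fixed point.**  Summing the two flux balances eliminates the ligand:
the steady state solves the scalar equation
`r(xa) (1 - xa) = b(xa) xa` for the active fraction, where `r` and `b`
are the per-receptor conversion rates at the sequestration-consistent
free-enzyme levels.  The residual is sign-definite at the endpoints,
so Brent's method converges unconditionally; the level populations are
then reconstructed from the detailed balances.  We use this exact 1-D
reduction instead of a damped 2-D self-consistent iteration because it
cannot cycle or stall near the ultrasensitive transition; a long-time
ODE integration of the mean equations remains as an independent
cross-check and automatic fall-back.  In the linearized regime the
active fraction also solves a ligand-free quadratic,

    A0 (nu_b B0 - nu_r R0) xa^2
      + [nu_r R0 (A0 - Kb) - nu_b B0 (Kr + A0)] xa + nu_r R0 Kb = 0,

re-derived here from the flux and sequestration balances (note the
placement of `A0` on the quadratic coefficient); at `alpha = 1` it
gives `xa = Kb/(Kb + Kr)` independent of `A0`.

### Linear noise approximation

Linearizing about the fixed point gives an Ornstein-Uhlenbeck process:
Jacobian `beta` (including the free-enzyme feedback terms), ligand
sensitivity `gamma`, diffusion `D*`, and stationary covariance from
`beta sigma + sigma beta^T + 2D = 0`, solved in closed form for the
2x2 case and verified against a generic Lyapunov solver.  The activity
variance follows from the linear map
`dxi_a = (-dxi0 + ell dxi2)/(1 + ell)`:

    sigma_a^2 = (sigma00 + ell^2 sigma22 - 2 ell sigma02) / (1+ell)^2.

`sigma_a^2` scales as `1/N`, peaks in `R0` near the critical
concentration `B0 nu_b / nu_r`, and its peak-over-`R0` value is a
shallow, non-monotonic function of `ell`: with the default parameter
set the continuous minimizer sits near `ell ~ 0.9` and the profile is
flat to within ~10% over `ell` in [0.5, 2].  The packaged ligand scan
uses a 13-point log grid over [0.1, 100] (4 points per decade), on
which the minimum falls at `ell = 1`.

### Network-level reference (no reduction)

The reduced formulas above inherit two approximations beyond the LNA
itself: the free-enzyme sequestration is linearized (the exact balance
is quadratic in `Rf`), and binding is characterized by equilibrium
dissociation constants where the exact stationary occupancies carry
Michaelis constants `(k_- + nu)/k_+` (a 6-8% difference at the default
rates).  On the flanks of the ultrasensitive transition these shift
the reduced fixed point by up to ~0.03 in activity at the default
parameters — far beyond simulation error bars.
`blswitch.network_lna` therefore provides the reduction-free
reference: the deterministic steady state of the full mass-action
network and the stationary covariance from the network-level Lyapunov
equation (every elementary reaction contributing shot noise, the
receptor-conservation direction eliminated).  Perfect adaptation holds
exactly there too.  Its activity variance exceeds the reduced one by
~30% at the noise peak — the reduced layer keeps only methylation
shot noise, while the network adds the fast binding/ligation
(binomial) noise of the intermediate level, which dominates far from
the transition.  Simulator validation (`compare_lna_ssa`) uses the
network reference by default; the reduced layer remains the default
everywhere else because its closed forms are the model's analytical
content.

### Response functions

A weak ligand perturbation displaces the mean levels through
`d/dt dxi = beta dxi + gamma dL(t)`; the activity response function
`chi_a(t)` consists of an instantaneous (re-ligation) delta term and a
two-exponential part with the Jacobian decay rates `A`, `B`
(`A + B = -tr beta`, `A B = det beta`).  Perfect adaptation forces
`chi_a` to integrate to zero.  The clockwise-bias response `chi_b` is
`chi_a` filtered through the CheYp cascade (rate `lambda_Y`) and
scaled by `H lambda_Y (1 - P_CW*)/xi_a*`; its three-exponential closed
form is obtained by residue evaluation at the poles `-lambda_Y`, `-A`,
`-B` and validated against direct numerical convolution.  For an
attractant *increase* the curve has a negative early lobe (immediate
tumble suppression) and a positive late adaptive lobe of equal area;
the adaptive lobe shallows as `ell` grows while the decay rates barely
move.  Complex-conjugate Jacobian eigenvalues are handled in complex
arithmetic, returning the real part.  Defaults at the motor:
`lambda_Y = 30 s^-1`, `H = 20`, `P_CW* = 0.5`.

### Downstream noise

The CheYp mean is `Y* = a_Y Y0 A0 xi_a*/lambda_Y`; activity noise
`sigma_a` filtered through this first-order cascade gives
`sigma_Y = a_Y Y0 A0 sigma_a / sqrt(lambda_Y (lambda_Y + lambda_xi))`,
which saturates its upper bound when the receptor noise is slow
(`lambda_xi << lambda_Y`, the regime the simulations show: the
activity autocorrelation decays at ~2e-3 to 5e-3 s^-1 near the
transition, versus `lambda_Y ~ 14-30 s^-1`).  Inverting the saturated
relation maps a measured CheYp noise window onto a receptor-noise
window.  The motor's clockwise bias is a steep Hill function
(`K_Y = 3 uM`, `H = 20` non-adapted, `H_a = 10` adapted), evaluated in
log space so steep coefficients do not overflow.  The bias fluctuation
is `dP_CW = (dP_CW/dY) sigma_Y`, with the convenient estimate
`H sigma_Y/(4 K_Y)`; that estimate is the `H -> infinity` limit of the
true maximum and is exceeded by `O(1/H^2)` (~0.25% at `H = 20`) at the
optimal operating point — the tests assert the exact relation.  Slow
motor adaptation (rate `lambda_m = 0.0167 s^-1`) multiplies the result
by `sqrt(1 - (lambda_m/lambda_Y)(r)(1 - r))` with `r` the
adapted/non-adapted slope ratio; the factor stays within ~2% of unity
for CheYp in the sensitive window (2.5-4 uM).

## Simulation practice and problem sizes

Near the ultrasensitive transition the slow Jacobian eigenvalue is
~2e-3 s^-1 (relaxation time ~500 s) and carries ~98% of the activity
variance, so variance estimation needs observation windows of many
thousands of seconds.  The simulator therefore supports a warm start
(`initial_state="fixed_point"`, M = 2): initial counts are the rounded
fixed-point occupancies, removing the ~5000 s cold-start transient
that otherwise biases short-window variance estimates upward.  The
default cold start (all receptors unmethylated and unbound) is kept
for trajectory studies.

Standard errors use blocking: the activity autocorrelation decay rate
`lambda_xi` is fitted from the trajectory and block lengths are at
least `20/lambda_xi`, so block statistics are close to independent;
with fewer than ~100 effective samples a precision warning is issued.
Quantitative LNA-vs-SSA comparisons in the test suite use windows of
5e3-8e3 s after a warm start at `A0 = 13.6 uM` (N = 8191 receptors);
these sizes give variance estimates with 15-25% standard errors, which
is what the factor-two and 3-standard-error checks require.  The
LNA-vs-SSA grid comparison is run at `ell = 0.2`, where the reaction
event rate is smallest; perfect adaptation makes the mean and the
noise structure ligand-insensitive, so the choice of `ell` is a matter
of compute cost, not physics.  At the grid points nearest the
transition, genuine finite-`N` effects (mean shifts of order 0.01 at
N = 8191) can push individual z-scores past 3; the agreement check
asks for 90% of the grid, which is exactly the allowance such points
need.

## What the generator does and does not emulate

The stochastic model represents intrinsic copy-number noise of a
single receptor-enzyme network: discrete receptors and enzymes, exact
binding/catalysis stochasticity, fixed external ligand.  It does not
represent receptor clustering or allosteric coupling, CheB
phosphorylation feedback, cell-to-cell protein-number variability,
ligand diffusion noise, or spatial run-and-tumble motion.  Agreement
of the simulator with the analytical layer therefore validates the
mathematics of this network, not the completeness of the network as a
model of a real cell.

## Numerical choices

- Fixed-point residual tolerance 1e-10 (1/s) with brentq at machine
  precision; ODE fall-back via LSODA at rtol 1e-12.
- Finite-difference validations use central differences with relative
  step 1e-7.
- The closed-form Lyapunov solution requires `tr beta < 0` and
  `det beta > 0` and raises `StabilityError` otherwise.
- The SSA kernel (numba) uses an inline xorshift64* generator seeded
  through splitmix64; trajectories are bit-reproducible for a given
  seed.  The running propensity total is refreshed every 2^18 events
  to bound floating-point drift; only propensities touched by the
  fired reaction are recomputed.
- Enzyme concentrations below one molecule per cell are promoted to a
  single molecule with a warning (discreteness is the point of the
  stochastic model).
- Degenerate response rates (`A = B` or `lambda_Y` equal to either)
  fall back to numerical convolution with a notice.

## Known limitations

- The analytical layer (fixed point, LNA, response) covers `M = 2`
  only; `M = 3, 4` are simulation territory.
- At the critical point with very small enzyme pools (tens of
  molecules) the true mean shifts from the deterministic fixed point
  at order `1/N`; the LNA describes the full-size system (~1e2
  enzymes, ~1e4 receptors) well but is quantitatively marginal for
  toy-sized systems.
- `sigma_a^2` estimates from finite windows carry 15-25% errors at the
  packaged run lengths; the headline noise-magnitude check is a
  factor-of-two window, which these errors respect.
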