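# Methods

## Model

The batch culture is modelled as `dξ/dt = K·φ(ξ)` for the 11 extracellular
species, with the signed stoichiometric matrix `K` compiled from the nine
macroreaction schemes (`model.build_network`).  Units are mM for every
metabolite — the antibody is stored in mM even though measurement files
carry it on a 10⁻⁴ mM column scale — and 10⁶ cells/mL for the cell states,
so that a maximum rate φ* in pmol/(cell·h) times X gives mM/h directly.
The biomass "mM" unit is kept symbolic (the data source states no molar
basis for it).

Reaction rates are compound-Monod: φᵢ = φᵢ*·X·∏ⱼ Sⱼ/(K_Sj,i+Sⱼ), with the
substrate sets of the nine reactions fixed by the rate-law table (reactions
7–9 deliberately saturate on glutamine alone).  A `simplified` kinetics mode
implements the linear reduction φᵢ = φᵢ*·X used by one of the bundled
comparison parameter sets; in that mode negative maximum rates are allowed
(a net macroreaction may run backwards), whereas the saturable mode enforces
nonnegativity.

Viable cells grow exponentially (μX) until t_exp = 54 h and decline through
second-order death (k_d·X·X_d) throughout; dead cells accumulate the same
term, so d(X+X_d)/dt = μX during growth and 0 afterwards.

### Numerics

Simulation uses LSODA (`scipy.integrate.solve_ivp`) with rtol 1e-8 and
atol 1e-12 (the antibody lives at the 1e-4 mM scale).  The growth→decline
switch is handled by integrating the two phases separately and restarting at
t_exp, so the discontinuity is exact rather than smeared by a step function
inside the right-hand side.  Monod factors are undefined below zero, and
integrator overshoot near substrate depletion is expected, so the rate
function clamps negative states to zero (counted, logged at debug level) and
the returned trajectory is clipped at zero.

A caution on fixed-step integration: with the bundled real-data estimates
the glutamate equation is stiff (a near-zero quasi-steady glutamate pool
with a large rate constant), and an explicit Euler scheme at 0.001 h is
outside its stability region there.  The integrator-vs-Euler equivalence
test therefore uses the synthetic ground truth, whose time scales are
moderate.

## Data handling

Measurement tables are sparse (7 samples over 147 h, mean ± SD per point).
For estimation they are densified with the monotone shape-preserving
piecewise-cubic Hermite interpolant (PCHIP): continuous value and first
derivative, exact at every knot, and no overshoot — essential because
glutamine sits exactly at zero over the last three samples and any
undershoot would break the Monod factors.  Values are additionally clamped
at zero, extrapolation is refused, and the dense grid step is Ts = 0.1 h.
Discrete derivatives, where needed, are forward differences with a backward
difference at the final grid point (error proportional to Ts).

### The unmeasured glutamate trajectory

Glutamate appears in the Monod factors of reactions 2–4 but is not
measured.  Summing the GLN, GLU, ASN, ASP, ALA and PRO rows of `K` cancels
every reaction except biomass and antibody synthesis:

    d(GLN+GLU+ASN+ASP+ALA+PRO)/dt = −0.1797·dBM/dt − 0.2009·dMAb/dt,

and the right-hand side involves only measured variables.  Integrating gives
the glutamate trajectory in closed form from the interpolated measurements,
up to its initial value GLU(0), which is also unmeasured; the package
default is 1.5 mM, the smallest round value that keeps the reconstructed
trajectory comfortably positive over the whole batch given the observed
pool changes.  On synthetic data the reconstruction is exact at the sampling
knots (a property test).  For real data the choice of GLU(0) only affects
subproblems whose equations contain glutamate (P3, P4, P7, P8) and, because
the fitted half-saturation constants for glutamate end up far from the
reconstructed range, mostly rescales the non-identifiable φ*/K pairs rather
than the identifiable slopes.

## Particle swarm optimizer

Standard global-best PSO with per-particle, per-dimension uniform random
coefficients.  Three regimes: linearly scheduled inertia (0.9 → 0.4),
Clerc constriction h = 2/|2−α−√(α²−4α)| for α = c₁+c₂ > 4 (the printed
form of this expression has a negative denominator; the standard
absolute-value damping form is used), and time-varying acceleration
coefficients (cognitive 2.5 → 0.5, social 0.5 → 2.5) on top of the
scheduled inertia — the default for estimation.  Velocities are clamped to
20% of the box width per dimension; positions leaving the box are reflected
inside with the offending velocity component zeroed, which keeps positivity
bounds intact.  Initialization is uniform in the box for positions and in
±V_max for velocities.  The stopping rule is objective ≤ 1e-6 or the
iteration cap; the reference profile is 150 particles × 300 iterations and
the desk-scale default 50 × 100.  A non-finite objective value is treated
as +∞ and logged, never fatal.  The convergence condition
ω > (c₁+c₂)/2 − 1, 0 < ω < 1 is checked and logged as a warning when
violated, not enforced.

## Multistep estimation

Estimating all 23 parameters in one 23-dimensional search is expensive and
badly conditioned, so the problem is split into nine subproblems solved in a
fixed order with forward freezing (already-estimated parameters are never
updated).  Each subproblem fits the parameters of one balance equation by
minimizing Σₖ (ξ(k·Ts) − ξ̂(k·Ts))², where ξ̂ follows the explicit-Euler
recursion of that single equation with every *other* state pinned to its
interpolated measured trajectory (the viable-cell density in particular
always comes from the data, not from the cell model, which is fitted last).
The fitted state's own occurrences inside its rate expressions use the
predicted value, making each subproblem a genuine one-state simulation; P9
fits the coupled (X, X_d) pair jointly, summing both states' errors (the
decoupled alternative was evaluated and gave slightly degenerate decay
estimates).

The subproblem → equation mapping is forced by matching each parameter
group to the unique balance equation containing exactly those parameters
given the freezing order; the lactate, glutamate and ammonia equations are
never fitted (the latter two are unmeasured, and every lactate parameter is
already fixed by P4/P7/P8).  The error is accumulated over the full Ts grid
(N = 1470 points), not only at the 7 knots.

Search boxes: maximum rates and half-saturation constants span many orders
of magnitude, so they are searched on a log₁₀ scale over [1e-8, 1e7]; μ and
k_d are searched linearly on [1e-3, 1].  One PSO run per subproblem by
default; a restart option reruns each subproblem with derived seeds and
keeps the lowest objective (the objectives have many local minima).  All
seeds derive deterministically from a single run seed.

### Identifiability and simulation fidelity

With only 7 samples, most half-saturation constants are structurally
non-identifiable: when a fitted K far exceeds the substrate's observed
range, the factor S/(K+S) is indistinguishable from S/K and only the slope
φ*/K is pinned down.  The Monte Carlo study quantifies this (growth/decay
constants orders of magnitude more stable than the antibody or aspartate
half-saturation constants).

A consequence worth stating plainly: the one-step-ahead objective evaluated
along the measured trajectories does not constrain how a *fully simulated*
model closes its own feedback loops.  On the bundled data the glutamine
subproblem genuinely prefers (lower objective) solutions in which a
substantial share of glutamine consumption runs through the
aspartate-coupled reaction 6; in full simulation the weakly-fitted
asparagine/aspartate chain lets simulated aspartate fall below the measured
path, which throttles that route and re-routes the glutamine budget into
biomass synthesis, inflating the simulated biomass plateau above the
measured one (~24 mM vs ~18 mM) even though every subproblem fit is at or
below the objective values attainable anywhere else on the ridge.  Fitted
growth/decay constants are not the cause; the effect is a property of
equation-error estimation under structural non-identifiability, and users
validating a fit should always compare a full simulation against the data,
as the `simulate` command makes easy.

## Monte Carlo robustness study

Each replicate redraws every measured point from N(mean, sd²) truncated at
zero (points with sd = 0, such as the depleted glutamine tail, stay fixed),
re-interpolates, and reruns the full multistep estimation.  Replicate
perturbations are seeded as base seed + replicate index; the PSO seed is
shared across replicates so that only the data vary.  Replicates whose total
objective falls outside the quartile fence [q_low − 1.5·IQR, q_up + 1.5·IQR]
are excluded, with quartiles computed as medians of the exclusive halves
(the median itself belongs to neither half).  Per-parameter means and
standard deviations over the retained replicates are reported, the latter as
percent of the mean.

## Synthetic data generator

The generator simulates the full model from a known ground truth and
samples it at the 7 batch sampling times, emulating the structure of the
real table: same 11 measured variables, optional Gaussian noise either as a
coefficient of variation or reusing the real per-point standard deviations,
truncated at zero, with the applied sd recorded.  The `identifiable_preset`
ground truth uses μ = 0.043, k_d = 0.067, places every half-saturation
constant inside the range its substrate covers during the simulated batch
(within a factor 3 of the mid-range), and sets maximum rates so the batch
reproduces the familiar shapes — glucose declining to ~1.8 mM, glutamine
depleting, lactate/alanine accumulating, a biomass plateau near 18 mM and a
viable-cell peak near 0.8×10⁶ cells/mL.  The rates were chosen once by
matching target reaction extents over the batch and are fixed constants.

What the generator does *not* emulate: replicate structure (the real table
averages three experiments), measurement dropout, non-Gaussian error, or
model mismatch — synthetic recovery tests therefore demonstrate estimator
correctness under the model's own assumptions, not robustness to structural
error in real cultures.

## Problem sizes used in tests

Fitting tests use the 50×100 desk-scale profile and a fixed handful of
seeds; the Monte Carlo ordering check uses 30 replicates at 30×60; the
noise-monotonicity property averages over 5 seeds at 50×100.  These sizes
are the package's own defaults for routine use; the 150×300 reference
profile is available everywhere via configuration.

## Known limitations

- CO₂/off-gas exchange is not modelled; the batch form has no feed or
  dilution terms.
- GLU(0) is an assumption, not a measurement; fits report it in the config
  snapshot.
- The quartile fence needs ≥ 4 replicates; with tiny replicate counts its
  outlier decisions are crude.
- Explicit-Euler subproblem recursions inherit an O(Ts) bias; at Ts = 0.1 h
  this bias is visible in the recovered maximum rates (a few percent) even
  on noiseless data, and vanishes as Ts shrinks (verified down to 0.002 h in
  the tests).
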