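# Methods

This note records the scientific and numerical choices behind `biosos`:
what each model layer assumes, which parameters matter and why their
defaults look the way they do, what the synthetic-data generators emulate,
and where the design was genuinely open.

## Single-cell metabolic–redox network

The cell is a well-mixed reactor with 27 intracellular pools and 12
extracellular medium species, connected by 29 reactions. Rate laws are
products of Michaelis–Menten saturation terms `S/(Km+S)`, inhibition terms
`Ki/(Ki+I)` and cofactor-ratio terms `(A/B)/(Km+A/B)`; reversible
reactions carry an independent factor set per direction. Three regulatory
elements shape the culture phenotypes:

* **R0** — extracellular lactate inhibits glucose uptake
  (`Ki = 35 mM` on the lumped glycolysis step);
* **R1** — extracellular pyruvate inhibits the forward LDH term
  (`Ki = 2 mM`), with NADH/NAD ratio factors coupling LDH to redox state;
* **R2** — extracellular pyruvate inhibits net glutamine consumption
  (`Ki = 2 mM` on the forward glutaminolysis term).

Glycolysis is lumped into a single step (EGLC → 2 PYR + 2 NADH) that
doubles as the glucose-uptake reaction, with glucose carbons mapped to the
two pyruvates by the standard EMP pattern (C1–C3 reversed into one
pyruvate, C4–C6 into the other). A lumped product-inhibition factor
(intracellular pyruvate on glycolysis, `Ki = 0.3 mM`-scale pool units)
carries the observed substrate-substitution effect: supplementing pyruvate
raises the intracellular pyruvate pool and throttles glycolysis, lowering
specific glucose consumption without touching growth.

**Energy bookkeeping is implicit.** An earlier design carried ATP/ADP as a
third conserved cofactor pair, with growth as the only net ATP sink. At
this level of lumping that coupling is pathological: whenever growth
stalls (starvation, anoxia) ADP pins at zero and blocks the respiratory
chain exactly when its redox response matters, and under normal medium the
system admits a spurious collapsed-NAD fixed point. The lumped rate
constants therefore absorb energy stoichiometry; NAD⁺/NADH and FAD/FADH₂
remain explicit and are conserved by every reaction (a validated
structural invariant, and a tested trajectory invariant to solver
tolerance).

Oxygen is an environmental scalar in [0, 1] (fraction of normoxia)
multiplying the two oxidative-phosphorylation steps through
`O₂/(Km_O2+O₂)` with `Km_O2 = 0.02`; there is no dissolved-oxygen state
variable, since bulk oxygen is assumed non-limiting and intra-aggregate
oxygen transport is out of scope.

Growth is Monod-limited by extracellular glucose (`Km = 0.3 mM`) and
glutamine (`Km = 0.1 mM`) with `µ_max = 0.036 h⁻¹` (doubling time ≈ 19 h).
The biomass reaction drains precursor pools in fixed proportions; each
drain carries a small-`Km` (0.005) availability factor so the demand shuts
off smoothly as a pool approaches exhaustion instead of driving it
negative. The amino-acid demand vector is a placeholder proportional to
relative consumption rates and overridable in config.

Default rate constants sit at human-pluripotent-stem-cell literature
scale — specific glucose consumption ≈ 0.25 mmol/10⁹ cells/h, lactate
yield ≈ 1.8 mol/mol, glycolytic ATP-equivalent dominance — and are
labeled non-canonical: they were chosen once so that the default culture
reproduces the qualitative study contrasts (pyruvate lowers glucose and
glutamine consumption and raises alanine secretion; lactate suppresses
glucose uptake; starvation raises and anoxia crashes the redox ratio) and
then fixed. They are not estimates of any published parameter set.

Units: extracellular concentrations mM; intracellular pools mmol per 10⁹
cells; fluxes mmol per 10⁹ cells per h; VCD cells/mL. These combine as
`dC/dt = q·X·10⁻⁶ mM/h`.

The ODE system is integrated with LSODA at rtol 10⁻⁶ / atol 10⁻⁹,
split at oxygen-schedule breakpoints. Non-negativity is structural
(saturation factors vanish at zero), with a guard that rejects any
trajectory drifting below −100·atol. A 3-reaction toy network is checked
against Richardson-extrapolated fixed-step RK4 to 10⁻⁶ relative.

## Redox readouts

The enzymatic redox ratio is NAD⁺/(NAD⁺+NADH); the optical ratio is
FAD/(FAD+NAD(P)H). The model has no NADPH pool, so the optical ratio is
computed as FAD/(FAD+NADH) — an approximation that preserves the
qualitative behavior (both readouts are monotone images of the same
oxidation state here, which is why the synthetic dual-modality series are
rank-correlated).

Specific exchange rates use the log-mean VCD integral standard in batch
culture analysis: `q = −ΔC / (10⁻⁶ ∫X dt)` with the integral evaluated
piecewise under exponential growth between sampling points.

## ¹³C label propagation

MIDs are predicted by an EMU decomposition of the atom-mapped network:
starting from each tracked metabolite's full carbon set, producing
reactions are traced back through their atom maps, splitting each product
unit into the minimal substrate units whose balances close. Dynamic
(time-resolved) balances are the default — pools at 48 h of batch culture
are not at isotopic steady state — with the pool-size-weighted dilution
form `p·dm/dt = Σ v_in·(m_src − m)`; an isotopic steady-state shortcut
solves the size-cascaded linear systems instead. Fluxes and pool sizes are
interpolated from the culture trajectory, using gross forward and reverse
fluxes separately so reversible steps exchange label in both directions.

Boundary conventions: extracellular pools are fixed-MID boundaries (the
tracer mixture for the traced species, unlabeled otherwise — medium pools
are large relative to cellular exchange on the labeling horizon), and CO₂
consumed by pyruvate carboxylase is taken unlabeled, with CO₂ otherwise a
label sink. Tracer enrichment is molecule-level: a 99 %-enriched
[U-¹³C₃] tracer is 99 % fully-labeled molecules and 1 % unlabeled, so
positional labels are correlated rather than independent. Natural
isotopic abundance is not modeled (measured MIDs are assumed
pre-corrected); `convolve_correction` exposes a hook for a user-supplied
correction matrix.

The independent oracle integrates the full positional-isotopomer system
(2^c states per metabolite, exact for well-mixed pools since condensation
combines independent pools) and marginalizes to MIDs; it is capped at 20
total carbon positions and must agree with the EMU cascade to 10⁻⁶ per
mass channel on every shipped toy network, including a symmetric
fumarate-scrambling case (50/50 atom-map variants).

## Population balance

The aggregate size variable x is volume (µm³); diameters assume spheres.
The kernel's printed exponent is typographically ambiguous; the adopted
form is `exp(−k₁(x+x′)/(2a))` with the alternative `exp(−k₁((x+x′)/2)^a)`
behind `form="power"`. Defaults (`k = 1.2·10⁻¹¹ mL/h·µm^{−7/9}-scale`,
`k₁ = 1`, `a = 5·10⁷ µm³`, `α_G = 0.005 h⁻¹`, `M = 2.7·10⁸ µm³` ≈ an
800 µm aggregate) are fitted-scale: ~2000 aggregates/mL seeded near
265 µm mean diameter lose roughly two thirds of their number over five
days while the mean grows toward ~480 µm, the observed inverse
size–number relationship.

Coalescence uses the fixed-pivot sectional scheme on a geometric grid
(90 bins, 8 µm–1.5 mm diameter span): each merger product is split over
the two neighboring pivots conserving number and mass exactly, so the
constant-kernel count ODE is reproduced exactly up to integrator
tolerance and mass drift over five days stays below 0.5 % (limited only by
grid overflow). Growth advection is semi-Lagrangian: pivots move along
Gompertz characteristics (RK45 at rtol 10⁻¹⁰) and are remapped with the
same two-point rule. This replaces a flux-limited upwind scheme
deliberately: it has zero numerical diffusion of number and mass, and in
the pure-growth limit no remapping accumulates at all, so the mean of a
narrow pulse tracks the closed-form characteristic
`x(t) = M·exp(log(x₀/M)e^{−α_G t})` to integrator precision. With both
mechanisms active, operator splitting alternates coalescence and
advection sub-steps.

The sectional count trajectory is additionally checked against a
direct stochastic (Gillespie-type) simulation of pairwise coalescence
for 2000 particles.

## Reaction–diffusion

Aggregates are spheres with radial symmetry. Finite volumes on a uniform
radial grid handle the r = 0 singularity through the zero-area inner
face; the outer boundary is Dirichlet at the bulk concentration (no
external film resistance — well-stirred flasks; a Robin film condition is
available via `film_h`). The volumetric sink is the single-cell network's
exchange flux at the local extracellular concentrations times a constant
intra-aggregate cell density (default 2.5·10⁸ cells per mL of aggregate
volume), with the intracellular state held fixed (quasi-steady cells).
Growth-driven dilution inside aggregates is not modeled. Effective
diffusivities default to tissue-scale values (glucose 300 µm²/s, lactate
500 µm²/s, …), configurable per species.

Steady profiles come from damped Newton iteration on the method-of-lines
residual: the diffusion block is analytically tridiagonal per species and
the sink coupling is finite-differenced per species (vectorized over
nodes), assembled sparse. Convergence is declared at an absolute residual
scaled to both the sink magnitude and the roundoff floor of the discrete
diffusion operator (which dominates for very small aggregates). The
solver reproduces the zeroth-order parabolic profile, the first-order
Thiele profile `c(r) = c_R(R/r)·sinh(φr/R)/sinh(φ)` and the effectiveness
factor `(3/φ²)(φ·coth φ−1)` to 10⁻³ on 100-node grids, with second-order
grid convergence and surface-flux/volume-sink consistency within 1 %.

## Multiscale coupling

Per splitting step (default 0.5 h): (1) the size distribution advances
one coalescence+growth step, with the Gompertz rate scaled by
µ(bulk)/µ_max so aggregate expansion tracks metabolic state; (2) the
distribution is collapsed to 7 quadrature classes — contiguous count
quantiles represented by their mass-weighted mean size — conserving total
count and mass exactly; (3) each class's steady radial profile is solved
against the current bulk and its surface uptake, weighted by class
number density, updates the bulk balances; (4) a representative
intracellular state advances at bulk conditions; feeding events reset
medium concentrations instantaneously. VCD is the intra-aggregate cell
density times total aggregate volume per mL, with an exposed conversion
factor for calibrating dissociated-count measurements against that
integral.

Halving the splitting step changes 48-h bulk outputs by under 1 %
(a convergence gate in the test suite), and in the tiny-aggregate,
no-coalescence limit the simulator reproduces the monolayer model within
1 % — the structural consistency check between the two culture formats.
More quadrature classes improve the distribution integral at linear cost
in reaction–diffusion solves; 7 classes reproduce the mass integral of a
lognormal to well under 2 %.

## Calibration

The MSE objective averages squared residuals over datasets, state
variables, and each dataset's own time grid. Because it mixes units (mM
against cells/mL), each variable is normalized by its per-dataset maximum
absolute measurement before squaring — default ON; OFF reproduces the
literal objective, in which VCD dominates by ~10⁴. Replicates enter
through their mean. The KL objective compares per-time-point normalized
size distributions with 10⁻¹² smoothing on both sides (renormalized), and
is invariant under grid refinement of piecewise-constant densities. MAPE
excludes zero measurements with a warning — percentage metrics are
unstable at near-zero concentrations, which is also why low-concentration
species dominate reported MAPE tables.

Fitting is bounded multi-start local optimization (Latin-hypercube starts
plus the box center, deterministic per seed): trust-region least squares
when the objective exposes residual vectors, L-BFGS-B for scalar losses.
Two numerical choices matter in practice and are defaults: rate constants
are fitted in log₁₀ space (the landscape is far better conditioned across
multiplicative bounds), and the finite-difference Jacobian step is 10⁻³
in transformed units — well above the 10⁻⁶ ODE-solver noise floor, which
otherwise corrupts the gradient and stalls the optimizer at spurious
points. With these, all starts converge to the same optimum on the
synthetic suite, so cross-validation folds use a single start (the full
recovery benchmark uses three; the start count is a knob).

Identifiability: the acceptance benchmarks free four vmax-class
parameters (glycolysis, LDH, glutaminolysis, µ_max), each dominating one
observable family (glucose, lactate, glutamine, VCD). Km values are held
at literature-scale defaults; they are weakly identified by batch
trajectories that rarely traverse their saturation ranges.

The population-balance fit minimizes KL divergence between observed and
predicted distributions on days 1–3 only, over (log₁₀k, k₁, log₁₀α_G);
later days are excluded because declining viability distorts aggregation
dynamics that the model does not represent.

## Synthetic data

Generators are pure functions of (parameters, seed). The monolayer suite
reproduces the study layout exactly: four historic conditions (glucose
5.6/18.3 mM, lactate 0/20 mM, glutamine 2.7 mM, pyruvate 0.41 mM, seeded
at 3.2·10⁴ cells/mL, 6 replicates, sampled at 12/24/36/48 h) and four
pyruvate-supplemented conditions (glucose 10.4/33.6 mM, lactate 0/38 mM,
glutamine 4.69 mM, pyruvate 4.4 mM, 4.8·10⁴ cells/mL, 2 replicates,
24/48 h). Noise models: multiplicative Gaussian with fixed CV (default
5 %) for concentrations and VCD; additive Gaussian clipped to [0, 1] for
redox ratios; Dirichlet perturbation for MIDs with concentration chosen
so the expectation equals the clean MID (unbiased on the simplex).
Replicates are independent — shared-flask correlation structure is not
emulated.

Aggregate diameters are lognormal with day-wise means interpolating
265.4 µm (day 1) to 481.4 µm (day 5) linearly and a coefficient of
variation growing 0.15 → 0.30, emulating the observed upward shift and
spreading of the size distributions.

What passing tests show — and don't: the recovery and cross-validation
benchmarks demonstrate that the estimation machinery is correct and
well-conditioned when the data-generating process is the model itself
with independent multiplicative noise. Real cultures add model error
(compartmentalization, pH drift, viability decline), correlated
replicates and instrument-specific noise, so the synthetic MAPE values
bound optimizer/identifiability error only, not predictive accuracy on
experimental data.

## Known limitations

* No cytosolic/mitochondrial compartmentalization: a single pyruvate pool
  means TCA-intermediate labeling is overpredicted whenever exogenous
  pyruvate is heavily labeled, unless mitochondrial fluxes are
  parameterized low (slow citrate turnover reproduces the observed
  near-M+0 TCA labeling dynamically).
* Oxygen gradients inside aggregates are not modeled; the oxygen scalar
  acts only on oxidative phosphorylation globally.
* No aggregate breakage, dead-cell dynamics or shear effects; PBM fits
  should be restricted to the viability-stable early window.
* The energy (ATP) balance is implicit in lumped rate constants.
* All shipped kinetic parameters are synthetic-study calibrations, not
  measurements.
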