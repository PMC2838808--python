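# Methods

## The model and its role

`iterident` is an identification workbench for nonlinear dynamic
biochemical models written in control-affine form

    dx/dt = f(x, θ) + Σ_i u_i(t) · g_i(x, θ),      y_s = C x(t_s),

with binary piecewise-constant stimuli u(t), linear observables sampled at
discrete times and heteroscedastic Gaussian measurement noise.  The built-in
case study is the NF-κB regulatory module: 15 states (the IKK forms IKKn /
IKKa / IKKi, IκBα and A20 with their mRNAs, free NF-κB, the nuclear species
and the complexes, plus a control-gene transcript), 30 parameters, driven by
the TNF signal T_R ∈ {0, 1}.  TNF activates IKK (k1), active IKK
phosphorylates IκBα and thereby frees NF-κB, which translocates to the
nucleus (i1, volume ratio k_v = 5) and upregulates transcription of its own
inhibitors IκBα and A20; A20 in turn inactivates IKK (k2).  The interlocked
negative feedbacks produce the characteristic damped nuclear-NF-κB
oscillations (~100 min period under persistent TNF at the nominal
parameters).

Two structural facts anchor the test suite: active IKK is exactly zero in
resting cells, and the total NF-κB pool — free plus complexed, nuclear
species weighted 1/k_v — is conserved along every trajectory and equals
N_F = 0.06 µM (concentrations are cytoplasmic-volume normalised, so the
cytoplasmic volume V never appears on its own).

**Units.**  The customary values of the rate constants are per second
(e.g. c3a = 4·10⁻⁴ s⁻¹, a ~30 min mRNA half-life), while experiments are
specified in minutes and hours.  The model config therefore declares
`time_scale: 60`: all simulation and design bookkeeping is in minutes, and
the right-hand side carries the factor internally.  Parameter values are
used and reported exactly as customarily printed.

**Declarative definitions.**  Models are declared as sympy expression
strings (states, parameters, rhs, linear observables, seed state).  The same
definition feeds the numerical simulator (lambdified, with analytic state
and parameter Jacobians), the forward-sensitivity system and the symbolic
structural analysis; the NF-κB model additionally ships hand-written numba
kernels for speed, pinned against the symbolic definition by the test suite.
Control-affinity is verified symbolically at load time.

## Initial condition: the resting state

Wild-type experiments start from the unstimulated steady state.  It is
computed by integrating 10⁴ min with T_R = 0 from a documented seed state
(all IKK neutral at its production/degradation balance k_prod/k_deg, the
entire NF-κB pool bound in cytoplasmic IκBα|NF-κB complex), followed by a
Newton polish to ‖rhs‖ < 10⁻¹⁰.  Because the conservation law makes the
steady-state Jacobian singular, the conservation row is appended to the
Newton system, which keeps the polish on the correct invariant manifold.
During calibration the steady state is re-solved by Newton from the last
successful resting state (a ~1000× faster warm path); the result is
validated (residual norm, non-negativity) and the integration path is the
fallback.

## Noise model and the ES1 surrogate

Measurement noise is zero-mean Gaussian with σ = rel·|ŷ| + floor,
defaults rel = 0.10 (the customary "up to 10%" level) and floor = 10⁻⁶ in
each observable's units.  All experiments are in silico; replicates are
reproducible from a master seed, with replicate r's stream derived only
from (master_seed, r) so results are independent of execution order.

The published sampling schedules of the wild-type experiments are not
available, so a documented surrogate is used throughout ("ES1 surrogate"):

* persistent TNF, 4 h, 15 equispaced samples of the six observables
  A20 mRNA, total IKK (IKKn+IKKa+IKKi), active IKK, total cytoplasmic IκBα
  (free + NF-κB-bound), IκBα mRNA, nuclear NF-κB;
* persistent TNF, 6 h, 15 equispaced samples of nuclear NF-κB and total
  cytoplasmic IκBα;
* a 1 h TNF pulse, 6 h, same two observables.

The global ranking uses persistent, 1 h-pulse and 2 h-pulse stimulation
with all six observables over 6 h.

## Forward sensitivities

The variational system dS/dt = J_x S + J_θ, S(0) = ∂x₀/∂θ (with the
conservation row in the resting-state linearisation) is solved in two
passes: the states are integrated densely per stimulus segment (grid 0.5
min, geometrically refined just after each switch where the complex-
turnover modes of ~seconds live, never interpolating across a
discontinuity), then each sensitivity column is integrated against a cubic
interpolant of the trajectory with the analytic Jacobian (`engine="ode"`).
A midpoint exponential (Magnus) propagator over the same grid
(`engine="magnus"`) is exact for a frozen Jacobian, unconditionally stable
on the stiff decay modes and several-fold faster at ~1% accuracy; it serves
the screening loops (global ranking, design search).  The "ode" engine
agrees with central finite differences (step 10⁻⁵ relative, integrator at
10⁻¹¹) to 10⁻³ of each column's scale on the NF-κB model.

Relative sensitivities are s_rel = θ_j/max(|y|, floor_o) · ∂y/∂θ_j.  The
denominator floor is per observable: max(10⁻⁸, 0.01·max_t|y|).  A purely
absolute tiny floor lets samples where a signal has decayed to a sliver of
its range dominate any aggregate of s_rel — an artifact of the 1/|y|
weighting, not a property of the model — so the 1%-of-range component is
the default; both knobs are configurable.

## Structural identifiability

Observables are expanded around t = 0⁺: a Maclaurin series under constant
stimulus (Taylor variant) or a generating series over the alphabet
{f, g_i} (stimulus-family variant), with coefficients built from iterated
Lie derivatives and evaluated at the known resting state, which is treated
as a fixed known vector (the analysis asks about θ given x₀).  Expressions
are kept unexpanded and evaluated through CSE-compiled functions; Jacobians
with respect to θ use complex-step differentiation (machine precision for
these polynomial coefficient maps).  The rank test works in relative
coordinates (columns scaled by θ_j, rows normalised) with singular values
below 10⁻⁸·σ_max counted as zero, taking the maximum rank over several
random parameter draws; the series grows until the rank is stable for two
consecutive orders or an order cap (default 8 for toys; 4 is where the
15-state model reaches full rank).  Because the rank certificate is
numeric, a full-rank verdict without a completed symbolic reduction is
reported as *locally* identifiable.

The identifiability tableau is the boolean dependency pattern (structural
zeros detected at 5 random draws with tolerance 10⁻¹²·row scale).  The
minimum tableau takes the first rows in series order — order 0 for all
observables, then order 1, … — whose Jacobian already achieves the target
rank; when the full Jacobian is rank-deficient the same greedy selection is
labelled "partial" and only the sound part of the reduction runs.  The
reduction iterates: a row with a single surviving mark solves its parameter
(multiplicity from the polynomial degree, or a symbolic solve) and deletes
the column; stalled subsystems of up to 3 parameters are solved
symbolically with solution counts; anything that resists is reported
unresolved, never guessed.

On the NF-κB model the Taylor chain at order ≤ 3 solves exactly i1 (nuclear
import, from the first derivative of nuclear NF-κB), k1 (IKK activation,
from active IKK), c3a (IκBα-mRNA turnover, from its own first derivative)
and i1a (IκBα import, second derivative of nuclear NF-κB); the generating
series reaches full rank 13/13 at order 4 (t1 enters last — it multiplies
complexes that vanish at rest and needs three derivatives to become
visible).

## Global ranking and the θ_κ partition

Latin-hypercube samples (one draw per equal-probability interval per
parameter, seeded random pairing) are taken log-uniformly in three
reference-centred boxes: (θ*/2, 2θ*), (θ*/10, 10θ*), (θ*, 100θ*).  For
each draw the relative sensitivities over the three wild-type schemes are
aggregated into the importance factors

    δ_msqr = sqrt(mean s_rel²),  δ_mabs = mean |s_rel|,  δ_mean, δ_max, δ_min,

with N_D = n_lhs·n_e·n_o·n_s summands, plus per-experiment and
per-observable slices.  Failed draws are excluded and counted (> 20%
failures aborts).  The ranking uses δ_msqr averaged over the ranges; ties
break lexicographically.  Parameters whose factor falls below 1% of the
top value are proposed for fixing — on the NF-κB module that removes e2a,
t2 and t1, giving the 10-parameter subset θ_κ used for calibration.

## Calibration

The cost is the weighted least-squares function J(θ) = Σ (ỹ−y(θ))²/σ²
(maximum likelihood under known Gaussian noise; exact in-silico points with
σ = 0 get unit weight).  Simulation failures return the finite penalty
10¹⁰·(1+‖θ‖) — θ-dependent so the optimizer never sees a plateau — instead
of an exception.  The optimizer searches log₁₀-transformed box-bounded
parameters (they span orders of magnitude): a seeded Latin-hypercube
population feeds a reference set of best plus max-min-diverse members,
recombined pairwise with random line steps (r ∈ [−0.3, 1.3] per
coordinate), with periodic and final bounded trust-region Gauss-Newton
polish of the incumbent; everything is deterministic given the seed, and
the best-so-far trace is monotone by construction.  Default budget 10⁴
evaluations; Monte-Carlo replicate fits use a warm profile (no global
phase, local refinement started from the generating truth a priori, or
from the data fit a posteriori, budget 400).  Default bounds (θ*/10, 10θ*).

## Practical identifiability

A priori: n_reps in-silico replicates at the truth → warm calibration per
replicate → the solution cloud.  A posteriori: fit once, estimate the noise
scale from the weighted residual RMS, resample around the fitted
predictions.  The cloud is trimmed to its per-coordinate [0.05, 0.95]
quantile box (robust to estimates piling at the bounds), coordinates are
normalised by their trimmed means (so cross-parameter comparisons are
scale-free), and the covariance is decomposed into principal axes.
Reported per parameter: μ (trimmed mean), δ% = 100·|μ−θ*|/θ* (a priori
only), C_θ = half the [0.05, 0.95] interval width (config switch to
max-deviation), C% = 100·C_θ/μ.  Pairwise eccentricity measures
*correlation*: each coordinate is standardised to unit variance, so the
2-D ellipse axis ratio is sqrt((1+|ρ|)/(1−|ρ|)); without the
standardisation a pair of uncorrelated parameters with very different
relative uncertainties would masquerade as "eccentric".  Eccentricities
are capped at 10³ with a degeneracy flag.  The pseudo-volume (an overall
accuracy measure) is the product of the semi-axes of the mean-normalised
cloud's principal-axis ellipsoid.  Cost contours over parameter pairs use the χ²-style sub-level
set {J ≤ Jmin + 5.99}, whose principal-axis anisotropy flags correlation
valleys and whose contact with the grid boundary flags open-ended
(non-identifiable) directions.

## Optimal experimental design

The Fisher information F = Σ s sᵀ/σ² (sensitivities at the current
reference μ, σ from the noise model on the predicted signals) is additive
over experiments; new experiments maximise criterion(F_prior + F(design)),
D = det or E = λ_min (E is the default — it shrinks the longest ellipsoid
axis, i.e. the worst correlated direction).  Decision variables: up to 2
pulses encoded as sorted switch fractions (min width 1 min, a dangling
"on" closes at the horizon), the duration (default bounds 2–8 h), and up
to 15 sampling times encoded as positive gaps with min spacing 1 min —
all repaired, never rejected.  The search is seeded differential evolution
over the encoded unit cube with an explicit Latin-hypercube initial
population sized to the evaluation budget (default 600); the E-criterion
is non-smooth, so no gradient method is used.  Predicted uncertainties come
from the inverse (pseudo-inverse, flagged when singular) of the total FIM.

## The identification loop

One seeded configuration drives: optional structural analysis → ranking →
θ_κ partition → per iteration: a-priori Monte-Carlo cloud → uncertainty
report → freezing of parameters with δ% < 1 and C% < 10 (the order of the
measurement error) at their current μ → E-optimal design of a
complementary experiment with the current scheme's FIM as prior → repeat
(max 4 iterations).  Stage seeds derive from the master seed, reports are
timestamp-free JSON/CSV, and identical configs give byte-identical output.

## Problem sizes used by the test suite and acceptance script

Chosen so the whole suite runs on one CPU core in well under half an hour:
ranking at 40–60 LHS draws per range (the top/bottom groups are separated
by an order of magnitude, so small samples suffice); the ES1 Monte-Carlo
study at 200 replicates with warm-started fits; the loop-improvement check
at 60 replicates per cloud, three master seeds, OED budget 200.  The
acceptance script (`scripts/acceptance.py`) recomputes the ES1 cloud at
200 replicates.

## Known limitations

* The ES1 sampling schedules are surrogates; quantities that depend on the
  schedule (absolute C% levels, eccentricity magnitudes) should be read as
  order-of-magnitude reproductions, not replications.
* Warm-started replicate fits converge tightly along flat directions, so
  the cloud reflects the information content of the data with less
  optimizer-induced scatter than a cold multistart would add; weakly
  identified parameters may therefore show somewhat smaller C% than a
  full global-search study.
* The structural verdict for large models is numeric-local (random-draw
  Jacobian rank); global distinguishability of discrete parameter
  alternatives is outside scope.
* Synthetic data only: the noise generator emulates heteroscedastic
  Gaussian errors with independent replicates — no day effects, no
  correlated blotting errors, no systematic calibration bias; passing
  tests say nothing about those real-data failure modes.
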