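# Methods

## The model

`erlangcell` implements a Markovian multi-stage representation of a dividing
and dying cell population. A cell must traverse `N` sequential "stages"
(abstract exponential compartments, not biological cell-cycle phases), each
left at rate `lambda` (1/h), before it divides; at every stage an independent
exponential death clock with rate `mu` competes. The time to division is
therefore Erlang(`lambda`, `N`) distributed, which removes the exponential
distribution's excess of implausibly short division times while keeping the
whole system a linear Markov process.

Two variants are exposed:

* **Stage-cycling (MS)** — `StageChain`: a dividing cell's two daughters
  re-enter stage 1 of the same pool. Mean stage counts `M_j(t)` obey a
  linear ODE system whose closed-form solution is a sum over the `N`-th
  roots of unity; the package evaluates it in complex arithmetic and asserts
  that the imaginary residue stays below `1e-9 * C0` before taking real
  parts (the sum is provably real; floating point leaves residue).
* **Generation-tracking (MS-G)** — `GenerationSchedule`: daughters enter
  stage 1 of generation `g + 1`, matching how CFSE dye dilution classifies
  cells by completed divisions. Stage counts `N_g`, birth rates `lambda_g`
  and death rates `mu_g` may depend on the generation. Two death laws are
  supported, because both regimes are scientifically meaningful: a constant
  override `mu_g = mu` (under which the MS-G model collapses exactly onto
  the MS model when `N` and `lambda` are shared) and the linear law
  `mu_g = alpha * g`, expressing that cells become more death-prone as they
  accumulate divisions (so generation 0 never dies).

Founder cells always start in stage 1 of generation 0; the closed forms are
derived for that initial condition. Arbitrary nonnegative initial vectors
are accepted by the ODE engine and the simulator only — the constants that
would generalise the root-of-unity solution to other initial conditions are
not implemented, and such inputs are routed to the matrix-exponential path.

Key analytical results carried by the package, all covered by tests:

* late-time growth exponent `sigma_N = 2^{1/N} - 1` (per-capita rate
  `sigma_N * lambda - mu`), with `N * sigma_N -> log 2`: many short stages
  are *not* equivalent to one slow exponential step;
* ultimate extinction probabilities from the first-step recursion, with the
  closed branch `p_1 = (1-r)^{-N} - 1` (`r = mu/(mu+lambda)`) below the
  boundary `mu = sigma_N * lambda` and certain extinction at or above it;
* stationary stage occupancies `P*_j = (2^{1/N})^{N-j}(2^{1/N}-1)`,
  independent of rates and initial condition;
* per-compartment MS-G closed forms (Poisson-like terms in `lambda t`,
  evaluated through log-gamma so `Ng + j - 1` never overflows a factorial)
  and the single-stage partial-fraction forms.

## Numerical engines

**Matrix exponential.** The stacked MS-G mean system `dM/dt = A M` has a
*lower bidiagonal* coefficient matrix in generation-major ordering (the only
inter-generation entry, the doubled division flux, lands on the first
subdiagonal). The default solver exploits this by uniformisation: with
`theta = max(lambda_g + mu_g)` and `B = I + A/theta` (entrywise
nonnegative), `exp(At)v` is a Poisson-weighted series of `B^k v` with no
cancellation. Legs are capped at `theta * dt <= 500` so the weights stay in
normal double range, the series is truncated when the running term falls
below `1e-16` of the accumulated sum, and the inner loop compiles with
numba when available (a vectorised numpy fallback implements the same
recurrence). A dense scipy `expm` route is retained as an independent
cross-check and agrees to ~1e-13. Trajectories are validated nonnegative
(tolerance `-1e-9` relative, then clipped).

Overflowing draws (population beyond double range) raise a solver failure;
the inference layer converts that to an infinite distance.

**Generation truncation.** Mean solves track generations `0..G_max`
(default 15). Truncation only affects generations above `G_max` — the
cascade is lower triangular — but the merged "5+" observation class sums
the tail, so after every fit-path solve the terminal generation's share of
the population is checked against `1e-6`; violations double `G_max` (up to
95) and re-solve. Parameter draws so explosive that the dye range cannot
contain the population predict near-zero class counts and are rejected by
their distance; they cannot be *accepted* erroneously, because losing mass
can only move a prediction away from data.

**Stochastic simulator.** Exact Gillespie dynamics over (generation, stage)
compartments: cells within a compartment are exchangeable, so aggregated
hazards (`n * lambda_g` advance/divide, `n * mu_g` death) preserve
exactness at a fraction of the cost of per-cell event queues — necessary at
`C0 ~ 1e4-1e5` founders. The total hazard is maintained incrementally and
refreshed every ~4 million events to bound floating-point drift. Generations
extend dynamically (the biology has no ceiling; the dye does — merging to
"5+" happens only at observation time); a practical cap of 256 generations
and a configurable cell-count cap (default 1e9) convert runaway runs into
explicit errors, never silent truncation. Replicates draw substream seeds
from a `SeedSequence`, and the event loop uses only the Mersenne-Twister
`np.random` primitives so the numba-compiled and plain-Python paths produce
identical realisations.

Extinction estimation declares survival early once a run reaches an escape
threshold (default 1000 cells); the bias is bounded by the probability that
a 1000-cell supercritical population later dies out, which is negligible
against the binomial standard error at the replicate counts used.

**Cyton integrator.** The cyton model (independent division/death clocks
per generation, progressor fraction `gamma_g`) is integrated on a uniform
grid: generation-0 fluxes from the survival-weighted closed forms, later
generations by trapezoidal convolution, and generation means by cumulative
trapezoid — globally second order. The default step is `0.005 / max(rate)`:
at the more natural-looking `0.02 / max(rate)` the peak-normalised deviation
from the closed forms is ~6e-4 for exponential clocks, too coarse to serve
as a 1e-4-level oracle, while 0.005 gives ~4e-5 (halving the step quarters
the error, as the tests verify). Each clock density must pass a Simpson
normalisation self-check on the grid (tolerance 1e-6), which doubles as the
grid-resolution guard. Deviations are always quoted relative to each
generation's trajectory peak: generation curves span more than ten orders of
magnitude, and pointwise relative error at numerically-zero values carries
no information. Only exponential and Erlang clock families ship (the
exponential family admits rate 0 as the "never fires" death clock);
`gamma_g = 1` is the regime in which the cyton model coincides with the
generation-tracking models, and nothing is claimed for `gamma_g < 1`.

## Synthetic experiments

`generate_dataset` emulates an adoptive-transfer CFSE experiment: each
mouse is one independent realisation of the truth schedule observed at its
sacrifice day, with generations >= 5 merged into "5+". Defaults:

* design — sacrifice days (3, 4, 5, 6, 7, 10, 12, 18), with 3-7 mice per
  day drawn (seeded) from the design range;
* truth — `C0 = 4.5e4` transferred cells, generation 0 with 3 stages at
  0.05/h (mean 60 h to first division — activation is slow), later
  generations with 5 stages at 0.12/h (mean ~42 h), death slope
  `alpha = 2e-4`/h per division. These describe a fast, strongly
  proliferating CD8 clonotype under lymphopenia.

The noise is purely demographic: no measurement-error overlay (the fitting
target models means against empirical SDs and specifies no observation
noise), identical `C0` for every mouse (engraftment is treated as a single
unknown), and per-mouse counts rather than pooled organ totals. Passing
tests therefore certify the estimation machinery under ideal sampling; real
CFSE data add classification error near the dye limit, engraftment
variability and between-mouse heterogeneity that this generator
deliberately omits — as does the model itself, which excludes resource
competition (density-dependent birth rates), sibling correlations and
carrying capacities.

Summaries use the sample mean and the `ddof=1` sample SD per (class, time),
floored at 1 cell: the calibration distance divides by the SD, and the
floor covers single-replicate and identical-replicate degeneracies.

## Calibration

The distance between a parameter draw `theta = (C0, N0, N, lambda0,
lambda, alpha)` and the data is the standardised Euclidean norm over the
six generation classes and the design time points,
`d = sqrt(sum [ (x_M - x_D)/sigma_D ]^2)`. Priors are uniform: on the
base-10 exponent for `C0` (4..6), `lambda0`, `lambda` (-3..1) and `alpha`
(-5..-1), discrete on `{1..50}` for the stage counts. The exponential
variant pins `N0 = N = 1`.

The ABC-SMC scheduler sets the first tolerance to the median distance of
`n_prior_predictive` prior draws (default 10^4); those same draws, filtered
at that tolerance, *are* the first population — prior samples conditioned
on acceptance, so no second sampling pass is needed. Subsequent tolerances
are the median of the previously accepted distances (hence strictly
decreasing). Proposals resample the previous population by weight and
perturb with a uniform kernel — half-width equal to half the weighted SD of
each exponent, `{-1, 0, +1}` equiprobable on the stage counts, out-of-prior
proposals redrawn — with standard sequential importance weights (uniform
priors make the weight the reciprocal kernel mixture). Default iteration
counts are 16 (multi-stage) and 7 (exponential); a proposal budget per
iteration (2000 x particles) converts acceptance-rate collapse into an
early stop flagged on the returned posterior.

Model comparison uses a corrected Akaike score built from the best accepted
distance, `AICc = n ln(d_min^2/n) + 2k + 2k(k+1)/(n-k-1)`, with `n` the
number of (class, time) cells and `k` the free parameter count (6 vs 4).
This treats the squared distance as a weighted RSS under a Gaussian working
likelihood; it is one defensible convention, deliberately isolated in a
single function so another can be swapped in. Credible intervals are
weighted equal-tailed quantiles of the final population, on the exponent
scale for the log-sampled parameters.

## Problem sizes used in the tests

The test suite runs the recovery experiment at a reduced scale chosen to
exercise every code path at meaningful statistical power: first-week
designs (days 3-7, 5 mice/day — the window in which a fast clonotype is
informative before resource competition, which the model excludes, would
dominate), 200 particles, 8 SMC iterations, and 2000 prior-predictive
draws for the first tolerance, over 10 seeds. Coverage is assessed the way
calibration of a Bayesian procedure is normally tested: each repetition
draws its truth from the prior (screened only for simulability — mean-field
populations above ~3e6 cells by the last design day are redrawn), generates
a dataset from it, fits, and checks whether the weighted 95% intervals
contain the truth; under prior-drawn truths nominal intervals must cover at
~95% whenever the sampler is honest, at any stopping tolerance. A fixed
truth sitting at the edge of the stage-count/rate ridge is *not* covered at
this deliberately early stopping point — at eight iterations the tolerance
is still far above the demographic noise floor of the synthetic data, and
the intermediate posterior's `N0`/`lambda0` marginals are volume-dominated
by the high-`N0` end of the ridge (the paper-scale sixteen iterations
nearly resolve it); this is a property of early-stopped ABC, not of the
estimator at convergence. The model-comparison check fits both variants to
data generated by the default multi-stage truth and requires the corrected
Akaike score to prefer the multi-stage variant. Ensemble checks use 2000
replicates with 3-SE bands
(Poisson-floored for near-empty compartments and, where dozens of cells are
compared at once, a 10% allowance for 3-sigma exceedances).

## Known limitations

* Only serial per-stage chains (Erlang division) are represented; general
  phase-type division-time generators are out of scope.
* The closed-form single-stage (partial-fraction) solution is numerically
  ill-conditioned when generation rate sums nearly coincide; coincident
  sums raise an explicit error and near-coincident ones should be routed to
  the matrix-exponential engine (which the fitting path always uses).
* The AICc convention, the effective sample size `n`, and the perturbation
  scale of the ABC kernel are package choices where the methodology admits
  alternatives; each is isolated and documented above.
* Extremely explosive parameter draws are rejected through the
  truncated-system distance rather than an analytic bound; this is
  conservative (see "Generation truncation") but means their reported
  distances are a floor, not an estimate.
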