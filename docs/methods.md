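# Methods

## Model

`moodkf` models an individual's mood as a time-invariant linear-Gaussian
state-space process on a one-minute grid.  The latent state
`z_t ∈ R^N` (one coordinate per mood item) evolves every minute as

    z_t = A z_{t-1} + h + C u_t + eps_t,    eps_t ~ N(0, Sigma),

and is observed only at beep times, through the identity map,

    x_t = z_t + eta_t,                      eta_t ~ N(0, Gamma).

Sigma and Gamma are diagonal: noise is uncorrelated across items, and
all cross-item structure must come through `A` (interpretable as a
directed influence network: `a_ij` is the effect of item `j` on item
`i` one minute later) or through shared inputs.  Context inputs `u_t`
are one-hot vectors placed only on the grid rows where they were
reported; between beeps the latent state evolves freely.  The grid
spans the first to last beep including overnight gaps — long gaps are
handled by the same mechanism as short ones, which is the entire point
of the minute-grid formulation.  Timestamps are rounded to the nearest
minute; two beeps on the same minute are an error rather than a merge.

Assumptions worth stating plainly: linear time-invariant dynamics (no
switching, no slow parameter drift), Gaussian noise despite bounded
Likert scales, punctate inputs (a context report affects only that
minute), and a diagonal observation map (each rating measures exactly
one latent coordinate).

### Derived analytics

* **Timescale conversion.**  `matrix_power_rescale(A, s)` computes the
  principal eigen-power `V D^s V^-1`.  Eigen-pairs are sorted by
  descending real part (ties by descending imaginary part) and each
  eigenvector's largest-magnitude component is made positive, so
  reported eigenstructure is deterministic.  Hourly dynamics are
  `A^60`; fixed points are invariant to the conversion (the drive is
  resummed geometrically).
* **Stability.**  Eigenmodes are `V^-1 z`; each decays with its
  eigenvalue.  The determinant |A| (product of eigenvalues) summarizes
  overall persistence; it is reported with an explicit timescale tag
  because the per-minute and hourly values differ enormously
  (`|A^60| = |A|^60`).
* **Controllability.**  The block matrix `[C, AC, ..., A^{n-1}C]`
  (horizon defaults to N) is decomposed by SVD; left singular vectors
  with larger singular values are directions movable with less input
  energy.  The infinite-horizon Gramian `sum A^k C C' A'^k` is offered
  separately (discrete Lyapunov solve) for users who expect the
  Gramian proper.
* **Control planning.**  `plan_optimal_inputs` minimizes
  `sum_t (z_t - g)' Q (z_t - g) + sum_t u_t' R u_t` subject to the
  noise-free dynamics, solved exactly by a backward value recursion
  (affine LQ tracking); Q and R default to identity.  The terminal
  error decreases as R → 0 for targets inside the reachable subspace
  and saturates at the unreachable-component residual otherwise (with
  K < N inputs and slow dynamics the effective reachable subspace over
  a finite horizon can be much smaller than R^N).  An optional [0, 1]
  box constraint is solved by projected gradient on the stacked
  quadratic program and is approximate.  `min_energy_input` solves the
  exact-terminal problem by pseudoinverse of the horizon reachability
  matrix.

## Inference

The E-step runs the Kalman filter and RTS smoother over the full minute
grid (numba-compiled; tens of thousands of steps per pass).  Updates at
a beep are applied as sequential scalar-observation updates in Joseph
form — valid because the observation map is the identity and Gamma is
diagonal — skipping missing items; the marginal log-likelihood
accumulates the scalar predictive densities exactly.  Lag-one smoothed
cross-covariances come from the smoother gain
(`Cov(z_{t+1}, z_t | x) = P^s_{t+1} J_t'`).

The M-step is closed-form: `[A, h, C]` solve one joint linear system in
the smoothed transition moments; Sigma and Gamma are expected residual
variances projected to diagonal and floored at 1e-10; `mu0` absorbs the
first-state term (the first-state prior covariance `P0` is a fixed
identity by default, with an optional update flag — the model statement
itself does not pin it down).  If an M-step leaves the spectral radius
of `A` at or above 1, eigenvalue magnitudes are shrunk to `1 - 1e-6`
preserving eigenvectors — the minimal stability intervention.
Convergence is declared when the relative log-likelihood gain falls
below `tol` (default 1e-6, `max_iter` 200).  A log-likelihood decrease
beyond tolerance raises (EM guarantees monotonicity when no projection
was applied); after a projection it warns and stops.

**Initialization** is moment-matched: `A = 0.99 I` plus small seeded
jitter, `h = C = 0`, and the observed per-item variance split evenly
between the stationary latent process (giving
`Sigma = 0.5 var (1 - 0.99^2)`) and observation noise
(`Gamma = 0.5 var`).  The split matters: EM moves variance parameters
slowly, and an initialization that attributes all variance to
observation noise leaves the fitted process noise near zero at any
practical iteration budget, which silently destroys surrogate
simulation and dynamics recovery.  Estimation is deterministic given a
seed; an optional multi-start flag re-runs from jittered
initializations and keeps the best likelihood (the likelihood surface
is non-convex, so single-start results are local optima).

## Synthetic data generator

The generator emulates a standard experience-sampling acquisition:

* **Schedule** — 10 beeps/day, one uniform draw inside each of ten
  equal blocks of the 9:00–23:00 window, resampled (bounded retries,
  then a deterministic shift to the earliest feasible minute) until
  consecutive beeps are ≥ 30 minutes apart; 2–14 days.
* **Systems** — `A = Q D Q'` with `Q` random orthonormal and real
  eigenvalues stratified (evenly spaced plus jitter) across the slow
  band [0.995, 0.9995] per minute; a fast regime [0.8, 0.9] exists for
  process-speed experiments.  Stratification keeps the eigengap away
  from zero so "the dominant direction" is well defined.  The fixed
  point is standard normal per item and `h = (I - A) fp`; process
  noise defaults to 1e-4 per minute (observation-noise-dominated
  regime); observation noise variance spans 0.1–5; optional sparse
  random `C`.
* **Realism knobs** — optional 1–7 Likert rounding of observations and
  independent item nonresponse (`missing_rate`), emulating typical EMA
  compliance.

What the generator does *not* emulate: bounded-scale floor/ceiling
effects beyond optional rounding, autocorrelated or duration-valued
context inputs, structured (non-random) missingness, or between-day
nonstationarity.  Passing tests therefore demonstrate internal
consistency of the method under its own assumptions, not robustness to
every property of real clinical EMA data.

**Recovery studies** simulate, re-fit, and score: NRMSE (RMSE divided
by the range of the true values; a std-normalized variant is a flag)
between true and estimated parameters, per-trajectory NRMSE averaged
over items for latent states, absolute dot products between unit-norm
dominant eigenvectors, and controllability singular structure when
inputs are present.  Two reporting choices deserve emphasis:

* Dynamics-matrix recovery is scored on the *hourly* matrix `A^60` as
  well as the per-minute `A`.  All slow-regime per-minute matrices lie
  within ~0.004 of each other on an entry range of ~1, so per-minute
  NRMSE differences between study cells are in the fourth decimal —
  metric noise.  The hourly power spreads the same structure across
  [0.74, 0.97] and makes recovery quality visible.
* Factor cells share replicate seeds (common random numbers), pairing
  the factor comparisons and sharply reducing between-cell Monte-Carlo
  variance.

Studies default to 100 replicates per cell (a `--full` flag gives
1000); the validation suite uses 50 per cell and 30-iteration fits so
the whole run stays within minutes on one CPU.

**Known identifiability limits** (quantified by the studies): hourly
eigenvalues are biased toward faster decay on short series; the
dominant eigenvector saturates between 6 and 14 days under the slow
band (adjacent per-minute eigengap ~0.0015, hourly 0.97 vs 0.94 — the
data barely distinguish the two slowest modes, and paired comparisons
show ~50% win rates for 14 vs 6 days), so eigenvector recovery
improves sharply from 2 to 6 days and then flattens; free estimation of
sparse input weights adds many weakly-identified parameters and does
not improve dynamics recovery.

## Features, VAR baseline, surrogates

Summary features use the conventional beep-order definitions: inertia
is the lag-1 autocorrelation over consecutive beeps regardless of gap
length (a gap-stratified within-day variant is a flag), RMSSD is the
root-mean-square of successive differences, moments are
pairwise-deleted.  The VAR(1) baseline is per-equation OLS of each beep
on the previous beep, dropping pairs with any missing entry — the
discrete-time simplification the state-space model exists to avoid.
Surrogate checks re-simulate each individual from their fitted
parameters *on their own empirical beep schedule* (the conservative
choice) and correlate surrogate features with empirical features across
individuals, in parallel for the VAR route.  On complete data the VAR
route matches beep-order lag-1 autocorrelation essentially in-sample
(OLS fits exactly that statistic), so the state-space route's advantage
appears where real data live: with missing entries (which delete VAR
pairs wholesale) and at lags beyond one.

## Group statistics

Eigenvectors and singular vectors are sign-indeterminate, so group
pipelines first align each subject's vector against a valence reference
(`[+1, +1, -1, -1]` for cheerful/content/anxious/sad; flip iff the
inner product is negative, zero inner products flagged and left alone).
Aligned samples are compared with two-sample Hotelling T² (pooled
covariance, exact F conversion); univariate per-component comparisons
use Mann–Whitney U on absolute component values; symptom associations
use Spearman correlations; element-wise families (the N² dynamics
matrix entries) are Bonferroni-controlled with configurable family
size.  Group pipelines operate on hourly matrices by default.  The U
statistic reported is that of the first group; two-sided p-values
throughout.  Calibration is checked by Monte-Carlo simulation of whole
studies on synthetic eigenvector populations (mean direction plus
isotropic noise on the unit sphere, random sign flips): type-I error is
nominal and a planted valence-ward rotation of the mean direction is
detected with power above 0.8 at n = 20 per group.

## Numerical choices

* Joseph-form covariance updates and symmetrization after every
  predict/update keep covariances PSD.
* Matrix powers require a numerically diagonalizable matrix
  (eigenvector condition number below 1e12); non-integer powers of
  eigenvalues with non-positive real part take the principal branch
  with a warning; results with residual imaginary magnitude above
  tolerance warn and return the real part.
* Variance floors at 1e-10 prevent EM collapse; a tiny scaled ridge
  stabilizes the M-step normal equations.
* `I - A` is treated as singular above condition number 1e12, in which
  case fixed points are reported absent with a reason rather than
  computed.
* Degenerate inputs: a single-beep series yields a one-point grid
  (smoothed = filtered); an all-missing item is an error naming the
  item; duplicate beep minutes are an error naming the subject and
  minute.
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; study seeds are split with `SeedSequence`
  so replicates are independent and reproducible.

## Limitations

Linear dynamics cannot express multiple fixed points, limit cycles, or
state-dependent reactivity; Gaussian observation noise ignores Likert
boundedness; parameters are assumed constant over the fitted window
(fit phases separately when that is implausible); EM finds local optima
only; with K < N inputs most of mood space is only weakly controllable
over short horizons, so control plans should be read as directional
guidance, not point steering.
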