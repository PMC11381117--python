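# Methods

## Models

**Proxy process.** The signed maximum-deviation reach error evolves as

    e_{n+1} = e_n + f(e_n, ..., e_{n-k+1}) + sigma * dz_n,

with `dz` a standard-normal Wiener increment injected once per trial
transition and `sigma >= 0` its scale in cm. Eleven drift structures are
supported (four first-order polynomials in the current error and the
k-th-order linear-history family for k = 2..8). A simulation needs one
initial condition `e0` — the first-trial error of the curve; a k-deep
history is seeded by repeating `e0` k times. This padding is a package
choice: it is parameter-free and preserves the single stated initial
condition; nothing in the data constrains the pre-experiment history.

**Two-rate learner with proxy support.** A fast and a slow internal state
update on an error estimate ê:

    xf' = Af xf + Bf ê,   xs' = As xs + Bs ê,   yhat = xf + xs,
    ê_n = e_n                                   if observed,
          ê_{n-1} + a + b1 ê_{n-1} + b2 ê_{n-2} (+ sigma dz)  otherwise,

with the constraints `As > Af` (the slow state retains more) and
`Bf > Bs` (the fast state learns more). Both states start at zero, and
`yhat_n` is the model's prediction of the signed error on trial n. The
embedded second-order coefficients (a, b1, b2, sigma) are frozen at the
values obtained from the proxy-process regression of the same curve.

**Washout decay.** Post-training error magnitudes are fitted with
`A * exp(-n / tau)` (n = washout trial index from 0, tau in trials,
bounded (0.1, 300]); tau indexes skill retention. An optional additive
offset term is available and is used by the pipeline because the
generator's half-normal magnitude noise has a non-zero mean that would
otherwise inflate tau (without the offset the recovered tau is biased high
by ~20% at the default noise level; with it, recovery is within a few
percent).

## Estimation

All fitting is deterministic least squares (the Wiener term is switched
off; sigma enters only simulation and reporting). "Global search" is
realized as seeded multi-start bounded least squares
(`scipy.optimize.least_squares`, trf) — best of `n_starts` local solves
from uniform draws inside the bounds, with a deterministic first start at
the no-drift/no-learning baseline (zeros clipped into the box). Analytic
Jacobians are propagated through the trial recursion by forward
sensitivity analysis (verified against finite differences in the tests);
the inner recursions are JIT-compiled with numba with pure-Python
fallbacks.

Default coefficient bounds: a ∈ [−5, 5] cm/trial; b-coefficients ∈ [−2, 2];
c ∈ [−1, 1]; d ∈ [−0.5, 0.5]; Af, As ∈ [−1, 1]; Bf, Bs ∈ [−2, 2]. The
two-rate constraints are enforced by reparameterization
(Af, dA ≥ 0, Bs, dB ≥ 0 with As = Af + dA, Bf = Bs + dB) plus a penalty
residual keeping As ≤ 1. Trajectories are capped at 1e8 and flagged
divergent; divergent objectives evaluate as large flat residuals, so the
optimizer rejects that region. Curve-level divergence is reported, and
divergent curves are excluded (with a log entry) from steady-state tables.

**Objective semantics.** The default proxy-process objective simulates the
deterministic recursion over *all* consecutive trials from `e0` and sums
squared deviations at the observed no-vision trials. An alternative
"anchored" objective — forward predictions re-anchored at every observed
error, i.e. the gap-bridging semantics the two-rate learner uses — is
available on `ProxyProcessModel`. It was not made the default because it
biases single-curve coefficient estimates: conditioning on re-anchored
data lets richer histories act as better one-gap-ahead predictors even
when the generating process is second-order, which distorts both the
recovered coefficients and structure comparison.

**Noise scale.** `sigma` is estimated as the (population) standard
deviation of the fit residuals divided by the number of learning-curve
trials. The divisor is configurable (`n` or `sqrt_n`); the plain-`n`
reading is the default.

**Residuals** exist only at no-vision trials — the error metric is defined
nowhere else. For the two-rate fit the trial-0 observation seeds ê and is
excluded from the objective (its prediction is identically zero, a
constant residual).

## Model selection

Within each EA coordinate, subjects are exhaustively partitioned 4/5 : 1/5
(test size max(1, round(n/5)); all C(n, test) splits); within each control
subject, learning tasks are partitioned the same way. For each partition
and structure the *average model* of the training fits is simulated on
every test curve from that curve's own `e0` and scored by RMSE at its
no-vision trials; the partition is summarized by the mode of a Gaussian
KDE (Silverman bandwidth, 512-point grid over the data range ± 3
bandwidths) across its test-curve RMSEs. Partition values are pooled
across coordinates/subjects, then every ordered pair of structures is
tested with a left-tailed Wilcoxon signed-rank test at alpha = 0.01,
Bonferroni-corrected by the number of ordered pairs (110 for 11
structures). Model score = wins − losses; ties at the top are reported as
co-winners.

**Average model = coefficient-wise median.** Single-curve least-squares
estimates of these recursions are heavy-tailed: on a noisy curve the
global minimum occasionally sits in a different dynamical regime, pinning
a b-coefficient near its bound. An arithmetic mean over a training set is
dragged by one such fit into dynamics unlike any member's, and in seeded
experiments this randomized the structure ranking; the coefficient-wise
median — still a single parameter set, permutation-invariant, identical
to the mean for one or two fits — keeps the average model inside the
consensus regime, and the generating structure then wins the
cross-validation in essentially every replicate. The arithmetic mean
remains available (`average_model(..., method="mean")`).

Pooling choice: test-curve RMSEs are pooled within a partition and the KDE
mode is taken across them; whether to KDE per curve first is not
determined by the procedure's description, and this is the simpler
reading.

## Inference

Bootstrap resampling is weighted by 1/RMSE of each contributing fit, with
the RMSE floored at its 1st percentile across curves so near-perfect fits
cannot dominate. The exact bootstrap construction of the tests is a
package choice, built to preserve classical calibration:

* each of B replicates resamples the sample(s) with the weights;
* the test statistic (sign count for the sign test, Mann-Whitney U for the
  rank-sum) is computed per replicate;
* the consensus statistic — the median over replicates — is referred to
  its classical null distribution: the exact Binomial(n, 1/2) for the sign
  test, the continuity-corrected normal approximation for the rank-sum.

Under equal weights the consensus statistic equals the observed one and
the tests reduce to the classical exact sign test and rank-sum test, so
type-I calibration is preserved (measured ≈ 0.03–0.05 at alpha = 0.05);
unequal weights shift the consensus toward the reliable curves. Medians
and 95% CIs come from percentiles of the replicate medians (the point
estimate is the median of replicate medians, so it always lies inside its
own CI). All tests are two-sided except the model-selection signed-rank,
which is left-tailed. B defaults to 1e5 (1e4 in the test suite). Bonferroni
divisors: ordered pairs (m(m−1)) in model selection; the number of
non-control coordinates present for the EA tables.

## Synthetic data

The generator emulates the experiment's structure: three targets on a
15 cm equilateral triangle giving six directed reaches ≥ 60° apart; eight
tasks × 250 learning trials + 30 washout trials per direction; 74
no-vision catch trials per learning phase, never two in succession (masks
drawn exactly uniformly over valid configurations by a stars-and-bars
construction); control subjects at EA{gain 1, offset 0} and the others
drawing per task from the 11 non-control coordinates; cursor augmentation
ĉ = c_d + gain·(c − c_d) + offset·(c_0 − c_d) applied only to what the
learner sees, never to the error metric, which uses the unaugmented
trajectory (maximum perpendicular deviation from the ideal path, signed by
the first-exposure side).

Ground-truth error dynamics default to a second-order process per EA
coordinate with damped-oscillatory character (complex characteristic
roots; b1 = 0.2, b2 = −(0.42 + 0.06·gain), more negative at higher gain),
negative constant drift a = −0.08 at the coordinates where training drives
overcompensation, larger b1 at gain 0/offset 1, and Wiener scale
sigma = 0.2 cm at gain 0 (feedback carries no knowledge of results) and
0.12 cm elsewhere. The 0.12 cm default was calibrated so that single-curve
second-order fits show the fit quality reported for this paradigm (R²
median ≈ 0.62, IQR ≈ 0.38–0.77). First-trial errors e0 are drawn uniformly
from 2–6 cm with a random sign per curve, since only their definition (the
first-exposure error) is known. Recovery and selection experiments use the
per-curve noise condition sigma = 0.02·|e0|
(`DesignConfig.sigma_e0_fraction`). Washout magnitudes decay as
A·exp(−n/tau) from the final learning-phase magnitude plus half-normal
noise (scale 0.2 cm), with per-coordinate time constants (control 4.34,
gain 2 2.90, gain 3 21.1, otherwise 5 trials).

What the generator does **not** emulate: the eight specific nonlinear
visuomotor transformations (task identity is an opaque label), movement
kinematics beyond a smooth lateral-bump trajectory, speed feedback,
learning during post-launch corrections, and generalization between
movement directions. Passing tests therefore demonstrate that the
estimation and selection machinery recovers known dynamics of this form at
the study's design and noise scale — not that real behaviour follows these
exact dynamics.

## Problem sizes and determinism

The test suite and the acceptance script use reduced optimizer effort
(n_starts 4–50 instead of the 1000-fold default), 20 seeded replicates of
the 10-subject × 2-task × 6-direction selection experiment, 100-curve
recovery runs, 500-replicate calibration runs at B = 1e4, and a small
pipeline profile (4 subjects, 2 tasks, 3 directions, 60-trial curves) —
sizes chosen so the whole validation completes in minutes on one CPU while
leaving every statistical conclusion intact. One global seed derives all
stage seeds through `numpy.random.SeedSequence.spawn`; with a fixed seed
every output file is bit-reproducible.

## Known limitations

* Single-curve coefficient estimates are heavy-tailed by nature of the
  free-simulation objective; only group-level statistics (medians, the
  median average model) are stable.
* The rank-sum null uses the normal approximation with continuity
  correction; for very small groups (n < 8 per side) exact-level accuracy
  is approximate.
* With all-zero or constant observations several parameters are
  unidentifiable; fits return the no-drift/no-learning baseline and are
  flagged rather than rejected.
* The washout tau upper bound (300 trials) flags rather than fits
  non-decaying series.
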