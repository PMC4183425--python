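# Methods

## The model

Synaptic sizes — operationally, background-corrected fluorescence of a
tagged postsynaptic scaffold protein, tracked per synapse at fixed imaging
intervals — are modelled by the discrete-time stochastic recursion

    x_{t+1} = eps_t * x_t + eta_t

with `eps_t` (dimensionless) and `eta_t` (size units per step) drawn
i.i.d. at each step, independently of one another, from fixed parametric
distributions (a Kesten process). The multiplicative factor lumps all
turnover proportional to current size; the additive factor is the
size-independent injection that keeps trajectories away from zero. No
spatial structure, synapse coupling or explicit activity model is included:
the factors are effective variables summarizing many microscopic processes.

Behaviour is controlled by `E[ln eps]` (the *stability index*): negative
means trajectories fluctuate around a finite stationary state and the
population approaches a limiting distribution `f(x)`; positive means
log-sizes drift to infinity. In the stable regime the limiting law is
skewed and heavy-tailed, with `P(X > x) ~ x^(-mu)` where `mu > 0` solves
`E[eps^mu] = 1`. All `eps`-distributions sharing `mu` (a *mu-class*)
produce limiting distributions of (empirically) identical shape up to
scale; the `eta`-distribution sets only the scale, through the stationary
mean `E[eta] / (1 - E[eps])`.

### Default parameters

All defaults refer to 30-minute steps and sizes normalized to unit
population mean, the conditions of the time-lapse experiments the package
emulates:

| quantity | default | why |
| --- | --- | --- |
| `<eps>` (baseline) | 0.9923, Gaussian sd 0.05 | the iterated-mapping estimate for established synapses |
| `<eta>` (baseline) | 0.0077, Gaussian sd 0.03 | pinned by unit-mean stationarity, `<eta> = 1 - <eps>`; sd set so the R²-vs-k decay matches data |
| `<eps>` (new synapses) | 0.962 ± 0.06 | best fit of the formation curve; implies a ~13 h growth e-folding time |
| formation seed `x0` | 0.05 | just-detectable size of a nascent synapse |
| measurement noise CV | 0.1 | order of magnitude of fixed-specimen variability; a free, documented choice — no canonical number exists |
| low-pass window | 5 points | the standard smoothing applied before any estimation |

Note that the Gaussian `eta` is negative roughly 40% of the time; draws are
used as-is and only the resulting size is thresholded (below).

### Elimination

A trajectory whose next value `eps*x + eta` falls to or below zero is
eliminated: the step index is recorded, the trajectory is missing from that
step on, and it is excluded pairwise (not globally) from regressions. We
chose termination over clamping at zero because lost synapses are excluded
from subsequent analysis in the experiments this mirrors; under baseline
parameters the loss rate is of order 10 per 1000 synapses per 160 h, so the
choice is immaterial for population statistics. Under the baseline
parameters with a stationary 1087-synapse start, simulated loss counts over
320 steps straddle the reported 12/1087.

## Estimation

Iterating the recursion k times and averaging over the factor
distributions gives

    E[x_{t+k} | x_t] = <eps>^k x_t + <eta> (1 - <eps>^k) / (1 - <eps>)

so the population regression of `x_{t+k}` on `x_t` has slope `<eps>^k` and
intercept `(1 - <eps>^k) <x>` at stationarity. The estimator fits
`ln(slope_k) = k ln<eps>` by zero-intercept least squares over
`k = 1..k_max` (the theory forces the line through `(0, 0)`), exponentiates,
and derives `<eta> = (1 - <eps>) <x>`. Non-positive slopes, which can occur
at large lags in noisy data, are dropped with a warning.

Two pairing conventions exist because the experimental analyses use both:
`anchor="t0"` (default) regresses each later time point against the first;
`anchor="pooled"` uses all valid `(t, t+k)` pairs. Pooled pairing is the
basis of the per-lag diagnostic: additive measurement noise inflates
`Var(x_t)` without adding covariance, attenuating short-lag slopes, so
per-step estimates `slope_lag^(1/lag)` increase toward the truth with the
lag — the signature used to argue that single-step regressions are
noise-dominated. Second moments are *not* identifiable this way; the
residual-variance profile (squared one-step residuals binned by `x_t`,
quadratic fit; `c2 ~ Var(eps)`, `c0 ~ Var(eta)`, `c1 ~ 0` under
independence) is provided as a diagnostic, with 10 equal-count bins by
default, but no automatic variance matcher is implemented.

## Population statistics

* **Limiting samples** are always simulated (no closed form exists): one
  value per independent trajectory after a burn-in, started at the
  stationary mean. Eliminated trajectories are re-seeded and must complete
  a fresh burn-in; the re-seed count is reported so heavy-loss regimes are
  visible. A drift check compares the ensemble mean over the last two
  burn-in windows and errors if it moves by more than 1% beyond its
  Monte-Carlo wobble (the mean relaxes as an AR(1) with time constant
  `~1/(1 - <eps>)` steps, so the wobble allowance is
  autocorrelation-aware).
* **The mu solver** finds the root of `E[eps^mu] = 1` by bracketing plus
  Brent's method, with moments by adaptive quadrature over the positive
  support (closed forms for gamma and point masses). Distributions with
  more than 1e-6 mass at or below zero are rejected rather than silently
  truncated. The default bracket `(0, 50]` expands once automatically.
* **Tail exponents** use the CCDF convention `P(X > x) ~ x^(-mu)`: the
  negated slope of log-CCDF vs log-x over the upper tail fraction. On exact
  Pareto data the generator truth is recovered; on Kesten samples the
  estimate at accessible depths (tail fractions of 1-10% of samples up to
  ~1e5) sits noticeably *below* the asymptotic `mu` — for a mu-class-6
  process we observe ~4.5-4.8 — because the power law carries slowly
  decaying corrections. The fit's r² flags non-power-law tails; the
  pre-asymptotic bias is inherent, not a solver artefact, and is why shape
  claims rest on the KS collapse rather than on tail fits. (When quoting a
  pdf exponent instead of the CCDF convention, add 1.)
* **Collapse tests** z-score each sample with the population-sd
  (n-denominator) convention — fixed, documented, and immaterial to the
  conclusions — and compare two-sample KS statistics against the standard
  asymptotic 5% critical value. No p-values are claimed beyond the
  threshold comparison.
* **Perturbation protocols** switch the factor distributions mid-run with a
  continuous RNG stream, then compare switch-time vs final sizes of
  surviving synapses: mean ratio, raw and z-scored KS, Spearman rank
  correlation, and the binned change-vs-size line. The mean ratio has a
  closed-form oracle (iterate `m <- <eps>' m + <eta>'`), which the
  simulations match within sampling error; e.g. 0.992 -> 0.995 over 48
  half-hour steps gives ~1.128.
* **Log-normal comparison** fits by maximum likelihood (location fixed at
  zero) and reports sup-norm CDF discrepancies overall and below a low
  quantile (default 0.25), where a matched Kesten reference typically beats
  the log-normal fit.

## Formation kinetics

The expected size of a synapse growing from `x0` is the geometric series
`x0 <eps>^k + <eta>(1 - <eps>^k)/(1 - <eps>)`; normalized to a unit
asymptote this is `1 - <eps>^k`, an exponential approach with e-folding
time `tau = -dt/ln<eps>` (12.9 h for `<eps>` = 0.962 at 30-min steps).
Measured traces are baseline-subtracted, divided by the reference mean of
pre-existing synapses, aligned at detection and pooled with no
minimum-length filter, so per-point counts shrink with time since
detection. Fits weight points by `1/SEM²` where defined and, by default,
constrain `<eta> = (1 - <eps>) * asymptote`. Per-step values convert
between imaging intervals as `<eps>^(step ratio)` (0.74 per 10 min ↔ 0.405
per 30 min).

For synthetic formation data the detection rule (truncate each trace to
start at the first value exceeding a configurable threshold, e.g. 0.1 in
normalized units) is invented plumbing — real detection is a manual
judgement on images — and is not claimed to match any experimental
criterion; by default no threshold is applied and traces start at the seed.

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical structure the analysis relies on:
Kesten truth dynamics from a stationary initial sample, constant-CV
additive Gaussian measurement noise (truncated at zero; an absolute-sd mode
exists), centered moving-average filtering with truncated edge windows,
unit-mean normalization, parameter switches, seeded births and recorded
eliminations, with a ground-truth event log. It does **not** emulate
optics (bleaching, focal drift, PSF overlap between neighbouring puncta),
tracking errors, heterogeneity of parameters across synapses or neurons, or
any temporal correlation of the factors. Passing the closure tests
therefore shows the estimators are correct *under the model's assumptions*
(i.i.d. factors, stationarity, multiplicative-plus-additive noise
structure), not that real data satisfies them.

## Numerical choices and problem sizes

Simulations in the test suite use the study-scale configurations (1087 or
1000 synapses, 48 half-hour steps; 200 formation trajectories of 60 steps;
limiting samples of 1e4 after 1500-step burn-ins) with small numbers of
replicate seeds, chosen as the sizes at which the reported quantities are
resolvable against their own Monte-Carlo error. Stochastic assertions use
3-standard-error bands or seed-majority votes; coverage-style criteria
(e.g. the formation curve lying within 2 SEM of the analytic mean at >=95%
of time points) are evaluated as a median over a fixed block of seeds,
since the per-seed fraction is itself a noisy statistic whose expectation
sits near the threshold. Quadrature targets 1e-10 relative accuracy;
root-finding tolerances are 1e-10 on `mu` and 1e-12 on mu-class
construction. All randomness flows through explicitly seeded
`numpy.random.default_rng` generators; identical seeds give bitwise
identical ensembles.

## Known limitations

* Factor variances are not estimated, only diagnosed; the defaults follow
  the R²-decay matching described above.
* The tail-exponent estimator is honest about, but cannot remove, the
  pre-asymptotic bias of Kesten tails at desk-scale sample sizes.
* Elimination-and-reseed in limiting samples slightly censors the low end
  of the distribution in heavy-loss regimes; the reported re-seed count is
  the guard.
* Gaussian `eps` families with sd much above ~0.15 at means below 1 acquire
  non-negligible mass at `eps <= 0` and are rejected by the log/power
  moment machinery; use gamma families to model broader multiplicative
  factors.
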