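# synkesten

Kesten-process modelling and estimation of synaptic size dynamics.

Long-term time-lapse imaging of fluorescently tagged postsynaptic scaffold
proteins (e.g. PSD-95:EGFP) shows that individual synapses fluctuate
strongly for days while the population's skewed, heavy-tailed size
distribution stays put — and that perturbations such as activity blockade
rescale that distribution without preserving the size ranking of
individual synapses. `synkesten` implements the minimal stochastic model
that reconciles these observations, for computational neuroscientists and
quantitative biologists analysing per-synapse trajectory data:

    x_{t+1} = ε_t · x_t + η_t

a random multiplicative factor ε (size-proportional turnover) plus a
random additive factor η (size-independent injection), drawn i.i.d. each
imaging step — the **Kesten process**. For ⟨ln ε⟩ < 0 the process is
statistically stable with a limiting distribution whose tail falls as
P(X > x) ~ x^(−μ), μ the positive root of ⟨ε^μ⟩ = 1.

The package provides:

* **model** — factor distributions (degenerate / Gaussian / uniform /
  gamma), ensemble simulation with elimination bookkeeping, stability
  index ⟨ln ε⟩, stationary mean ⟨η⟩/(1 − ⟨ε⟩);
* **estimation** — the k-iterated-mapping estimator: population
  regressions of x_{t+k} on x_t have slope ⟨ε⟩^k, so a zero-intercept fit
  of ln(slope) vs k recovers ⟨ε⟩, with split-half validation,
  residual-variance and per-lag noise diagnostics;
* **population** — limiting samples, μ-class solver, tail exponents,
  z-scored Kolmogorov–Smirnov collapse tests, Δsize-vs-size structure,
  rank-order analysis, parameter-switch perturbation protocols, and a
  log-normal comparison fit;
* **formation** — growth of new synapses: the geometric-series mean curve
  x₀⟨ε⟩^k + ⟨η⟩(1 − ⟨ε⟩^k)/(1 − ⟨ε⟩), its e-folding time τ = −Δt/ln⟨ε⟩,
  pooling of detection-aligned variable-length traces, curve fitting, and
  per-step parameter conversion between imaging intervals;
* **synthetic** — seed-reproducible mock experiments (truth + measurement
  noise + low-pass filter + normalization + perturbations + births) with a
  ground-truth event log;
* **io / cli** — a plain CSV/TSV trajectory-table format, a
  spreadsheet-grid converter, and a `synkesten` command with `simulate`,
  `estimate`, `scaling`, `formation`, `generate` and `mu` subcommands.

## Worked example

Simulate an ensemble at the baseline parameters for established synapses
(⟨ε⟩ = 0.9923 ± 0.05, ⟨η⟩ = 0.0077 ± 0.03 per 30-minute step, unit-mean
stationary start) and recover the parameters from the trajectories alone:

```python
import numpy as np
from synkesten import DistributionSpec, KestenParams, simulate_ensemble, mu_exponent
from synkesten.estimation import estimate_eps_mean
from synkesten.population import limiting_sample
from synkesten.formation import growth_timescale

params = KestenParams(
    eps=DistributionSpec.gaussian(0.9923, 0.05),
    eta=DistributionSpec.gaussian(0.0077, 0.03),
    dt_minutes=30.0,
)
init = limiting_sample(params, 1087, 2000, seed=1).values   # stationary sample
ens = simulate_ensemble(params, init, 48, seed=2)           # 24 hours
est = estimate_eps_mean(ens, k_max=48)
print(f"eps_mean       = {est.eps_mean:.4f}")
print(f"eta_mean       = {est.eta_mean_implied:.4f}")
print(f"lost synapses  = {(ens.elimination_step >= 0).sum()} / {ens.n_synapses}")
print(f"slope(k=48)    = {est.per_k[-1].slope:.3f}  (predicted {est.eps_mean**48:.3f})")
print(f"tau            = {growth_timescale(0.962, 30.0):.1f} h")
print(f"mu             = {mu_exponent(params.eps):.2f}")
```

```
eps_mean       = 0.9941
eta_mean       = 0.0059
lost synapses  = 0 / 1087
slope(k=48)    = 0.750  (predicted 0.754)
tau            = 12.9 h
mu             = 7.18
```

Reading the output: the estimator lands within ~0.002 of the generating
⟨ε⟩ = 0.9923 from a single 24-hour window (averaging over replicate
simulations tightens this to the third decimal); the implied additive mean
follows from the unit-mean constraint ⟨η⟩ = 1 − ⟨ε⟩; the 48-step
regression slope matches its predicted ⟨ε⟩^48; a newly forming synapse
with the faster ⟨ε⟩ = 0.962 approaches the population mean with a ~13 h
e-folding time; and the baseline ε-distribution belongs to μ-class ≈ 7,
i.e. a limiting distribution with a power-law tail exponent near 7.

The same pipeline runs from the shell:

```sh
synkesten generate --config experiment.yaml --out-dir out/
synkesten estimate out/observed.csv --kmax 48
synkesten mu --family gaussian --mean 0.9923 --sd 0.05
```

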