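"""Population-level statistics of Kesten size distributions.

Covers the limiting distribution (simulation, tail exponent, mu-class),
the distribution-collapse analyses used to characterize synaptic scaling
(z-scored KS comparison, size-change-vs-size structure, rank order), the
parameter-switch perturbation protocol, and a log-normal comparison fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .distributions import DistributionSpec, mu_exponent  # noqa: F401  (re-export)
from .model import Ensemble, KestenParams, simulate_ensemble, stationary_mean

__all__ = [
    "SizeSample",
    "ScalingReport",
    "limiting_sample",
    "mu_exponent",
    "tail_exponent",
    "zscore",
    "collapse_test",
    "ks_critical_value",
    "delta_vs_initial",
    "rank_order_analysis",
    "perturbation_experiment",
    "lognormal_comparison",
]


@dataclass
class SizeSample:
    """A sample of positive sizes in normalized fluorescence units."""

    values: np.ndarray
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValueError("a size sample needs at least 2 values")
        if np.any(self.values <= 0) or np.any(~np.isfinite(self.values)):
            raise ValueError("size samples must be positive and finite")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class ScalingReport:
    """Before/after comparison of a perturbed population."""

    mean_ratio: float
    ks_raw: float
    ks_z: float
    ks_critical: float
    rank_rho: float
    binned_delta: "object"  # pandas.DataFrame (bin center, mean dx, sd dx, n)
    delta_fit: dict  # slope, intercept, zero_crossing


def limiting_sample(
    params: KestenParams, n: int, burn_in: int, seed: int, label: str = ""
) -> SizeSample:
    """One draw per independent trajectory after a burn-in.

    Trajectories start at the stationary mean; eliminated ones are re-seeded
    there and must complete a fresh burn-in before contributing (the re-seed
    count is reported in ``meta``).  A drift check on the ensemble mean over
    the last stretch of the burn-in guards against an insufficient
    ``burn_in``.
    """
    params.require_stable()
    m0 = stationary_mean(params)
    rng = np.random.default_rng(seed)
    x = np.full(n, m0)
    age = np.zeros(n, dtype=int)
    out = np.full(n, np.nan)
    n_reseeded = 0
    mean_trace = []
    max_steps = 20 * burn_in
    for step in range(max_steps):
        eps = params.eps.sample(n, rng)
        eta = params.eta.sample(n, rng)
        x_new = eps * x + eta
        died = (x_new <= 0) & np.isnan(out)
        n_reseeded += int(died.sum())
        x = np.where(died, m0, x_new)
        age = np.where(died, 0, age + 1)
        # freeze a trajectory's value once it has burned in; later deaths of
        # other trajectories must not restart it
        mature = (age >= burn_in) & np.isnan(out)
        out[mature] = x[mature]
        if step < burn_in:
            mean_trace.append(x.mean())
        if not np.isnan(out).any():
            break
    else:
        raise RuntimeError(
            "could not complete burn-in: trajectories keep being eliminated"
        )
    x = out
    trace = np.asarray(mean_trace)
    tail = max(1, burn_in // 10)
    last, prev = trace[-tail:].mean(), trace[-2 * tail : -tail].mean()
    # systematic drift beyond 1%, over and above the Monte-Carlo wobble of
    # the windowed ensemble mean; the mean relaxes as an AR(1) with time
    # constant ~1/(1 - <eps>) steps, so windows hold few independent values
    tau = min(float(burn_in), 1.0 / max(1.0 - params.eps.mean(), 1e-12))
    n_eff = max(1.0, tail / tau)
    wobble = 3.0 * trace[-2 * tail :].std() * math.sqrt(2.0 / n_eff)
    if abs(last - prev) > 0.01 * abs(prev) + wobble:
        raise RuntimeError(
            "burn-in too short: ensemble mean still drifting by > 1% "
            f"({prev:.4g} -> {last:.4g})"
        )
    return SizeSample(x, label=label, meta={"n_reseeded": n_reseeded})


@dataclass(frozen=True)
class TailFit:
    exponent: float
    r_squared: float
    n_tail: int


def tail_exponent(sample: SizeSample, tail_fraction: float = 0.1) -> TailFit:
    """Power-law exponent of the upper tail from the log-log CCDF slope.

    Convention: P(X > x) ~ x**(-mu), so the returned exponent is the negated
    OLS slope of log CCDF against log x over the top ``tail_fraction`` of the
    sample.  A low r-squared flags the absence of a power-law tail.
    """
    if not 0 < tail_fraction <= 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5]")
    vals = np.sort(sample.values)
    n = vals.size
    m = int(math.floor(n * tail_fraction))
    if m < 100:
        raise ValueError(f"need >= 100 tail points, got {m}")
    # empirical CCDF at the i-th largest value is i/n (exclude the last point
    # where the CCDF is 0)
    x = vals[-m:-1]
    ccdf = (n - np.arange(n - m, n - 1)) / n
    res = stats.linregress(np.log(x), np.log(ccdf))
    return TailFit(
        exponent=float(-res.slope),
        r_squared=float(res.rvalue**2),
        n_tail=m,
    )


def zscore(values: np.ndarray) -> np.ndarray:
    """Center and scale to unit population sd (divide by the n-denominator sd)."""
    v = np.asarray(values, dtype=float)
    sd = v.std()  # ddof=0 convention, fixed
    if sd == 0:
        raise ValueError("zero variance: z-score undefined")
    return (v - v.mean()) / sd


def collapse_test(a: SizeSample, b: SizeSample) -> dict:
    """Two-sample KS statistics on raw and on z-scored values.

    A small ``ks_z`` with a large ``ks_raw`` is the signature of scaling:
    the distributions differ in scale but collapse onto a common shape.
    """
    ks_raw = stats.ks_2samp(a.values, b.values).statistic
    ks_z = stats.ks_2samp(zscore(a.values), zscore(b.values)).statistic
    return {"ks_raw": float(ks_raw), "ks_z": float(ks_z)}


def ks_critical_value(n1: int, n2: int, alpha: float = 0.05) -> float:
    """Asymptotic two-sample KS critical value c(alpha)*sqrt((n1+n2)/(n1*n2))."""
    c = math.sqrt(-0.5 * math.log(alpha / 2.0))
    return c * math.sqrt((n1 + n2) / (n1 * n2))


def delta_vs_initial(
    ens: Ensemble, interval_hours: float, n_bins: int = 10
) -> tuple["object", dict]:
    """Size change over an interval against initial size.

    Returns an equal-count binned table (pandas DataFrame with bin-mean x,
    mean and sd of dx, n) and the OLS fit of dx on x with its zero crossing.
    On stationary Kesten data the fitted line has slope <eps>**k - 1 < 0 and
    crosses zero at the population mean.
    """
    import pandas as pd

    dt = ens.dt_hours
    k_real = interval_hours / dt
    k = int(round(k_real))
    if abs(k_real - k) > 1e-9 or k < 1 or k >= ens.n_times:
        raise ValueError(
            f"interval {interval_hours} h is not a multiple of dt on the grid"
        )
    x0, xk = ens.sizes[:, 0], ens.sizes[:, k]
    ok = np.isfinite(x0) & np.isfinite(xk)
    x, dx = x0[ok], xk[ok] - x0[ok]
    if x.size < max(3, n_bins):
        raise ValueError("too few synapses alive at both endpoints")

    order = np.argsort(x, kind="stable")
    xs, ds = x[order], dx[order]
    edges = np.linspace(0, xs.size, n_bins + 1).astype(int)
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b > a:
            rows.append(
                (xs[a:b].mean(), ds[a:b].mean(), ds[a:b].std(ddof=1) if b - a > 1 else 0.0, b - a)
            )
    table = pd.DataFrame(rows, columns=["x", "mean_dx", "sd_dx", "n"])

    res = stats.linregress(x, dx)
    slope, intercept = float(res.slope), float(res.intercept)
    fit = {
        "slope": slope,
        "intercept": intercept,
        "zero_crossing": -intercept / slope if slope != 0 else float("nan"),
        "n_points": int(x.size),
    }
    return table, fit


def rank_order_analysis(before: SizeSample, after: SizeSample) -> dict:
    """Spearman correlation of matched synapses plus the rank-curve data.

    ``rank_curves`` pairs each synapse's rank in the *before* sample with its
    before and after values, for plots of rank-order preservation.  A
    deterministic monotone transform gives rho = 1; stochastic Kesten
    evolution shuffles ranks and gives 0 < rho < 1.
    """
    import pandas as pd

    if before.n != after.n:
        raise ValueError("before/after samples must be matched and equal length")
    rho = stats.spearmanr(before.values, after.values).statistic
    order = np.argsort(before.values, kind="stable")
    curves = pd.DataFrame(
        {
            "rank": np.arange(1, before.n + 1),
            "before": before.values[order],
            "after": after.values[order],
        }
    )
    return {"rank_rho": float(rho), "rank_curves": curves}


def perturbation_experiment(
    init: np.ndarray,
    params_before: KestenParams,
    params_after: KestenParams,
    steps_before: int,
    steps_after: int,
    seed: int,
) -> tuple[Ensemble, ScalingReport]:
    """Simulate a mid-experiment parameter switch and report the rescaling.

    The population evolves ``steps_before`` steps under the baseline
    parameters; at the switch (e.g. drug application) the factor
    distributions change and evolution continues for ``steps_after`` steps.
    The report compares switch-time against final sizes of synapses alive at
    both, and the size-change structure over the post-switch interval.
    """
    if params_before.dt_minutes != params_after.dt_minutes:
        raise ValueError("time step must not change at the switch")
    rng = np.random.default_rng(seed)
    ens_a = simulate_ensemble(
        params_before, init, steps_before, seed, rng=rng
    )
    last = ens_a.sizes[:, -1]
    start_b = np.where(np.isfinite(last), last, 0.0)
    ens_b = simulate_ensemble(
        params_after,
        start_b,
        steps_after,
        seed,
        rng=rng,
        t0_hours=float(ens_a.times_hours[-1]),
    )
    # stitch: a synapse dead before the switch stays dead afterwards
    dead = ~ens_a.alive[:, -1]
    ens_b.sizes[dead] = np.nan
    ens_b.alive[dead] = False
    sizes = np.hstack([ens_a.sizes, ens_b.sizes[:, 1:]])
    alive = np.hstack([ens_a.alive, ens_b.alive[:, 1:]])
    elim = ens_a.elimination_step.copy()
    relim = ens_b.elimination_step
    new_death = (elim < 0) & (relim >= 0) & ~dead
    elim[new_death] = steps_before + relim[new_death]
    times = np.concatenate([ens_a.times_hours, ens_b.times_hours[1:]])
    full = Ensemble(times, sizes, alive, elim, tags=dict(ens_a.tags))
    full.validate()

    ok = np.isfinite(sizes[:, steps_before]) & np.isfinite(sizes[:, -1])
    if ok.sum() < 3:
        raise ValueError("too few synapses survive the protocol")
    at_switch = SizeSample(sizes[ok, steps_before], label="switch")
    at_end = SizeSample(sizes[ok, -1], label="end")
    ks = collapse_test(at_switch, at_end)

    post = Ensemble(
        ens_b.times_hours,
        ens_b.sizes,
        ens_b.alive,
        ens_b.elimination_step,
        tags=dict(ens_b.tags),
    )
    table, fit = delta_vs_initial(
        post, steps_after * params_after.dt_hours
    )
    report = ScalingReport(
        mean_ratio=float(at_end.values.mean() / at_switch.values.mean()),
        ks_raw=ks["ks_raw"],
        ks_z=ks["ks_z"],
        ks_critical=ks_critical_value(at_switch.n, at_end.n),
        rank_rho=rank_order_analysis(at_switch, at_end)["rank_rho"],
        binned_delta=table,
        delta_fit=fit,
    )
    return full, report


def _ecdf(sample: np.ndarray):
    xs = np.sort(sample)

    def cdf(x):
        return np.searchsorted(xs, x, side="right") / xs.size

    return cdf


def lognormal_comparison(
    sample: SizeSample, kesten_reference: SizeSample, low_quantile: float = 0.25
) -> dict:
    """Compare a size sample against a log-normal MLE fit and a Kesten reference.

    Reports the sup-norm CDF discrepancy of the sample against (a) the fitted
    log-normal and (b) the empirical CDF of the Kesten reference, plus the
    same discrepancies restricted to the lower ``low_quantile`` of the
    sample, where the two model families differ most.
    """
    vals = sample.values
    shape, _, scale = stats.lognorm.fit(vals, floc=0)
    ln = stats.lognorm(shape, scale=scale)
    grid = np.sort(np.concatenate([vals, kesten_reference.values]))
    emp = _ecdf(vals)(grid)
    err_ln = np.abs(emp - ln.cdf(grid))
    err_kest = np.abs(emp - _ecdf(kesten_reference.values)(grid))
    cut = np.quantile(vals, low_quantile)
    low = grid <= cut
    return {
        "lognormal_fit_params": {"sigma": float(shape), "scale": float(scale)},
        "cdf_error_lognormal": float(err_ln.max()),
        "cdf_error_kesten": float(err_kest.max()),
        "low_tail_errors": {
            "lognormal": float(err_ln[low].max()) if low.any() else 0.0,
            "kesten": float(err_kest[low].max()) if low.any() else 0.0,
        },
    }
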