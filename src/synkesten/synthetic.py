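"""Synthetic time-lapse experiments with the structure the analysis assumes.

Generates complete mock imaging experiments: Kesten ground-truth dynamics,
additive measurement noise calibrated as a coefficient of variation (the
quantity a fixed-specimen control reports), 5-point low-pass filtering,
unit-mean normalization, mid-experiment parameter switches (drug
application protocols), new-synapse seeding and elimination.  Every stage
is seed-reproducible and logged, so pipeline tests can join observed data
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formation import FormationTrace
from .model import Ensemble, KestenParams, simulate_ensemble

__all__ = [
    "NoiseModel",
    "ExperimentConfig",
    "GeneratedExperiment",
    "add_measurement_noise",
    "lowpass",
    "normalize",
    "generate_experiment",
    "simulate_formation_traces",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive measurement noise.

    By default the noise sd is proportional to the true size
    (``sd = cv_noise * x``), matching how fixed-specimen variability is
    reported as a per-synapse coefficient of variation.  Setting
    ``absolute_sd`` instead applies a size-independent sd.
    """

    cv_noise: float = 0.1
    absolute_sd: float | None = None

    def __post_init__(self) -> None:
        if self.cv_noise < 0:
            raise ValueError("cv_noise must be >= 0")
        if self.absolute_sd is not None and self.absolute_sd < 0:
            raise ValueError("absolute_sd must be >= 0")


@dataclass
class ExperimentConfig:
    """Full protocol for one synthetic experiment."""

    n_synapses: int
    duration_hours: float
    dt_minutes: float
    baseline: KestenParams
    perturbations: list = field(default_factory=list)  # (switch_hours, KestenParams)
    formation_events: list = field(default_factory=list)  # (birth_hours, x0)
    noise: NoiseModel | None = None
    filter_window: int | None = None
    normalization: str | None = None  # t0_mean | experiment_mean
    seed: int = 0
    burn_in: int = 1000  # steps used to draw the stationary initial sample

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_hours * 60.0 / self.dt_minutes))

    def validate(self) -> None:
        problems = []
        if self.n_synapses < 1:
            problems.append("n_synapses must be >= 1")
        if self.duration_hours <= 0:
            problems.append("duration_hours must be positive")
        if self.dt_minutes <= 0:
            problems.append("dt_minutes must be positive")
        for t, _ in self.perturbations:
            if not 0 < t < self.duration_hours:
                problems.append(f"switch time {t} h outside the experiment")
        for t, x0 in self.formation_events:
            if not 0 <= t < self.duration_hours:
                problems.append(f"birth time {t} h outside the experiment")
            if x0 < 0:
                problems.append(f"formation seed x0={x0} must be >= 0")
        if self.filter_window is not None and (
            self.filter_window < 1 or self.filter_window % 2 == 0
        ):
            problems.append("filter_window must be odd and >= 1")
        if self.normalization not in (None, "t0_mean", "experiment_mean"):
            problems.append(f"unknown normalization {self.normalization!r}")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))


@dataclass
class GeneratedExperiment:
    truth: Ensemble
    observed: Ensemble
    log: "object"  # pandas.DataFrame: event, time_hours, synapse, detail


def add_measurement_noise(
    ens: Ensemble, model: NoiseModel, seed: int
) -> Ensemble:
    """Add zero-mean Gaussian observation noise, truncated at zero.

    Aliveness is unchanged: noise degrades the measurement, it does not
    eliminate the synapse.
    """
    out = ens.copy()
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal(out.sizes.shape)
    if model.absolute_sd is not None:
        sd = model.absolute_sd
    else:
        sd = model.cv_noise * np.where(np.isfinite(out.sizes), out.sizes, 0.0)
    noisy = out.sizes + sd * draws
    out.sizes = np.where(out.alive, np.maximum(noisy, 0.0), out.sizes)
    return out


def lowpass(ens: Ensemble, window: int) -> Ensemble:
    """Centered moving average per trajectory with a truncated edge window.

    Missing values are excluded from each window's average, so the series
    length is preserved and aliveness is untouched.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    out = ens.copy()
    if window > 1:
        import pandas as pd

        df = pd.DataFrame(out.sizes.T)  # rows = time
        rolled = df.rolling(window, center=True, min_periods=1).mean()
        out.sizes = np.where(out.alive, rolled.to_numpy().T, np.nan)
    out.tags["filtered"] = window
    return out


def normalize(ens: Ensemble, mode: str) -> Ensemble:
    """Divide all sizes by a reference mean (idempotent per mode).

    ``t0_mean`` uses the mean over synapses alive at the first time point;
    ``experiment_mean`` uses the grand mean over all alive entries.
    """
    out = ens.copy()
    if mode == "t0_mean":
        ref = np.nanmean(out.sizes[out.alive[:, 0], 0])
    elif mode == "experiment_mean":
        ref = np.nanmean(out.sizes[out.alive])
    else:
        raise ValueError("mode must be 't0_mean' or 'experiment_mean'")
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError("normalization reference mean must be positive")
    out.sizes = out.sizes / ref
    out.tags["normalization"] = mode
    return out


def _parameter_schedule(config: ExperimentConfig) -> list:
    """(start_step, params) segments covering 0..n_steps."""
    dt_h = config.dt_minutes / 60.0
    switches = sorted(
        (int(round(t / dt_h)), p) for t, p in config.perturbations
    )
    schedule = [(0, config.baseline)] + switches
    return schedule


def generate_experiment(config: ExperimentConfig) -> GeneratedExperiment:
    """Run the full protocol: truth dynamics, then the observation pipeline.

    The ground-truth ensemble starts from a stationary sample of the
    baseline process, applies parameter switches at the configured times and
    inserts formation events as new rows (missing before birth).  The
    observed ensemble is truth + noise + optional filter + normalization.
    The log records every switch, birth and elimination with its step.
    """
    import pandas as pd

    config.validate()
    from .population import limiting_sample  # deferred: avoids import cycle

    dt_h = config.dt_minutes / 60.0
    n_steps = config.n_steps
    rng = np.random.default_rng(config.seed)
    init = limiting_sample(
        config.baseline,
        config.n_synapses,
        config.burn_in,
        seed=int(rng.integers(2**31)),
    ).values

    births = [
        (int(round(t / dt_h)), float(x0)) for t, x0 in config.formation_events
    ]
    n_total = config.n_synapses + len(births)
    sizes = np.full((n_total, n_steps + 1), np.nan)
    alive = np.zeros((n_total, n_steps + 1), dtype=bool)
    elim = np.full(n_total, -1, dtype=int)
    events = []

    x = np.full(n_total, np.nan)
    live = np.zeros(n_total, dtype=bool)
    x[: config.n_synapses] = init
    live[: config.n_synapses] = True
    for j, (b, x0) in enumerate(births):
        if b == 0:
            x[config.n_synapses + j] = x0
            live[config.n_synapses + j] = True
        events.append(
            {
                "event": "birth",
                "time_hours": b * dt_h,
                "synapse": config.n_synapses + j,
                "detail": f"x0={x0}",
            }
        )
    sizes[live, 0] = x[live]
    alive[:, 0] = live

    schedule = _parameter_schedule(config)
    for t0_step, params in schedule[1:]:
        events.append(
            {
                "event": "switch",
                "time_hours": t0_step * dt_h,
                "synapse": -1,
                "detail": (
                    f"eps={params.eps.family}{params.eps.params}, "
                    f"eta={params.eta.family}{params.eta.params}"
                ),
            }
        )

    seg = 0
    for k in range(1, n_steps + 1):
        while seg + 1 < len(schedule) and k > schedule[seg + 1][0]:
            seg += 1
        params = schedule[seg][1]
        eps = params.eps.sample(n_total, rng)
        eta = params.eta.sample(n_total, rng)
        x_new = eps * x + eta
        died = live & (x_new <= 0)
        for i in np.flatnonzero(died):
            events.append(
                {
                    "event": "elimination",
                    "time_hours": k * dt_h,
                    "synapse": int(i),
                    "detail": f"step={k}",
                }
            )
        elim[died] = k
        live = live & ~died
        x = np.where(live, x_new, np.nan)
        for j, (b, x0) in enumerate(births):
            if b == k:
                idx = config.n_synapses + j
                x[idx] = x0
                live[idx] = True
        sizes[live, k] = x[live]
        alive[:, k] = live

    times = np.arange(n_steps + 1) * dt_h
    truth = Ensemble(
        times,
        sizes,
        alive,
        elim,
        tags={
            "dt_minutes": config.dt_minutes,
            "seed": config.seed,
            "normalization": "none",
            "filtered": "none",
        },
    )
    truth.validate()

    observed = truth
    if config.noise is not None:
        observed = add_measurement_noise(
            observed, config.noise, seed=int(rng.integers(2**31))
        )
    if config.filter_window is not None:
        observed = lowpass(observed, config.filter_window)
    if config.normalization is not None:
        observed = normalize(observed, config.normalization)
    observed.validate()

    log = pd.DataFrame(
        events, columns=["event", "time_hours", "synapse", "detail"]
    ).sort_values(["time_hours", "synapse"], kind="stable").reset_index(drop=True)
    return GeneratedExperiment(truth=truth, observed=observed, log=log)


def simulate_formation_traces(
    params: KestenParams,
    n: int,
    n_steps: int,
    x0: float,
    seed: int,
    detection_threshold: float | None = None,
) -> list:
    """Simulate tracked new-synapse trajectories seeded at x0.

    Returns :class:`FormationTrace` objects in normalized units (baseline 0,
    reference mean 1), each truncated at elimination if it occurs.  With a
    ``detection_threshold``, each trace instead starts at the first step its
    size exceeds the threshold — invented plumbing standing in for the
    manual identification of new puncta in images; traces never reaching
    the threshold are dropped.
    """
    ens = simulate_ensemble(params, np.full(n, x0), n_steps, seed)
    traces = []
    for i in range(n):
        row = ens.sizes[i]
        vals = row[np.isfinite(row)]
        if detection_threshold is not None:
            above = np.flatnonzero(vals > detection_threshold)
            if above.size == 0:
                continue
            vals = vals[above[0]:]
        if vals.size:
            traces.append(FormationTrace(values=vals))
    return traces
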