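"""The Kesten process for synaptic sizes: definition, simulation, stability.

A synapse's size (fluorescence of a tagged scaffold protein, in normalized
units) evolves in discrete time as

    x_{t+1} = eps_t * x_t + eta_t

with eps_t, eta_t drawn i.i.d. at each step from fixed distributions.
The multiplicative factor lumps all size-proportional turnover; the additive
factor is the size-independent "injection" that keeps trajectories away from
zero.  For E[ln eps] < 0 the process is statistically stable and approaches
a skewed, heavy-tailed limiting distribution; for E[ln eps] > 0 it diverges.

A trajectory whose next value eps*x + eta falls to or below zero is
*eliminated*: the step is recorded and the trajectory is missing from then
on, mirroring synapse loss in the experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .distributions import DistributionSpec, stability_index

__all__ = [
    "KestenParams",
    "Ensemble",
    "sample_factors",
    "kesten_step",
    "simulate_ensemble",
    "stability_index",
    "stationary_mean",
]


@dataclass(frozen=True)
class KestenParams:
    """Process definition: eps and eta distributions plus the time step."""

    eps: DistributionSpec
    eta: DistributionSpec
    dt_minutes: float = 30.0

    def __post_init__(self) -> None:
        if self.dt_minutes <= 0:
            raise ValueError("dt_minutes must be positive")

    @property
    def dt_hours(self) -> float:
        return self.dt_minutes / 60.0

    def require_stable(self) -> None:
        """Raise unless E[ln eps] < 0 (stationary-regime operations only)."""
        if stability_index(self.eps) >= 0:
            raise ValueError(
                "operation requires the stable regime E[ln eps] < 0"
            )


@dataclass
class Ensemble:
    """A synapse-by-time size matrix with aliveness bookkeeping.

    ``sizes`` is (n_synapses, n_times) with NaN marking missing values
    (before birth or after elimination).  ``alive`` is the congruent boolean
    mask; ``elimination_step`` holds the step index at which a synapse was
    eliminated, or -1.  ``tags`` records provenance (normalization mode,
    filter window, seed, dt).
    """

    times_hours: np.ndarray
    sizes: np.ndarray
    alive: np.ndarray
    elimination_step: np.ndarray
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_hours = np.asarray(self.times_hours, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.alive = np.asarray(self.alive, dtype=bool)
        self.elimination_step = np.asarray(self.elimination_step, dtype=int)

    @property
    def n_synapses(self) -> int:
        return self.sizes.shape[0]

    @property
    def n_times(self) -> int:
        return self.sizes.shape[1]

    @property
    def dt_hours(self) -> float:
        return float(self.times_hours[1] - self.times_hours[0])

    def validate(self) -> None:
        if self.sizes.shape != self.alive.shape:
            raise ValueError("sizes and alive masks differ in shape")
        if self.sizes.shape[1] != self.times_hours.size:
            raise ValueError("time axis length mismatch")
        diffs = np.diff(self.times_hours)
        if self.times_hours.size > 1:
            if np.any(diffs <= 0):
                raise ValueError("times must be strictly increasing")
            if np.any(np.abs(diffs - diffs[0]) > 1e-9):
                raise ValueError("times must be uniformly spaced")
        if np.any(self.sizes[self.alive] < 0):
            raise ValueError("negative size at an alive entry")
        if np.any(np.isnan(self.sizes[self.alive])):
            raise ValueError("NaN size at an alive entry")

    def copy(self) -> "Ensemble":
        return Ensemble(
            self.times_hours.copy(),
            self.sizes.copy(),
            self.alive.copy(),
            self.elimination_step.copy(),
            dict(self.tags),
        )


def sample_factors(spec: DistributionSpec, n: int, seed: int) -> np.ndarray:
    """Reproducible i.i.d. draws of a random factor."""
    rng = np.random.default_rng(seed)
    return spec.sample(n, rng)


def kesten_step(x: float, eps: float, eta: float) -> Optional[float]:
    """One update eps*x + eta; ``None`` signals elimination (result <= 0)."""
    if x < 0:
        raise ValueError("size must be non-negative")
    new = eps * x + eta
    return new if new > 0 else None


def simulate_ensemble(
    params: KestenParams,
    init_sizes: np.ndarray,
    n_steps: int,
    seed: int,
    *,
    rng: np.random.Generator | None = None,
    t0_hours: float = 0.0,
) -> Ensemble:
    """Simulate the ensemble for ``n_steps`` steps from ``init_sizes``.

    Eliminated trajectories (eps*x + eta <= 0) get their elimination step
    recorded and are NaN from that step on.  Passing ``rng`` continues an
    existing generator stream (used by the perturbation protocols); otherwise
    a fresh ``default_rng(seed)`` is created, so identical (params, init,
    seed) give bitwise-identical output.
    """
    init = np.asarray(init_sizes, dtype=float)
    if init.ndim != 1 or init.size == 0:
        raise ValueError("init_sizes must be a non-empty vector")
    if np.any(init < 0):
        raise ValueError("init_sizes must be non-negative")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    n = init.size
    sizes = np.full((n, n_steps + 1), np.nan)
    alive = np.zeros((n, n_steps + 1), dtype=bool)
    elim = np.full(n, -1, dtype=int)

    x = init.copy()
    live = np.ones(n, dtype=bool)
    sizes[:, 0] = x
    alive[:, 0] = True
    for k in range(1, n_steps + 1):
        eps = params.eps.sample(n, rng)
        eta = params.eta.sample(n, rng)
        x_new = eps * x + eta
        died = live & (x_new <= 0)
        elim[died] = k
        live = live & ~died
        x = np.where(live, x_new, np.nan)
        sizes[live, k] = x[live]
        alive[:, k] = live

    times = t0_hours + np.arange(n_steps + 1) * params.dt_hours
    ens = Ensemble(times, sizes, alive, elim, tags={
        "dt_minutes": params.dt_minutes,
        "seed": seed,
        "normalization": "none",
        "filtered": "none",
    })
    ens.validate()
    return ens


def stationary_mean(params: KestenParams) -> float:
    """Mean of the limiting distribution, E[eta] / (1 - E[eps])."""
    m_eps = params.eps.mean()
    if m_eps >= 1:
        raise ValueError("no stationary mean: E[eps] >= 1")
    return params.eta.mean() / (1.0 - m_eps)
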