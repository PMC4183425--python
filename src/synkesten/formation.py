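"""Growth kinetics of newly formed synapses under the Kesten recursion.

A new postsynaptic density starts near zero and, iterating the mean map
x -> <eps>*x + <eta>, its expected size follows a geometric series

    E[x_k] = x0*<eps>**k + <eta>*(1 - <eps>**k)/(1 - <eps>)

i.e. an exponential approach to the stationary mean with e-folding time
tau = -dt/ln<eps>.  Under the experimental normalization (sizes divided by
the mean of the neuron's pre-existing synapses, so the asymptote is 1 and
<eta> = 1 - <eps>) the curve is simply 1 - <eps>**k for x0 = 0.

Measured formation trajectories start at detection and have varying
lengths; they are baseline-subtracted, normalized, aligned at detection and
pooled into a mean +/- SEM growth curve that the analytic form is fit to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "FormationTrace",
    "GrowthCurve",
    "mean_growth",
    "growth_timescale",
    "convert_timestep",
    "align_and_pool",
    "fit_formation",
]


@dataclass(frozen=True)
class FormationTrace:
    """One tracked new synapse.

    ``values`` runs from the detection point onward (raw fluorescence);
    ``baseline`` is the fluorescence measured at the site before a PSD was
    detectable and ``reference_mean`` the mean fluorescence of the neuron's
    pre-existing synapses, used for normalization.
    """

    values: np.ndarray
    baseline: float = 0.0
    reference_mean: float = 1.0

    def normalized(self) -> np.ndarray:
        if self.reference_mean <= 0:
            raise ValueError("reference mean must be positive")
        return (np.asarray(self.values, dtype=float) - self.baseline) / self.reference_mean


@dataclass
class GrowthCurve:
    """Pooled mean +/- SEM trajectory aligned at detection."""

    t_since_detection: np.ndarray  # hours
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray  # contributing trajectories per time point

    def __post_init__(self) -> None:
        self.t_since_detection = np.asarray(self.t_since_detection, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        self.n = np.asarray(self.n, dtype=int)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_hours": self.t_since_detection,
                "mean": self.mean,
                "sem": self.sem,
                "n": self.n,
            }
        )


def mean_growth(eps_mean: float, eta_mean: float, x0: float, k) -> np.ndarray:
    """Expected size after k steps of the mean map from x0."""
    if not 0 < eps_mean < 1:
        raise ValueError("eps_mean must be in (0, 1)")
    if x0 < 0:
        raise ValueError("x0 must be non-negative")
    kk = np.asarray(k, dtype=float)
    ek = np.power(eps_mean, kk)
    return x0 * ek + eta_mean * (1.0 - ek) / (1.0 - eps_mean)


def growth_timescale(eps_mean: float, dt_minutes: float) -> float:
    """e-folding time tau = -dt/ln<eps> of the mean growth curve, in hours."""
    if not 0 < eps_mean < 1:
        raise ValueError("eps_mean must be in (0, 1)")
    if dt_minutes <= 0:
        raise ValueError("dt_minutes must be positive")
    return -(dt_minutes / 60.0) / math.log(eps_mean)


def convert_timestep(eps_mean: float, step_ratio: float) -> float:
    """Re-express <eps> at a coarser/finer step: <eps>**step_ratio.

    ``step_ratio`` is new step / old step, e.g. 3 converts a per-10-min value
    to its per-30-min equivalent.
    """
    if eps_mean <= 0:
        raise ValueError("eps_mean must be positive")
    if step_ratio <= 0:
        raise ValueError("step_ratio must be positive")
    return float(eps_mean**step_ratio)


def align_and_pool(traces: list, dt_minutes: float) -> GrowthCurve:
    """Normalize, align at detection and pool variable-length trajectories.

    All trajectories are kept regardless of length; the per-time-point count
    ``n`` therefore decreases with time since detection.  SEM is the
    sample-sd / sqrt(n) where n >= 2 and 0 where a single trajectory remains.
    """
    if not traces:
        raise ValueError("need at least one trajectory")
    series = [t.normalized() for t in traces]
    length = max(s.size for s in series)
    mat = np.full((len(series), length), np.nan)
    for i, s in enumerate(series):
        mat[i, : s.size] = s
    n = np.sum(np.isfinite(mat), axis=0)
    mean = np.nanmean(mat, axis=0)
    sem = np.zeros(length)
    for j in np.flatnonzero(n >= 2):
        sd = np.nanstd(mat[:, j], ddof=1)
        # identical values can leave O(1e-18) rounding dust in the sd
        if sd > 1e-12 * max(1.0, abs(mean[j])):
            sem[j] = sd / math.sqrt(n[j])
    t = np.arange(length) * (dt_minutes / 60.0)
    return GrowthCurve(t, mean, sem, n)


def fit_formation(
    curve: GrowthCurve,
    dt_minutes: float,
    constrain_eta: bool = True,
    asymptote: float = 1.0,
    x0: float | None = None,
) -> dict:
    """Least-squares fit of the analytic mean growth curve.

    With ``constrain_eta`` the additive mean is tied to the asymptote,
    <eta> = (1 - <eps>) * asymptote, leaving <eps> (and x0, unless given)
    free; otherwise <eta> is fit as well.  Points are weighted by 1/SEM**2
    where the SEM is positive, and left unweighted otherwise.
    """
    if curve.mean.size < 5:
        raise ValueError("need at least 5 time points to fit")
    k = curve.t_since_detection / (dt_minutes / 60.0)
    y = curve.mean
    sigma = np.where(curve.sem > 0, curve.sem, np.nan)
    use_sigma = np.isfinite(sigma).all()

    fit_x0 = x0 is None
    if constrain_eta:
        if fit_x0:
            f = lambda kk, e, x_0: mean_growth(e, (1 - e) * asymptote, x_0, kk)
            p0, bounds = [0.95, 0.05], ([1e-6, 0.0], [1 - 1e-9, np.inf])
        else:
            f = lambda kk, e: mean_growth(e, (1 - e) * asymptote, x0, kk)
            p0, bounds = [0.95], ([1e-6], [1 - 1e-9])
    else:
        if fit_x0:
            f = lambda kk, e, h, x_0: mean_growth(e, h, x_0, kk)
            p0, bounds = [0.95, 0.05, 0.05], (
                [1e-6, -np.inf, 0.0],
                [1 - 1e-9, np.inf, np.inf],
            )
        else:
            f = lambda kk, e, h: mean_growth(e, h, x0, kk)
            p0, bounds = [0.95, 0.05], ([1e-6, -np.inf], [1 - 1e-9, np.inf])

    try:
        popt, _ = optimize.curve_fit(
            f,
            k,
            y,
            p0=p0,
            sigma=sigma if use_sigma else None,
            absolute_sigma=False,
            bounds=bounds,
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"formation fit did not converge: {exc}") from exc

    eps = float(popt[0])
    if constrain_eta:
        eta = (1.0 - eps) * asymptote
        x0_fit = float(popt[1]) if fit_x0 else float(x0)
    else:
        eta = float(popt[1])
        x0_fit = float(popt[2]) if fit_x0 else float(x0)
    return {
        "eps_mean": eps,
        "eta_mean": eta,
        "x0": x0_fit,
        "tau_hours": growth_timescale(eps, dt_minutes),
    }
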