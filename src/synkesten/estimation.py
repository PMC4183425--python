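"""Estimating Kesten parameters from trajectory ensembles.

Averaging the k-fold iterated recursion over the factor distributions gives

    E[x_{t+k} | x_t] = <eps>**k * x_t + <eta> * (1 - <eps>**k) / (1 - <eps>)

so a linear regression of x_{t+k} on x_t across the synapse population has
slope <eps>**k.  Fitting ln(slope_k) against k through the origin and
exponentiating recovers <eps> per step; the unit-mean normalization then
pins the additive mean to <eta> = (1 - <eps>) * <x>.

Two pairing conventions are supported: ``anchor="t0"`` regresses every later
time point against the first one (one fit per lag k, the default), and
``anchor="pooled"`` uses all valid (t, t+k) pairs, which is the natural
choice when quantifying how measurement noise attenuates short-lag slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import Ensemble

__all__ = [
    "RegressionFit",
    "EpsEstimate",
    "iterated_mapping",
    "estimate_eps_mean",
    "predict_slopes",
    "implied_eta_mean",
    "residual_variance_profile",
    "pairwise_lag_estimate",
    "split_half_validation",
]


class InsufficientDataError(ValueError):
    """Fewer valid pairs than the regression needs."""


@dataclass(frozen=True)
class RegressionFit:
    """One least-squares fit of x_{t+k} on x_t."""

    k: int
    slope: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass
class EpsEstimate:
    """Output of the iterated-mapping procedure."""

    eps_mean: float
    eta_mean_implied: float
    pop_mean: float
    per_k: list = field(default_factory=list)
    logslope_fit: dict = field(default_factory=dict)


def _pairs(ens: Ensemble, k: int, anchor: str) -> tuple[np.ndarray, np.ndarray]:
    if k < 1:
        raise ValueError("lag k must be >= 1")
    if k >= ens.n_times:
        raise InsufficientDataError(f"lag {k} exceeds the series length")
    if anchor == "t0":
        x0, xk = ens.sizes[:, 0], ens.sizes[:, k]
        ok = np.isfinite(x0) & np.isfinite(xk)
        return x0[ok], xk[ok]
    if anchor == "pooled":
        a = ens.sizes[:, : ens.n_times - k].ravel()
        b = ens.sizes[:, k:].ravel()
        ok = np.isfinite(a) & np.isfinite(b)
        return a[ok], b[ok]
    raise ValueError("anchor must be 't0' or 'pooled'")


def _ols(x: np.ndarray, y: np.ndarray, k: int) -> RegressionFit:
    if x.size < 3:
        raise InsufficientDataError(
            f"need >= 3 valid pairs for the lag-{k} regression, got {x.size}"
        )
    res = stats.linregress(x, y)
    return RegressionFit(
        k=k,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(x.size),
    )


def iterated_mapping(ens: Ensemble, k: int, anchor: str = "t0") -> RegressionFit:
    """OLS fit of x_{t+k} on x_t; slope estimates <eps>**k."""
    x, y = _pairs(ens, k, anchor)
    return _ols(x, y, k)


def estimate_eps_mean(
    ens: Ensemble, k_max: int, anchor: str = "t0"
) -> EpsEstimate:
    """Recover <eps> by fitting ln(slope_k) = k * ln<eps> through the origin.

    Non-positive slopes (possible at large lags in noisy data) are dropped
    with a warning.  The implied additive mean uses the population mean at
    the first time point, which is 1 under unit-mean normalization.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    fits = [iterated_mapping(ens, k, anchor) for k in range(1, k_max + 1)]
    ks = np.array([f.k for f in fits], dtype=float)
    slopes = np.array([f.slope for f in fits])
    pos = slopes > 0
    if not pos.any():
        raise InsufficientDataError("all iterated-mapping slopes non-positive")
    if not pos.all():
        warnings.warn(
            f"dropping {int((~pos).sum())} non-positive slope(s) from the "
            "log-slope fit",
            stacklevel=2,
        )
    kk, ls = ks[pos], np.log(slopes[pos])
    coef = float(np.sum(kk * ls) / np.sum(kk * kk))  # zero-intercept OLS
    fitted = coef * kk
    ss_res = float(np.sum((ls - fitted) ** 2))
    ss_tot = float(np.sum((ls - ls.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    eps_mean = float(np.exp(coef))

    x0 = ens.sizes[:, 0]
    pop_mean = float(np.nanmean(x0))
    return EpsEstimate(
        eps_mean=eps_mean,
        eta_mean_implied=implied_eta_mean(eps_mean, pop_mean),
        pop_mean=pop_mean,
        per_k=fits,
        logslope_fit={"slope_per_k": coef, "r_squared": r2},
    )


def predict_slopes(eps_mean: float, ks) -> np.ndarray:
    """Predicted iterated-mapping slopes <eps>**k."""
    if eps_mean <= 0:
        raise ValueError("eps_mean must be positive")
    return np.power(eps_mean, np.asarray(ks, dtype=float))


def implied_eta_mean(eps_mean: float, pop_mean: float) -> float:
    """Additive mean pinned by stationarity: (1 - <eps>) * <x>."""
    if pop_mean <= 0:
        raise ValueError("population mean must be positive")
    return (1.0 - eps_mean) * pop_mean


def residual_variance_profile(ens: Ensemble, n_bins: int = 10) -> dict:
    """Quadratic profile of one-step residual variance against size.

    Under the model Var[x_{t+1} | x_t] = Var(eps) * x_t**2 + Var(eta), so the
    squared residuals of the pooled one-step regression, binned by x_t and
    fitted with a quadratic, estimate Var(eps) in ``c2``, Var(eta) in ``c0``
    and (when eps and eta are independent) ~0 in ``c1``.
    """
    x, y = _pairs(ens, 1, "pooled")
    fit = _ols(x, y, 1)
    resid2 = (y - fit.slope * x - fit.intercept) ** 2
    order = np.argsort(x, kind="stable")
    xs, rs = x[order], resid2[order]
    if xs.size < max(3 * n_bins, 30):
        raise InsufficientDataError("too few one-step pairs for binning")
    edges = np.linspace(0, xs.size, n_bins + 1).astype(int)
    bx = np.array([xs[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    bv = np.array([rs[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    c2, c1, c0 = np.polyfit(bx, bv, 2)
    return {
        "c2": float(c2),
        "c1": float(c1),
        "c0": float(c0),
        "bin_x": bx,
        "bin_var": bv,
    }


def pairwise_lag_estimate(ens: Ensemble, lag: int) -> float:
    """Per-step <eps> estimate from all pairs a fixed lag apart.

    The pooled slope over pairs (x_t, x_{t+lag}) estimates <eps>**lag; its
    lag-th root is the per-step value.  With additive measurement noise the
    short-lag estimates are biased low and improve as the lag grows.
    """
    fit = iterated_mapping(ens, lag, anchor="pooled")
    if fit.slope <= 0:
        raise InsufficientDataError(f"non-positive pooled slope at lag {lag}")
    return float(fit.slope ** (1.0 / lag))


def split_half_validation(ens: Ensemble, seed: int, k_max: int) -> dict:
    """Estimate <eps> on a random half of the synapses, predict the other.

    Returns the half-A estimate together with predicted (<eps_A>**k) and
    observed per-k slopes on half B.
    """
    n = ens.n_synapses
    if n < 6:
        raise InsufficientDataError("need at least 6 synapses to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half_a, half_b = perm[: n // 2], perm[n // 2 :]

    def subset(idx) -> Ensemble:
        return Ensemble(
            ens.times_hours,
            ens.sizes[idx],
            ens.alive[idx],
            ens.elimination_step[idx],
            dict(ens.tags),
        )

    est_a = estimate_eps_mean(subset(half_a), k_max)
    ens_b = subset(half_b)
    observed = np.array(
        [iterated_mapping(ens_b, k).slope for k in range(1, k_max + 1)]
    )
    ks = np.arange(1, k_max + 1)
    return {
        "eps_half_a": est_a.eps_mean,
        "ks": ks,
        "predicted_slopes_b": predict_slopes(est_a.eps_mean, ks),
        "observed_slopes_b": observed,
    }
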