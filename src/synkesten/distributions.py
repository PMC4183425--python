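"""Parametric families for the random factors of the Kesten recursion.

The multiplicative factor ``eps`` and the additive factor ``eta`` of the
recursion ``x_{t+1} = eps_t * x_t + eta_t`` are each drawn i.i.d. from a
fixed distribution.  Four families cover everything the model needs:
a point mass (for deterministic limits), Gaussian, uniform and gamma.

Two scalar functionals of the ``eps`` distribution control the qualitative
behaviour of the process:

* ``stability_index`` — E[ln eps].  Negative means the process is
  statistically stable and approaches a limiting distribution; positive
  means log-sizes drift to +inf.
* ``mu_exponent`` — the positive root mu of E[eps**mu] = 1, which sets the
  power-law exponent of the limiting distribution's upper tail,
  P(X > x) ~ x**(-mu).  Distributions sharing mu form a "mu-class" and
  produce limiting distributions of (empirically) identical shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, special, stats

__all__ = [
    "DistributionSpec",
    "stability_index",
    "mu_exponent",
    "mu_class_spec",
]

_FAMILIES = ("degenerate", "gaussian", "uniform", "gamma")

#: mass at or below zero above which log/power moments are refused
_NEGATIVE_MASS_TOL = 1e-6


class ParameterError(ValueError):
    """Invalid family parameters."""


@dataclass(frozen=True)
class DistributionSpec:
    """One random factor of the Kesten recursion.

    Use the family constructors (:meth:`degenerate`, :meth:`gaussian`,
    :meth:`uniform`, :meth:`gamma`) rather than the raw constructor.
    """

    family: str
    params: tuple = field(default=())

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterError(f"unknown family {self.family!r}")
        p = self.params
        if self.family == "degenerate":
            if len(p) != 1:
                raise ParameterError("degenerate takes a single value")
        elif self.family == "gaussian":
            if len(p) != 2 or p[1] < 0:
                raise ParameterError("gaussian needs (mean, sd) with sd >= 0")
        elif self.family == "uniform":
            if len(p) != 2 or p[0] > p[1]:
                raise ParameterError("uniform needs (low, high) with low <= high")
        elif self.family == "gamma":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ParameterError("gamma needs (shape, scale), both > 0")

    # -- constructors -------------------------------------------------
    @classmethod
    def degenerate(cls, value: float) -> "DistributionSpec":
        return cls("degenerate", (float(value),))

    @classmethod
    def gaussian(cls, mean: float, sd: float) -> "DistributionSpec":
        return cls("gaussian", (float(mean), float(sd)))

    @classmethod
    def uniform(cls, low: float, high: float) -> "DistributionSpec":
        return cls("uniform", (float(low), float(high)))

    @classmethod
    def gamma(cls, shape: float, scale: float) -> "DistributionSpec":
        return cls("gamma", (float(shape), float(scale)))

    # -- moments ------------------------------------------------------
    def mean(self) -> float:
        if self.family == "degenerate":
            return self.params[0]
        if self.family == "gaussian":
            return self.params[0]
        if self.family == "uniform":
            return 0.5 * (self.params[0] + self.params[1])
        shape, scale = self.params
        return shape * scale

    def variance(self) -> float:
        if self.family == "degenerate":
            return 0.0
        if self.family == "gaussian":
            return self.params[1] ** 2
        if self.family == "uniform":
            return (self.params[1] - self.params[0]) ** 2 / 12.0
        shape, scale = self.params
        return shape * scale**2

    def sd(self) -> float:
        return math.sqrt(self.variance())

    # -- sampling -----------------------------------------------------
    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` i.i.d. values using ``rng``."""
        if n < 1:
            raise ParameterError("n must be >= 1")
        if self.family == "degenerate":
            return np.full(n, self.params[0])
        if self.family == "gaussian":
            return rng.normal(self.params[0], self.params[1], size=n)
        if self.family == "uniform":
            return rng.uniform(self.params[0], self.params[1], size=n)
        shape, scale = self.params
        return rng.gamma(shape, scale, size=n)

    # -- density / support helpers ------------------------------------
    def frozen(self):
        """The matching ``scipy.stats`` frozen distribution (continuous only)."""
        if self.family == "gaussian":
            return stats.norm(self.params[0], self.params[1])
        if self.family == "uniform":
            lo, hi = self.params
            return stats.uniform(lo, hi - lo)
        if self.family == "gamma":
            shape, scale = self.params
            return stats.gamma(shape, scale=scale)
        raise ParameterError("degenerate distribution has no density")

    def prob_nonpositive(self) -> float:
        """P(X <= 0)."""
        if self.family == "degenerate":
            return float(self.params[0] <= 0)
        if self.family == "gamma":
            return 0.0
        if self.family == "gaussian" and self.params[1] == 0:
            return float(self.params[0] <= 0)
        return float(self.frozen().cdf(0.0))


def _expect_positive(spec: DistributionSpec, func) -> float:
    """E[func(X) | X > 0] by adaptive quadrature over the positive support.

    For the model's parameter regimes P(X <= 0) is negligible, so the
    conditional expectation and the plain expectation agree to ~1e-6.
    """
    if spec.family == "degenerate":
        return func(spec.params[0])
    frz = spec.frozen()
    if spec.family == "gaussian":
        m, s = spec.params
        if s == 0:
            return func(m)
        lo, hi = max(0.0, m - 12 * s), m + 12 * s
    elif spec.family == "uniform":
        lo, hi = max(0.0, spec.params[0]), spec.params[1]
    else:  # gamma
        lo, hi = frz.ppf(1e-12), frz.ppf(1 - 1e-13)
    mass = frz.cdf(hi) - frz.cdf(lo)
    val, _ = integrate.quad(
        lambda x: func(x) * frz.pdf(x), lo, hi, limit=400, epsabs=1e-12, epsrel=1e-10
    )
    return val / mass


def stability_index(eps: DistributionSpec) -> float:
    """E[ln eps] — negative in the stable regime, positive in the divergent one.

    Raises ``ValueError`` if the distribution places more than negligible
    mass at eps <= 0, where the logarithm is undefined.
    """
    if eps.prob_nonpositive() > _NEGATIVE_MASS_TOL:
        raise ValueError(
            "stability index undefined: eps has non-negligible mass at <= 0"
        )
    if eps.family == "degenerate":
        return math.log(eps.params[0])
    if eps.family == "gamma":
        shape, scale = eps.params
        return float(special.digamma(shape) + math.log(scale))
    return _expect_positive(eps, math.log)


def power_moment(spec: DistributionSpec, mu: float) -> float:
    """E[X**mu] over the positive support of ``spec``."""
    if spec.prob_nonpositive() > _NEGATIVE_MASS_TOL:
        raise ValueError("power moment restricted to distributions on (0, inf)")
    if spec.family == "degenerate":
        return spec.params[0] ** mu
    if spec.family == "gamma":
        shape, scale = spec.params
        return float(
            math.exp(mu * math.log(scale) + special.gammaln(shape + mu) - special.gammaln(shape))
        )
    return _expect_positive(spec, lambda x: x**mu)


def mu_exponent(
    eps: DistributionSpec, mu_max: float = 50.0, tol: float = 1e-10
) -> float:
    """Positive root mu of E[eps**mu] = 1 (the tail exponent of the limit law).

    Requires the stable regime E[ln eps] < 0; the root exists when the
    distribution has enough mass above 1 that E[eps**m] eventually exceeds 1.
    The bracket expands automatically beyond ``mu_max`` once before giving up.
    """
    if eps.family == "degenerate" or eps.variance() == 0:
        raise ValueError("degenerate eps: E[eps**mu] = 1 only at mu = 0")
    if stability_index(eps) >= 0:
        raise ValueError("mu exponent requires the stable regime E[ln eps] < 0")

    def g(mu: float) -> float:
        return power_moment(eps, mu) - 1.0

    hi = 1.0
    limit = mu_max
    for _ in range(2):  # one automatic bracket expansion
        while hi <= limit and g(hi) <= 0:
            hi *= 1.5
        if hi <= limit:
            break
        limit *= 4
    if g(hi) <= 0:
        raise ValueError("no positive root of E[eps**mu] = 1 in bracket")
    lo = hi / 1.5
    while g(lo) >= 0:  # ensure sign change (g < 0 just above 0)
        lo /= 2.0
        if lo < 1e-8:
            break
    return float(optimize.brentq(g, lo, hi, xtol=tol))


def mu_class_spec(family: str, mu: float, *, sd: float | None = None,
                  width: float | None = None, shape: float | None = None
                  ) -> DistributionSpec:
    """Construct a spec in a given mu-class, i.e. with E[eps**mu] = 1.

    One secondary parameter fixes the family's spread and the location is
    solved for: ``sd`` for gaussian, ``width`` (high - low) for uniform,
    ``shape`` for gamma (scale solved in closed form).
    """
    if mu <= 0:
        raise ParameterError("mu must be positive")
    if family == "gamma":
        if shape is None:
            raise ParameterError("gamma mu-class needs shape")
        scale = math.exp(-(special.gammaln(shape + mu) - special.gammaln(shape)) / mu)
        return DistributionSpec.gamma(shape, scale)

    if family == "gaussian":
        if sd is None or sd <= 0:
            raise ParameterError("gaussian mu-class needs sd > 0")
        make = lambda m: DistributionSpec.gaussian(m, sd)
    elif family == "uniform":
        if width is None or width <= 0:
            raise ParameterError("uniform mu-class needs width > 0")
        make = lambda m: DistributionSpec.uniform(m - width / 2, m + width / 2)
    else:
        raise ParameterError(f"unsupported family {family!r} for mu-class construction")

    def g(m: float) -> float:
        return power_moment(make(m), mu) - 1.0

    # location just below 1 keeps E[ln eps] < 0 while E[eps**mu] reaches 1
    lo = 0.5
    hi = 1.0
    while g(hi) < 0:
        hi += 0.05
    root = optimize.brentq(g, lo, hi, xtol=1e-12)
    return make(float(root))
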