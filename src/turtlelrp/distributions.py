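"""Probability-distribution primitives shared across the package.

Every uncertain input (vital rates, migration proportions, abundance
summaries) is configured as a :class:`Dist` — a small frozen descriptor of a
distribution family plus its parameters.  Sampling always goes through a
caller-supplied :class:`numpy.random.Generator`, so reproducibility is
governed entirely by seed policy at the call site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = ["ConfigurationError", "Dist"]


class ConfigurationError(ValueError):
    """Invalid distribution or estimator configuration."""


@dataclass(frozen=True)
class Dist:
    """A configured univariate distribution.

    Supported families:

    ``point``
        Degenerate at ``args[0]``.
    ``uniform``
        ``U(lo, hi)``.
    ``beta``
        ``Beta(a, b)`` shape parameters.
    ``trunc_beta``
        ``Beta(a, b)`` truncated below at ``lower``; sampled exactly by
        inverse CDF on the truncated region.
    ``normal``
        ``N(mean, sd)``.
    ``lognormal``
        parameters are the mean and sd of ``log X``.
    """

    family: str
    args: tuple[float, ...]

    # -- constructors -----------------------------------------------------
    @classmethod
    def point(cls, x: float) -> "Dist":
        return cls("point", (float(x),))

    @classmethod
    def uniform(cls, lo: float, hi: float) -> "Dist":
        if not lo < hi:
            raise ConfigurationError(f"uniform bounds must satisfy lo < hi, got ({lo}, {hi})")
        return cls("uniform", (float(lo), float(hi)))

    @classmethod
    def beta(cls, a: float, b: float) -> "Dist":
        if a <= 0 or b <= 0:
            raise ConfigurationError(f"beta shapes must be positive, got ({a}, {b})")
        return cls("beta", (float(a), float(b)))

    @classmethod
    def trunc_beta(cls, a: float, b: float, lower: float) -> "Dist":
        if a <= 0 or b <= 0:
            raise ConfigurationError(f"beta shapes must be positive, got ({a}, {b})")
        if not 0.0 < lower < 1.0:
            raise ConfigurationError(f"truncation bound must lie in (0,1), got {lower}")
        return cls("trunc_beta", (float(a), float(b), float(lower)))

    @classmethod
    def normal(cls, mean: float, sd: float) -> "Dist":
        if sd < 0:
            raise ConfigurationError(f"normal sd must be nonnegative, got {sd}")
        return cls("normal", (float(mean), float(sd)))

    @classmethod
    def lognormal(cls, mean_log: float, sd_log: float) -> "Dist":
        if sd_log < 0:
            raise ConfigurationError(f"lognormal sd must be nonnegative, got {sd_log}")
        return cls("lognormal", (float(mean_log), float(sd_log)))

    # -- moments ----------------------------------------------------------
    def mean(self) -> float:
        f, a = self.family, self.args
        if f == "point":
            return a[0]
        if f == "uniform":
            return 0.5 * (a[0] + a[1])
        if f == "beta":
            return a[0] / (a[0] + a[1])
        if f == "trunc_beta":
            sa, sb, lo = a
            # E[X | X > lo] for Beta(sa, sb) via regularized incomplete beta.
            tail = 1.0 - special.betainc(sa, sb, lo)
            tail_up = 1.0 - special.betainc(sa + 1.0, sb, lo)
            return (sa / (sa + sb)) * tail_up / tail
        if f == "normal":
            return a[0]
        if f == "lognormal":
            return float(np.exp(a[0] + 0.5 * a[1] ** 2))
        raise ConfigurationError(f"unknown family {f!r}")

    # -- sampling ---------------------------------------------------------
    def sample(self, rng: np.random.Generator, n: int | None = None):
        """Draw ``n`` variates (or a scalar when ``n`` is None)."""
        f, a = self.family, self.args
        size = n
        if f == "point":
            return a[0] if n is None else np.full(n, a[0])
        if f == "uniform":
            return rng.uniform(a[0], a[1], size=size)
        if f == "beta":
            return rng.beta(a[0], a[1], size=size)
        if f == "trunc_beta":
            sa, sb, lo = a
            flo = stats.beta.cdf(lo, sa, sb)
            u = rng.uniform(flo, 1.0, size=size)
            return stats.beta.ppf(u, sa, sb)
        if f == "normal":
            return rng.normal(a[0], a[1], size=size)
        if f == "lognormal":
            return rng.lognormal(a[0], a[1], size=size)
        raise ConfigurationError(f"unknown family {f!r}")

    def scaled(self, k: float) -> "Dist":
        """Distribution of ``k·X`` where it stays inside a supported family."""
        f, a = self.family, self.args
        if f == "point":
            return Dist.point(a[0] * k)
        if f == "uniform":
            lo, hi = sorted((a[0] * k, a[1] * k))
            return Dist.uniform(lo, hi)
        if f == "normal":
            return Dist.normal(a[0] * k, a[1] * abs(k))
        if f == "lognormal":
            if k <= 0:
                raise ConfigurationError("lognormal scaling requires k > 0")
            return Dist.lognormal(a[0] + np.log(k), a[1])
        raise ConfigurationError(f"cannot scale family {f!r}")
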