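"""PBR / RVLL limit reference point estimators.

The limit on annual human-caused removals is a tuned percentile of the
Monte-Carlo distribution of

    0.5 (lambda_m - 1) N f_a

where ``lambda_m`` is the maximum annual growth multiplier, ``N`` the local
abundance (individuals for PBR, adult equivalents for RVLL — the units ride
along from the abundance sample), and ``f_a`` an adjustment factor in (0, 1]
absorbing bias and stricter objectives.  The percentile and ``f_a`` are set
by management strategy evaluation (see :mod:`turtlelrp.mse`).  Empirical
percentiles use linear interpolation between order statistics (the numpy
default), fixed as the package convention.

Relation to the legacy published PBR form ``0.5 R_max N_min F_r``:
``lambda_m - 1`` stands in for ``R_max`` (age-structured context), the tuned
percentile of the whole LRP distribution replaces the fixed 20th-percentile
minimum abundance ``N_min`` (capturing growth-rate as well as abundance
uncertainty), and ``f_a`` generalizes the recovery factor ``F_r``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import AbundanceSamples
from .distributions import ConfigurationError

__all__ = [
    "LRPSamples",
    "lrp_distribution",
    "lrp_at_percentile",
    "removals_to_interactions",
    "lrp_grid",
]

#: Expected deaths per observed fishery interaction in the drift gillnet
#: fishery; converts removal limits to interaction limits.
DISCARD_MORTALITY = 0.68


@dataclass(frozen=True)
class LRPSamples:
    """Monte-Carlo sample of the annual removal limit distribution."""

    samples: np.ndarray
    f_a: float
    units: str

    def __len__(self):
        return len(self.samples)


def lrp_distribution(lambda_samples: np.ndarray,
                     abundance: AbundanceSamples,
                     f_a: float) -> LRPSamples:
    """Elementwise ``0.5 (lambda - 1) N f_a`` over paired Monte-Carlo draws.

    ``lambda_samples`` are drawn independently of the abundance sample; units
    are inherited from the abundance sample (individuals -> PBR, adult
    equivalents -> RVLL).
    """
    if not 0.0 < f_a <= 1.0:
        raise ConfigurationError(f"f_a={f_a} outside (0, 1]")
    lam = np.asarray(lambda_samples, float)
    n = np.asarray(abundance.samples, float)
    if lam.shape != n.shape:
        raise ValueError(f"paired samples must match: {lam.shape} vs {n.shape}")
    return LRPSamples(samples=0.5 * (lam - 1.0) * n * f_a, f_a=f_a,
                      units=abundance.units)


def lrp_at_percentile(samples: LRPSamples, q: float, years: float = 1.0) -> float:
    """The q-th percentile of the limit distribution, scaled to a horizon.

    Returns the raw value; reporting rounds to one decimal.
    """
    if not 0.0 < q < 100.0:
        raise ConfigurationError(f"percentile q={q} outside (0, 100)")
    if len(samples) == 0:
        raise ValueError("empty LRP sample")
    return float(np.percentile(samples.samples, q) * years)


def removals_to_interactions(removals: float, mortality: float = DISCARD_MORTALITY) -> float:
    """Convert a removal limit to a fishery-interaction limit."""
    if not 0.0 < mortality <= 1.0:
        raise ConfigurationError(f"discard mortality {mortality} outside (0, 1]")
    return removals / mortality


def lrp_grid(lambda_samples: np.ndarray,
             abundance: AbundanceSamples,
             percentiles,
             f_a_values,
             years: float = 1.0) -> pd.DataFrame:
    """Limit values over a percentile x f_a grid (rows: percentile).

    Exactly proportional to ``f_a`` along columns and non-decreasing down the
    percentile axis.
    """
    percentiles = list(percentiles)
    f_a_values = list(f_a_values)
    if not percentiles or not f_a_values:
        raise ConfigurationError("percentile and f_a grids must be nonempty")
    cols = {}
    for fa in f_a_values:
        d = lrp_distribution(lambda_samples, abundance, fa)
        cols[fa] = [lrp_at_percentile(d, q, years) for q in percentiles]
    out = pd.DataFrame(cols, index=pd.Index(percentiles, name="percentile"))
    out.columns.name = "f_a"
    return out
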