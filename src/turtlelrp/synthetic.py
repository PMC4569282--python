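"""Synthetic data generators emulating the analysis' field inputs.

Three data streams feed the abundance estimators in a real application: a
long nest-count index series at the West Papua index beaches (declining about
6% per year), a noisy nearshore aerial-survey series off California
proportional to it, and satellite-tag migration outcomes plus bycatch
carapace-length records.  The generators here produce series and records
with that statistical structure so every stage of the pipeline can run and
be validated against known truth without any field data.

The state-space forecaster is a local level with drift on log counts fitted
by maximum likelihood (Kalman filtering via statsmodels); it exists to turn a
count series into a forecast sampler for the survey estimator.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .abundance import QuantitySampler, sampler_from_summary
from .distributions import Dist

__all__ = [
    "simulate_nest_counts",
    "simulate_survey_series",
    "simulate_tag_and_size_records",
    "beta_posterior",
    "fit_count_trend",
    "survey_forecast_sampler",
]


def simulate_nest_counts(rng: np.random.Generator,
                         years: int = 30,
                         annual_trend: float = 0.94,
                         obs_cv: float = 0.20,
                         initial_count: float = 10500.0,
                         first_year: int = 1985) -> pd.DataFrame:
    """Nest-count index series: multiplicative trend, lognormal observation.

    Defaults give a series declining 6%/yr over three decades, scaled so the
    terminal latent count is consistent with roughly 320 females nesting
    annually at 5.5 nests each.

    Returns a frame with columns ``year``, ``latent``, ``observed``.
    """
    if annual_trend <= 0:
        raise ValueError(f"annual_trend must be positive, got {annual_trend}")
    if obs_cv < 0:
        raise ValueError(f"obs_cv must be nonnegative, got {obs_cv}")
    t = np.arange(years)
    latent = initial_count * annual_trend ** t
    if obs_cv > 0:
        sd_log = np.sqrt(np.log1p(obs_cv ** 2))
        observed = latent * rng.lognormal(-0.5 * sd_log ** 2, sd_log, size=years)
    else:
        observed = latent.copy()
    return pd.DataFrame({"year": first_year + t, "latent": latent, "observed": observed})


def simulate_survey_series(rng: np.random.Generator,
                           nest_series: pd.DataFrame,
                           scale: float = 0.032,
                           obs_cv: float = 0.30,
                           lt_sd: float = 0.14) -> pd.DataFrame:
    """Aerial-survey series proportional to the latent nest index.

    ``scale`` is turtles surveyed per latent nest (constant through time —
    the proportionality assumption behind the survey forecast).  Observation
    noise is lognormal per year; a single systematic factor ~ N(1, lt_sd)
    shared by the whole series emulates error from estimated line-transect
    parameters.
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    lt = rng.normal(1.0, lt_sd) if lt_sd > 0 else 1.0
    while lt <= 0:
        lt = rng.normal(1.0, lt_sd)
    latent = nest_series["latent"].to_numpy() * scale
    if obs_cv > 0:
        sd_log = np.sqrt(np.log1p(obs_cv ** 2))
        observed = latent * lt * rng.lognormal(-0.5 * sd_log ** 2, sd_log, size=len(latent))
    else:
        observed = latent * lt
    return pd.DataFrame({"year": nest_series["year"].to_numpy(),
                         "latent": latent, "observed": observed})


def beta_posterior(successes: int, failures: int) -> Dist:
    """Beta posterior for a binomial proportion, package convention.

    Jeffreys offsets (+0.5, +0.5), except that a zero count opposite a
    positive count is floored at shape 1 — the convention that reproduces
    the published parameterizations (23/37 -> Beta(23.5, 14.5); 10/16 ->
    Beta(10.5, 6.5); 5/5 -> Beta(5.5, 1)).  With no data at all the Jeffreys
    prior Beta(0.5, 0.5) is returned.
    """
    if successes < 0 or failures < 0:
        raise ValueError("counts must be nonnegative")
    a = successes + 0.5
    b = failures + 0.5
    if successes == 0 and failures > 0:
        a = 1.0
    if failures == 0 and successes > 0:
        b = 1.0
    return Dist.beta(a, b)


def simulate_tag_and_size_records(rng: np.random.Generator,
                                  true_props=(0.62, 0.63, 0.9),
                                  n_tags_per_stage=(37, 16, 5),
                                  true_adult_fraction: float = 0.5,
                                  n_sizes: int = 4) -> dict:
    """Binomial tag-migration outcomes and bycatch size records.

    Each migration stage draws successes ~ Binomial(n, p); the size records
    draw the count of measured turtles above the adult-length cut.  Returns
    the raw counts together with the beta posteriors built by
    :func:`beta_posterior`.
    """
    stages = []
    for p, n in zip(true_props, n_tags_per_stage):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion {p} outside [0, 1]")
        s = int(rng.binomial(n, p)) if n > 0 else 0
        stages.append({"n": n, "successes": s,
                       "posterior": beta_posterior(s, n - s)})
    n_adult = int(rng.binomial(n_sizes, true_adult_fraction)) if n_sizes > 0 else 0
    return {
        "migration_stages": stages,
        "size_records": {"n": n_sizes, "adults": n_adult,
                         "posterior": beta_posterior(n_adult, n_sizes - n_adult)},
    }


def fit_count_trend(series: pd.DataFrame, forecast_steps: int = 0):
    """Fit a local level with drift to log counts; optionally forecast.

    Returns ``(trend_multiplier, forecast_mean, forecast_se_log)`` where the
    trend multiplier is ``exp(drift)`` and the forecast (when requested) is
    for the latent level ``forecast_steps`` years past the end of the series,
    on the count scale with its log-scale standard error.
    """
    from statsmodels.tsa.statespace.structural import UnobservedComponents

    y = np.log(series["observed"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = UnobservedComponents(y, level="local linear deterministic trend")
        res = model.fit(disp=0)
        trend = float(np.exp(res.params[model.param_names.index("trend")])) \
            if "trend" in model.param_names else float(np.exp(res.trend["smoothed"][-1]))
        if forecast_steps > 0:
            fc = res.get_forecast(forecast_steps)
            mean_log = float(fc.predicted_mean[-1])
            se_log = float(fc.se_mean[-1])
            return trend, float(np.exp(mean_log)), se_log
    return trend, None, None


def survey_forecast_sampler(rng: np.random.Generator,
                            nest_series: pd.DataFrame,
                            survey_series: pd.DataFrame,
                            target_year: int = 2014) -> QuantitySampler:
    """Forecast sampler for the survey index in ``target_year``.

    Simplified two-stage version of the state-space linkage: the nest series
    (less noisy, longer) is fitted and forecast to the target year; the
    survey series is tied to it by the ratio of survey observations to the
    fitted nest level, whose sampling spread supplies the dominant share of
    the forecast uncertainty.  Returns a lognormal sampler.
    """
    last = int(nest_series["year"].max())
    steps = max(target_year - last, 0)
    if steps > 0:
        _, nest_fc, nest_se = fit_count_trend(nest_series, forecast_steps=steps)
    else:
        _, nest_fc, nest_se = fit_count_trend(nest_series, forecast_steps=1)
        nest_fc = float(nest_series["observed"].iloc[-1])
    merged = survey_series.merge(nest_series[["year", "observed"]], on="year",
                                 suffixes=("_survey", "_nest"))
    log_ratio = np.log(merged["observed_survey"].to_numpy()
                       / merged["observed_nest"].to_numpy())
    ratio_mean = float(np.mean(log_ratio))
    ratio_sd = float(np.std(log_ratio, ddof=1)) if len(log_ratio) > 1 else 0.0
    mean_log = np.log(nest_fc) + ratio_mean
    sd_log = float(np.sqrt(nest_se ** 2 + ratio_sd ** 2 / max(len(log_ratio), 1)
                           + ratio_sd ** 2))
    if sd_log == 0.0:
        return QuantitySampler(Dist.point(np.exp(mean_log)), allow_zero=True)
    return QuantitySampler(Dist.lognormal(mean_log, sd_log))
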