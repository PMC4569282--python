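# Methods

This note records the model, its parameterization, the simulation design,
and the choices made where the published description of the assessment left
the design open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Population model

The population is boreal-summer-nesting western Pacific leatherbacks,
treated as closed.  Dynamics follow a post-breeding-census
Leslie–Lefkovitch matrix: age classes 0..α−1 plus a single adult stage with
survival `P_adult` on the diagonal, dimension α+1 with age at first
reproduction α = 13 (fixed; the effect of bias in α is explored in a
sensitivity trial with true α = 20).  Because the census is post-breeding,
fertilities include parental survival — `F_adult = P_adult · PF · (1/RI) ·
CF · CS` eggs per year, and the neophyte (first-nesting) class carries an
extra factor `f_neo` — so eggs and hatchlings hold reproductive value and
removals of any stage can be expressed in adult equivalents `v_a / v_adult`.

Parameter defaults (units, source character):

| parameter | default | notes |
|---|---|---|
| λ_m | U(1.04, 1.06) | maximum annual growth multiplier, from recovering reference populations |
| α | 13 yr | fixed |
| P_adult = P_α | U(0.88, 0.96) | final sub-adult survival set equal to adult |
| erosion | Beta(9.7, 20.2) | proportion of nests destroyed |
| emergence | Beta(2.8, 4.2) | hatchlings per egg in intact nests |
| first-day survival | 0.55 | fixed |
| RI | 2.5 yr | remigration interval |
| PF | Beta(27.5, 10.5) | proportion female (27 of 37 sexed animals) |
| CF, CS | 5.5 nests/yr, 78 eggs | clutch frequency and size |
| f_neo | 0.68 | neophyte fecundity factor |

`P_hatch = emergence × (1 − erosion) × first-day survival` evaluates to
0.149 at the means (printed as 0.15).

### Juvenile survival solve

Only the product of the unknown juvenile survivals enters the dominant
eigenvalue, so the characteristic (renewal) equation

`1 = L [ F_α λ^(−α) + F_adult P_α λ^(−α−1) / (1 − P_adult/λ) ]`

is linear in the survivorship `L = s_0 s_1 … s_(α−2)` and is solved in
closed form (no iteration; the assembled matrix is verified to reproduce
the target λ within 1e−6, and targets at or below the `P_adult` floor or
requiring L > 1 raise an infeasibility error naming the draw).  The solved
product is then spread over ages with `j(a) = c_0 + c_1 ln(a+1)` — survival
rises with size and size rises asymptotically with age — anchored so the
curve meets `P_adult` at age α−1 while the product constraint holds exactly
(the slope may go slightly negative for rare draws with very low hatchling
survival; `j(0) ≤ 1` caps it).  Age-0 survival is `P_hatch × j(0)`.  The
exact functional form and anchoring are a package choice: the source
description specifies only "a logarithmic curve", and quantities that
depend on the curve's details (notably the naive-approach adult-equivalent
total) are treated as approximate.

The "steeper juvenile curve" sensitivity construction is a power transform
of the fitted curve about its geometric mean in log space
(`ln j' = k (ln j − m) + m`, k = 1.5), which preserves the survivorship
product — hence λ — exactly while steepening the early rise.  A re-centred
straight-line steepening cannot preserve the product with survivals capped
at 1, which is why the transform is used instead.

## Abundance estimators

All three estimators are 2000-draw Monte-Carlo samplers anchored to
n̂2014 — the mean annual nesting females in 2014, reconstructed from its
printed summary (median 318, 90% CI 302–334) as a quantile-matched normal
(the interval is symmetric; asymmetric summaries become lognormal).

* **naive** (adult equivalents): total adults = n̂2014 · RI / PF; local
  adults = × 1.0% range fraction (a configured constant — the GIS overlay is
  out of scope); adult equivalents = × Σ w_a v_a of the means-case matrix
  with λ fixed at its mean.
* **survey** (individuals): (days in WCEEZ / 365) × survey forecast ×
  ε_LT, with days ~ N(100, 13), ε_LT ~ N(1, 0.14) (non-positive draws
  redrawn; probability ~1e−12), and the forecast supplied by the
  state-space fit to (synthetic) series — see below.
* **tag** (individuals): (days/365) × Beta(23.5, 14.5) × Beta(10.5, 6.5) ×
  Beta(5.5, 1) × (RI − 1) × n̂2014, expanded by the adult fraction
  (Beta(2.5, 2.5) truncated below at 0.23, sampled exactly by inverse CDF
  on the truncated region) and PF.

Summaries report the median, the 2.5th/97.5th percentiles, and CV =
sd/mean.  Empirical percentiles use linear interpolation between order
statistics (numpy default), fixed as the package convention.

## Management strategy evaluation

Each of 2000 simulations draws its own true life history (its own random
substream; infeasible draws are redrawn within-stream).  Populations start
at the stable age distribution of their true matrix, scaled so
adult-equivalent abundance equals the start level (0.5K for the N_MNP
objective, 0.1K for N_collapse and rebuilding; K = 10,000 adult
equivalents, an arbitrary scale — risk results are exactly invariant to K,
and the test suite asserts it).

**Density dependence** acts on fertilities: each year the fertility row is
scaled by the closed-form multiplier that sets the asymptotic growth rate
to `λ(N) = 1 + (λ_m − 1)(1 − N_AE/K)` at the current adult-equivalent
abundance, giving maximum net productivity at 0.5K.  If the target falls to
or below the `P_adult` floor (possible only above K), reproduction shuts
off.  With the matched age structure, a quota of `0.5(λ_m − 1) · 0.5K`
holds the population at 0.5K exactly (asserted to 1e−12 in tests); from an
unmatched stable-at-λ_m structure the transient overshoots by at most a
few percent before returning.

**Observation model.**  Each simulation carries one persistent
multiplicative estimation error, lognormal with median 1 and the approach's
assessment CV (naive 11%, survey 33%, tag 50%), reflecting that an
assessment's data sources — and hence its bias — persist from year to year.
The assessment's median is anchored to the true adult class: all three
estimators chain back to counts of nesting females, so the median estimate
is the adult count expanded with the estimation model's stable structure
(Σw per adult for individuals; Σw·v per adult for adult equivalents).  The
mismatch between that fixed expansion and each simulation's true structure
is the structural component of estimation bias; it is what transmits the
maturity-age and structure biases of the sensitivity trials to RVLL (and,
through the expansion, mildly to PBR) exactly in the published directions.
The λ estimate is always U(1.04, 1.06) regardless of the truth.

**Management model.**  The quota is the chosen percentile of the estimated
LRP distribution — computed as the exact percentile of
`0.5(λ̂ − 1) × lognormal(median 1, CV)` times the estimated abundance and
`f_a` — set once from the initial assessment and held constant over the
evaluation horizon (`quota_mode="initial"`, the default).  Removals equal
the quota exactly (catch monitoring is assumed perfect) and are debited at
a uniform per-capita rate across all age classes; a quota exceeding the
population zeroes it.  Annual recomputation from the current estimated
abundance is available as `quota_mode="annual"`; it is a markedly
stabilizing feedback (tuning percentiles roughly double), and the
fixed-initial-quota reading is the one consistent with the published
tuning results, which is why it is the default.  The projected-limit
trajectory uses the annually-updating rule, since it depicts limits
tracking a rebuilding population.

**Risk and tuning.**  Risk per (percentile, f_a) cell is the fraction of
simulations whose final adult head count falls below the threshold — the
stable-structure adult abundance at N_MNP for the N_MNP objective (equal to
the initial adults when starting there), the initial adult count for the
adult-decline/N_collapse objective.  The same parameter draws, persistent
errors and rate quantiles are shared by every cell (common random numbers),
so risk is monotone in both percentile and f_a by construction.  Tuning
returns the highest percentile within tolerance (5% for N_MNP, 2.5% for
N_collapse) per f_a.  Rebuilding trials run 200 years from 0.1K at ten f_a
values (0.1..1.0) with a zero-removal twin per simulation sharing all
draws; ratios of first-passage times to the N_MNP adult level are censored
at the horizon when the managed run never rebuilds (ratio =
horizon/twin-time, flagged).

Default grids: percentiles {2.5, 5, 10, 15, 20, 25, 30, 40, 50}, f_a {0.6,
1} for threshold objectives, 40-year horizon (about two generations;
generation time itself is not modelled).

## Synthetic data

The generators emulate the statistical structure of the field inputs, not
their ecology:

* **nest counts** — a multiplicative 6%/yr decline (trend 0.94) over 30
  years with lognormal observation noise (CV 0.2), scaled so the terminal
  latent level matches ~320 nesting females at 5.5 nests each;
* **aerial surveys** — proportional to the latent nest index (0.032
  turtles surveyed per nest, chosen so the 2014 level is ~56 animals, the
  order of the nearshore index), with lognormal year noise (CV 0.3) and one
  series-wide systematic factor N(1, 0.14) matching ε_LT;
* **tag and size records** — binomial outcomes at the study's sample sizes.
  Beta posteriors use Jeffreys offsets (+0.5, +0.5) with a zero count
  opposite a positive count floored at shape 1 — the convention inferred
  from the published parameter pairs (23/37 → Beta(23.5, 14.5), 10/16 →
  Beta(10.5, 6.5), 5/5 → Beta(5.5, 1)); no data at all returns the
  Jeffreys prior.

The survey forecaster is a local level with deterministic drift on log
counts (maximum likelihood via Kalman filtering), linked to the survey
series by the sampling distribution of the log survey/nest ratio.  It
exists to produce a forecast sampler, not to reproduce any particular
published state-space formulation.

What the generators do *not* emulate: oceanographic covariates of survey
variability, autocorrelated observation error, metapopulation exchange,
or trends in the survey/nest proportionality.  Passing tests therefore
show that the pipeline recovers known truth under its own assumptions, not
that those assumptions hold for the real series.  At the study's actual
record sizes (5 tags to the WCEEZ, 4 measured bycaught animals) the beta
priors shrink proportions near 1 noticeably downward — visible as a ~20%
downward pull in end-to-end recovery — so the recovery test uses 10× record
counts to isolate pipeline correctness.

## Known limitations

* The naive approach shows essentially zero MSE risk at f_a = 0.6 in this
  reconstruction (tuning returns the top of the grid): with uniform
  per-capita removals, a stable true structure and an 11% assessment CV,
  the adult-equivalent rule is benign.  The published account reports
  materially higher risk for this approach; whatever observation-model
  detail drives it (for example random age composition of removals) is not
  recoverable from the printed description.  Tag and survey tunings, and
  the ≥75%-above-N_MNP summary, do not depend on this.
* Environmental and demographic process stochasticity are not modelled;
  all between-simulation variation is parameter and estimation
  uncertainty.  Removals are deterministic expectations (fractional
  animals allowed).
* The Table-3-style naive median depends on the juvenile-curve details and
  is treated as an approximate cross-check (±15%), and the survey median
  depends on the synthetic series calibration; neither is asserted tightly.
* The 1.0% range fraction and the 2014 nesting forecast are configured
  inputs, not computed ones.
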