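# turtlelrp

Removal limit reference points (LRPs) for western Pacific leatherback turtles
(*Dermochelys coriacea*) in the U.S. West Coast Exclusive Economic Zone
(WCEEZ), for quantitative ecologists and stock-assessment analysts working on
bycatch limits for data-poor, long-lived marine megafauna.

The package estimates how many leatherbacks can be removed per year (or per
five years) by all human causes in the WCEEZ while still meeting population
conservation objectives, and uses closed-loop simulation to tune the
estimator so those objectives are met with stated probability.

## The method

A local limit is a tuned percentile of the Monte-Carlo distribution of

```
LRP = 0.5 (λ_m − 1) N f_a
```

where `λ_m` is the maximum annual population growth multiplier
(`λ_m ~ U(1.04, 1.06)`), `N` the local abundance, and `f_a ∈ (0, 1]` an
adjustment factor.  With `N` in individuals this is the Potential Biological
Removal (PBR) form; with `N` in adult equivalents (each animal weighted by
its reproductive value relative to an adult) it is the Reproductive Value
Loss Limit (RVLL), which makes removals of eggs, juveniles and adults
commensurable.

Three estimators of local abundance feed the limit, in increasing order of
local information:

| approach | information | estimator | units |
|---|---|---|---|
| naive  | range fraction only (1.0% of the stock's range lies in the WCEEZ) | RVLL | adult equivalents |
| survey | nearshore aerial survey index, prorated by residence time | PBR | individuals |
| tag    | satellite-tag migration proportions × sex ratio × bycatch size composition | PBR | individuals |

Reproductive values come from a post-breeding-census Leslie–Lefkovitch
matrix (age classes 0..12 plus an adult stage; dimension α+1 = 14 with age
at first reproduction α = 13).  For each parameter draw the juvenile
survival needed to reach the drawn `λ_m` is solved from the characteristic
equation and spread over ages with a logarithmic-in-age curve.

The percentile and `f_a` are tuned by management strategy evaluation (MSE):
an age-structured operating model with logistic density dependence on
fertilities, an observation model with approach-specific persistent
estimation error, and an output-control rule limiting annual mortality to
the LRP.  Tuning selects the highest percentile keeping the probability of
ending below the maximum-net-productivity level `N_MNP = 0.5K` after 40
years within 5% (and below `N_collapse = 0.1K` within 2.5%).  Sensitivity
trials probe biases in maturity age, juvenile survival shape, fertility,
adult survival, starting structure, and depletion level.

All field inputs are either printed constants or emulated by the
`turtlelrp.synthetic` generators (declining nest-count index, proportional
aerial-survey series, binomial tag and size records), so the whole pipeline
runs without any data download.

## Worked example

```python
import numpy as np
from turtlelrp import (estimate_tag, summarize_abundance, lrp_distribution,
                       lrp_at_percentile, removals_to_interactions)
from turtlelrp.mse import TrialConfig, run_base_trials, tune

rng = np.random.default_rng(1)
ab = estimate_tag(rng, 2000)                      # satellite-tag pathway
s = summarize_abundance(ab)
print(f"median {s['median']:.0f} individuals, CV {s['cv_pct']:.0f}%")

lam = rng.uniform(1.04, 1.06, 2000)
lim = lrp_at_percentile(lrp_distribution(lam, ab, 0.6), 15.0, years=5.0)
print(f"five-year limit: {lim:.1f} removals "
      f"= {removals_to_interactions(lim):.1f} interactions")

t = tune(run_base_trials(TrialConfig(objective="nmnp", approach="tag",
                                     n_sims=2000, seed=1)))
print(t)
```

prints

```
median 106 individuals, CV 52%
five-year limit: 4.8 removals = 7.0 interactions
TuningResult(f_a=0.6: 15.0th, f_a=1.0: 2.5th; tolerance=0.05)
```

Reading: roughly 106 leatherbacks use the WCEEZ annually (about half of one
percent of the nesting stock's adult-equivalent footprint); holding
human-caused removals below ~4.8 turtles per five years (about 7 observed
fishery interactions at 0.68 deaths per interaction) keeps the population's
chance of slipping below its maximum-net-productivity level under 5%, and
the MSE confirms the 15th percentile with `f_a = 0.6` as the highest safe
tuning.

A full report bundle (abundance table, limit grid, risk surfaces, tuning,
rebuild times, projected-limit trajectory) comes from one call or the CLI:

```bash
turtlelrp report --seed 1 --outdir out/
turtlelrp lrp --approach tag --fa 0.6 --percentile 15 --years 5 --seed 1
turtlelrp simulate-data --kind nests --seed 1 --out nests.csv
```

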