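# darkcut

Thermal-index engineering and risk models for **dark cutting** in
grain-fed beef cattle.

A carcass is a *dark cutter* (DC) when its ultimate pH at grading is
**≥ 5.7** — the Meat Standards Australia non-compliance threshold. Dark
cutting is driven by depleted muscle glycogen at slaughter and costs
feedlots a per-kilogram price deduction; heat load in the week before
cattle leave the feedlot is one of the suspected contributors. This
package implements the full analysis pipeline for quantifying that
risk from feedlot records, carcass grading data and on-site weather
stations:

* **Thermal indices** from 15-minute weather observations — the
  temperature–humidity index
  `THI = 0.8·T_A + (RH/100)·(T_A − 14.4) + 46.4`, the two-branch cattle
  heat-load index
  `HLI_{BGT>25} = 8.62 + 0.38·RH + 1.55·BGT − 0.5·WS + e^{2.4−WS}` /
  `HLI_{BGT≤25} = 10.66 + 0.28·RH + 1.3·BGT − WS`, black globe
  temperature estimated as
  `BGT = 1.33·T_A − 2.65·√T_A + 3.21·log₁₀(SR+1) + 3.5`, and the
  **accumulated heat load** — a non-negative balance that gains
  `(HLI − 86)/M` per observation above the upper threshold and decays
  by `(HLI − 77)/M` below the lower one (`M` = observations per hour).
* **Exposure features** — for each animal, the 7 days before feedlot
  departure summarised into daily-mean/min/max/range covariates for
  T_A, RH, SR, WS, THI and HLI, total rain, hours per day at HLI ≥ 86,
  and days with ≥ 6 h at HLI ≤ 70.
* **Record handling** — NLIS-keyed merge of feedlot and carcass data,
  derivation of days on feed (DOF), average daily gain and transport
  time, DC classification, incidence tables and crude odds ratios.
* **Risk models** — the base production-factor logistic model
  `logit P(DC) = β₀ + β₁·DOF/10 + β₂·HGP + β₃·sex + abattoir + feedlot`
  and three climatic mixed-logistic models (raw weather / THI / HLI
  covariates with sex and HGP fixed and crossed random intercepts for
  feedlot and slaughter date), fitted by maximum likelihood with a
  Laplace approximation for the random effects. Coefficients are
  reported as odds ratios with Wald 95% CIs.
* **Synthetic data** — a weather/herd/outcome generator with known
  ground truth that emulates the seven-feedlot, ~140,000-head study
  population, used for end-to-end testing and parameter recovery.

## Worked example

```python
from darkcut import (estimate_bgt, compute_thi, compute_hli,
                     accumulate_heat_load)
from darkcut import simulate, models

# a hot, sunny, still afternoon observation
bgt = estimate_bgt(32.0, 850.0)          # 40.47 degC
thi = compute_thi(32.0, 45.0)            # 79.92
hli = compute_hli(bgt, 45.0, 1.5)        # 90.16  (above the 86 threshold)
ahl = accumulate_heat_load([hli] * 8)    # 8.33 after 2 h at 15-min cadence

# recover known odds ratios from a synthetic 20,000-head herd
conf = simulate.HerdSimConfig(seed=1).scaled(20_000)
recs = simulate.simulate_outcomes(simulate.simulate_herd(conf), conf)
y, X, _, _ = models.build_design(recs, models.base_model_spec())
fit = models.fit_logistic(y, X)
```

The fit prints (generating values 1.02, 2.29 and 1.14):

```
dof_per_10d  OR 1.024  95% CI [1.017, 1.031]
hgp[yes]     OR 2.444  95% CI [2.222, 2.688]
sex[M]       OR 1.096  95% CI [1.009, 1.191]
```

i.e. each extra 10 days on feed multiplies the odds of a dark cutter
by ~1.02, hormone-growth-promotant treatment by ~2.3, and steers carry
slightly higher odds than heifers — each generating value inside its
fitted 95% CI.

## Command line

```sh
darkcut simulate --out data/ --seed 1           # synthetic CSV bundle
darkcut indices  --weather data/weather_B.csv --out idx_B.csv
darkcut features --indices data/ --animals data/animals.csv --out expo.csv
darkcut merge    --animals data/animals.csv --carcasses data/carcasses.csv --out merged.csv
darkcut summarize --data merged.csv --by feedlot --denominator total
darkcut fit      --data merged.csv --model base --out basefit
darkcut run      --config run.yaml              # full pipeline
darkcut recovery --replicates 40 --n-animals 20000 --seed 0
```

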