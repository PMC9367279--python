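# Methods

## The outcome and the data model

Dark cutting (DC) is defined on ultimate pH measured at carcass
grading: `DC ⇔ pH_u ≥ 5.7`, with the boundary value non-compliant.
The unit of analysis is one animal/carcass, keyed by its NLIS
identifier. Feedlot records (induction/exit dates and weights, sex,
hormone-growth-promotant status, morbidity, exit and abattoir-arrival
times) and abattoir grading records (pH, loin temperature, hump
height) are inner-joined on NLIS; unmatched ids on either side are
counted and reported, never dropped silently. Derived fields:

* `DOF = exit date − induction date` in whole calendar days;
* `ADG = (exit weight − entry weight)/DOF`, undefined (and reported)
  at `DOF = 0`;
* transport hours from exit to abattoir arrival; when only clock
  times are available a negative difference is assumed to cross one
  midnight and gains 24 h once, and differences beyond 24 h are
  rejected as recording errors.

## Thermal indices

From 15-minute station records of ambient temperature `T_A` (°C),
relative humidity `RH` (%), solar radiation `SR` (W/m²), wind speed
`WS` (m/s) and rainfall (mm):

* `THI = 0.8·T_A + (RH/100)·(T_A − 14.4) + 46.4`. At 14.4 °C the
  humidity term vanishes; this is used as a unit test invariant.
* Black globe temperature is not measured by the stations and is
  estimated by the standard predictor
  `BGT = 1.33·T_A − 2.65·√T_A + 3.21·log₁₀(SR + 1) + 3.5`. The
  estimator is a pluggable function so measured BGT or an alternative
  model can be injected. For sub-zero winter nights, outside the
  predictor's original domain, the root is continued as
  `sign(T_A)·√|T_A|`, which keeps the function continuous through 0.
* HLI uses the nonlinear branch
  `8.62 + 0.38·RH + 1.55·BGT − 0.5·WS + e^{2.4−WS}` when
  `BGT > 25 °C` and the linear branch
  `10.66 + 0.28·RH + 1.3·BGT − WS` otherwise. The boundary value
  25 °C is assigned to the linear branch; the resulting ≈1-unit jump
  is inherent to the two-branch formulation and is documented rather
  than smoothed.
* Accumulated heat load (AHL) is a running balance starting at 0:
  each observation adds `(HLI − U)/M` when `HLI > U` (default upper
  threshold `U = 86`, where the reference animal gains heat), adds the
  negative `(HLI − L)/M` when `HLI < L` (default lower threshold
  `L = 77`, where cattle dissipate heat), is unchanged in the
  thermoneutral band, and is clamped at 0 after every step. `M` is
  the number of observations per hour (4 at 15-minute cadence), so a
  constant exceedance integrates to degree-hours. The printed
  conditional form of this rule in the source literature is
  typographically ambiguous; the implementation follows the described
  behaviour (gain above, decay below, floor at zero) and is verified
  against an independent scalar trace on thousands of random series.

Station QC masks physically implausible values
(`T_A ∈ [−20, 55] °C`, `RH ∈ [0, 100]`, `WS ∈ [0, 60] m/s`,
`SR ∈ [0, 1500] W/m²`; configurable), regularises the series onto its
expected grid, linearly interpolates gaps up to a configurable maximum
(default 6 h; rain gaps are zero-filled), and reports longer gaps
without failing — downstream exposure windows decide what coverage
they require.

## Exposure windows

Each animal's climate exposure is the half-open window
`[exit − 7 days, exit)` of its feedlot's index series. Summaries
follow heat-load convention: per station-local calendar day compute
mean, min, max and range of each variable, then average those across
the days in the window (a window-global mode is available). Rain is
summed. Two threshold durations are kept: average hours per day with
`HLI ≥ 86`, and the count of days with at least 6 h at `HLI ≤ 70`
(cold-side exposure). The hours-per-day form is the modelling
covariate because a per-hour odds ratio is only interpretable under a
duration reading; the day-count variant is computed alongside.
Windows with point coverage below 0.8 (configurable) yield a
missing-exposure flag rather than a biased summary. Whether the
window should end at the recorded exit time or the preceding midnight
is not determinable from the study description; exit time is used and
the choice is configurable.

## Risk models

**Base model** (production factors, ordinary logistic GLM):
intercept, `DOF/10`, HGP (reference *no*), sex (reference female),
abattoir (reference abattoir 1) and feedlot (reference A) fixed
effects. Under the study's supply structure — feedlots D and E both
consigning exclusively to abattoir 1 — the feedlot-E indicator is an
exact linear combination of the abattoir indicators
(`f_E = (1 − ab₂ − ab₃) − f_D`), so feedlot E is merged into the
baseline; the design builder additionally QR-checks for rank
deficiency and raises naming any aliased columns. Morbidity is
available as an optional term, off by default. The GLM is fitted by
IRLS (statsmodels, Binomial family) with Wald standard errors from
the inverse observed information; a coefficient whose magnitude on
the standardised-covariate scale exceeds 15 flags probable separation
on the result.

**Climatic models** (mixed logistic): sex and HGP fixed plus, per
model, (1) SR, WS, rain, RH, T_A; (2) SR, WS, rain, THI; (3) rain and
HLI summaries — each in mean/range/max/min (or HLI-threshold)
variants, 12 fits in all, with crossed random intercepts for feedlot
and slaughter date. Feedlots whose station data are unusable are
excluded from the climatic fits, mirroring the study's exclusions.

The mixed fits maximise the Laplace-approximate marginal likelihood,
written in-package because no installed Python library offers Laplace
ML for crossed binomial random intercepts: for fixed random-effect
standard deviations σ the joint penalised log-likelihood is maximised
over (β, u) by damped Newton iteration (coefficient-change tolerance
10⁻⁸), and the profiled objective

    ℓ_pen(β̂, û) − Σ_f q_f·log σ_f − ½·log det(Z'WZ + D)

is optimised over σ by bounded Powell search. Because profiling β at
the joint mode ignores the β-dependence of the log-determinant term,
β is then refined once against the true Laplace marginal objective
(random effects re-profiled per evaluation) — this recovers lme4
(`glmer`, nAGQ = 1) estimates to ~4 decimal places on crossed designs,
which is verified in the test suite by calling R's lme4 as an
independent oracle. The crossed-intercept cross-products `Z'WZ`,
`X'WZ` and `Z'r` are assembled from `bincount`/cell-count reductions,
so no indicator matrix is materialised and a Newton step costs
O(n·p + q²). A fitted standard deviation below 10⁻³ (variance 10⁻⁶)
is numerically zero and collapses the term, making the fit reduce
*exactly* to the plain logistic model — the degenerate-equivalence
test asserts agreement to well below 10⁻⁴. Fixed-effect standard
errors come from the fixed-effect block of the inverse joint observed
information at the mode, matching lme4's reported values. Wald
z-tests provide p-values throughout; no multiple-testing adjustment
is applied, matching the source analysis.

## Synthetic generator

The generator exists because the study's industry data are not
deposited; its defaults emulate the published study conditions.

* **Weather**: southern-hemisphere seasonality (temperature peak
  mid-January) plus a mid-afternoon-peaking diurnal cycle and AR(1)
  noise (per-step coefficient 0.95, marginal SD 1.5 °C); humidity
  anti-correlated with the diurnal temperature excursion and clamped
  to [5, 100]%; solar radiation a half-sine over a seasonally varying
  day length scaled by per-day cloud factors; gamma wind speed;
  Bernoulli wet days (p = 0.25) with exponential daily totals
  (mean 6 mm) spread over random intervals. Generated series always
  pass QC with zero masked points (a property test).
* **Herd**: seven feedlots with the published composition — sizes
  7,472/18,546/18,989/62,349/6,082/8,237/19,147; HGP usage from 0% to
  100% per feedlot (72.7% overall); male shares giving 71.5% overall;
  per-feedlot truncated-normal days on feed averaging 128 overall;
  the published feedlot→abattoir supply map (abattoir 1 processing
  48.6% of carcasses). Entry weights ~N(380, 40) kg and daily gains
  ~N(1.8, 0.25) kg/day are typical grain-fed values. Exit dates are
  uniform over the simulated year.
* **Outcomes**: `logit P(DC) = x'β_true + u_feedlot + v_date` with
  configurable true coefficients and random-intercept SDs (defaults
  0, matching the fixed-effects base model). Default `β_true` are the
  logs of the published base-model odds ratios (intercept 0.197,
  DOF-per-10 1.02, HGP 2.29, steer 1.14, abattoir 2/3 3.66/0.88,
  feedlots B–G 1.27/0.95/2.21/—/0.51/0.97, feedlot E sharing the
  baseline). Note that this printed intercept, combined with the
  other printed odds ratios at realistic covariate values, implies a
  much higher DC prevalence (~50%) than the 2.8% the study observed;
  parameter recovery is prevalence-agnostic, so the published values
  are used exactly as printed rather than re-balanced. Ultimate pH is
  drawn from truncated normals on the matching side of 5.7 (DC:
  mean 5.9, SD 0.15; compliant: mean 5.5, SD 0.06), so pH
  classification reproduces the simulated flag for every record.

The generator reproduces marginal compositions, a shared station per
feedlot and logistic outcome structure; it does not emulate lot-level
comingling, within-pen correlation beyond the random intercepts,
spatial microclimate, or the real data's inter-table inconsistencies.
Passing recovery tests therefore demonstrate estimator correctness
under the stated generative model, not robustness to those real-data
features.

## Problem sizes and numerical choices

Parameter-recovery checks run at the full study scale (~140,000
animals, single fit) and at 20,000 animals × 40 replicates for CI
coverage; the end-to-end pipeline test uses a 5,000-animal herd with
four stations at 15-minute resolution for ~380 days. Logistic IRLS
tolerance is 10⁻¹⁰; the Laplace inner Newton uses step-halving and
tolerance 10⁻⁸; Powell variance search uses σ-tolerance 10⁻³ within
bounds [0, 5]. Zero cells in crude 2×2 odds ratios receive the
Haldane–Anscombe +0.5 correction; a zero margin is reported as
undefined. Empty weather series, empty exposure overlaps and
single-level factors raise informative errors rather than degenerate
fits.

## Known limitations

* The THI source text is typographically garbled and even ambiguous
  about whether its temperature argument is dry-bulb or
  wet-bulb/dew-point; the canonical dry-bulb (ambient) form is
  implemented and the tension documented, not resolved.
* The criterion by which three of the seven stations' data were
  "deemed erroneous" in the study is unstated; QC here flags only
  range violations and gaps, and exclusion is a configuration choice.
* The per-feedlot percentage tables in the source reproduce only
  under a DC/compliant denominator while the HGP table reproduces
  under DC/total; both conventions are implemented behind an explicit
  flag (default DC/total, the standard incidence definition).
* Laplace ML for binary responses with small cluster counts carries
  the usual mild variance-component bias relative to adaptive
  quadrature; with two crossed factors, quadrature is not practical
  and Laplace matches the reference R implementation.
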