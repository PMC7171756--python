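# Methods

## Decision problem and model structure

The model compares two strategies for adults with advanced hepatocellular
carcinoma progressing under sorafenib: cabozantinib plus best supportive
care (BSC) versus BSC alone. Health is represented by three states —
stable, progressive, dead — and the cohort is tracked over 84 cycles of one
calendar month (treated as equivalent to a 30-day cycle over this horizon),
a lifetime horizon in this palliative setting.

State occupancy uses the partitioned-survival identity rather than an
independently parameterized transition matrix: the stable fraction at time
t is the progression-free survival S_PFS(t), the dead fraction is
1 − S_OS(t), and the progressive fraction is S_OS(t) − S_PFS(t). This
derives all transitions directly from the two fitted curves and is the
standard construction when only OS and PFS curves are available; an
equivalent per-cycle transition-probability view is exposed via
`cycle_transition_prob` (p = 1 − S(t+Δ)/S(t)) for inspection. If the
extrapolated curves cross in the tail, the progressive fraction is clamped
at 0, the excess assigned to dead, and a warning logged; the calibrated
base-case curves do not cross.

## Survival curves and fitting

Five families are supported in conventional parameterizations
(time in months):

| family       | S(t)                      | parameters              |
|--------------|---------------------------|-------------------------|
| exponential  | exp(−λt)                  | rate λ > 0              |
| Weibull      | exp(−(t/λ)^γ)             | scale λ > 0, shape γ > 0|
| Gompertz     | exp((b/a)(1 − e^{at}))    | shape a > 0, rate b > 0 |
| log-logistic | 1/(1 + (t/α)^β)           | scale α > 0, shape β > 0|
| lognormal    | 1 − Φ((ln t − μ)/σ)       | log-mean μ, log-sd σ > 0|

Gompertz shapes a ≤ 0 are rejected at validation because they make S(t)
level off above zero — an improper lifetime distribution for this setting.

Fitting minimizes Σ(s_i − S(t_i))² over the KM points with multi-start
local least squares (five starts per family derived from a crude curve
median; positive parameters log-transformed so every iterate stays in the
domain). Model selection ranks by SSR, then AIC, then BIC, then a fixed
family order; AIC/BIC use the least-squares Gaussian forms
n·ln(SSR/n) + 2k and n·ln(SSR/n) + k·ln(n), the only forms consistent with
reporting negative criteria from curve-level (not individual-level) data.
A flat curve (all survival values equal) is flagged degenerate and reported
at the exponential λ→0 boundary. When a family whose hazard eventually
vanishes (log-logistic, lognormal) wins for an overall-survival endpoint, a
plausibility warning is attached — a long-run hazard falling to zero is
clinically implausible for palliative OS — but the ranking is not
overridden.

## Base-case calibration

The originally fitted Weibull parameters are not in the public record, but
the published base case reports the discounted life years per state, which
constrain the model just as tightly. For each arm the package solves for a
Weibull per endpoint such that

1. the median equals the trial median (10.2/8.0 months OS, 5.2/1.9 months
   PFS), via the scale, and
2. the model's discounted state life years equal the published values
   (stable 0.646/0.341, total 1.151/0.973 years), via the shape
   (brentq root-find; at a fixed median the discounted tail mass is
   monotone in the shape, so the root is unique).

The calibrated shapes are ~1.0–1.1, consistent with the reported
monotonically-increasing-hazard footnote. With the published cost tables
this reproduces the published cost breakdown and all four headline ICERs
to better than 0.1% ($306,662 vs $306,778 per LY in Germany, etc.).

## Accrual rules

Per cycle k (start time t = k months), discount factor d(k) = 1.03^(−t/12),
no half-cycle correction (configurable; the published arithmetic is
consistent with none):

- LY: (stable + progressive)·d(k)/12; QALY additionally weighted by state
  utilities (base 0.76/0.68).
- Drug and adverse-event costs: stable occupancy only (therapy until
  progression, and AEs are treatment-driven).
- Consultation, laboratory, imaging: all alive occupancy.
- First-cycle versus subsequent-cycle monthly amounts follow the published
  bracket convention (one-time AE treatments and hospitalizations are
  loaded on cycle 1).

These rules were fixed by reconciling them against the published breakdown:
every category matches to ≤1% except the US laboratory rows, which behave
as if one extra subsequent month were counted in the source (a <0.1% effect
on totals).

Scenario switches: a therapy cap (drug cost only in the first N stable
cycles); a progression rebate crediting one monthly drug price for the
cohort mass newly entering the progressive state (the cohort translation of
"subtract a month's price for each patient who progresses") — entering mass
is the stable outflow minus that cycle's deaths attributed to stable,
deaths being split across states proportionally to start-of-cycle occupancy
since a partitioned-survival model cannot attribute deaths exactly; named
utility variant sets; and a progressive-utility decrement of 0.005 per
cycle of model time (a cohort model does not track time since progression,
so the decrement is applied on the model clock — a conservative
simplification).

## Economics

ICERs are Δcost/Δeffect (cabozantinib − BSC); when the incremental effect
is not positive the ICER is undefined and a dominance label is reported
instead. Thresholds are exact products factor × GDP per capita for factors
3/6/9. Currency conversion divides by the 2019 purchasing-power parities
(0.741 €/$, 0.689 £/$). Adverse events are screened with a Pearson
chi-squared test on all-grade incidence counts per arm without continuity
correction (at arm sizes of 470/237 the correction is immaterial); only
p < 0.05 events are costed, as the incidence-weighted sum of grade-level
treatment costs. Break-even price analysis bisects the monthly drug price
on [0, list price] to ±$1 against a threshold ICER.

## Sensitivity analyses

- **One-way**: each parameter varied over low/high (default ±25% of base;
  discount rate over its recommended 0–5% borders), bar width
  |ICER_high − ICER_low|, sorted descending. Drug price and the stable
  utility dominate, as in the source analysis.
- **Scenarios**: base case, 4-cycle therapy cap, progression rebate, three
  alternative utility sets, decreasing progressive utility.
- **PSA** (default 10,000 iterations, seeded `numpy` Generator): gamma for
  every cost parameter with shape (mean/se)², scale se²/mean; scaled beta
  on [0, 0.05] with concentration 10 (α=6, β=4, mean exactly 3%) for the
  discount rate; normal truncated to [0,1] by resampling for utilities.
  Utilities are drawn once per iteration and applied to both arms — the
  source model uses common utility inputs, and independent per-arm draws
  would manufacture spurious effectiveness reversals. Survival-curve
  uncertainty is not propagated (the stated PSA inputs are costs,
  discounting and utilities). Cost-effectiveness probability is P(NMB > 0),
  which is sign-safe when an iteration's incremental effect is ≤ 0.

The exact PSA hyperparameters of the source analysis are not in the public
record; the defaults here are se = 20% of the mean for costs and sd 0.05
for utilities, chosen as conventional magnitudes for this literature. The
acceptability probabilities are therefore qualitatively, not numerically,
comparable to the source (same ordering: Germany far likelier than the US
to reach any threshold, probabilities monotone in the factor).

## Synthetic data

The generator emulates the trial the published curves came from: Weibull
event times (default shape 1.3, giving the reported increasing hazard)
median-matched to the four printed medians, arm sizes 470/237,
administrative censoring at 24 months plus independent Uniform(0, c)
censoring with c solved so the overall censoring rate hits a 20% default,
and product-limit KM estimation sampled on a monthly grid to month 24 to
mimic digitization. Censoring is independent of the event time by
construction — dependent censoring biases the KM estimator.

What it does not emulate: the real trial's censoring pattern (unpublished),
treatment crossover, dose reductions, non-proportional hazards or any
deviation from Weibull event times. Passing round-trip tests therefore
shows the fitting machinery is correct and unbiased under the model's own
assumptions, not that the Weibull family is right for the real disease.

At n=500 the sampling noise of a KM-derived median is itself about 5% (sd),
so the parameter-recovery checks bound the mean fitted median over 10 seeds
at ±5% and individual seeds at ±15%.

## Numerical choices and problem sizes

- Calibration and break-even root-finds: brentq, xtol 1e-10 and $1.
- Optimizer: `scipy.optimize.least_squares` (TRF), xtol 1e-12, best of five
  starts; self-consistency on noiseless curves recovers parameters to 1e-6.
- Ties in model selection break by the declared family order
  (exponential, Weibull, Gompertz, log-logistic, lognormal).
- Occupancy sums to 1 by construction; conservation, monotone-dead and
  category-decomposition invariants are asserted in tests at 1e-12/1e-9.
- Default problem sizes: 84 cycles, 10,000 PSA iterations, n=500 recovery
  cohorts over 10 seeds, 20-curve grid-search oracle comparisons — the full
  suite runs in well under a minute.

## Known limitations

- The calibration targets printed, rounded life-year values; residual
  disagreement with the source ICERs (<0.1%) reflects that rounding.
- Scenario ICERs that depend on the survival curves' early shape (the
  4-cycle therapy cap) are more sensitive to the unpublished fitted
  parameters than the base case; the package's cap scenario lands ~6%
  below the source value.
- The US laboratory cost rows of the source table are internally
  inconsistent with its own accrual arithmetic (see Accrual rules).
- No expected-value-of-perfect-information analysis, no correlated PSA
  sampling, no individual-level simulation.
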