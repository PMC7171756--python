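# hcc-cea

Cost-effectiveness analysis of cabozantinib versus best supportive care
(BSC) as second-line therapy for advanced hepatocellular carcinoma (HCC),
from the perspective of the German statutory health insurance and a US
cash-price scenario.

Cabozantinib is a tyrosine kinase inhibitor approved for HCC after
sorafenib failure on the strength of the CELESTIAL trial (median overall
survival 10.2 vs 8.0 months; progression-free survival 5.2 vs 1.9 months).
This package asks what that survival gain costs per (quality-adjusted) life
year, and whether it clears willingness-to-pay thresholds set at multiples
of GDP per capita. It is aimed at health-economics researchers and
reviewers who want a transparent, fully scripted and testable version of
such a model.

## Model

A three-state partitioned-survival cohort model (stable → progressive →
dead) over a lifetime horizon of 84 monthly cycles:

- **State occupancy** is read off parametric survival curves:
  stable(t) = S_PFS(t), dead(t) = 1 − S_OS(t), progressive(t) the
  difference (clamped at 0 if the extrapolated curves cross).
- **Survival extrapolation**: exponential, Weibull, Gompertz, log-logistic
  and lognormal curves are fitted to digitized Kaplan-Meier points by
  minimizing the sum of squared residuals; families are ranked by SSR with
  least-squares AIC/BIC (n·ln(SSR/n) + penalty) as tie-breakers and a
  long-run-hazard plausibility check. Weibull wins for all four curves.
- **Accrual**: life years and QALYs (utilities 0.76 stable / 0.68
  progressive) accrue over alive occupancy; drug ($6841/month Germany,
  $21,581/month US) and adverse-event costs accrue in stable cycles;
  consultation, laboratory and imaging costs in all alive cycles; all
  discounted at 3%/year, (1.03)^(−t/12).
- **Decision rule**: ICER = ΔCost/ΔEffect against thresholds of 3/6/9 ×
  GDP per capita ($54,457 Germany, $62,853 US); probabilistic results use
  net monetary benefit, NMB = λ·ΔEffect − ΔCost.
- **Uncertainty**: one-way (tornado) analysis, published scenario set
  (4-cycle therapy cap, progression rebate, utility variants), and a
  10,000-iteration probabilistic sensitivity analysis (gamma costs,
  scaled-beta discount rate, truncated-normal utilities) with
  cost-effectiveness acceptability curves.

Because the underlying trial data are not public, the `simulate` module
generates everything the pipeline consumes: individual Weibull event times
median-matched to the trial, independent right-censoring, and product-limit
KM curves (cross-checked against lifelines).

## Worked example

```python
from hcc_cea import basecase

model = basecase.build_country_model("germany")
result = basecase.evaluate(model)
print(f"cabozantinib ${result.intervention.cost:,.0f} vs BSC ${result.comparator.cost:,.0f}")
print(f"dLY={result.d_ly:.3f}, dQALY={result.d_qaly:.3f}")
print(f"ICER {result.icer_per_ly:,.0f} $/LY, {result.icer_per_qaly:,.0f} $/QALY")
```

prints

```
cabozantinib $56,654 vs BSC $2,068
dLY=0.178, dQALY=0.145
ICER 306,662 $/LY, 375,315 $/QALY
```

— a gain of about 2.2 months of life (0.178 LY, 0.145 QALY) for roughly
$54,600 more, i.e. ~$307k per life year: far above the primary $163,371
(3 × GDP) threshold, so cabozantinib is not cost-effective at the German
reimbursement price (and ~3× further from it at US prices). The survival
inputs behind this are calibrated so the trial medians and the published
discounted state life-years are matched exactly (see `docs/methods.md`).

The same steps are available as numbered drivers under `analysis/`
(simulate → fit → base case → scenarios/tornado → PSA), each writing its
tables to `results/`, and as a CLI:

```sh
hcc-cea simulate --seed 1 --out results
hcc-cea fit --km results/km_points.csv --out results
hcc-cea run --country both --out results
hcc-cea psa --seed 1 --out results
```

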