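# pktsurv

Pre-transplant graft-survival prediction for pediatric kidney
transplantation (PKT): a discrete-time hazard modeling toolkit for
clinical epidemiologists and registry statisticians who develop, validate
and adapt survival prediction models across countries.

## What it does

Children receiving a kidney transplant face donor-selection trade-offs —
wait on dialysis for a well-matched deceased donor, or accept a
less-matched living donor pre-emptively?  A prediction model built only on
covariates known *before* transplantation can inform that decision.
`pktsurv` implements the full modeling pipeline:

* **Discrete-time hazard model.**  Follow-up is expanded to a
  person-period file (one row per at-risk month) and the monthly hazard of
  graft loss is fitted by logistic regression,

  `h(t|x) = expit(a + x'b + B(t)'g)`,

  where `x` holds recipient age, donor age, living-donor status,
  pre-emptive transplantation, re-transplant, HLA and HLA-DR mismatch
  counts and primary-disease category, and `B(t)` is a five-column natural
  cubic spline in months since transplant (interior knots at the
  0.05/0.35/0.65/0.95 quantiles of the at-risk months).  Predicted
  survival is `S(t) = prod_{m<=t} (1 - h(m|x))` — an individual monthly
  survival curve, enabling donor-scenario comparison per patient.
* **Validation.**  Subject-level 80/20 derivation/validation split,
  time-dependent ROC-AUC (cumulative cases / dynamic controls) at each
  post-transplant anniversary with bootstrap CIs, decile calibration
  against Kaplan-Meier observation, Hosmer-Lemeshow chi-square; external
  validation applies a model unchanged to a new cohort.
* **Country adaptation.**  Full coefficient re-estimation on a new
  population, country dummy variables, and inverse-size country weighting
  (`w_c = N/(K n_c)`) for pooled international models.
* **Synthetic registry.**  A generator emulating a four-country European
  PKT study population (2475 transplantations, 2005–2021) with outcomes
  from a known hazard, so every stage is testable end to end without
  access to registry microdata.  Cohort description (median [IQR] /
  % (n) tables, Kaplan-Meier, log-rank) is included.

See `docs/methods.md` for model details, defaults and limitations.

## Worked example

```python
import pktsurv as pk

# synthetic four-country registry; apply eligibility + complete-case rules
table = pk.generate_registry(pk.default_profiles(), pk.default_truth(), seed=42)
cohort, log = pk.apply_inclusion(table)

# fit a national model on the French cohort (80/20 split, seed-fixed)
fr = pk.CohortTable(df=cohort.df[cohort.df.country == "FR"].reset_index(drop=True))
model, report = pk.reestimate(fr, seed=7, n_boot=200)

# discrimination and calibration on the held-out 20%
for row in report.auc_by_year:
    if row.year in (1, 5, 10):
        print(f"year {row.year:2d}: AUC {row.auc:.2f} "
              f"(95% CI {row.ci_low:.2f}-{row.ci_high:.2f})")
print(f"Hosmer-Lemeshow: {report.hl_statistic:.2f} on {report.hl_df} df, "
      f"P = {report.hl_p:.2f}")

# donor-scenario comparison for one recipient
recipient = {"recipient_age": 10.0, "donor_age": 45.0, "living_donor": 0,
             "preemptive": 0, "retransplant": 0, "hla_mm": 4, "hla_dr_mm": 1,
             "primary_disease": "CAKUT", "country": "FR"}
curves = pk.compare_scenarios(model, recipient,
    [{"label": "matched living donor", "living_donor": 1, "hla_mm": 2, "preemptive": 1},
     {"label": "deceased donor, 4 MM", "living_donor": 0, "hla_mm": 4}],
    horizon=120)
for c in curves:
    print(f"{c.label}: S(12) = {c.survival[11]:.3f}, "
          f"S(60) = {c.survival[59]:.3f}, S(120) = {c.survival[119]:.3f}")
```

Output:

```
year  1: AUC 0.55 (95% CI 0.41-0.68)
year  5: AUC 0.64 (95% CI 0.56-0.72)
year 10: AUC 0.66 (95% CI 0.58-0.74)
Hosmer-Lemeshow: 12.00 on 8 df, P = 0.15
matched living donor: S(12) = 0.976, S(60) = 0.946, S(120) = 0.911
deceased donor, 4 MM: S(12) = 0.944, S(60) = 0.874, S(120) = 0.798
```

Reading: on the held-out fifth of the simulated French cohort the model
ranks 10-year graft loss with AUC 0.66 (the simulated effect sizes bound
attainable discrimination), calibration is not rejected (P = .15), and for
this 10-year-old recipient a well-matched pre-emptive living donation is
predicted to improve 10-year graft survival by about 11 percentage points
over a 4-mismatch deceased donor.

A `pktsurv` console script exposes the same pipeline
(`simulate`, `filter`, `fit`, `predict`, `validate`, `adapt`,
`international`, `report`, `run`); try `pktsurv --help`.

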