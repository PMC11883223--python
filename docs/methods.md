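# Methods

## The model

`pktsurv` predicts graft survival after pediatric kidney transplantation
(PKT) from covariates known *before* the transplant: recipient age, donor
age, living- vs deceased-donor, pre-emptive transplantation, re-transplant,
HLA and HLA-DR mismatch counts, and the primary disease that caused kidney
failure (eight categories, reference CAKUT).

Follow-up is discretized into months.  Each transplantation contributes one
row per at-risk month to a *person-period file*; the row outcome is 1 only
in the month of graft loss (return to dialysis or re-transplantation).
Death with a functioning graft and administrative end of follow-up are
censoring: the final row keeps outcome 0.  The monthly hazard is

    h(t | x) = expit( a + x'b + B(t)'g ),

where `B(t)` is a five-column natural cubic spline in the month index `t`,
so the baseline hazard varies smoothly with time since transplant and the
relative effect of time is estimated rather than assumed constant.
Predicted survival is the cumulative product `S(t) = prod_{m<=t} (1-h(m|x))`,
which yields an individual monthly survival curve per covariate profile and
supports donor-scenario comparison for a fixed recipient
(`compare_scenarios` permits overriding donor-side fields only).

### Spline basis

Interior knots sit at the 0.05/0.35/0.65/0.95 quantiles of the
person-period month column (all at-risk months, not event months, so the
basis covers the whole follow-up distribution); boundary knots at the
observed minimum and maximum.  Four interior knots give five time columns.
The basis is the truncated-power restricted-cubic form: identity column
plus four restricted cubic terms scaled by the squared boundary span.  It
is C2 everywhere and exactly linear beyond the boundary knots, so
predictions extrapolate linearly (on the log-odds scale) past the observed
follow-up.  The tests verify span-equivalence against an independent
natural-spline implementation.

### Fitting

Maximum likelihood by Newton-Raphson with step halving on the row-weighted
Bernoulli log-likelihood; convergence when the relative log-likelihood
change is below 1e-10, at most 100 iterations.  Reference categories are
fixed (disease: CAKUT; country: largest cohort, alphabetical tie-break) so
coefficients are reproducible.  Complete separation (diverging
coefficients, |log-odds| > 30) raises an error unless a ridge penalty is
set; `penalty=1e-6` is the documented fallback for tiny fixtures, with the
intercept left unpenalized.  The default era term is off for 2005-2021
cohorts (a single era); decade dummies (`era_levels`) reproduce the older
multi-era design when wanted.  Continuous covariates enter linearly in
years; mismatch counts as integers; no centering or scaling.

## Validation

* **Split** — subject-level simple random 80/20, derivation size
  `ceil(0.8 n)`, deterministic given the seed.
* **Time-dependent AUC** — cumulative-cases / dynamic-controls at each
  anniversary (month 12t): cases lost the graft at or before 12t; controls
  are event-free and followed through month 12t (a subject censored exactly
  at 12t without an event is a control, since its status at the anniversary
  is known); subjects censored strictly earlier are excluded.  AUC is
  pairwise concordance of the risk score `1 - S(12t)` with half-credit
  ties, computed by midranks; a brute-force pair count is the test oracle.
  Confidence intervals are percentile bootstrap over subjects (default
  2000 resamples, seeded).  IPCW-weighted estimators are a possible
  variant, not implemented.  AUC > 0.7 is annotated as "good".
* **Calibration** — deciles by rank of predicted survival (stable order on
  ties), mean predicted vs Kaplan-Meier observed survival at the horizon
  (default 60 months).
* **Hosmer-Lemeshow** — deciles of predicted event probability by the
  horizon, statistic `sum (O-E)^2/E` over groups and both outcomes, df =
  groups - 2, restricted to subjects whose status at the horizon is
  observable.  Zero-expected cells merge into a neighbor (df shrinks, merge
  counted).  Caveat: the `groups - 2` reference is derived for a model
  evaluated on its own estimation sample; for predictions imported from
  elsewhere the statistic is closer to chi-square(groups) and the test
  over-rejects (we measure ~0.13 instead of 0.05 under the null).  The
  null-calibration test therefore uses the development-sample setting.
* **External validation** — the fitted model applied unchanged (no refit);
  unknown category levels fail loudly, listing the offending levels.

## Country adaptation

Re-estimation refits *all* coefficients on the new cohort with identical
predictors and methodology, including re-placing the knots on the new
derivation person-period file.  The pooled international model adds
one-hot country dummies (reference = largest cohort) and inverse-size
country weights `w_c = N/(K n_c)`, computed on the derivation cohort after
the split; weights multiply each subject's person-period rows in the
likelihood, so total weight equals the record count and equal-sized
cohorts reduce to unweighted fitting.  No standard errors are reported
under weighting; interest is in point prediction and validation metrics.

## Synthetic registry

The generator emulates the *structure* of a four-country European PKT
study population (2475 transplantations: 273 Dutch, 1622 French, 356
German, 224 other; 2005-2021, the "other" cohort 2011-2021): per-country
living-donor, pre-emptive and re-transplant fractions taken from the
published counts; truncated normal/log-normal age distributions matched by
eye to published medians/IQRs (the French deceased-donor pool is young,
log-normal median 15 y; Dutch donors are living-donor-dominated and
older); categorical HLA/HLA-DR mismatch and eight-category disease mixes.

Outcomes are drawn from a known discrete-time hazard.  The default time
effect was obtained once by least-squares projection of a plausible
declining monthly hazard (0.55%/month in month 1 falling to 0.13%/month
after year 5; ~18% cumulative loss at 10 years for a covariate-neutral
profile, ~20% on the realized mix) onto the spline basis.  Default effect
sizes (log-odds per unit, monthly scale): living donor -0.35, pre-emptive
-0.25, re-transplant +0.45, HLA mismatch +0.08/unit, HLA-DR +0.12/unit,
donor age -0.010/y, recipient age +0.02/y, glomerulopathy +0.30,
microvascular thrombopathy +0.40, ciliopathy -0.10.

Censoring: loss to follow-up is geometric (0.001/month — registries are
near-mandatory, calibrated so simulated follow-up medians match the
published 76 [37-133] months); death with a functioning graft is an
independent 0.0005/month and is treated as graft survival; administrative
censoring at `min(admin_horizon, 12*(study_end_year - transplant_year))`
(study end 2022), or at a fixed horizon when `study_end_year=None`.
Within a month, failure takes precedence over death, death over dropout,
dropout over administrative end.  Months are 1-based.

What the generator does *not* emulate: waitlist and allocation dynamics,
center effects within countries, covariate dependence (covariates are
drawn independently given country), era trends in the hazard, and
informative censoring.  Passing tests therefore demonstrate correctness of
the estimation and validation machinery under a known data law — not
clinical performance on real registry data, which is unavailable for
redistribution.

## Problem sizes and numerical choices

Test and acceptance runs use: parameter recovery at 3000 subjects /
120-month horizon / 20 seeds (estimates are unbiased; per-coefficient
sampling SE at ~600 events is ~0.12-0.15 for the rarer binary covariates);
Kaplan-Meier vs truth at 10 000 subjects (tolerance 0.02); decile
self-calibration at 5000 subjects (tolerance 0.03 at month 60);
Hosmer-Lemeshow null calibration at 600 subjects x 200 replicates;
two-country heterogeneity designs at 900 subjects per country x 20 seeds
(the second country flips the donor-age and recipient-age coefficient
signs and shifts the baseline +0.3, mirroring the qualitative
cross-country heterogeneity the method is meant to expose).  Grid-search
likelihood oracles refine exhaustively to a 1e-3 spacing; survival
identities are checked to 1e-12.

Known limitations: no competing-risk treatment of death (censoring by
design); no IPCW in the AUC; bootstrap CIs are percentile (no BCa); the
ridge fallback is a numerical device, not a tuned regularizer; predictions
far beyond the boundary knot rely on log-odds-linear extrapolation.

## Cohort CSV column dictionary

One row per transplantation; UTF-8, comma-separated, header row, '.'
decimal point, empty cell = missing.

| column | type | meaning |
|---|---|---|
| subject_id | str | unique identifier |
| country | str | cohort label (NL/FR/DE/OTHER in the default generator) |
| transplant_year | int | calendar year of surgery |
| recipient_age | float, years | age at surgery (< 19 for eligibility) |
| donor_age | float, years | donor age |
| living_donor | 0/1 | living vs deceased donor |
| preemptive | 0/1 | transplant before dialysis initiation |
| retransplant | 0/1 | not the first graft |
| hla_mm | int 0-6 | HLA mismatch count |
| hla_dr_mm | int 0-2 | HLA-DR mismatch count |
| primary_disease | str | one of the eight categories (see `DISEASE_CATEGORIES`) |
| multi_organ | 0/1 | combined-organ transplantation (excluded) |
| in_europe | 0/1 | performed in Europe (exclusion criterion) |
| follow_up_months | int >= 1 | observed follow-up |
| graft_loss | 0/1 | dialysis return / re-transplant need |
| death_with_function | 0/1 | death with functioning graft (censoring) |
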