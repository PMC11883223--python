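"""Model updating for new populations.

A prediction model rarely transports across countries unchanged: case mix,
allocation policy and clinical practice differ.  The updating strategy here
is full coefficient re-estimation on the new cohort with the *identical*
predictor set and methodology (person-period expansion, quantile knots,
80/20 split), plus two devices for pooled international fits:

* country dummy variables (reference = largest cohort), absorbing
  country-level baseline differences;
* inverse-size country weights ``w_c = N / (K * n_c)``, which equalize each
  country's total influence on the likelihood while preserving the overall
  effective sample size (weights sum to the record count).

Weights multiply each subject's person-period rows in the log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .hazard import FittedHazardModel, ModelSpec, expand_person_period, fit_hazard
from .validation import ValidationReport, internal_validate, split_cohort

__all__ = [
    "WeightScheme",
    "country_weights",
    "add_country_dummies",
    "reestimate",
    "build_international_model",
]


@dataclass(frozen=True)
class WeightScheme:
    """Per-country record weights normalized so total weight = total count."""

    weights: dict  # country -> weight

    def per_record(self, cohort: CohortTable) -> pd.Series:
        return cohort.df["country"].map(self.weights).astype(float)


def country_weights(cohort: CohortTable) -> WeightScheme:
    """Inverse-size weights w_c = N / (K * n_c): smaller cohorts count more."""
    counts = cohort.df["country"].value_counts()
    if counts.empty:
        raise ValueError("cohort has no countries")
    n_total, k = int(counts.sum()), len(counts)
    return WeightScheme(weights={c: n_total / (k * n_c) for c, n_c in counts.items()})


def _largest_country(cohort: CohortTable) -> str:
    counts = cohort.df["country"].value_counts()
    # deterministic tie-break: alphabetical among equally largest
    top = counts[counts == counts.max()].index
    return sorted(top)[0]


def add_country_dummies(spec: ModelSpec, cohort: CohortTable) -> ModelSpec:
    """Add one-hot country indicators, reference = largest cohort."""
    levels = sorted(cohort.df["country"].unique())
    if len(levels) < 2:
        warnings.warn("single-country cohort: country dummies are a no-op", UserWarning)
        return spec
    return replace(spec, country_levels=tuple(levels), country_ref=_largest_country(cohort))


def reestimate(cohort: CohortTable, seed: int, spec: ModelSpec = ModelSpec(),
               years=tuple(range(1, 16)), horizon: int = 60, n_boot: int = 2000,
               label: str | None = None):
    """Re-fit all coefficients on a new cohort with the original methodology.

    Splits 80/20, re-places spline knots on the new derivation person-period
    months, fits the identical predictor set, and internally validates on
    the held-out 20%.  Returns ``(FittedHazardModel, ValidationReport)``.
    Pure function: inputs are not mutated.
    """
    derivation, valid = split_cohort(cohort, fraction=0.8, seed=seed)
    pp = expand_person_period(derivation)
    model = fit_hazard(pp, spec)
    report = internal_validate(model, valid, years=years, horizon=horizon,
                               n_boot=n_boot, seed=seed,
                               label=label or f"internal[{cohort.source}]")
    return model, report


def build_international_model(cohort: CohortTable, seed: int,
                              spec: ModelSpec = ModelSpec(),
                              years=tuple(range(1, 16)), horizon: int = 60,
                              n_boot: int = 2000, weighted: bool = True):
    """Pooled multi-country model: dummies + inverse-size weights + 80/20 fit.

    Weights are computed on the derivation cohort (post-split).  Returns
    ``(model, report, weight_scheme)``.
    """
    if cohort.df["country"].nunique() < 2:
        raise ValueError("international model needs at least 2 countries")
    derivation, valid = split_cohort(cohort, fraction=0.8, seed=seed)
    spec = add_country_dummies(spec, derivation)
    scheme = country_weights(derivation)
    w = scheme.per_record(derivation) if weighted else None
    pp = expand_person_period(derivation, weights=w)
    model = fit_hazard(pp, spec)
    report = internal_validate(model, valid, years=years, horizon=horizon,
                               n_boot=n_boot, seed=seed, label="internal[international]")
    return model, report, scheme
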