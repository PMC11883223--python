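"""Registry-style cohort I/O and eligibility filtering.

A cohort is one row per transplantation with pre-transplant covariates,
country, era, follow-up and outcome flags.  Files are plain CSV (UTF-8,
comma separator, header row, '.' decimal point); missing values are empty
cells, never sentinel numerics.

Eligibility mirrors the validation-study design: transplantations performed
2005-2021 in recipients under 19 years of age, single-organ, within Europe,
complete-case on every model covariate and outcome field.  Exclusions are
logged per reason, applied in that fixed order (first matching rule wins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DISEASE_CATEGORIES",
    "COLUMNS",
    "COVARIATE_FIELDS",
    "CohortTable",
    "CohortError",
    "read_cohort",
    "write_cohort",
    "apply_inclusion",
]

#: Primary-disease categories (reference category first).
DISEASE_CATEGORIES = (
    "CAKUT",
    "ciliopathy",
    "glomerulopathy",
    "tubulopathy",
    "microvascular_thrombopathy",
    "hereditary_nephropathy",
    "metabolic_nephropathy",
    "other",
)

#: Fixed CSV column order.
COLUMNS = (
    "subject_id",
    "country",
    "transplant_year",
    "recipient_age",
    "donor_age",
    "living_donor",
    "preemptive",
    "retransplant",
    "hla_mm",
    "hla_dr_mm",
    "primary_disease",
    "multi_organ",
    "in_europe",
    "follow_up_months",
    "graft_loss",
    "death_with_function",
)

#: Model covariates + outcome fields checked by the complete-case rule.
COVARIATE_FIELDS = (
    "recipient_age",
    "donor_age",
    "living_donor",
    "preemptive",
    "retransplant",
    "hla_mm",
    "hla_dr_mm",
    "primary_disease",
)
_OUTCOME_FIELDS = ("follow_up_months", "graft_loss", "death_with_function")

_FLAG_FIELDS = ("living_donor", "preemptive", "retransplant", "multi_organ", "in_europe", "graft_loss", "death_with_function")

ELIGIBLE_YEARS = (2005, 2021)
MAX_RECIPIENT_AGE = 19.0  # strictly below; "under 19 years of age" at surgery


class CohortError(ValueError):
    """Malformed cohort file or invalid record content."""


@dataclass
class CohortTable:
    """Ordered collection of transplant records plus provenance metadata."""

    df: pd.DataFrame
    source: str | None = None
    filter_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise CohortError(f"cohort is missing columns: {missing}")
        ids = self.df["subject_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise CohortError(f"duplicate subject_id: {dup!r}")
        self.df = self.df.loc[:, list(COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def countries(self) -> pd.Series:
        return self.df["country"]


def _validate(df: pd.DataFrame, source: str) -> None:
    disease = df["primary_disease"].dropna()
    bad = set(disease) - set(DISEASE_CATEGORIES)
    if bad:
        raise CohortError(f"{source}: unknown primary_disease categories {sorted(bad)}")
    for col in _FLAG_FIELDS:
        vals = df[col].dropna()
        if not vals.isin([0, 1, 0.0, 1.0]).all():
            raise CohortError(f"{source}: column {col} must be 0/1")
    fum = df["follow_up_months"].dropna()
    if (fum < 1).any():
        raise CohortError(f"{source}: follow_up_months must be >= 1")
    both = (df["graft_loss"] == 1) & (df["death_with_function"] == 1)
    if both.any():
        raise CohortError(f"{source}: graft_loss and death_with_function both set")
    if (df["recipient_age"].dropna() < 0).any():
        raise CohortError(f"{source}: negative recipient_age")


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV into a typed table; empty cells stay missing (NaN)."""
    try:
        df = pd.read_csv(path, dtype={"subject_id": str, "country": str, "primary_disease": str})
    except (pd.errors.ParserError, ValueError) as exc:
        raise CohortError(f"{path}: malformed CSV ({exc})") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing columns {missing}")
    for col in COLUMNS:
        if col in ("subject_id", "country", "primary_disease"):
            continue
        try:
            df[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            line = int(bad.index[0]) + 2 if len(bad) else "?"
            raise CohortError(f"{path}: non-numeric value in column {col!r} at line {line}") from exc
    _validate(df, str(path))
    return CohortTable(df=df, source=str(path))


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort CSV with the fixed column order; flags as 0/1 integers."""
    df = cohort.df.loc[:, list(COLUMNS)].copy()
    for col in _FLAG_FIELDS + ("transplant_year", "hla_mm", "hla_dr_mm", "follow_up_months"):
        if df[col].notna().all():
            df[col] = df[col].astype(np.int64)
    df.to_csv(path, index=False)


def apply_inclusion(cohort: CohortTable) -> tuple[CohortTable, dict]:
    """Apply eligibility rules; return the retained cohort and an exclusion log.

    Rules, in order (first match assigns the reason):

    1. ``year`` — transplant_year outside 2005-2021 (or missing);
    2. ``age`` — recipient_age >= 19 years at transplantation;
    3. ``multi_organ`` — combined-organ transplantation;
    4. ``outside_europe`` — performed outside Europe;
    5. ``incomplete`` — any missing model covariate or outcome field
       (complete-case rule).

    The log maps reason -> count and carries n_input / n_retained; retained
    plus excluded always equals the input count.  Idempotent.
    """
    df = cohort.df
    year = df["transplant_year"]
    reasons = pd.Series(pd.NA, index=df.index, dtype="object")

    excl_year = year.isna() | (year < ELIGIBLE_YEARS[0]) | (year > ELIGIBLE_YEARS[1])
    excl_age = df["recipient_age"].isna() | (df["recipient_age"] >= MAX_RECIPIENT_AGE)
    excl_multi = df["multi_organ"].isna() | (df["multi_organ"] == 1)
    excl_geo = df["in_europe"].isna() | (df["in_europe"] == 0)
    excl_miss = df[list(COVARIATE_FIELDS) + list(_OUTCOME_FIELDS)].isna().any(axis=1)

    for reason, mask in [
        ("year", excl_year),
        ("age", excl_age),
        ("multi_organ", excl_multi),
        ("outside_europe", excl_geo),
        ("incomplete", excl_miss),
    ]:
        reasons[mask & reasons.isna()] = reason

    keep = reasons.isna()
    counts = reasons.value_counts().to_dict()
    log = {
        "n_input": int(len(df)),
        "n_retained": int(keep.sum()),
        "excluded": {r: int(counts.get(r, 0)) for r in
                     ("year", "age", "multi_organ", "outside_europe", "incomplete")
                     if counts.get(r, 0)},
    }
    out = CohortTable(df=df[keep].reset_index(drop=True),
                      source=cohort.source,
                      filter_log=cohort.filter_log + [log])
    return out, log
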