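"""Discrimination and calibration assessment of fitted hazard models.

Internal validation follows the derivation/validation design: a subject-level
80/20 random split, time-dependent ROC-AUC at each post-transplant
anniversary, decile calibration against Kaplan-Meier observed survival, and
the Hosmer-Lemeshow chi-square.  External validation applies a fitted model
unchanged to a new cohort and produces the same report.

Time-dependent AUC uses the cumulative-cases / dynamic-controls definition
at year t (month 12t): cases experienced graft loss at or before month 12t;
controls are event-free and still under observation at month 12t; subjects
censored strictly earlier without an event are excluded.  The AUC is the
concordance of the risk score 1 - S(12t) over all case-control pairs, ties
counted one half; confidence intervals by seeded subject-level percentile
bootstrap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .cohort import CohortTable
from .hazard import FittedHazardModel, predict_survival_matrix

__all__ = [
    "YearAUC",
    "ValidationReport",
    "split_cohort",
    "year_auc",
    "calibration_table",
    "hosmer_lemeshow",
    "internal_validate",
    "external_validate",
]

GOOD_AUC = 0.7  # annotation threshold for "good" discrimination


def split_cohort(cohort: CohortTable, fraction: float = 0.8, seed: int = 0):
    """Random subject-level derivation/validation split (ceil(f*n) derivation)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie strictly in (0, 1), got {fraction}")
    n = len(cohort)
    if n < 10:
        raise ValueError("cohort too small to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_der = math.ceil(fraction * n)
    der_idx = np.sort(order[:n_der])
    val_idx = np.sort(order[n_der:])
    make = lambda idx, tag: CohortTable(
        df=cohort.df.iloc[idx].reset_index(drop=True),
        source=f"{cohort.source}[{tag}]", filter_log=list(cohort.filter_log))
    return make(der_idx, "derivation"), make(val_idx, "validation")


def _case_control(follow_up, event, month: int):
    follow_up = np.asarray(follow_up)
    event = np.asarray(event).astype(bool)
    cases = event & (follow_up <= month)
    controls = ~cases & (follow_up >= month)
    return cases, controls


def _concordance(risk, cases, controls) -> float:
    # rank formulation of pairwise concordance with half-credit ties
    r = stats.rankdata(np.concatenate([risk[cases], risk[controls]]))
    n1, n0 = cases.sum(), controls.sum()
    return float((r[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass(frozen=True)
class YearAUC:
    year: int
    auc: float | None
    ci_low: float | None
    ci_high: float | None
    n_cases: int
    n_controls: int

    @property
    def good(self) -> bool | None:
        return None if self.auc is None else self.auc > GOOD_AUC


def year_auc(surv_at_t, follow_up, event, year: int,
             n_boot: int = 2000, seed: int = 0) -> YearAUC:
    """Cumulative/dynamic AUC at post-transplant year ``year``.

    ``surv_at_t`` is the predicted survival probability at month 12*year per
    subject; the risk score is its complement.  Returns AUC None when there
    is no case or no control at that year.
    """
    month = 12 * year
    risk = 1.0 - np.asarray(surv_at_t, dtype=float)
    cases, controls = _case_control(follow_up, event, month)
    n1, n0 = int(cases.sum()), int(controls.sum())
    if n1 == 0 or n0 == 0:
        return YearAUC(year, None, None, None, n1, n0)
    auc = _concordance(risk, cases, controls)
    lo = hi = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        eligible = np.flatnonzero(cases | controls)
        fu = np.asarray(follow_up)[eligible]
        ev = np.asarray(event)[eligible]
        rk = risk[eligible]
        cs = cases[eligible]
        vals = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(eligible), len(eligible))
            c = cs[idx]
            if c.any() and (~c).any():
                vals.append(_concordance(rk[idx], c, ~c))
        lo, hi = (float(v) for v in np.percentile(vals, [2.5, 97.5]))
    return YearAUC(year, float(auc), lo, hi, n1, n0)


def calibration_table(surv_at_horizon, follow_up, event, horizon: int,
                      groups: int = 10) -> pd.DataFrame:
    """Decile calibration: mean predicted vs Kaplan-Meier observed survival.

    Subjects are ranked by predicted survival (stable order breaks ties) and
    cut into ``groups`` near-equal bins; within each bin the observed value
    is the Kaplan-Meier estimate at ``horizon`` months.
    """
    pred = np.asarray(surv_at_horizon, dtype=float)
    n = len(pred)
    if groups > n:
        raise ValueError(f"groups={groups} exceeds number of subjects {n}")
    order = np.argsort(pred, kind="stable")
    rows = []
    for b, idx in enumerate(np.array_split(order, groups)):
        kmf = KaplanMeierFitter()
        kmf.fit(np.asarray(follow_up)[idx], np.asarray(event)[idx])
        rows.append({
            "bin": b + 1,
            "n": int(len(idx)),
            "mean_predicted": float(pred[idx].mean()),
            "observed_km": float(kmf.predict(horizon)),
        })
    return pd.DataFrame(rows)


def hosmer_lemeshow(p_event, observed, groups: int = 10):
    """Hosmer-Lemeshow chi-square over deciles of predicted event probability.

    ``statistic = sum over groups and both outcomes of (O - E)^2 / E``;
    df = effective groups - 2.  A group with an expected cell of zero is
    merged with its neighbor (df shrinks; merges reported).

    Returns ``(statistic, df, p_value, n_merged)``.
    """
    p = np.asarray(p_event, dtype=float)
    y = np.asarray(observed, dtype=float)
    n = len(p)
    if n < groups:
        raise ValueError(f"need at least {groups} subjects, got {n}")
    order = np.argsort(p, kind="stable")
    bins = [list(idx) for idx in np.array_split(order, groups)]
    # merge bins whose expected event or non-event count is zero
    merged = 0
    i = 0
    while i < len(bins):
        e1 = p[bins[i]].sum()
        e0 = len(bins[i]) - e1
        if (e1 == 0.0 or e0 == 0.0) and len(bins) > 1:
            j = i + 1 if i + 1 < len(bins) else i - 1
            bins[j] = bins[i] + bins[j]
            del bins[i]
            merged += 1
            i = 0  # re-scan: the merge can still leave a zero cell
        else:
            i += 1
    stat = 0.0
    for idx in bins:
        e1 = p[idx].sum()
        e0 = len(idx) - e1
        o1 = y[idx].sum()
        o0 = len(idx) - o1
        stat += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
    df = max(len(bins) - 2, 1)
    return float(stat), int(df), float(stats.chi2.sf(stat, df)), merged


@dataclass
class ValidationReport:
    """Per-year discrimination plus calibration and Hosmer-Lemeshow at a horizon."""

    cohort_label: str
    horizon: int
    auc_by_year: list  # list[YearAUC]
    calibration: pd.DataFrame
    hl_statistic: float
    hl_df: int
    hl_p: float
    n_subjects: int

    def to_dict(self) -> dict:
        return {
            "cohort_label": self.cohort_label,
            "horizon": self.horizon,
            "auc_by_year": [vars(a) | {"good": a.good} for a in self.auc_by_year],
            "calibration": self.calibration.to_dict(orient="records"),
            "hl": {"statistic": self.hl_statistic, "df": self.hl_df, "p": self.hl_p},
            "n_subjects": self.n_subjects,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationReport":
        aucs = [YearAUC(a["year"], a["auc"], a["ci_low"], a["ci_high"],
                        a["n_cases"], a["n_controls"]) for a in d["auc_by_year"]]
        return cls(cohort_label=d["cohort_label"], horizon=d["horizon"],
                   auc_by_year=aucs, calibration=pd.DataFrame(d["calibration"]),
                   hl_statistic=d["hl"]["statistic"], hl_df=d["hl"]["df"],
                   hl_p=d["hl"]["p"], n_subjects=d["n_subjects"])

    @classmethod
    def from_json(cls, s: str) -> "ValidationReport":
        return cls.from_dict(json.loads(s))


def _known_status_at(follow_up, event, horizon):
    """Subjects whose event-by-horizon status is observable."""
    cases, controls = _case_control(follow_up, event, horizon)
    return cases | controls, cases


def internal_validate(model: FittedHazardModel, cohort: CohortTable,
                      years=tuple(range(1, 16)), horizon: int = 60,
                      groups: int = 10, n_boot: int = 2000, seed: int = 0,
                      label: str = "internal") -> ValidationReport:
    """Score a held-out cohort with a fitted model and assemble the report.

    AUC is computed per anniversary year; the calibration table and the
    Hosmer-Lemeshow test use predicted event probability by ``horizon``
    months against observed status (subjects with unknown status at the
    horizon - censored earlier without an event - are excluded from HL).
    """
    df = cohort.df
    max_month = max(12 * max(years), horizon)
    S = predict_survival_matrix(model, df, max_month)
    fu = df["follow_up_months"].to_numpy(int)
    ev = df["graft_loss"].to_numpy(int)
    ss = np.random.SeedSequence(seed).generate_state(len(years)) & 0x7FFFFFFF
    aucs = [year_auc(S[:, 12 * yr - 1], fu, ev, yr, n_boot=n_boot, seed=int(s))
            for yr, s in zip(years, ss)]
    cal = calibration_table(S[:, horizon - 1], fu, ev, horizon, groups=groups)
    known, is_case = _known_status_at(fu, ev, horizon)
    hl_stat, hl_df, hl_p, _ = hosmer_lemeshow(
        1.0 - S[known, horizon - 1], is_case[known], groups=groups)
    return ValidationReport(cohort_label=label, horizon=horizon, auc_by_year=aucs,
                            calibration=cal, hl_statistic=hl_stat, hl_df=hl_df,
                            hl_p=hl_p, n_subjects=len(df))


def external_validate(model: FittedHazardModel, cohort: CohortTable,
                      years=tuple(range(1, 16)), horizon: int = 60,
                      groups: int = 10, n_boot: int = 2000, seed: int = 0,
                      label: str = "external") -> ValidationReport:
    """Apply a fitted model *unchanged* to a new cohort and report performance.

    Category levels of the external cohort must be mappable onto the model's
    encoding; unknown disease or country levels raise a validation error
    listing the offending levels (via the design builder).
    """
    return internal_validate(model, cohort, years=years, horizon=horizon,
                             groups=groups, n_boot=n_boot, seed=seed, label=label)
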