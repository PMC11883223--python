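"""Cohort description tables and survival comparison.

Produces registry-paper style baseline tables (median [IQR] for continuous
variables with Kruskal-Wallis across cohorts; % (n) for categorical with
chi-squared homogeneity tests) and Kaplan-Meier / log-rank graft-survival
comparisons between cohorts.  Percentages are displayed round-half-up;
medians and quartiles round to integers for ages and months.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .cohort import DISEASE_CATEGORIES, CohortTable

__all__ = ["SummaryTable", "KMEstimate", "pct", "fmt_pct_n", "fmt_median_iqr",
           "summarize_cohorts", "km_estimate", "log_rank"]


def pct(count: int, n: int) -> int:
    """Round-half-up percentage, as printed in registry baseline tables."""
    if n <= 0:
        raise ValueError("cohort size must be positive")
    return int((Decimal(count) * 100 / Decimal(n)).quantize(Decimal(1), rounding=ROUND_HALF_UP))


def fmt_pct_n(count: int, n: int) -> str:
    return f"{pct(count, n)} ({count})"


def fmt_median_iqr(values) -> str:
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    r = lambda x: int(Decimal(float(x)).quantize(Decimal(1), rounding=ROUND_HALF_UP))
    return f"{r(med)} [{r(q1)}–{r(q3)}]"


_CONTINUOUS = ("follow_up_months", "recipient_age", "donor_age", "hla_mm")
_BINARY = ("graft_loss", "living_donor", "preemptive", "retransplant")


@dataclass
class SummaryTable:
    """Per-cohort baseline characteristics with overall homogeneity tests."""

    df: pd.DataFrame  # one row per variable; one column per cohort + test info

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def _require(dfs: dict, column: str) -> None:
    for label, df in dfs.items():
        if column not in df.columns:
            raise KeyError(f"variable {column!r} absent from cohort {label!r}")


def summarize_cohorts(cohorts: dict) -> SummaryTable:
    """Baseline table across labeled cohorts (CohortTable or DataFrame values).

    Continuous variables: ``median [Q1-Q3]`` + Kruskal-Wallis (tie-corrected).
    Binary/categorical variables: ``pct (n)`` + chi-squared without continuity
    correction; disease categories are tested one row at a time (category vs
    rest), mirroring per-row p-values of registry baseline tables.  With a
    single cohort the tests are omitted.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    dfs = {lab: (c.df if isinstance(c, CohortTable) else c) for lab, c in cohorts.items()}
    labels = list(dfs)
    multi = len(labels) > 1
    rows = []

    def add(variable, summaries, test, stat, p):
        row = {"variable": variable, **dict(zip(labels, summaries))}
        row.update({"test": test, "statistic": stat, "p": p})
        rows.append(row)

    for var in _CONTINUOUS:
        _require(dfs, var)
        groups = [dfs[lab][var].dropna().to_numpy(float) for lab in labels]
        stat = p = None
        if multi:
            stat, p = stats.kruskal(*groups)
        add(var, [fmt_median_iqr(g) for g in groups],
            "Kruskal-Wallis" if multi else None, stat, p)

    def chi2_binary(masks):
        table = np.array([[m.sum(), (~m).sum()] for m in masks])
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return stat, p

    for var in _BINARY:
        _require(dfs, var)
        masks = [dfs[lab][var].dropna().to_numpy(float) == 1 for lab in labels]
        stat = p = None
        if multi:
            stat, p = chi2_binary(masks)
        add(var, [fmt_pct_n(int(m.sum()), len(m)) for m in masks],
            "chi-squared" if multi else None, stat, p)

    _require(dfs, "primary_disease")
    for cat in DISEASE_CATEGORIES:
        masks = [dfs[lab]["primary_disease"].dropna() == cat for lab in labels]
        stat = p = None
        if multi:
            stat, p = chi2_binary([m.to_numpy() for m in masks])
        add(f"disease:{cat}", [fmt_pct_n(int(m.sum()), len(m)) for m in masks],
            "chi-squared" if multi else None, stat, p)

    return SummaryTable(df=pd.DataFrame(rows))


@dataclass
class KMEstimate:
    """Product-limit graft-survival estimate for one group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    label: str | None = None

    def at(self, t: float) -> float:
        """S(t): survival at the last event time <= t (1.0 before the first)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(follow_up, event, group=None) -> list[KMEstimate]:
    """Kaplan-Meier estimate(s); death with functioning graft enters as event=0."""
    follow_up = np.asarray(follow_up)
    if (follow_up < 1).any():
        raise ValueError("follow-up must be >= 1 month")
    event = np.asarray(event)
    if group is None:
        group = np.zeros(len(follow_up))
        labels = [None]
    else:
        group = np.asarray(group)
        labels = list(pd.unique(group))
    out = []
    for lab in labels:
        m = group == (lab if lab is not None else 0)
        kmf = KaplanMeierFitter()
        kmf.fit(follow_up[m], event[m])
        tab = kmf.event_table
        sf = kmf.survival_function_
        out.append(KMEstimate(times=sf.index.to_numpy(float),
                              survival=sf.iloc[:, 0].to_numpy(float),
                              at_risk=tab["at_risk"].to_numpy(float),
                              label=None if lab is None else str(lab)))
    return out


def log_rank(follow_up, event, group):
    """Log-rank chi-square comparing graft survival across groups.

    Returns ``(statistic, df, p)`` with df = number of groups - 1.
    """
    group = np.asarray(group)
    k = len(pd.unique(group))
    if k < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if not np.asarray(event).astype(bool).any():
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(np.asarray(follow_up), group, np.asarray(event))
    return float(res.test_statistic), k - 1, float(res.p_value)
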