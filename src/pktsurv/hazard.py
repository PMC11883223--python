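"""Discrete-time logistic hazard model on a person-period file.

The follow-up of each transplantation is expanded to one row per at-risk
month; graft loss in the final month is a binary event, death with a
functioning graft and administrative end are censoring (event 0).  The
monthly hazard is modeled by logistic regression on the pre-transplant
covariates plus a five-column natural-spline time basis, fitted by
Newton-Raphson on the (optionally row-weighted) Bernoulli log-likelihood

    l(b) = sum_i w_i [ y_i log h_i + (1 - y_i) log(1 - h_i) ],
    h_i = expit(x_i . b).

Predicted graft survival is the cumulative product S(t) = prod_{m<=t}
(1 - h(m | x)), one monthly curve per covariate profile.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import COVARIATE_FIELDS, DISEASE_CATEGORIES, CohortTable
from .splines import SplineSpec, place_knots, spline_design

__all__ = [
    "ModelSpec",
    "PersonPeriodTable",
    "FittedHazardModel",
    "SurvivalCurve",
    "FitError",
    "SeparationError",
    "EncodingError",
    "expand_person_period",
    "fit_hazard",
    "predict_hazard",
    "predict_survival",
    "predict_survival_matrix",
    "compare_scenarios",
]

NUMERIC_COVARIATES = (
    "recipient_age",
    "donor_age",
    "living_donor",
    "preemptive",
    "retransplant",
    "hla_mm",
    "hla_dr_mm",
)

#: Donor-side fields a scenario comparison may override.
DONOR_FIELDS = ("donor_age", "living_donor", "hla_mm", "hla_dr_mm", "preemptive")

_COEF_BOUND = 30.0  # |log-odds| beyond this is treated as separation


class FitError(RuntimeError):
    """The likelihood cannot be maximized (e.g. no events)."""


class SeparationError(FitError):
    """Complete separation: coefficients diverge without a ridge penalty."""


class EncodingError(KeyError):
    """A category level absent from the model's encoding map."""


@dataclass(frozen=True)
class ModelSpec:
    """Predictor selection and encoding choices for a hazard fit.

    ``include_disease`` / ``include_time`` exist for reduced fits on tiny
    fixtures (e.g. intercept + one covariate, constant-in-time hazard); the
    full model keeps both on.
    """

    covariates: tuple[str, ...] = NUMERIC_COVARIATES
    disease_ref: str = "CAKUT"
    country_levels: tuple[str, ...] | None = None  # None = no country dummies
    country_ref: str | None = None
    era_levels: tuple[int, ...] | None = None  # decade starts, e.g. (1990, 2000, 2010)
    include_disease: bool = True
    include_time: bool = True
    penalty: float = 0.0


@dataclass
class PersonPeriodTable:
    """One row per subject per at-risk month, with spline time columns."""

    df: pd.DataFrame
    spline_spec: SplineSpec

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_events(self) -> int:
        return int(self.df["event"].sum())


def expand_person_period(cohort: CohortTable, spec: SplineSpec | None = None,
                         weights: pd.Series | None = None) -> PersonPeriodTable:
    """Expand a filtered cohort to its person-period file.

    Each subject contributes rows for months 1..follow_up_months; the event
    indicator is 1 only in the final month and only for graft loss.  When
    ``spec`` is None, knots are placed at the default quantiles of the
    expanded month column.  ``weights`` (indexed like the cohort) are
    replicated across a subject's months; default 1.
    """
    df = cohort.df
    fu = df["follow_up_months"].to_numpy()
    if np.isnan(fu).any() or (fu < 1).any():
        raise ValueError("follow_up_months must be >= 1 and complete")
    fu = fu.astype(int)
    reps = np.repeat(np.arange(len(df)), fu)
    month = np.concatenate([np.arange(1, f + 1) for f in fu]) if len(df) else np.array([], int)
    event = np.zeros(len(month), dtype=int)
    if len(df):
        last = np.cumsum(fu) - 1
        event[last] = df["graft_loss"].to_numpy(int)

    keep = ["subject_id", "country", "transplant_year", "primary_disease", *NUMERIC_COVARIATES]
    pp = df.iloc[reps][keep].reset_index(drop=True)
    pp.insert(1, "month", month)
    pp.insert(2, "event", event)
    if weights is None:
        pp["weight"] = 1.0
    else:
        pp["weight"] = weights.to_numpy(float)[reps]
    if spec is None:
        spec = place_knots(month)
    basis = spline_design(month, spec) if len(pp) else np.zeros((0, spec.n_basis))
    for j in range(spec.n_basis):
        pp[f"t{j + 1}"] = basis[:, j]
    return PersonPeriodTable(df=pp, spline_spec=spec)


# --- design matrix --------------------------------------------------------

def _design_columns(spec: ModelSpec) -> list[str]:
    cols = ["(intercept)"]
    cols += [c for c in spec.covariates]
    if spec.include_disease:
        cols += [f"disease:{d}" for d in DISEASE_CATEGORIES if d != spec.disease_ref]
    if spec.country_levels:
        cols += [f"country:{c}" for c in spec.country_levels if c != spec.country_ref]
    if spec.era_levels:
        cols += [f"era:{e}" for e in sorted(spec.era_levels)[1:]]
    return cols


def _build_design(df: pd.DataFrame, spec: ModelSpec, time_basis: np.ndarray | None) -> np.ndarray:
    n = len(df)
    blocks = [np.ones((n, 1))]
    blocks.append(df[list(spec.covariates)].to_numpy(float))
    if spec.include_disease:
        disease = df["primary_disease"]
        unknown = set(disease.unique()) - set(DISEASE_CATEGORIES)
        if unknown:
            raise EncodingError(f"unknown primary_disease levels: {sorted(unknown)}")
        for d in DISEASE_CATEGORIES:
            if d != spec.disease_ref:
                blocks.append((disease == d).to_numpy(float)[:, None])
    if spec.country_levels:
        levels = set(spec.country_levels)
        unknown = set(df["country"].unique()) - levels
        if unknown:
            raise EncodingError(f"unknown country levels: {sorted(unknown)}")
        for c in spec.country_levels:
            if c != spec.country_ref:
                blocks.append((df["country"] == c).to_numpy(float)[:, None])
    if spec.era_levels:
        eras = sorted(spec.era_levels)
        decade = (df["transplant_year"].to_numpy(int) // 10) * 10
        unknown = set(np.unique(decade)) - set(eras)
        if unknown:
            raise EncodingError(f"transplant decades outside era levels: {sorted(unknown)}")
        for e in eras[1:]:
            blocks.append((decade == e).astype(float)[:, None])
    if time_basis is not None:
        blocks.append(time_basis)
    return np.hstack(blocks)


# --- fitting --------------------------------------------------------------

def _weighted_loglik(X, y, w, beta, penalty):
    eta = X @ beta
    ll = float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))
    if penalty > 0:
        ll -= penalty * float(beta[1:] @ beta[1:])  # intercept unpenalized
    return ll


def _newton_logistic(X, y, w, penalty=0.0, tol=1e-10, maxiter=100):
    n, p = X.shape
    beta = np.zeros(p)
    rate = float(np.clip(np.average(y, weights=w), 1e-10, 1 - 1e-10))
    beta[0] = logit(rate)
    ll = _weighted_loglik(X, y, w, beta, penalty)
    converged = False
    pen_vec = np.full(p, 2.0 * penalty)
    pen_vec[0] = 0.0
    for _ in range(maxiter):
        mu = expit(X @ beta)
        grad = X.T @ (w * (y - mu)) - pen_vec * beta
        wd = w * mu * (1.0 - mu)
        H = (X * wd[:, None]).T @ X + np.diag(pen_vec)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving keeps the iteration ascent-safe
        new_ll = ll
        for k in range(30):
            cand = beta + step / (2 ** k)
            new_ll = _weighted_loglik(X, y, w, cand, penalty)
            if new_ll >= ll - 1e-14:
                beta = cand
                break
        if abs(new_ll - ll) <= tol * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    return beta, ll, converged


@dataclass
class FittedHazardModel:
    """Coefficients, spline layout and encoding of a fitted hazard model."""

    coef: dict  # design-column name -> coefficient
    spline_spec: SplineSpec
    model_spec: ModelSpec
    log_likelihood: float
    converged: bool
    n_obs: int
    n_events: int

    @property
    def intercept(self) -> float:
        return self.coef["(intercept)"]

    @property
    def beta(self) -> dict:
        """Covariate and disease-category coefficients (no time, no dummies)."""
        return {k: v for k, v in self.coef.items()
                if k in self.model_spec.covariates or k.startswith("disease:")}

    @property
    def gamma(self) -> np.ndarray:
        if not self.model_spec.include_time:
            return np.zeros(self.spline_spec.n_basis)
        return np.array([self.coef[f"t{j + 1}"] for j in range(self.spline_spec.n_basis)])

    @property
    def country_dummies(self) -> dict:
        return {k: v for k, v in self.coef.items() if k.startswith("country:")}

    # -- serialization (bit-stable: canonical key order, repr floats) ------
    def to_dict(self) -> dict:
        ms = self.model_spec
        return {
            "coef": dict(self.coef),
            "spline_spec": self.spline_spec.to_dict(),
            "model_spec": {
                "covariates": list(ms.covariates),
                "disease_ref": ms.disease_ref,
                "country_levels": list(ms.country_levels) if ms.country_levels else None,
                "country_ref": ms.country_ref,
                "era_levels": list(ms.era_levels) if ms.era_levels else None,
                "penalty": ms.penalty,
            },
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_events": self.n_events,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "FittedHazardModel":
        ms = d["model_spec"]
        spec = ModelSpec(
            covariates=tuple(ms["covariates"]),
            disease_ref=ms["disease_ref"],
            country_levels=tuple(ms["country_levels"]) if ms["country_levels"] else None,
            country_ref=ms["country_ref"],
            era_levels=tuple(ms["era_levels"]) if ms["era_levels"] else None,
            penalty=ms["penalty"],
        )
        return cls(coef=dict(d["coef"]), spline_spec=SplineSpec.from_dict(d["spline_spec"]),
                   model_spec=spec, log_likelihood=d["log_likelihood"],
                   converged=d["converged"], n_obs=d["n_obs"], n_events=d["n_events"])

    @classmethod
    def from_json(cls, s: str) -> "FittedHazardModel":
        return cls.from_dict(json.loads(s))


def fit_hazard(pp: PersonPeriodTable, spec: ModelSpec = ModelSpec()) -> FittedHazardModel:
    """Maximize the weighted Bernoulli log-likelihood of the person-period file.

    Newton-Raphson with step halving; convergence when the relative
    log-likelihood change drops below 1e-10 (at most 100 iterations).
    Raises :class:`FitError` when there are no rows or no events, and
    :class:`SeparationError` when coefficients diverge and ``spec.penalty``
    is zero; a small ridge (e.g. 1e-6) resolves separation on tiny fixtures.
    """
    df = pp.df
    if len(df) == 0:
        raise FitError("empty person-period table")
    y = df["event"].to_numpy(float)
    if y.sum() == 0:
        raise FitError("no events in person-period table; hazard not identifiable")
    w = df["weight"].to_numpy(float)
    if (w <= 0).any():
        raise FitError("weights must be positive")
    if spec.include_time:
        basis = df[[f"t{j + 1}" for j in range(pp.spline_spec.n_basis)]].to_numpy(float)
        time_names = [f"t{j + 1}" for j in range(pp.spline_spec.n_basis)]
    else:
        basis, time_names = None, []
    X = _build_design(df, spec, basis)
    names = _design_columns(spec) + time_names

    beta, ll, converged = _newton_logistic(X, y, w, penalty=spec.penalty)
    if np.abs(beta).max() > _COEF_BOUND or not converged:
        if spec.penalty <= 0:
            raise SeparationError(
                "coefficients diverged or fit failed to converge; "
                "likely complete separation - retry with spec.penalty > 0")
        warnings.warn("penalized fit did not fully converge", RuntimeWarning)
    return FittedHazardModel(
        coef=dict(zip(names, (float(b) for b in beta))),
        spline_spec=pp.spline_spec,
        model_spec=spec,
        log_likelihood=float(ll),
        converged=bool(converged),
        n_obs=int(len(df)),
        n_events=int(y.sum()),
    )


# --- prediction -----------------------------------------------------------

def _records_frame(record) -> pd.DataFrame:
    if isinstance(record, pd.DataFrame):
        return record
    if isinstance(record, pd.Series):
        return record.to_frame().T
    return pd.DataFrame([record])


def _covariate_lp(model: FittedHazardModel, df: pd.DataFrame) -> np.ndarray:
    spec = model.model_spec
    X = _build_design(df, spec, None)
    names = _design_columns(spec)
    coefs = np.array([model.coef[c] for c in names])
    return X @ coefs


def predict_hazard(model: FittedHazardModel, record, month) -> np.ndarray | float:
    """Monthly hazard(s) of graft loss for one covariate profile."""
    if not model.converged:
        raise FitError("model did not converge; refuse to predict")
    month_arr = np.atleast_1d(np.asarray(month))
    if (month_arr < 1).any():
        raise ValueError("month must be >= 1")
    df = _records_frame(record)
    lp_x = _covariate_lp(model, df)
    lp_t = spline_design(month_arr, model.spline_spec) @ model.gamma
    h = expit(lp_x[0] + lp_t)
    return float(h[0]) if np.isscalar(month) else h


@dataclass
class SurvivalCurve:
    """Monthly predicted hazard and graft survival for one profile."""

    months: np.ndarray
    hazard: np.ndarray
    survival: np.ndarray
    label: str | None = None


def predict_survival_matrix(model: FittedHazardModel, cohort_df: pd.DataFrame,
                            horizon: int) -> np.ndarray:
    """Predicted survival S(t), shape (n_subjects, horizon), t = 1..horizon."""
    if not model.converged:
        raise FitError("model did not converge; refuse to predict")
    lp_x = _covariate_lp(model, cohort_df)
    lp_t = spline_design(np.arange(1, horizon + 1), model.spline_spec) @ model.gamma
    h = expit(lp_x[:, None] + lp_t[None, :])
    return np.cumprod(1.0 - h, axis=1)


def predict_survival(model: FittedHazardModel, record, horizon: int,
                     label: str | None = None) -> SurvivalCurve:
    """Individual monthly survival curve S(t) = prod_{m<=t} (1 - h(m))."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    months = np.arange(1, horizon + 1)
    h = predict_hazard(model, record, months)
    return SurvivalCurve(months=months, hazard=h, survival=np.cumprod(1.0 - h), label=label)


def compare_scenarios(model: FittedHazardModel, record, donor_variants, horizon: int):
    """One survival curve per donor scenario for a fixed recipient.

    Each variant is a mapping of donor-side overrides (donor_age,
    living_donor, hla_mm, hla_dr_mm, preemptive) optionally with a
    ``"label"``; touching a recipient-side field raises ``ValueError``.
    """
    base = _records_frame(record).iloc[0].to_dict()
    curves = []
    for i, variant in enumerate(donor_variants):
        variant = dict(variant)
        lab = variant.pop("label", f"scenario-{i + 1}")
        bad = set(variant) - set(DONOR_FIELDS)
        if bad:
            raise ValueError(f"scenario overrides must be donor-side fields, got {sorted(bad)}")
        rec = dict(base)
        rec.update(variant)
        curves.append(predict_survival(model, rec, horizon, label=lab))
    return curves
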