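"""Shared fixtures: toy cohorts, a session-wide synthetic registry, oracles."""

import numpy as np
import pandas as pd
import pytest

import pktsurv as pk
from pktsurv.cohort import COLUMNS
from pktsurv.hazard import PersonPeriodTable
from pktsurv.splines import SplineSpec


def make_cohort_df(n=8, seed=0, **overrides):
    """Small well-formed cohort frame with reproducible covariates."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n)],
        "country": "NL",
        "transplant_year": rng.integers(2005, 2022, n),
        "recipient_age": rng.uniform(0.5, 18.5, n).round(2),
        "donor_age": rng.uniform(5, 55, n).round(2),
        "living_donor": rng.integers(0, 2, n),
        "preemptive": rng.integers(0, 2, n),
        "retransplant": rng.integers(0, 2, n),
        "hla_mm": rng.integers(0, 7, n),
        "hla_dr_mm": rng.integers(0, 3, n),
        "primary_disease": rng.choice(list(pk.DISEASE_CATEGORIES), n),
        "multi_organ": 0,
        "in_europe": 1,
        "follow_up_months": rng.integers(1, 120, n),
        "graft_loss": rng.integers(0, 2, n),
        "death_with_function": 0,
    })
    for k, v in overrides.items():
        df[k] = v
    df.loc[df["graft_loss"] == 1, "death_with_function"] = 0
    return df


@pytest.fixture
def toy_cohort():
    return pk.CohortTable(df=make_cohort_df(n=12, seed=3), source="toy")


@pytest.fixture(scope="session")
def default_registry():
    """One 2475-record registry shared across tests (expensive-ish)."""
    return pk.generate_registry(pk.default_profiles(), pk.default_truth(), seed=20250901)


@pytest.fixture(scope="session")
def fitted_model(default_registry):
    """A fitted French-cohort model plus its validation report."""
    fr = pk.CohortTable(
        df=default_registry.df[default_registry.df["country"] == "FR"].reset_index(drop=True),
        source="FR")
    model, report = pk.reestimate(fr, seed=11, n_boot=100)
    return model, report, fr


DUMMY_SPEC = SplineSpec(interior_knots=(5.0, 10.0, 20.0, 40.0), boundary_knots=(1.0, 60.0))


def toy_person_period(rows, covariates=("x1",)):
    """Hand-built person-period table: rows of (y, cov values...)."""
    df = pd.DataFrame(rows, columns=["event", *covariates])
    df.insert(0, "subject_id", [f"R{i}" for i in range(len(df))])
    df["month"] = 1
    df["weight"] = 1.0
    return PersonPeriodTable(df=df, spline_spec=DUMMY_SPEC)


def grid_search_logistic(X, y, step=1e-3, half_width=6.0, points=13):
    """Independent likelihood maximizer: iterative exhaustive grid refinement.

    Evaluates the Bernoulli log-likelihood on a full cartesian grid around
    the current center, shrinking the spacing until it is <= ``step``.
    Suitable for <= 3 free parameters.
    """
    from itertools import product

    p = X.shape[1]

    def ll(beta):
        eta = X @ np.asarray(beta)
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    center = np.zeros(p)
    width = half_width
    while True:
        offsets = np.linspace(-width, width, points)
        best, best_ll = None, -np.inf
        for combo in product(offsets, repeat=p):
            cand = center + np.array(combo)
            v = ll(cand)
            if v > best_ll:
                best, best_ll = cand, v
        center = best
        spacing = offsets[1] - offsets[0]
        if spacing <= step:
            return center
        width = 2.0 * spacing  # keep neighbors of the best grid point in range


def brute_force_auc(risk, cases, controls):
    """Exhaustive pairwise concordance with half-credit for ties."""
    s = 0.0
    for rc in risk[cases]:
        for rn in risk[controls]:
            s += 1.0 if rc > rn else (0.5 if rc == rn else 0.0)
    return s / (cases.sum() * controls.sum())
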