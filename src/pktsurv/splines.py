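"""Natural (restricted) cubic spline basis for the post-transplant time axis.

The discrete-time hazard model lets the baseline hazard vary smoothly with
months since transplantation.  Time enters the logistic linear predictor
through a natural cubic spline: piecewise cubic between knots, twice
continuously differentiable everywhere, and constrained to be *linear*
beyond the boundary knots so that extrapolation past the observed follow-up
is tame.

The basis used here is the truncated-power ("Harrell") parametrization.
With boundary knots ``b0 < b1`` and interior knots ``k1 < ... < k_q`` the
basis has ``q + 1`` columns: the identity column ``t`` plus one restricted
cubic term per knot except the last two.  Four interior knots therefore
yield five time columns.  Any natural-spline parametrization (e.g. R's
``ns``) spans the same function space; only the coefficients differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineSpec", "SplineError", "place_knots", "spline_design", "DEFAULT_QUANTILES"]

#: Quantiles of the person-period time column at which interior knots sit.
DEFAULT_QUANTILES = (0.05, 0.35, 0.65, 0.95)


class SplineError(ValueError):
    """Raised for degenerate knot configurations."""


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout of a natural cubic spline on the month axis.

    Parameters
    ----------
    interior_knots
        Strictly increasing interior knot positions (months).
    boundary_knots
        ``(low, high)`` bracketing every interior knot; the spline is linear
        outside this interval.
    """

    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]

    def __post_init__(self) -> None:
        interior = tuple(float(k) for k in self.interior_knots)
        boundary = tuple(float(k) for k in self.boundary_knots)
        if len(boundary) != 2:
            raise SplineError("boundary_knots must be a (low, high) pair")
        knots = (boundary[0], *interior, boundary[1])
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise SplineError(f"knots must be strictly increasing, got {knots}")
        object.__setattr__(self, "interior_knots", interior)
        object.__setattr__(self, "boundary_knots", boundary)

    @property
    def all_knots(self) -> tuple[float, ...]:
        return (self.boundary_knots[0], *self.interior_knots, self.boundary_knots[1])

    @property
    def n_basis(self) -> int:
        """Number of basis columns (interior knot count + 1)."""
        return len(self.interior_knots) + 1

    def to_dict(self) -> dict:
        return {
            "interior_knots": list(self.interior_knots),
            "boundary_knots": list(self.boundary_knots),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(tuple(d["interior_knots"]), tuple(d["boundary_knots"]))


def place_knots(times, quantiles=DEFAULT_QUANTILES) -> SplineSpec:
    """Place interior knots at empirical quantiles of the at-risk months.

    Quantiles are computed with linear interpolation on the full
    person-period time column (every at-risk month, not event months only),
    so the basis covers the whole follow-up distribution.  Boundary knots
    sit at the observed minimum and maximum.

    Raises
    ------
    SplineError
        If fewer than 10 distinct time values are supplied or the resulting
        knots are not strictly increasing (degenerate time distribution).
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0 or np.unique(t).size < 10:
        raise SplineError("need at least 10 distinct time values to place knots")
    interior = np.quantile(t, np.asarray(quantiles, dtype=float))
    return SplineSpec(tuple(interior), (float(t.min()), float(t.max())))


def spline_design(t, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural-spline basis at months ``t``.

    Returns an ``(len(t), spec.n_basis)`` array.  Column 0 is ``t`` itself;
    the remaining columns are restricted cubic terms scaled by the squared
    boundary span so coefficients are on comparable scales.  Evaluation is
    defined for all real ``t``: the restriction makes every column exactly
    linear outside the boundary knots.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    k = np.asarray(spec.all_knots)
    span2 = (k[-1] - k[0]) ** 2

    def cube(x, knot):
        return np.maximum(x - knot, 0.0) ** 3

    cols = [t]
    # one restricted term per knot except the last two; the two trailing
    # truncated cubics cancel the quadratic and cubic growth beyond k[-1]
    for j in range(len(k) - 2):
        c = (
            cube(t, k[j])
            - cube(t, k[-2]) * (k[-1] - k[j]) / (k[-1] - k[-2])
            + cube(t, k[-1]) * (k[-2] - k[j]) / (k[-1] - k[-2])
        )
        cols.append(c / span2)
    return np.column_stack(cols)
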