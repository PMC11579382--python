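"""Truncated-power spline bases for growth-trajectory models.

The mean log-BMI curve is modelled with polynomials of age plus truncated
power terms ``(t - kappa)_+^p`` that switch on above each knot ``kappa``.
All design matrices produced here share a fixed, documented column order:
polynomial terms of increasing degree first, then one truncated-power
column per knot in knot order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["SplineSpec", "truncated_power", "design_matrix", "integral_row"]

# form -> (polynomial degree, truncated-power degree; 0 = no knot terms)
_FORMS: dict[str, tuple[int, int]] = {
    "intercept": (0, 0),
    "linear": (1, 0),
    "quadratic": (2, 0),
    "cubic_slope": (3, 0),
    "linear_spline": (1, 1),
    "quadratic_spline": (2, 2),
    "cubic_spline": (3, 3),
}


def truncated_power(t, kappa: float, power: int):
    """Evaluate the truncated power basis ``(t - kappa)_+^power``.

    Zero for ``t <= kappa``; ``(t - kappa)**power`` above the knot.
    ``power`` must be 1, 2 or 3 (linear/quadratic/cubic splines).
    """
    if power not in (1, 2, 3):
        raise ValueError(f"power must be 1, 2 or 3, got {power}")
    t = np.asarray(t, dtype=float)
    out = np.where(t > kappa, t - kappa, 0.0) ** power
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SplineSpec:
    """Basis specification: functional form plus knot ages in years.

    Forms ``intercept``/``linear``/``quadratic``/``cubic_slope`` are plain
    polynomials (no knots allowed).  ``linear_spline`` adds ``(t-k)_+``
    terms to a linear trend, ``quadratic_spline`` adds ``(t-k)_+^2`` to a
    quadratic, and ``cubic_spline`` adds ``(t-k)_+^3`` to a full cubic.
    """

    form: str
    knots: tuple[float, ...] = field(default=())

    def __post_init__(self):
        if self.form not in _FORMS:
            raise ValueError(f"unknown spline form {self.form!r}")
        object.__setattr__(self, "knots", tuple(float(k) for k in self.knots))
        _, tp_degree = _FORMS[self.form]
        if tp_degree == 0 and self.knots:
            raise ValueError(f"form {self.form!r} takes no knots")
        if tp_degree > 0 and not self.knots:
            raise ValueError(f"form {self.form!r} requires at least one knot")
        if any(b <= a for a, b in zip(self.knots, self.knots[1:])):
            raise ValueError("knots must be strictly increasing")

    @property
    def degree(self) -> int:
        return _FORMS[self.form][0]

    @property
    def tp_degree(self) -> int:
        return _FORMS[self.form][1]

    @property
    def n_columns(self) -> int:
        return self.degree + 1 + len(self.knots)

    @property
    def column_names(self) -> list[str]:
        names = ["intercept"] + [f"age^{j}" for j in range(1, self.degree + 1)]
        names += [f"(age-{k:g})+^{self.tp_degree}" for k in self.knots]
        return names

    def label(self) -> str:
        if self.knots:
            return f"{self.form}({','.join(f'{k:g}' for k in self.knots)})"
        return self.form


def design_matrix(ages, spec: SplineSpec) -> np.ndarray:
    """Basis design matrix for a vector of ages (rows) under ``spec``.

    Column order: ``1, t, ..., t^degree`` then one truncated-power column
    per knot.  Ages must be finite and non-negative.
    """
    t = np.atleast_1d(np.asarray(ages, dtype=float))
    if not np.all(np.isfinite(t)):
        raise ValueError("ages must be finite")
    if np.any(t < 0):
        raise ValueError("ages must be non-negative")
    cols = [t**j for j in range(spec.degree + 1)]
    cols += [truncated_power(t, k, spec.tp_degree) for k in spec.knots]
    return np.column_stack(cols)


def integral_row(spec: SplineSpec, a: float, b: float) -> np.ndarray:
    """Row vector of ``int_a^b basis_j(t) dt`` for each design column.

    Uses the monomial antiderivative ``t^(j+1)/(j+1)`` and, for truncated
    power terms, ``(t-k)_+^(p+1)/(p+1)`` — exact whether the knot falls
    below, inside or above the window.  Dotting this row with a coefficient
    vector gives the closed-form area under the fitted curve on [a, b].
    """
    if b < a:
        raise ValueError("window must have a <= b")
    vals = [
        (b ** (j + 1) - a ** (j + 1)) / (j + 1) for j in range(spec.degree + 1)
    ]
    p = spec.tp_degree
    for k in spec.knots:
        upper = max(b - k, 0.0) ** (p + 1) / (p + 1)
        lower = max(a - k, 0.0) ** (p + 1) / (p + 1)
        vals.append(upper - lower)
    return np.asarray(vals)


def random_is_reduction(fixed: SplineSpec, random: SplineSpec) -> bool:
    """True when the random basis is a sub-model of the fixed basis.

    A random basis is admissible when its polynomial degree and number of
    knot terms do not exceed the fixed basis's, with knots shared.
    """
    if random.degree > fixed.degree:
        return False
    if random.tp_degree > 0:
        if random.knots != fixed.knots[: len(random.knots)]:
            return False
        if random.tp_degree > max(fixed.tp_degree, 0):
            return False
    return True
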