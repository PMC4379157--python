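"""Uncertain measured quantities and first-order standard-error propagation.

Every number that flows through the nitrogen budget is a :class:`Quantity`:
a value in declared units together with a standard error (SE).  The
propagation rules are the standard first-order ones used throughout
agronomic budget work:

* sums and differences combine component SEs in quadrature
  (root sum of squares), assuming independent errors;
* multiplication or division by an exact conversion factor scales the SE
  by the same factor;
* products of two uncertain quantities use the first-order delta
  approximation (needed only for the tracer step, where a fraction
  multiplies an uptake).

Unit tags are plain strings; sums and differences require matching tags.
No covariances are modelled — all measured inputs are treated as
independent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Quantity",
    "UnitsError",
    "BudgetWarning",
    "DegenerateSampleWarning",
    "NegativeValueWarning",
    "combine_sum",
    "scale",
    "product",
    "replicate_stats",
]


class UnitsError(ValueError):
    """Raised when quantities with incompatible unit tags are combined."""


class BudgetWarning(UserWarning):
    """Base class for non-fatal diagnostics raised by the budget pipeline."""


class DegenerateSampleWarning(BudgetWarning):
    """A replicate group too small to estimate a standard error (n = 1)."""


class NegativeValueWarning(BudgetWarning):
    """A physically implausible negative estimate; reported, never clamped."""


@dataclass(frozen=True)
class Quantity:
    """A measured value with a standard error and a unit tag.

    Parameters
    ----------
    value
        The point estimate, in ``units``.
    se
        Standard error of the estimate (same units); 0 for exact constants.
    units
        Free-form unit tag, e.g. ``"kg N ha-1"``.  Empty means
        dimensionless or unit-agnostic.
    """

    value: float
    se: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"value must be finite, got {self.value!r}")
        if not (math.isfinite(self.se) and self.se >= 0.0):
            raise ValueError(f"se must be finite and >= 0, got {self.se!r}")

    # Arithmetic sugar delegating to the propagation functions below.
    def __add__(self, other: "Quantity") -> "Quantity":
        return combine_sum([self, other])

    def __sub__(self, other: "Quantity") -> "Quantity":
        return combine_sum([self, other], signs=[1, -1])

    def __mul__(self, factor: float) -> "Quantity":
        return scale(self, factor)

    __rmul__ = __mul__

    def __truediv__(self, factor: float) -> "Quantity":
        return scale(self, 1.0 / factor)

    def with_units(self, units: str) -> "Quantity":
        return Quantity(self.value, self.se, units)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        tag = f" {self.units}" if self.units else ""
        return f"{self.value:g} ± {self.se:g}{tag}"


def _common_units(quantities: Sequence[Quantity], override: str | None) -> str:
    tags = {q.units for q in quantities if q.units}
    if len(tags) > 1:
        raise UnitsError(
            f"cannot add or subtract quantities with mixed units: {sorted(tags)}"
        )
    if override is not None:
        return override
    return tags.pop() if tags else ""


def combine_sum(
    quantities: Iterable[Quantity],
    signs: Sequence[int] | None = None,
    units: str | None = None,
) -> Quantity:
    """Signed sum of quantities with root-sum-of-squares SE.

    ``SE_z = sqrt(SE_a^2 + SE_b^2 + ...)`` regardless of sign, the standard
    rule for the SE of sums and differences of independent measurements.

    Raises :class:`UnitsError` when non-empty unit tags differ.
    """
    qs = list(quantities)
    if not qs:
        raise ValueError("combine_sum requires at least one quantity")
    if signs is None:
        signs = [1] * len(qs)
    signs = list(signs)
    if len(signs) != len(qs):
        raise ValueError("signs must match quantities in length")
    if any(s not in (-1, 1) for s in signs):
        raise ValueError("signs must be +1 or -1")
    out_units = _common_units(qs, units)
    value = math.fsum(s * q.value for s, q in zip(signs, qs))
    se = math.sqrt(math.fsum(q.se**2 for q in qs))
    return Quantity(value, se, out_units)


def scale(q: Quantity, factor: float, units: str | None = None) -> Quantity:
    """Multiply by an exact conversion factor; SE scales by |factor|."""
    if not math.isfinite(factor):
        raise ValueError(f"conversion factor must be finite, got {factor!r}")
    return Quantity(q.value * factor, q.se * abs(factor), units if units is not None else q.units)


def product(a: Quantity, b: Quantity, units: str = "") -> Quantity:
    """First-order (delta-method) product of two independent quantities.

    ``SE_z^2 = (a SE_b)^2 + (b SE_a)^2``, the small-error approximation.
    Used where a dimensionless fraction multiplies a measured flux.
    """
    value = a.value * b.value
    se = math.hypot(a.value * b.se, b.value * a.se)
    return Quantity(value, se, units)


def replicate_stats(values: Iterable[float], units: str = "") -> Quantity:
    """Mean and standard error of a set of replicate measurements.

    SE = sample standard deviation (ddof=1) / sqrt(n).  NaNs are dropped so
    ragged replicate tables (unequal n across quantities) can share one
    frame.  A single replicate yields SE 0 with a
    :class:`DegenerateSampleWarning`; an empty group is an error.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    n = arr.size
    if n == 0:
        raise ValueError("replicate_stats requires at least one value")
    if n == 1:
        warnings.warn(
            "single replicate: standard error reported as 0",
            DegenerateSampleWarning,
            stacklevel=2,
        )
        return Quantity(float(arr[0]), 0.0, units)
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / math.sqrt(n))
    return Quantity(mean, se, units)
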