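"""¹⁵N pool-dilution accounting for the labelled-residue experiment.

A rice crop grown on plots amended with ¹⁵N-enriched residue carries an
isotopic signature between the unenriched background (natural abundance,
≈ 0.366 atom % ¹⁵N) and the enrichment of the applied residue.  Two-pool
mixing gives the fraction of plant N derived from the residue::

    fNdr = (atom%15N_sample - atom%15N_background)
           / (atom%15N_input - atom%15N_background)

Scaling by total aboveground-biomass N uptake and by the labelled share
of the residue mixture yields the absolute N flux from residue (Ndr,
kg N ha⁻¹).  The same fNdr applied to any N pool (aboveground biomass,
soil to 30 cm) converts to a percent recovery of the applied tracer, and
whatever is not recovered above- or belowground is counted as lost.

Samples falling outside the [background, input] enrichment interval —
possible through instrument noise — produce fNdr outside [0, 1].  The raw
value is returned with a :class:`TracerRangeWarning`; clamping would bias
the downstream flux estimate and is deliberately avoided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .quantity import (
    BudgetWarning,
    Quantity,
    product,
    replicate_stats,
)

__all__ = [
    "NATURAL_ABUNDANCE_ATOM_PCT",
    "InvalidTracerError",
    "TracerRangeWarning",
    "IsotopeMeasure",
    "ResidueApplication",
    "TracerResult",
    "fraction_n_derived_from_residue",
    "atom_percent_for_fraction",
    "n_derived_from_residue",
    "percent_recovered",
    "percent_loss",
    "fndr_from_replicates",
    "ndr_from_replicates",
    "ndr_quantity",
]

#: Natural abundance of ¹⁵N in atmospheric N₂, atom percent.  A
#: plausibility reference for background samples, not a hard bound.
NATURAL_ABUNDANCE_ATOM_PCT = 0.3663


class InvalidTracerError(ValueError):
    """Input residue enrichment equals the background — mixing is undefined."""


class TracerRangeWarning(BudgetWarning):
    """Sample enrichment outside [background, input]; fNdr outside [0, 1]."""


@dataclass(frozen=True)
class IsotopeMeasure:
    """Atom percent ¹⁵N of a sample (0–100)."""

    atom_percent_15n: float

    def __post_init__(self) -> None:
        _check_atom_pct(self.atom_percent_15n, "atom_percent_15n")

    def __float__(self) -> float:
        return float(self.atom_percent_15n)


def _check_atom_pct(x: float, name: str) -> None:
    if not (math.isfinite(x) and 0.0 <= x <= 100.0):
        raise ValueError(f"{name} must be an atom percent in [0, 100], got {x!r}")


def _as_atom_pct(x: "float | IsotopeMeasure", name: str) -> float:
    v = float(x)
    _check_atom_pct(v, name)
    return v


@dataclass(frozen=True)
class ResidueApplication:
    """The labelled/unlabelled residue mixture incorporated before planting.

    Masses are dry weight kg ha⁻¹; N contents kg N ha⁻¹; C:N dimensionless.
    """

    mass_labeled: float
    mass_unlabeled: float
    n_labeled: float
    n_unlabeled: float
    cn_labeled: float
    cn_unlabeled: float
    atom_pct_labeled: float
    atom_pct_unlabeled: float

    def __post_init__(self) -> None:
        for name in ("mass_labeled", "mass_unlabeled", "n_labeled", "n_unlabeled"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mass_labeled + self.mass_unlabeled <= 0:
            raise ValueError("total residue mass must be positive")
        _check_atom_pct(self.atom_pct_labeled, "atom_pct_labeled")
        _check_atom_pct(self.atom_pct_unlabeled, "atom_pct_unlabeled")

    @property
    def proportion_labeled(self) -> float:
        """Mass share of the labelled residue in the applied mixture."""
        return self.mass_labeled / (self.mass_labeled + self.mass_unlabeled)

    @property
    def applied_15n_kg_ha(self) -> float:
        """N applied as labelled residue — the tracer amount for recoveries."""
        return self.n_labeled


@dataclass(frozen=True)
class TracerResult:
    """Summary of a pool-dilution experiment for one site/treatment."""

    fndr: float
    ndr: float
    pct_recovered_above: float
    pct_recovered_below: float
    pct_loss: float

    def __post_init__(self) -> None:
        total = self.pct_recovered_above + self.pct_recovered_below + self.pct_loss
        if abs(total - 100.0) > 1e-9:
            raise ValueError(
                f"recoveries + loss must equal 100 exactly, got {total!r}"
            )


def fraction_n_derived_from_residue(
    sample: "float | IsotopeMeasure",
    background: "float | IsotopeMeasure",
    input_residue: "float | IsotopeMeasure",
) -> float:
    """Two-pool mixing fraction of plant N derived from labelled residue.

    Returns ``(sample - background) / (input - background)``.  Raises
    :class:`InvalidTracerError` when input equals background.  Values
    outside [0, 1] are returned raw with a :class:`TracerRangeWarning`.
    """
    s = _as_atom_pct(sample, "sample")
    b = _as_atom_pct(background, "background")
    i = _as_atom_pct(input_residue, "input_residue")
    denom = i - b
    if denom == 0.0:
        raise InvalidTracerError(
            "input residue enrichment equals background; fNdr is undefined"
        )
    f = (s - b) / denom
    if not (0.0 <= f <= 1.0):
        warnings.warn(
            f"sample enrichment {s} outside [background {b}, input {i}]: "
            f"fNdr = {f:.4g} outside [0, 1] (returned unclamped)",
            TracerRangeWarning,
            stacklevel=2,
        )
    return f


def atom_percent_for_fraction(
    fndr: float,
    background: "float | IsotopeMeasure",
    input_residue: "float | IsotopeMeasure",
) -> float:
    """Forward mixing model: the sample atom % implied by a true fNdr.

    The exact inverse of :func:`fraction_n_derived_from_residue`; used by
    the synthetic-data generator and by round-trip tests.
    """
    b = _as_atom_pct(background, "background")
    i = _as_atom_pct(input_residue, "input_residue")
    return b + fndr * (i - b)


def n_derived_from_residue(
    fndr: float, total_agb_n_uptake: float, proportion_labeled: float
) -> float:
    """Absolute N uptake from residue: fNdr × uptake × labelled share.

    ``total_agb_n_uptake`` is aboveground-biomass N uptake in the residue
    treatment (kg N ha⁻¹); ``proportion_labeled`` is the labelled mass
    share of the residue mixture, so the fraction measured against the
    labelled pool is rescaled to the whole mixture.
    """
    if total_agb_n_uptake < 0:
        raise ValueError("total_agb_n_uptake must be >= 0")
    if not (0.0 < proportion_labeled <= 1.0):
        raise ValueError("proportion_labeled must be in (0, 1]")
    if fndr < 0:
        raise ValueError("fndr must be >= 0 for a flux estimate")
    return fndr * total_agb_n_uptake * proportion_labeled


def percent_recovered(
    fndr_pool: float, total_n_in_pool: float, applied_15n: float
) -> float:
    """Percent of applied tracer N recovered in a pool.

    ``100 × (fNdr_pool × total N in pool) / applied ¹⁵N``, where the pool
    is e.g. aboveground biomass or soil to 30 cm at harvest.
    """
    if applied_15n <= 0:
        raise ValueError("applied_15n must be > 0")
    return 100.0 * (fndr_pool * total_n_in_pool) / applied_15n


def percent_loss(recovered_above: float, recovered_below: float) -> float:
    """Percent of applied tracer unaccounted for: 100 − (above + below).

    May be negative when recoveries overshoot 100 % (measurement error);
    flagged with a warning, never clamped.
    """
    for name, v in (("recovered_above", recovered_above), ("recovered_below", recovered_below)):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"{name} must be in [0, 100], got {v!r}")
    loss = 100.0 - (recovered_above + recovered_below)
    if loss < 0:
        warnings.warn(
            f"recoveries sum to {recovered_above + recovered_below:.4g} % > 100 %",
            TracerRangeWarning,
            stacklevel=2,
        )
    return loss


def fndr_from_replicates(
    samples: Iterable["float | IsotopeMeasure"],
    background: "float | IsotopeMeasure",
    input_residue: "float | IsotopeMeasure",
) -> Quantity:
    """Mean ± SE of fNdr computed per replicate, then averaged.

    Computing the fraction per replicate before averaging preserves the
    replicate-level spread for SE reporting, instead of averaging the
    atom-% readings first.
    """
    fs = [
        fraction_n_derived_from_residue(s, background, input_residue)
        for s in samples
    ]
    return replicate_stats(fs, units="")


def ndr_from_replicates(
    samples: Sequence["float | IsotopeMeasure"],
    uptakes_kg_ha: Sequence[float],
    background: "float | IsotopeMeasure",
    input_residue: "float | IsotopeMeasure",
    proportion_labeled: float,
) -> Quantity:
    """N derived from residue, mean ± SE over paired replicates.

    Each replicate pairs a tiller enrichment with that microplot's
    aboveground N uptake; Ndr is computed per replicate and the replicate
    Ndr values are averaged, keeping the natural pairing.
    """
    if len(samples) != len(uptakes_kg_ha):
        raise ValueError("samples and uptakes must pair one-to-one")
    if not (0.0 < proportion_labeled <= 1.0):
        raise ValueError("proportion_labeled must be in (0, 1]")
    # Per-replicate fNdr may be slightly negative from instrument noise
    # (warned above); it is carried through unclamped so the replicate
    # mean stays unbiased.
    ndrs = [
        fraction_n_derived_from_residue(s, background, input_residue)
        * u
        * proportion_labeled
        for s, u in zip(samples, uptakes_kg_ha)
    ]
    return replicate_stats(ndrs, units="kg N ha-1")


def ndr_quantity(
    fndr: Quantity, uptake: Quantity, proportion_labeled: float
) -> Quantity:
    """Ndr from summary-level fNdr and uptake (delta-method SE)."""
    if not (0.0 < proportion_labeled <= 1.0):
        raise ValueError("proportion_labeled must be in (0, 1]")
    q = product(fndr, uptake, units="kg N ha-1")
    return Quantity(q.value * proportion_labeled, q.se * proportion_labeled, q.units)
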