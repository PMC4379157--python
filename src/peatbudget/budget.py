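"""Assembly of the annual soil-N mineralization budget.

The growing-season ledger starts from total aboveground N uptake in
fertilizer-omission (0N) plots and peels off every non-peat source —
residue-derived N, surface-water N, shallow-groundwater N, atmospheric
deposition, and biological N₂ fixation.  The remainder is N mineralized
from the surface peat::

    surface_peat_N = uptake_0N − (Ndr + Ndsw + Ndgw + deposition + fixation)

Shallow groundwater N is itself attributed to subsurface peat
mineralization, so the peat-derived total adds it back::

    peat_total_N = surface_peat_N + Ndgw

Plants capture only a fraction (NUE, N uptake efficiency, default 0.50)
of the N actually mineralized, so gross growing-season mineralization is
the peat total divided by NUE.

The winter-fallow ledger reads accumulated soil NO₃-N just before the
summer flood (assumed denitrified on flooding, hence a real annual loss)
and subtracts the share mineralized from decomposing crop residue; the
remainder is fallow-season peat mineralization.  Annual mineralization is
the sum of the two seasons.

Two SE conventions are offered for the peat total (``se_mode``):

* ``"paper"`` (default): SE(peat_total) = rss(SE(surface_peat), SE(Ndgw)),
  i.e. the groundwater SE enters both the surface-peat line and the
  total.  This matches how budget tables of this kind are conventionally
  propagated line by line.
* ``"consistent"``: the total is propagated directly from
  uptake − Ndr − Ndsw − deposition − fixation, in which Ndgw cancels
  algebraically and its SE does not enter.  This is the statistically
  faithful sampling SE and is what a Monte-Carlo rerun of the chain
  reproduces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .quantity import (
    NegativeValueWarning,
    Quantity,
    combine_sum,
    scale,
)

__all__ = [
    "N_UNITS",
    "BudgetConstants",
    "FallowMeasurements",
    "NBudgetResult",
    "surface_peat_n",
    "peat_total_n",
    "growing_season_mineralization",
    "residue_n_mineralized_fallow",
    "fallow_peat_mineralization",
    "annual_mineralization",
    "assemble_budget",
]

N_UNITS = "kg N ha-1"


@dataclass(frozen=True)
class BudgetConstants:
    """Literature-derived constants of the growing-season budget.

    Atmospheric deposition (wet + dry) and biological N₂ fixation by
    free-living cyanobacteria are not measured on site; they enter as
    exact constants (SE 0).  NUE is the assumed N uptake efficiency.
    """

    n_deposition: float = 6.0
    n_fixation: float = 25.0
    nue: float = 0.50

    def __post_init__(self) -> None:
        if self.n_deposition < 0 or self.n_fixation < 0:
            raise ValueError("deposition and fixation must be >= 0")
        if not (0.0 < self.nue <= 1.0):
            raise ValueError("nue must be in (0, 1]")

    @property
    def deposition_q(self) -> Quantity:
        return Quantity(self.n_deposition, 0.0, N_UNITS)

    @property
    def fixation_q(self) -> Quantity:
        return Quantity(self.n_fixation, 0.0, N_UNITS)


@dataclass(frozen=True)
class FallowMeasurements:
    """Winter-fallow inputs: residue N before/after decomposition and soil NO₃-N.

    ``soil_no3_at_flooding`` is the NO₃-N accumulated by late spring,
    assumed lost to denitrification once the field is flooded.
    """

    residue_n_fall: Quantity
    residue_n_spring: Quantity
    soil_no3_at_flooding: Quantity

    def __post_init__(self) -> None:
        for name in ("residue_n_fall", "residue_n_spring", "soil_no3_at_flooding"):
            if getattr(self, name).value < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_net_mineralization(
        cls, residue_min: Quantity, soil_no3: Quantity
    ) -> "FallowMeasurements":
        """Build from an already-differenced residue mineralization line.

        Summary tables often report only the overwinter residue N loss
        (fall − spring) with its SE.  Storing it as the fall value with a
        zero spring value preserves both the difference and its SE.
        """
        zero = Quantity(0.0, 0.0, residue_min.units or N_UNITS)
        return cls(residue_min, zero, soil_no3)


@dataclass(frozen=True)
class NBudgetResult:
    """The full annual N ledger for one site, every line as value ± SE."""

    uptake_0n: Quantity
    ndr: Quantity
    ndsw: Quantity
    ndgw: Quantity
    n_deposition: Quantity
    n_fixation: Quantity
    surface_peat_n: Quantity
    peat_total_n: Quantity
    nmin_growing: Quantity
    residue_min_fallow: Quantity
    nmin_fallow: Quantity
    nmin_total: Quantity

    def lines(self) -> dict[str, Quantity]:
        """Ledger lines in presentation order."""
        return {
            "uptake_0n": self.uptake_0n,
            "ndr": self.ndr,
            "ndsw": self.ndsw,
            "ndgw": self.ndgw,
            "n_deposition": self.n_deposition,
            "n_fixation": self.n_fixation,
            "surface_peat_n": self.surface_peat_n,
            "peat_total_n": self.peat_total_n,
            "nmin_growing": self.nmin_growing,
            "residue_min_fallow": self.residue_min_fallow,
            "nmin_fallow": self.nmin_fallow,
            "nmin_total": self.nmin_total,
        }


def surface_peat_n(
    uptake_0n: Quantity,
    ndr: Quantity,
    ndsw: Quantity,
    ndgw: Quantity,
    consts: BudgetConstants,
) -> Quantity:
    """Surface-peat N uptake: 0N uptake minus all other known sources.

    A negative remainder (sources exceeding uptake) implies a soil N sink;
    it is returned with a warning, not clamped.
    """
    q = combine_sum(
        [uptake_0n, ndr, ndsw, ndgw, consts.deposition_q, consts.fixation_q],
        signs=[1, -1, -1, -1, -1, -1],
        units=N_UNITS,
    )
    if q.value < 0:
        warnings.warn(
            f"surface peat N is negative ({q.value:.3g} {N_UNITS}): known "
            "sources exceed measured uptake",
            NegativeValueWarning,
            stacklevel=2,
        )
    return q


def peat_total_n(surface_peat: Quantity, ndgw: Quantity) -> Quantity:
    """Total peat-derived N: surface peat plus groundwater N (assumed peat-derived).

    SE combines the two line SEs in quadrature (the line-by-line table
    convention; see module docstring on ``se_mode``).
    """
    return combine_sum([surface_peat, ndgw], units=N_UNITS)


def growing_season_mineralization(peat_total: Quantity, nue: float) -> Quantity:
    """Gross growing-season peat N mineralization: peat total / NUE.

    Division by the exact NUE factor scales value and SE alike.
    """
    if nue <= 0:
        raise ValueError("nue must be > 0")
    return scale(peat_total, 1.0 / nue)


def residue_n_mineralized_fallow(f: FallowMeasurements) -> Quantity:
    """N released from crop residue over the winter fallow: fall − spring."""
    return combine_sum(
        [f.residue_n_fall, f.residue_n_spring], signs=[1, -1], units=N_UNITS
    )


def fallow_peat_mineralization(
    f: FallowMeasurements, residue_min: Quantity
) -> Quantity:
    """Fallow-season peat N mineralization: soil NO₃-N minus residue release."""
    q = combine_sum(
        [f.soil_no3_at_flooding, residue_min], signs=[1, -1], units=N_UNITS
    )
    if q.value < 0:
        warnings.warn(
            f"fallow peat mineralization is negative ({q.value:.3g} {N_UNITS})",
            NegativeValueWarning,
            stacklevel=2,
        )
    return q


def annual_mineralization(growing: Quantity, fallow: Quantity) -> Quantity:
    """Annual SOM-N mineralization: growing + fallow season."""
    return combine_sum([growing, fallow], units=N_UNITS)


def assemble_budget(
    uptake_0n: Quantity,
    ndr: Quantity,
    ndsw: Quantity,
    ndgw: Quantity,
    fallow: FallowMeasurements,
    consts: BudgetConstants | None = None,
    se_mode: str = "paper",
) -> NBudgetResult:
    """Run the full annual N ledger for one site.

    ``se_mode`` selects the SE convention for the peat total (and hence
    everything downstream of it); see the module docstring.
    """
    if se_mode not in ("paper", "consistent"):
        raise ValueError("se_mode must be 'paper' or 'consistent'")
    consts = consts or BudgetConstants()
    surface = surface_peat_n(uptake_0n, ndr, ndsw, ndgw, consts)
    if se_mode == "paper":
        total = peat_total_n(surface, ndgw)
    else:
        # Ndgw cancels algebraically: total = uptake − Ndr − Ndsw − dep − fix.
        total = combine_sum(
            [uptake_0n, ndr, ndsw, consts.deposition_q, consts.fixation_q],
            signs=[1, -1, -1, -1, -1],
            units=N_UNITS,
        )
    nmin_g = growing_season_mineralization(total, consts.nue)
    res_min = residue_n_mineralized_fallow(fallow)
    nmin_f = fallow_peat_mineralization(fallow, res_min)
    nmin_t = annual_mineralization(nmin_g, nmin_f)
    return NBudgetResult(
        uptake_0n=uptake_0n,
        ndr=ndr,
        ndsw=ndsw,
        ndgw=ndgw,
        n_deposition=consts.deposition_q,
        n_fixation=consts.fixation_q,
        surface_peat_n=surface,
        peat_total_n=total,
        nmin_growing=nmin_g,
        residue_min_fallow=res_min,
        nmin_fallow=nmin_f,
        nmin_total=nmin_t,
    )
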