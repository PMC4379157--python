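"""N delivered to the crop by surface irrigation water and shallow groundwater.

Surface water: the seasonal mean mineral-N concentration (NH₄-N + NO₃-N)
at the field inlet, multiplied by the crop-coefficient-adjusted cumulative
evapotranspiration over the flooded period, gives the mass of dissolved N
drawn into the root zone::

    Ndsw (kg N ha⁻¹) = mean N_inlet (mg L⁻¹) × ETa (L ha⁻¹) × 10⁻⁶ kg mg⁻¹

with 1 m of water over 1 ha ≡ 10⁷ L ha⁻¹ (an exact conversion).

Shallow groundwater: paired in-field mesocosms with (perforated base) and
without (sealed base) access to the subsoil isolate the groundwater
contribution as the difference in aboveground N uptake::

    Ndgw = uptake(+groundwater) − uptake(−groundwater)

A negative contrast (exclusion exceeding access) is physically odd but is
reported with a warning rather than floored at zero, so that downstream
uncertainty propagation stays unbiased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .quantity import (
    NegativeValueWarning,
    Quantity,
    combine_sum,
    replicate_stats,
    scale,
)

__all__ = [
    "LITERS_PER_HA_PER_M",
    "WaterSeries",
    "EtModel",
    "MesocosmContrast",
    "seasonal_mean_inlet_n",
    "surface_water_n",
    "groundwater_n",
]

#: Exact conversion: a 1 m water depth over 1 ha is 10^7 litres.
LITERS_PER_HA_PER_M = 1.0e7


@dataclass(frozen=True)
class WaterSeries:
    """Inlet water sampling dates with NH₄-N and NO₃-N concentrations (mg N L⁻¹)."""

    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"date", "nh4_n_mg_l", "no3_n_mg_l"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"WaterSeries frame missing columns: {sorted(missing)}")
        if len(self.samples) == 0:
            raise ValueError("WaterSeries requires at least one sample")
        conc = self.samples[["nh4_n_mg_l", "no3_n_mg_l"]]
        if (conc.to_numpy() < 0).any():
            raise ValueError("water N concentrations must be >= 0")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[object, float, float]]
    ) -> "WaterSeries":
        """Build from (date, nh4_n, no3_n) tuples."""
        df = pd.DataFrame(records, columns=["date", "nh4_n_mg_l", "no3_n_mg_l"])
        return cls(df)

    @property
    def total_n_mg_l(self) -> pd.Series:
        return self.samples["nh4_n_mg_l"] + self.samples["no3_n_mg_l"]


@dataclass(frozen=True)
class EtModel:
    """Cumulative evapotranspiration over the flooded period, with crop coefficient.

    ``cumulative_et_m`` is reference ET in metres of water; the crop
    coefficient (Kc, ≈ 1.06 for flooded rice) adjusts it to crop ETa.
    """

    cumulative_et_m: float
    crop_coefficient: float = 1.06

    def __post_init__(self) -> None:
        if self.cumulative_et_m <= 0:
            raise ValueError("cumulative_et_m must be > 0")
        if self.crop_coefficient <= 0:
            raise ValueError("crop_coefficient must be > 0")

    @property
    def eta_liters_per_ha(self) -> float:
        """Crop-adjusted cumulative ET as a water volume per hectare."""
        return self.cumulative_et_m * LITERS_PER_HA_PER_M * self.crop_coefficient


@dataclass(frozen=True)
class MesocosmContrast:
    """Mean ± SE aboveground N uptake with and without groundwater access."""

    uptake_plus_gw: Quantity
    uptake_minus_gw: Quantity

    @classmethod
    def from_replicates(
        cls, plus_values: Sequence[float], minus_values: Sequence[float]
    ) -> "MesocosmContrast":
        return cls(
            replicate_stats(plus_values, units="kg N ha-1"),
            replicate_stats(minus_values, units="kg N ha-1"),
        )


def seasonal_mean_inlet_n(series: WaterSeries) -> Quantity:
    """Unweighted seasonal mean of total mineral N across sampling dates.

    NH₄-N and NO₃-N are summed per date before averaging (by linearity the
    order does not matter).  The SE is the between-date spread of totals;
    no time weighting is applied.
    """
    return replicate_stats(series.total_n_mg_l, units="mg N L-1")


def surface_water_n(mean_conc: "Quantity | float", et: EtModel) -> Quantity:
    """N input from surface irrigation water (kg N ha⁻¹).

    Multiplies the seasonal mean inlet concentration by the crop-adjusted
    ET volume; the mg→kg and m→L conversions are exact, so the SE scales
    by the same factor.
    """
    if not isinstance(mean_conc, Quantity):
        mean_conc = Quantity(float(mean_conc), 0.0, "mg N L-1")
    if mean_conc.value < 0:
        raise ValueError("mean inlet concentration must be >= 0")
    factor = et.eta_liters_per_ha * 1.0e-6  # mg L-1 -> kg ha-1
    return scale(mean_conc, factor, units="kg N ha-1")


def groundwater_n(contrast: MesocosmContrast) -> Quantity:
    """N contribution of shallow groundwater from the mesocosm uptake contrast.

    Value: uptake(+gw) − uptake(−gw); SE combines the two treatment SEs in
    quadrature.  A negative estimate is returned with a warning.
    """
    q = combine_sum(
        [contrast.uptake_plus_gw, contrast.uptake_minus_gw],
        signs=[1, -1],
        units="kg N ha-1",
    )
    if q.value < 0:
        warnings.warn(
            f"groundwater N contribution is negative ({q.value:.3g} kg N ha-1); "
            "reported unclamped",
            NegativeValueWarning,
            stacklevel=2,
        )
    return q
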