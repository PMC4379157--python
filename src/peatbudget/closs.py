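"""Soil C loss and land-surface subsidence from annual N mineralization.

Because microbial oxidation of soil organic matter releases C and N in
the stoichiometric ratio of the soil, annual C mineralization is the
annual SOM-N mineralization times the soil C:N ratio (mass basis, to
30 cm).  Crediting the annual C returned in crop residue at tillage
gives the net soil C loss::

    C_mineralized = Nmin_total × C:N
    net_C_loss    = C_mineralized − residue_C_input

Net C loss converts to a subsidence rate through the carbon content of
the organic matter (0.58 g C g⁻¹ SOM), the soil bulk density, and the
fraction of observed subsidence attributable to SOM oxidation rather
than compaction (f_min ≈ 0.67 for post-1995 Delta peat)::

    subsidence (cm yr⁻¹) = [(net_C_loss / SOM %C) / bulk_density] / f_min

with net C loss first converted from kg ha⁻¹ to g cm⁻² (× 10⁻⁵, exact).

Because gross mineralization scales as 1/NUE, the whole chain is rerun
over a grid of NUE assumptions to quantify the model's sensitivity to
that single assumed efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .budget import (
    BudgetConstants,
    FallowMeasurements,
    NBudgetResult,
    assemble_budget,
)
from .quantity import Quantity, combine_sum, scale

__all__ = [
    "C_UNITS",
    "KG_HA_TO_G_CM2",
    "SoilProfile",
    "CLossResult",
    "SiteInputs",
    "c_mineralized",
    "net_c_loss",
    "subsidence_rate",
    "run_site",
    "nue_sensitivity",
    "kg_ha_to_g_cm2",
    "g_cm2_to_kg_ha",
]

C_UNITS = "kg C ha-1"

#: Exact conversion: 1 kg ha⁻¹ = 10⁻⁵ g cm⁻².
KG_HA_TO_G_CM2 = 1.0e-5


def kg_ha_to_g_cm2(x: float) -> float:
    return x * KG_HA_TO_G_CM2


def g_cm2_to_kg_ha(x: float) -> float:
    return x / KG_HA_TO_G_CM2


@dataclass(frozen=True)
class SoilProfile:
    """Soil stoichiometry and physical properties used in the C conversion.

    ``cn_ratio`` — soil C:N mass ratio to 30 cm (kg C per kg N).
    ``som_pct_c`` — carbon fraction of soil organic matter (g C g⁻¹ SOM).
    ``bulk_density_g_cm3`` — bulk density of the upper profile.
    ``f_min`` — fraction of subsidence attributable to SOM oxidation.
    ``cn_ratio_se`` — optional SE on C:N, used only by the Monte-Carlo
    path (the analytic chain treats C:N as a point value).
    """

    cn_ratio: float
    bulk_density_g_cm3: float
    som_pct_c: float = 0.58
    f_min: float = 0.67
    cn_ratio_se: float = 0.0

    def __post_init__(self) -> None:
        if self.cn_ratio <= 0:
            raise ValueError("cn_ratio must be > 0")
        if self.bulk_density_g_cm3 <= 0:
            raise ValueError("bulk_density_g_cm3 must be > 0")
        if self.som_pct_c <= 0:
            raise ValueError("som_pct_c must be > 0")
        if not (0.0 < self.f_min <= 1.0):
            raise ValueError("f_min must be in (0, 1]")
        if self.cn_ratio_se < 0:
            raise ValueError("cn_ratio_se must be >= 0")


@dataclass(frozen=True)
class CLossResult:
    """Annual C balance and subsidence estimate for one site."""

    c_mineralized: Quantity
    residue_c_input: Quantity
    net_c_loss: Quantity
    subsidence_cm_yr: Quantity


@dataclass(frozen=True)
class SiteInputs:
    """Everything the annual budget needs for one site, as summary quantities."""

    uptake_0n: Quantity
    ndr: Quantity
    ndsw: Quantity
    ndgw: Quantity
    fallow: FallowMeasurements
    residue_c_input: Quantity
    profile: SoilProfile
    constants: BudgetConstants = BudgetConstants()

    def with_nue(self, nue: float) -> "SiteInputs":
        return replace(self, constants=replace(self.constants, nue=nue))


def c_mineralized(nmin_total: Quantity, cn_ratio: float) -> Quantity:
    """Annual C mineralized: N mineralized × soil C:N (exact-factor SE)."""
    if cn_ratio <= 0:
        raise ValueError("cn_ratio must be > 0")
    return scale(nmin_total, cn_ratio, units=C_UNITS)


def net_c_loss(c_min: Quantity, residue_c_input: Quantity) -> Quantity:
    """Net annual soil C loss: mineralized C minus the residue C credit.

    ``residue_c_input`` is stored as a positive credit (C returned to the
    soil in crop residue at tillage) and subtracted here.
    """
    return combine_sum([c_min, residue_c_input], signs=[1, -1], units=C_UNITS)


def subsidence_rate(net_c: Quantity, profile: SoilProfile) -> Quantity:
    """Annual subsidence implied by a net soil C loss.

    Converts kg C ha⁻¹ to g C cm⁻², divides by the SOM carbon fraction to
    get a SOM mass per area, by bulk density to get a depth, and by f_min
    to account for concurrent compaction/consolidation.
    """
    factor = KG_HA_TO_G_CM2 / (
        profile.som_pct_c * profile.bulk_density_g_cm3 * profile.f_min
    )
    return scale(net_c, factor, units="cm yr-1")


def run_site(
    inputs: SiteInputs,
    nue: float | None = None,
    se_mode: str = "paper",
) -> tuple[NBudgetResult, CLossResult]:
    """Evaluate the complete N-budget → C-loss → subsidence chain for a site."""
    if nue is not None:
        inputs = inputs.with_nue(nue)
    budget = assemble_budget(
        inputs.uptake_0n,
        inputs.ndr,
        inputs.ndsw,
        inputs.ndgw,
        inputs.fallow,
        inputs.constants,
        se_mode=se_mode,
    )
    c_min = c_mineralized(budget.nmin_total, inputs.profile.cn_ratio)
    net = net_c_loss(c_min, inputs.residue_c_input)
    sub = subsidence_rate(net, inputs.profile)
    closs = CLossResult(
        c_mineralized=c_min,
        residue_c_input=inputs.residue_c_input,
        net_c_loss=net,
        subsidence_cm_yr=sub,
    )
    return budget, closs


def nue_sensitivity(
    inputs: SiteInputs,
    nue_grid: "list[float]",
    se_mode: str = "paper",
) -> list[tuple[float, Quantity]]:
    """Net C loss across a grid of NUE assumptions.

    The full budget is re-evaluated per NUE value; net C loss is strictly
    decreasing and convex in NUE (it scales as 1/NUE).
    """
    if not nue_grid:
        raise ValueError("nue_grid must be nonempty")
    for nue in nue_grid:
        if not (0.0 < nue <= 1.0):
            raise ValueError(f"nue grid values must be in (0, 1], got {nue!r}")
    out: list[tuple[float, Quantity]] = []
    for nue in nue_grid:
        _, closs = run_site(inputs, nue=nue, se_mode=se_mode)
        out.append((nue, closs.net_c_loss))
    return out
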