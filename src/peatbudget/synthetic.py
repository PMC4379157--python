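"""Synthetic field-season generator for the annual N budget.

No raw plot-level data are deposited for this kind of study — published
tables carry site means and standard errors only.  This module therefore
simulates complete measurement campaigns with the statistical structure
the analysis assumes, so that every pipeline stage and the
parameter-recovery tests run without any external data:

* replicate 0N-plot uptakes ~ Normal(mean, plot sd);
* harvest tiller atom-% ¹⁵N obtained by pushing a true fNdr through the
  forward two-pool mixing model, then jittering with instrument noise;
* paired mesocosm uptakes whose treatment means differ by the true
  groundwater contribution;
* inlet water concentrations ~ Normal truncated at zero (concentrations
  cannot be negative — the one deliberate departure from the untruncated
  error model assumed by the analytic propagation);
* fallow-season residue and soil NO₃-N replicates with Normal noise.

Replicate noise defaults are calibrated so that the SE of a site mean at
the study's replication (n = 4 plots, 5 water dates, ...) matches the
magnitudes reported for this cropping system — e.g. a plot sd of
20 kg N ha⁻¹ gives SE 10 at n = 4.

The scenario's ground truth is always written alongside the data
(``truth.json``); recovery tests compare pipeline estimates against
:func:`closed_form_truth`, never against values re-derived from the
noisy files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .budget import BudgetConstants, FallowMeasurements, NBudgetResult
from .closs import CLossResult, SiteInputs, SoilProfile, run_site
from .quantity import Quantity
from .tracer import atom_percent_for_fraction
from .water import EtModel, surface_water_n

__all__ = [
    "SiteScenario",
    "SyntheticDataset",
    "generate",
    "true_site_inputs",
    "closed_form_truth",
]

# Labelled share of the default residue mixture (1310 kg labelled in
# 5010 kg total) and the default true residue-derived N flux it implies.
_DEFAULT_PROPORTION_LABELED = 1310.0 / (1310.0 + 3700.0)
_DEFAULT_TRUE_FNDR = 1.9 / (135.0 * _DEFAULT_PROPORTION_LABELED)


@dataclass(frozen=True)
class SiteScenario:
    """True parameter values and noise levels for one simulated site.

    Defaults describe a "Site-1-like" peat rice field: 0N uptake
    185 kg N ha⁻¹, groundwater contribution 61.7 kg N ha⁻¹, seasonal
    inlet N 0.43 mg L⁻¹, soil C:N 14.4, bulk density 0.555 g cm⁻³.
    """

    site: str = "1"
    seed: int = 1

    # 0N fertilizer-omission plots
    uptake_0n_mean: float = 185.0
    uptake_0n_sd: float = 20.0
    n_plots: int = 4
    grain_yield_mean: float = 7.9
    grain_yield_sd: float = 0.5

    # Labelled-residue microplots
    true_fndr: float = _DEFAULT_TRUE_FNDR
    residue_uptake_mean: float = 135.0
    residue_uptake_sd: float = 14.0
    tiller_atom_pct_sd: float = 0.10
    n_microplots: int = 4
    background_atom_pct: float = 0.3673
    input_atom_pct: float = 9.0693
    mass_labeled: float = 1310.0
    mass_unlabeled: float = 3700.0

    # Mesocosm groundwater contrast
    mesocosm_minus_mean: float = 127.0
    true_ndgw: float = 61.7
    mesocosm_sd: float = 12.7
    n_mesocosms: int = 4

    # Inlet water and evapotranspiration
    water_conc_mean: float = 0.4315
    water_conc_sd: float = 0.4325
    n_water_dates: int = 5
    nh4_fraction: float = 0.8
    et_m: float = 0.634
    crop_coefficient: float = 1.06

    # Winter fallow
    residue_n_fall_mean: float = 37.2
    residue_n_spring_mean: float = 20.3
    fallow_residue_sd: float = 2.0
    n_residue_plots: int = 5
    soil_no3_mean: float = 20.3
    soil_no3_sd: float = 1.4
    n_soil_samples: int = 4
    residue_c_mean: float = 1872.0
    residue_c_sd: float = 306.0

    # Soil profile and budget constants
    cn_ratio: float = 14.4
    som_pct_c: float = 0.58
    bulk_density: float = 0.555
    f_min: float = 0.67
    nue_true: float = 0.50
    n_deposition: float = 6.0
    n_fixation: float = 25.0

    def __post_init__(self) -> None:
        positive = (
            "uptake_0n_mean",
            "residue_uptake_mean",
            "mesocosm_minus_mean",
            "water_conc_mean",
            "et_m",
            "crop_coefficient",
            "cn_ratio",
            "som_pct_c",
            "bulk_density",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "uptake_0n_sd",
            "residue_uptake_sd",
            "tiller_atom_pct_sd",
            "mesocosm_sd",
            "water_conc_sd",
            "fallow_residue_sd",
            "soil_no3_sd",
            "residue_c_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "n_plots",
            "n_microplots",
            "n_mesocosms",
            "n_water_dates",
            "n_residue_plots",
            "n_soil_samples",
        ):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2 to estimate an SE")
        if not (0.0 <= self.true_fndr <= 1.0):
            raise ValueError("true_fndr must be in [0, 1]")
        if not (0.0 < self.nue_true <= 1.0):
            raise ValueError("nue_true must be in (0, 1]")
        if not (0.0 < self.f_min <= 1.0):
            raise ValueError("f_min must be in (0, 1]")
        if not (0.0 <= self.nh4_fraction <= 1.0):
            raise ValueError("nh4_fraction must be in [0, 1]")

    @property
    def proportion_labeled(self) -> float:
        return self.mass_labeled / (self.mass_labeled + self.mass_unlabeled)

    @property
    def true_ndr(self) -> float:
        return (
            self.true_fndr * self.residue_uptake_mean * self.proportion_labeled
        )

    @property
    def et_model(self) -> EtModel:
        return EtModel(self.et_m, self.crop_coefficient)

    @property
    def constants(self) -> BudgetConstants:
        return BudgetConstants(self.n_deposition, self.n_fixation, self.nue_true)

    @property
    def profile(self) -> SoilProfile:
        return SoilProfile(
            cn_ratio=self.cn_ratio,
            bulk_density_g_cm3=self.bulk_density,
            som_pct_c=self.som_pct_c,
            f_min=self.f_min,
        )


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated measurement tables plus the scenario ground truth."""

    scenario: SiteScenario
    tables: dict[str, pd.DataFrame] = field(repr=False)
    truth: dict = field(repr=False)

    def write(self, outdir: "str | Path") -> Path:
        """Write the CSV tables and ``truth.json`` to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "truth.json").write_text(
            json.dumps(self.truth, indent=2, sort_keys=True) + "\n"
        )
        return outdir


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """Normal(mean, sd) conditioned on being nonnegative."""
    if sd == 0:
        return np.full(n, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def generate(scenario: SiteScenario) -> SyntheticDataset:
    """Simulate one site's complete measurement campaign.

    Deterministic given the scenario (including its seed): the same
    scenario always produces identical tables.
    """
    s = scenario
    rng = np.random.default_rng(s.seed)
    site = s.site

    # 0N plots
    uptakes = rng.normal(s.uptake_0n_mean, s.uptake_0n_sd, s.n_plots)
    yields = rng.normal(s.grain_yield_mean, s.grain_yield_sd, s.n_plots)
    plots = pd.DataFrame(
        {
            "site": site,
            "treatment": "0N",
            "replicate": np.arange(1, s.n_plots + 1),
            "agb_n_uptake_kg_ha": uptakes,
            "grain_yield_mg_ha": yields,
        }
    )

    # Labelled-residue microplots: forward mixing model plus instrument noise
    true_atom_pct = atom_percent_for_fraction(
        s.true_fndr, s.background_atom_pct, s.input_atom_pct
    )
    tiller_atom_pct = rng.normal(true_atom_pct, s.tiller_atom_pct_sd, s.n_microplots)
    microplot_uptake = rng.normal(
        s.residue_uptake_mean, s.residue_uptake_sd, s.n_microplots
    )
    isotope = pd.DataFrame(
        {
            "site": site,
            "treatment": "15N_residue",
            "replicate": np.arange(1, s.n_microplots + 1),
            "pool": "tiller",
            "atom_pct_15n": tiller_atom_pct,
            "total_n_kg_ha": microplot_uptake,
        }
    )

    # Mesocosm contrast
    minus = rng.normal(s.mesocosm_minus_mean, s.mesocosm_sd, s.n_mesocosms)
    plus = rng.normal(
        s.mesocosm_minus_mean + s.true_ndgw, s.mesocosm_sd, s.n_mesocosms
    )
    mesocosm = pd.DataFrame(
        {
            "site": np.repeat(site, 2 * s.n_mesocosms),
            "treatment": np.repeat(["plus_gw", "minus_gw"], s.n_mesocosms),
            "replicate": np.tile(np.arange(1, s.n_mesocosms + 1), 2),
            "agb_n_uptake_kg_ha": np.concatenate([plus, minus]),
        }
    )

    # Inlet water sampling over the flooded period
    totals = _truncated_normal(rng, s.water_conc_mean, s.water_conc_sd, s.n_water_dates)
    dates = pd.date_range("2012-06-21", periods=s.n_water_dates, freq="23D")
    water = pd.DataFrame(
        {
            "site": site,
            "date": dates.strftime("%Y-%m-%d"),
            "location": "inlet",
            "depth_cm": 0,
            "nh4_n_mg_l": totals * s.nh4_fraction,
            "no3_n_mg_l": totals * (1.0 - s.nh4_fraction),
        }
    )

    # Winter fallow: residue decomposition plots and pre-flood soil NO3-N
    n_fallow = max(s.n_residue_plots, s.n_soil_samples)
    fall = np.full(n_fallow, np.nan)
    spring = np.full(n_fallow, np.nan)
    no3 = np.full(n_fallow, np.nan)
    residue_c = np.full(n_fallow, np.nan)
    fall[: s.n_residue_plots] = rng.normal(
        s.residue_n_fall_mean, s.fallow_residue_sd, s.n_residue_plots
    )
    spring[: s.n_residue_plots] = rng.normal(
        s.residue_n_spring_mean, s.fallow_residue_sd, s.n_residue_plots
    )
    no3[: s.n_soil_samples] = rng.normal(
        s.soil_no3_mean, s.soil_no3_sd, s.n_soil_samples
    )
    residue_c[: s.n_residue_plots] = rng.normal(
        s.residue_c_mean, s.residue_c_sd, s.n_residue_plots
    )
    fallow = pd.DataFrame(
        {
            "site": site,
            "replicate": np.arange(1, n_fallow + 1),
            "residue_n_fall": fall,
            "residue_n_spring": spring,
            "soil_no3_at_flooding": no3,
            "residue_c_input": residue_c,
        }
    )

    budget, closs = closed_form_truth(s)
    truth = {
        "scenario": dataclasses.asdict(s),
        "true_lines": {
            **{k: q.value for k, q in budget.lines().items()},
            "c_mineralized": closs.c_mineralized.value,
            "net_c_loss": closs.net_c_loss.value,
            "subsidence_cm_yr": closs.subsidence_cm_yr.value,
        },
        "analytic_se": {
            **{k: q.se for k, q in budget.lines().items()},
            "c_mineralized": closs.c_mineralized.se,
            "net_c_loss": closs.net_c_loss.se,
            "subsidence_cm_yr": closs.subsidence_cm_yr.se,
        },
    }
    tables = {
        "plots": plots,
        "isotope": isotope,
        "mesocosm": mesocosm,
        "water": water,
        "fallow": fallow,
    }
    return SyntheticDataset(scenario=s, tables=tables, truth=truth)


def true_site_inputs(scenario: SiteScenario) -> SiteInputs:
    """Scenario truth as summary quantities with theoretical SEs.

    Values are the scenario's true parameters; SEs are the closed-form
    standard errors of the corresponding estimators at the scenario's
    noise levels and replication (e.g. plot sd / √n for the uptake mean,
    a first-order product SE for the residue-derived N).  The truncated
    water sampling is treated as untruncated here, consistent with the
    analytic error model; the resulting bias is small and documented.
    """
    s = scenario
    U = "kg N ha-1"
    uptake = Quantity(s.uptake_0n_mean, s.uptake_0n_sd / math.sqrt(s.n_plots), U)

    # Per-replicate Ndr sd via the delta method, then /sqrt(n).
    fndr_sd = s.tiller_atom_pct_sd / (s.input_atom_pct - s.background_atom_pct)
    ndr_rep_sd = s.proportion_labeled * math.hypot(
        s.residue_uptake_mean * fndr_sd, s.true_fndr * s.residue_uptake_sd
    )
    ndr = Quantity(s.true_ndr, ndr_rep_sd / math.sqrt(s.n_microplots), U)

    conc = Quantity(
        s.water_conc_mean,
        s.water_conc_sd / math.sqrt(s.n_water_dates),
        "mg N L-1",
    )
    ndsw = surface_water_n(conc, s.et_model)

    ndgw = Quantity(
        s.true_ndgw, s.mesocosm_sd * math.sqrt(2.0 / s.n_mesocosms), U
    )

    fallow_se = s.fallow_residue_sd / math.sqrt(s.n_residue_plots)
    fallow = FallowMeasurements(
        residue_n_fall=Quantity(s.residue_n_fall_mean, fallow_se, U),
        residue_n_spring=Quantity(s.residue_n_spring_mean, fallow_se, U),
        soil_no3_at_flooding=Quantity(
            s.soil_no3_mean, s.soil_no3_sd / math.sqrt(s.n_soil_samples), U
        ),
    )
    residue_c = Quantity(
        s.residue_c_mean,
        s.residue_c_sd / math.sqrt(s.n_residue_plots),
        "kg C ha-1",
    )
    return SiteInputs(
        uptake_0n=uptake,
        ndr=ndr,
        ndsw=ndsw,
        ndgw=ndgw,
        fallow=fallow,
        residue_c_input=residue_c,
        profile=s.profile,
        constants=s.constants,
    )


def analysis_settings(scenario: SiteScenario):
    """Pipeline settings matching a scenario's design constants.

    Background/input enrichment, ET model, budget constants and the soil
    profile are experimental design choices, not measurements; the
    pipeline receives them through configuration.  This helper mirrors a
    scenario into an :class:`~peatbudget.io.AnalysisSettings` so a
    generated dataset can be pushed straight through the estimators.
    """
    from .io import AnalysisSettings, SiteSoil

    s = scenario
    return AnalysisSettings(
        background_atom_pct=s.background_atom_pct,
        input_atom_pct=s.input_atom_pct,
        proportion_labeled=s.proportion_labeled,
        et_m=s.et_m,
        crop_coefficient=s.crop_coefficient,
        n_deposition=s.n_deposition,
        n_fixation=s.n_fixation,
        nue=s.nue_true,
        som_pct_c=s.som_pct_c,
        f_min=s.f_min,
        sites={
            s.site: SiteSoil(
                cn_ratio=s.cn_ratio, bulk_density_g_cm3=s.bulk_density
            )
        },
    )


def closed_form_truth(
    scenario: SiteScenario, se_mode: str = "consistent"
) -> tuple[NBudgetResult, CLossResult]:
    """The exact budget implied by a scenario's true parameters.

    The recovery oracle for parameter-recovery tests: values are computed
    by running the deterministic chain on the true inputs; SEs are the
    theoretical sampling SEs from :func:`true_site_inputs`.  The default
    ``se_mode="consistent"`` gives the statistically faithful SE of each
    estimator (no double-counted groundwater term), which is what
    coverage of a pipeline estimate should be judged against.
    """
    return run_site(true_site_inputs(scenario), se_mode=se_mode)
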