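"""Readers, configuration, fixtures, and report writing for the budget pipeline.

The pipeline consumes tidy CSV tables of raw field measurements
(fertilizer-omission plots, labelled-residue microplots, mesocosm pairs,
inlet water chemistry, fallow-season residue and soil N), reduces each to
a site-level summary quantity, assembles the annual N budget and C-loss
chain, and writes a machine-readable JSON report plus a human-readable
tidy CSV.

Readers follow a tolerant-reader contract: missing required columns or
unparseable/negative values are hard errors that name the offending rows,
while extra columns are accepted with a warning.

A packaged fixture (``twitchell_2012``) carries the published site-level
summary inputs for the two Twitchell Island rice fields, so the full
chain can be exercised offline without any raw data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .budget import BudgetConstants, FallowMeasurements, NBudgetResult
from .closs import CLossResult, SiteInputs, SoilProfile, nue_sensitivity, run_site
from .montecarlo import MCSummary, monte_carlo_budget
from .quantity import BudgetWarning, Quantity, replicate_stats
from .tracer import ndr_from_replicates
from .water import (
    EtModel,
    MesocosmContrast,
    WaterSeries,
    groundwater_n,
    seasonal_mean_inlet_n,
    surface_water_n,
)

__all__ = [
    "SchemaError",
    "ExtraColumnWarning",
    "SCHEMAS",
    "read_measurements",
    "AnalysisSettings",
    "RunConfig",
    "SiteSoil",
    "site_inputs_from_tables",
    "SiteReport",
    "BudgetReport",
    "run_budget",
    "write_report",
    "load_twitchell_2012",
    "round_for_display",
]

log = logging.getLogger("peatbudget")


class SchemaError(ValueError):
    """A measurement table violates its declared schema."""


class ExtraColumnWarning(BudgetWarning):
    """A measurement table carries columns beyond its schema (accepted)."""


#: Required, optional (known but not needed) and value (numeric,
#: nonnegative) columns per table kind.
SCHEMAS: dict[str, dict[str, list[str]]] = {
    "plots": {
        "required": ["site", "treatment", "replicate", "agb_n_uptake_kg_ha"],
        "optional": ["grain_yield_mg_ha"],
        "values": ["agb_n_uptake_kg_ha"],
    },
    "mesocosm": {
        "required": ["site", "treatment", "replicate", "agb_n_uptake_kg_ha"],
        "optional": [],
        "values": ["agb_n_uptake_kg_ha"],
    },
    "water": {
        "required": ["site", "date", "location", "nh4_n_mg_l", "no3_n_mg_l"],
        "optional": ["depth_cm"],
        "values": ["nh4_n_mg_l", "no3_n_mg_l"],
    },
    "isotope": {
        "required": [
            "site",
            "treatment",
            "replicate",
            "pool",
            "atom_pct_15n",
            "total_n_kg_ha",
        ],
        "optional": [],
        "values": ["atom_pct_15n", "total_n_kg_ha"],
    },
    "fallow": {
        "required": [
            "site",
            "residue_n_fall",
            "residue_n_spring",
            "soil_no3_at_flooding",
        ],
        "optional": ["replicate", "residue_c_input"],
        "values": [
            "residue_n_fall",
            "residue_n_spring",
            "soil_no3_at_flooding",
            "residue_c_input",
        ],
    },
}


def read_measurements(path: "str | Path", schema: str) -> pd.DataFrame:
    """Read and validate one measurement CSV against its schema.

    Raises :class:`SchemaError` for missing columns, unparseable numeric
    cells, or negative measurements (with 1-based data row numbers);
    warns on extra columns but keeps them.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; one of {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema]
    df = pd.read_csv(path)
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    known = set(spec["required"]) | set(spec["optional"])
    extra = [c for c in df.columns if c not in known]
    if extra:
        warnings.warn(
            f"{path}: extra columns {extra} accepted and ignored by the "
            "standard pipeline",
            ExtraColumnWarning,
            stacklevel=2,
        )
    df = df.copy()
    df["site"] = df["site"].astype(str)
    for col in spec["values"]:
        if col not in df.columns:
            continue
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna()
        if bad.any():
            rows = [int(i) + 2 for i in df.index[bad]]  # +2: header + 1-based
            raise SchemaError(f"{path}: unparseable values in {col!r}, rows {rows}")
        neg = coerced < 0
        if neg.any():
            rows = [int(i) + 2 for i in df.index[neg]]
            raise SchemaError(f"{path}: negative values in {col!r}, rows {rows}")
        df[col] = coerced
    log.info("read %s: %d rows from %s", schema, len(df), path)
    return df


class QuantityModel(BaseModel):
    """A value ± SE pair as it appears in configuration files."""

    value: float
    se: float = 0.0

    def to_quantity(self, units: str) -> Quantity:
        return Quantity(self.value, self.se, units)


class SiteSoil(BaseModel):
    """Per-site soil profile and residue-C credit."""

    cn_ratio: float
    bulk_density_g_cm3: float
    residue_c_input: Optional[QuantityModel] = None
    cn_ratio_se: float = 0.0


class AnalysisSettings(BaseModel):
    """Everything the estimators need besides the measurement tables."""

    background_atom_pct: float = 0.3673
    input_atom_pct: float = 9.0693
    proportion_labeled: float = 1310.0 / 5010.0
    et_m: float = 0.634
    crop_coefficient: float = 1.06
    n_deposition: float = 6.0
    n_fixation: float = 25.0
    nue: float = 0.50
    som_pct_c: float = 0.58
    f_min: float = 0.67
    sites: dict[str, SiteSoil] = Field(default_factory=dict)
    nue_grid: list[float] = Field(default_factory=lambda: [0.50])
    mc_draws: int = 10_000
    mc_seed: int = 1432
    se_mode: Literal["paper", "consistent"] = "paper"
    truncate_negative: bool = False

    @field_validator("nue_grid")
    @classmethod
    def _grid_nonempty(cls, v: list[float]) -> list[float]:
        if not v:
            raise ValueError("nue_grid must be nonempty")
        return v

    @property
    def et_model(self) -> EtModel:
        return EtModel(self.et_m, self.crop_coefficient)

    @property
    def constants(self) -> BudgetConstants:
        return BudgetConstants(self.n_deposition, self.n_fixation, self.nue)

    def profile_for(self, site: str) -> SoilProfile:
        soil = self.sites[site]
        return SoilProfile(
            cn_ratio=soil.cn_ratio,
            bulk_density_g_cm3=soil.bulk_density_g_cm3,
            som_pct_c=self.som_pct_c,
            f_min=self.f_min,
            cn_ratio_se=soil.cn_ratio_se,
        )


class RunConfig(AnalysisSettings):
    """A full pipeline run: measurement CSV paths plus analysis settings."""

    plots_csv: Path
    mesocosm_csv: Path
    water_csv: Path
    isotope_csv: Path
    fallow_csv: Path
    out_dir: Optional[Path] = None

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls.model_validate(raw)
        for name in ("plots_csv", "mesocosm_csv", "water_csv", "isotope_csv", "fallow_csv"):
            p = getattr(cfg, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        return cfg

    def config_hash(self) -> str:
        # out_dir does not affect results, so reruns into different
        # directories hash (and report) identically
        payload = json.dumps(
            self.model_dump(mode="json", exclude={"out_dir"}),
            sort_keys=True,
            default=str,
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def site_inputs_from_tables(
    tables: Mapping[str, pd.DataFrame], settings: AnalysisSettings
) -> dict[str, SiteInputs]:
    """Reduce raw measurement tables to per-site summary inputs.

    Sites are taken from the plots table; every other table must cover
    the same sites.  Per-site soil parameters come from
    ``settings.sites`` (raising a named error when absent).
    """
    inputs: dict[str, SiteInputs] = {}
    sites = sorted(tables["plots"]["site"].astype(str).unique())
    for site in sites:
        if site not in settings.sites:
            raise SchemaError(f"no soil profile configured for site {site!r}")

        plots = tables["plots"]
        zero_n = plots[(plots["site"] == site) & (plots["treatment"] == "0N")]
        if len(zero_n) == 0:
            raise SchemaError(f"no 0N plot rows for site {site!r}")
        uptake = replicate_stats(zero_n["agb_n_uptake_kg_ha"], units="kg N ha-1")
        log.info("site %s: 0N uptake %s from %d plots", site, uptake, len(zero_n))

        iso = tables["isotope"]
        tillers = iso[(iso["site"] == site) & (iso["pool"] == "tiller")]
        if len(tillers) == 0:
            raise SchemaError(f"no tiller isotope rows for site {site!r}")
        ndr = ndr_from_replicates(
            tillers["atom_pct_15n"].tolist(),
            tillers["total_n_kg_ha"].tolist(),
            settings.background_atom_pct,
            settings.input_atom_pct,
            settings.proportion_labeled,
        )
        log.info("site %s: residue-derived N %s (pool dilution)", site, ndr)

        water = tables["water"]
        inlet = water[(water["site"] == site) & (water["location"] == "inlet")]
        if len(inlet) == 0:
            raise SchemaError(f"no inlet water rows for site {site!r}")
        series = WaterSeries(inlet.reset_index(drop=True))
        conc = seasonal_mean_inlet_n(series)
        ndsw = surface_water_n(conc, settings.et_model)
        log.info("site %s: surface-water N %s (conc x ETa)", site, ndsw)

        meso = tables["mesocosm"]
        plus = meso[(meso["site"] == site) & (meso["treatment"] == "plus_gw")]
        minus = meso[(meso["site"] == site) & (meso["treatment"] == "minus_gw")]
        if len(plus) == 0 or len(minus) == 0:
            raise SchemaError(f"missing mesocosm treatment rows for site {site!r}")
        contrast = MesocosmContrast.from_replicates(
            plus["agb_n_uptake_kg_ha"].tolist(), minus["agb_n_uptake_kg_ha"].tolist()
        )
        ndgw = groundwater_n(contrast)
        log.info("site %s: groundwater N %s (mesocosm contrast)", site, ndgw)

        fal = tables["fallow"]
        frows = fal[fal["site"] == site]
        if len(frows) == 0:
            raise SchemaError(f"no fallow rows for site {site!r}")
        fallow = FallowMeasurements(
            residue_n_fall=replicate_stats(frows["residue_n_fall"], units="kg N ha-1"),
            residue_n_spring=replicate_stats(
                frows["residue_n_spring"], units="kg N ha-1"
            ),
            soil_no3_at_flooding=replicate_stats(
                frows["soil_no3_at_flooding"], units="kg N ha-1"
            ),
        )

        soil = settings.sites[site]
        if "residue_c_input" in frows.columns and frows["residue_c_input"].notna().any():
            residue_c = replicate_stats(frows["residue_c_input"], units="kg C ha-1")
        elif soil.residue_c_input is not None:
            residue_c = soil.residue_c_input.to_quantity("kg C ha-1")
        else:
            raise SchemaError(
                f"site {site!r}: residue C input neither measured (fallow table) "
                "nor configured"
            )

        inputs[site] = SiteInputs(
            uptake_0n=uptake,
            ndr=ndr,
            ndsw=ndsw,
            ndgw=ndgw,
            fallow=fallow,
            residue_c_input=residue_c,
            profile=settings.profile_for(site),
            constants=settings.constants,
        )
    return inputs


# ---------------------------------------------------------------------------
# Reports


#: units and a short derivation tag per report line
LINE_META: dict[str, tuple[str, str]] = {
    "uptake_0n": ("kg N ha-1", "replicate mean, 0N plots"),
    "ndr": ("kg N ha-1", "15N pool dilution x uptake x labelled share"),
    "ndsw": ("kg N ha-1", "mean inlet conc x crop-adjusted ET"),
    "ndgw": ("kg N ha-1", "mesocosm uptake contrast"),
    "n_deposition": ("kg N ha-1", "literature constant"),
    "n_fixation": ("kg N ha-1", "literature constant"),
    "surface_peat_n": ("kg N ha-1", "uptake minus known sources"),
    "peat_total_n": ("kg N ha-1", "surface peat + groundwater"),
    "nmin_growing": ("kg N ha-1", "peat total / NUE"),
    "residue_min_fallow": ("kg N ha-1", "residue N fall - spring"),
    "nmin_fallow": ("kg N ha-1", "soil NO3 - residue mineralization"),
    "nmin_total": ("kg N ha-1", "growing + fallow"),
    "c_mineralized": ("kg C ha-1", "N mineralized x soil C:N"),
    "residue_c_input": ("kg C ha-1", "measured residue C at tillage"),
    "net_c_loss": ("kg C ha-1", "C mineralized - residue C"),
    "subsidence_cm_yr": ("cm yr-1", "net C / (SOM %C x BD x f_min)"),
}


def round_for_display(line_item: str, x: float) -> float:
    """Display rounding: N lines to 1 dp, C lines to integers, subsidence 2 dp."""
    units = LINE_META.get(line_item, ("", ""))[0]
    if units == "kg C ha-1":
        return float(round(x))
    if units == "cm yr-1":
        return round(x, 2)
    return round(x, 1)


def _sig12(x: float) -> float:
    return float(f"{x:.12g}")


@dataclass
class SiteReport:
    """All computed results for one site."""

    inputs: SiteInputs
    budget: NBudgetResult
    closs: CLossResult
    sensitivity: list[tuple[float, Quantity]]
    mc: Optional[dict[str, MCSummary]] = None

    def lines(self) -> dict[str, Quantity]:
        out = dict(self.budget.lines())
        out["c_mineralized"] = self.closs.c_mineralized
        out["residue_c_input"] = self.closs.residue_c_input
        out["net_c_loss"] = self.closs.net_c_loss
        out["subsidence_cm_yr"] = self.closs.subsidence_cm_yr
        return out


@dataclass
class BudgetReport:
    """Per-site results plus a provenance block for reproducibility."""

    sites: dict[str, SiteReport]
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        out: dict = {"provenance": self.provenance, "sites": {}}
        for site, rep in self.sites.items():
            lines = {}
            for name, q in rep.lines().items():
                units, how = LINE_META[name]
                lines[name] = {
                    "value": _sig12(q.value),
                    "se": _sig12(q.se),
                    "units": units,
                    "derivation": how,
                }
            entry: dict = {
                "lines": lines,
                "nue": rep.inputs.constants.nue,
                "sensitivity": [
                    {"nue": nue, "net_c_loss": _sig12(q.value), "se": _sig12(q.se)}
                    for nue, q in rep.sensitivity
                ],
            }
            if rep.mc is not None:
                entry["monte_carlo"] = {
                    name: {
                        "mean": _sig12(s.mean),
                        "sd": _sig12(s.sd),
                        "q025": _sig12(s.q025),
                        "q975": _sig12(s.q975),
                    }
                    for name, s in rep.mc.items()
                }
            out["sites"][site] = entry
        return out

    def to_tidy_frame(self) -> pd.DataFrame:
        """Human-readable tidy table (display rounding applied)."""
        rows = []
        for site, rep in self.sites.items():
            nue = rep.inputs.constants.nue
            for name, q in rep.lines().items():
                units, _ = LINE_META[name]
                rows.append(
                    {
                        "site": site,
                        "nue": nue,
                        "line_item": name,
                        "value": round_for_display(name, q.value),
                        "se": round_for_display(name, q.se),
                        "units": units,
                    }
                )
            for g_nue, q in rep.sensitivity:
                rows.append(
                    {
                        "site": site,
                        "nue": g_nue,
                        "line_item": "net_c_loss",
                        "value": round_for_display("net_c_loss", q.value),
                        "se": round_for_display("net_c_loss", q.se),
                        "units": "kg C ha-1",
                    }
                )
        return pd.DataFrame(rows)


def run_budget(config: RunConfig, with_mc: bool = True) -> BudgetReport:
    """Execute the full pipeline for a validated run configuration.

    Reads and validates every table before any computation, reduces them
    to site inputs, evaluates the budget, the NUE sensitivity scan and
    (optionally) the Monte-Carlo twin, and — when ``config.out_dir`` is
    set — writes ``report.json`` and ``closs_report.csv``.
    """
    tables = {
        "plots": read_measurements(config.plots_csv, "plots"),
        "mesocosm": read_measurements(config.mesocosm_csv, "mesocosm"),
        "water": read_measurements(config.water_csv, "water"),
        "isotope": read_measurements(config.isotope_csv, "isotope"),
        "fallow": read_measurements(config.fallow_csv, "fallow"),
    }
    site_inputs = site_inputs_from_tables(tables, config)
    reports: dict[str, SiteReport] = {}
    for site, inputs in site_inputs.items():
        budget, closs = run_site(inputs, se_mode=config.se_mode)
        sens = nue_sensitivity(inputs, config.nue_grid, se_mode=config.se_mode)
        mc = (
            monte_carlo_budget(
                inputs,
                n_draws=config.mc_draws,
                seed=config.mc_seed,
                truncate_negative=config.truncate_negative,
            )
            if with_mc
            else None
        )
        reports[site] = SiteReport(inputs, budget, closs, sens, mc)
    report = BudgetReport(
        sites=reports,
        provenance={
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "mc_seed": config.mc_seed,
            "se_mode": config.se_mode,
        },
    )
    if config.out_dir is not None:
        write_report(report, config.out_dir)
    return report


def write_report(report: BudgetReport, out_dir: "str | Path") -> Path:
    """Write ``report.json`` (full precision) and ``closs_report.csv`` (rounded)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(
        json.dumps(report.to_json_dict(), indent=2, sort_keys=True) + "\n"
    )
    report.to_tidy_frame().to_csv(out_dir / "closs_report.csv", index=False)
    return out_dir


# ---------------------------------------------------------------------------
# Packaged fixture


def load_twitchell_2012() -> tuple[dict[str, SiteInputs], dict]:
    """Published site-level inputs for the two Twitchell Island rice fields.

    Returns per-site :class:`SiteInputs` built from the packaged summary
    table (site means ± SE of every budget input) plus the raw metadata
    mapping.  The fallow residue-mineralization line is stored as an
    already-differenced quantity, hence
    :meth:`FallowMeasurements.from_net_mineralization`.
    """
    ref = resources.files("peatbudget") / "data" / "twitchell_2012.yaml"
    meta = yaml.safe_load(ref.read_text())
    consts = BudgetConstants(**meta["constants"])
    inputs: dict[str, SiteInputs] = {}
    for site, vals in meta["sites"].items():
        q = lambda key, units="kg N ha-1": Quantity(  # noqa: E731
            float(vals[key]["value"]), float(vals[key].get("se", 0.0)), units
        )
        fallow = FallowMeasurements.from_net_mineralization(
            q("residue_min_fallow"), q("soil_no3_at_flooding")
        )
        profile = SoilProfile(
            cn_ratio=float(vals["cn_ratio"]),
            bulk_density_g_cm3=float(vals["bulk_density_g_cm3"]),
            som_pct_c=float(meta["som_pct_c"]),
            f_min=float(meta["f_min"]),
        )
        inputs[str(site)] = SiteInputs(
            uptake_0n=q("uptake_0n"),
            ndr=q("ndr"),
            ndsw=q("ndsw"),
            ndgw=q("ndgw"),
            fallow=fallow,
            residue_c_input=q("residue_c_input", "kg C ha-1"),
            profile=profile,
            constants=consts,
        )
    return inputs, meta
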