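"""Synthetic measurement campaigns and parameter recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from peatbudget.closs import run_site
from peatbudget.io import site_inputs_from_tables
from peatbudget.synthetic import (
    SiteScenario,
    analysis_settings,
    closed_form_truth,
    generate,
)


def estimate(scenario, seed=None):
    """Generate a campaign and push it through the estimation pipeline."""
    if seed is not None:
        scenario = dataclasses.replace(scenario, seed=seed)
    ds = generate(scenario)
    settings = analysis_settings(scenario)
    return site_inputs_from_tables(ds.tables, settings)[scenario.site]


class TestGeneration:
    def test_same_scenario_same_seed_identical(self, scenario):
        a, b = generate(scenario), generate(scenario)
        for name in a.tables:
            pd.testing.assert_frame_equal(a.tables[name], b.tables[name])
        assert a.truth == b.truth

    def test_written_files_are_byte_identical(self, scenario, tmp_path):
        d1 = generate(scenario).write(tmp_path / "a")
        d2 = generate(scenario).write(tmp_path / "b")
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_tables_cover_all_pipeline_schemas(self, scenario):
        ds = generate(scenario)
        assert set(ds.tables) == {"plots", "isotope", "mesocosm", "water", "fallow"}
        assert len(ds.tables["plots"]) == scenario.n_plots
        assert len(ds.tables["mesocosm"]) == 2 * scenario.n_mesocosms

    def test_water_concentrations_nonnegative(self):
        sc = SiteScenario(seed=3, water_conc_mean=0.05, water_conc_sd=0.5)
        water = generate(sc).tables["water"]
        assert (water[["nh4_n_mg_l", "no3_n_mg_l"]].to_numpy() >= 0).all()

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ValueError):
            SiteScenario(n_plots=1)
        with pytest.raises(ValueError):
            SiteScenario(true_fndr=1.5)

    def test_truth_written_alongside_data(self, scenario, tmp_path):
        out = generate(scenario).write(tmp_path)
        assert (out / "truth.json").exists()


class TestNoiseFreeLimit:
    def test_pipeline_recovers_closed_form_exactly_without_noise(self, quiet):
        sc = SiteScenario(
            seed=9,
            uptake_0n_sd=0,
            residue_uptake_sd=0,
            tiller_atom_pct_sd=0,
            mesocosm_sd=0,
            water_conc_sd=0,
            fallow_residue_sd=0,
            soil_no3_sd=0,
            residue_c_sd=0,
        )
        inputs = estimate(sc)
        budget, closs = run_site(inputs, se_mode="consistent")
        truth_b, truth_c = closed_form_truth(sc)
        assert budget.peat_total_n.value == pytest.approx(
            truth_b.peat_total_n.value, abs=1e-9
        )
        assert closs.net_c_loss.value == pytest.approx(
            truth_c.net_c_loss.value, abs=1e-9
        )


class TestClosedFormTruth:
    def test_site1_like_defaults_reach_published_magnitudes(self, scenario):
        _, closs = closed_form_truth(scenario)
        assert closs.net_c_loss.value == pytest.approx(2473, abs=2)
        assert round(closs.subsidence_cm_yr.value, 2) == 0.11

    def test_break_even_scenario_nets_zero(self):
        sc = SiteScenario(nue_true=1.0)
        balanced = dataclasses.replace(
            sc,
            residue_n_fall_mean=sc.residue_n_spring_mean,  # no fallow residue release
            soil_no3_mean=0.0,
        )
        # residue C set to exactly offset mineralized C
        b2, _ = closed_form_truth(balanced)
        offset = dataclasses.replace(
            balanced, residue_c_mean=b2.nmin_total.value * sc.cn_ratio
        )
        _, c3 = closed_form_truth(offset)
        assert c3.net_c_loss.value == pytest.approx(0, abs=1e-9)

    def test_doubling_cn_doubles_c_mineralized(self, scenario):
        _, c1 = closed_form_truth(scenario)
        _, c2 = closed_form_truth(
            dataclasses.replace(scenario, cn_ratio=2 * scenario.cn_ratio)
        )
        assert c2.c_mineralized.value == pytest.approx(2 * c1.c_mineralized.value)


N_RECOVERY_REPS = 200


@pytest.fixture(scope="module")
def recovery():
    """200 simulated campaigns pushed through the estimation pipeline."""
    import warnings

    sc = SiteScenario(seed=0)
    truth_b, _ = closed_form_truth(sc)
    ests = np.empty(N_RECOVERY_REPS)
    fndrs = np.empty(N_RECOVERY_REPS)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(N_RECOVERY_REPS):
            inputs = estimate(sc, seed=seed)
            b, _ = run_site(inputs, se_mode="consistent")
            ests[seed] = b.peat_total_n.value
            # implied fndr estimate from the ndr line
            fndrs[seed] = inputs.ndr.value / (
                sc.residue_uptake_mean * sc.proportion_labeled
            )
    return sc, truth_b, ests, fndrs


class TestParameterRecovery:
    def test_peat_total_estimator_unbiased(self, recovery):
        _, truth_b, ests, _ = recovery
        truth = truth_b.peat_total_n
        assert abs(ests.mean() - truth.value) < 0.5 * truth.se

    def test_nominal_coverage_of_theoretical_interval(self, recovery):
        """Across replicates, the estimate falls within ±1.96 theoretical SEs
        of truth ~95% of the time (the SE from the scenario's known noise
        model, free of small-sample SE-estimation inflation)."""
        _, truth_b, ests, _ = recovery
        truth = truth_b.peat_total_n
        coverage = np.mean(np.abs(ests - truth.value) <= 1.96 * truth.se)
        assert 0.91 <= coverage <= 0.99

    def test_fndr_estimate_unbiased(self, recovery):
        sc, _, _, fndrs = recovery
        se_of_mean = fndrs.std(ddof=1) / np.sqrt(len(fndrs))
        assert abs(fndrs.mean() - sc.true_fndr) < 4 * se_of_mean
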