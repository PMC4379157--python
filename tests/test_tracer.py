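"""¹⁵N pool-dilution accounting."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from peatbudget.tracer import (
    InvalidTracerError,
    ResidueApplication,
    TracerRangeWarning,
    TracerResult,
    atom_percent_for_fraction,
    fndr_from_replicates,
    fraction_n_derived_from_residue,
    n_derived_from_residue,
    ndr_from_replicates,
    percent_loss,
    percent_recovered,
)

BG = 0.3673
INPUT = 9.0693


class TestFndr:
    @pytest.mark.parametrize(
        "sample,expected",
        [
            (BG, 0.0),          # at background
            (INPUT, 1.0),       # at input enrichment
            (1.2375, 0.1000),   # 10 % mixing
        ],
    )
    def test_two_pool_mixing(self, sample, expected):
        assert fraction_n_derived_from_residue(sample, BG, INPUT) == pytest.approx(
            expected, abs=5e-5
        )

    def test_degenerate_tracer_rejected(self):
        with pytest.raises(InvalidTracerError):
            fraction_n_derived_from_residue(0.4, BG, BG)

    def test_sample_below_background_warns_not_clamps(self):
        with pytest.warns(TracerRangeWarning):
            f = fraction_n_derived_from_residue(0.30, BG, INPUT)
        assert f < 0  # raw value preserved

    @given(st.floats(0, 1))
    def test_round_trip_through_forward_model(self, true_fndr):
        sample = atom_percent_for_fraction(true_fndr, BG, INPUT)
        assert fraction_n_derived_from_residue(sample, BG, INPUT) == pytest.approx(
            true_fndr, abs=1e-12
        )

    @given(st.floats(0.4, 9.0), st.floats(0.4, 9.0))
    def test_strictly_increasing_in_sample_enrichment(self, s1, s2):
        f1 = fraction_n_derived_from_residue(s1, BG, INPUT)
        f2 = fraction_n_derived_from_residue(s2, BG, INPUT)
        assert (s1 < s2) == (f1 < f2) or s1 == s2


class TestNdr:
    def test_zero_fraction_zero_flux(self):
        assert n_derived_from_residue(0, 135, 0.2615) == 0.0

    def test_residue_flux_at_study_rates(self):
        # 10 % mixing, 135 kg uptake, 1310/5010 labelled share
        assert n_derived_from_residue(0.10, 135, 1310 / 5010) == pytest.approx(
            3.53, abs=0.005
        )

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            n_derived_from_residue(0.1, -1, 0.5)
        with pytest.raises(ValueError):
            n_derived_from_residue(0.1, 10, 0.0)


class TestRecoveryAndLoss:
    @pytest.mark.parametrize(
        "fndr,pool,applied,expected",
        [
            (0.0, 500, 12, 0.0),
            (0.10, 120, 12, 100.0),
            (0.05, 120, 12, 50.0),  # inside the 50-70 % soil-recovery band
        ],
    )
    def test_percent_recovered(self, fndr, pool, applied, expected):
        assert percent_recovered(fndr, pool, applied) == pytest.approx(expected)

    def test_zero_applied_rejected(self):
        with pytest.raises(ValueError):
            percent_recovered(0.1, 120, 0)

    @pytest.mark.parametrize(
        "above,below,expected", [(0, 0, 100), (30, 60, 10), (16, 60, 24)]
    )
    def test_percent_loss(self, above, below, expected):
        assert percent_loss(above, below) == pytest.approx(expected)

    def test_overshoot_flagged_not_clamped(self):
        with pytest.warns(TracerRangeWarning):
            assert percent_loss(60, 50) == pytest.approx(-10)

    @given(st.floats(0, 0.1), st.floats(50, 500), st.floats(50, 500))
    def test_mass_balance_closes_exactly(self, fndr, above_pool, below_pool):
        applied = 12.0
        above = percent_recovered(fndr, above_pool, applied)
        below = percent_recovered(fndr, below_pool, applied)
        if above + below <= 100:
            loss = percent_loss(above, below)
            assert above + below + loss == pytest.approx(100, abs=1e-9)

    def test_tracer_result_enforces_closure(self):
        TracerResult(0.1, 1.9, 16.0, 60.0, 24.0)
        with pytest.raises(ValueError):
            TracerResult(0.1, 1.9, 16.0, 60.0, 30.0)


class TestReplicateHandling:
    def test_fndr_averaged_after_per_replicate_computation(self):
        samples = [atom_percent_for_fraction(f, BG, INPUT) for f in (0.04, 0.05, 0.06, 0.05)]
        q = fndr_from_replicates(samples, BG, INPUT)
        assert q.value == pytest.approx(0.05, abs=1e-12)
        assert q.se > 0

    def test_ndr_pairs_tillers_with_microplot_uptake(self):
        samples = [atom_percent_for_fraction(0.05, BG, INPUT)] * 4
        q = ndr_from_replicates(samples, [130, 140, 130, 140], BG, INPUT, 1310 / 5010)
        assert q.value == pytest.approx(0.05 * 135 * 1310 / 5010, rel=1e-9)

    def test_mismatched_replicates_rejected(self):
        with pytest.raises(ValueError):
            ndr_from_replicates([1.0, 1.1], [100], BG, INPUT, 0.5)


class TestResidueApplication:
    def test_labelled_share(self):
        app = ResidueApplication(1310, 3700, 12, 35, 41, 35, INPUT, BG)
        assert app.proportion_labeled == pytest.approx(1310 / 5010)
        assert app.applied_15n_kg_ha == 12

    def test_empty_mixture_rejected(self):
        with pytest.raises(ValueError):
            ResidueApplication(0, 0, 0, 0, 41, 35, INPUT, BG)
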