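"""Annual N-budget ledger assembly."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from peatbudget.budget import (
    BudgetConstants,
    FallowMeasurements,
    annual_mineralization,
    assemble_budget,
    fallow_peat_mineralization,
    growing_season_mineralization,
    peat_total_n,
    residue_n_mineralized_fallow,
    surface_peat_n,
)
from peatbudget.quantity import NegativeValueWarning, Quantity

U = "kg N ha-1"


def q(value, se=0.0):
    return Quantity(value, se, U)


CONSTS = BudgetConstants()


class TestSurfacePeat:
    def test_site1_ledger(self):
        out = surface_peat_n(q(185.0), q(1.9), q(2.9), q(61.7), CONSTS)
        assert out.value == pytest.approx(87.5)

    def test_site2_ledger(self):
        out = surface_peat_n(q(167.0), q(3.8), q(3.0), q(39.6), CONSTS)
        assert out.value == pytest.approx(89.6)

    def test_uptake_equal_to_sources_gives_zero(self):
        out = surface_peat_n(q(97.5), q(1.9), q(2.9), q(61.7), CONSTS)
        assert out.value == pytest.approx(0.0)

    def test_negative_residual_warns(self):
        with pytest.warns(NegativeValueWarning):
            surface_peat_n(q(50.0), q(1.9), q(2.9), q(61.7), CONSTS)


class TestPeatTotal:
    @pytest.mark.parametrize(
        "surface,gw,expected", [(87.5, 61.7, 149.2), (89.6, 39.6, 129.2)]
    )
    def test_groundwater_attributed_to_peat(self, surface, gw, expected):
        assert peat_total_n(q(surface), q(gw)).value == pytest.approx(expected)

    def test_se_combines_line_ses(self):
        assert peat_total_n(q(87.5, 13.5), q(61.7, 9.0)).se == pytest.approx(
            16.2, abs=0.05
        )


class TestGrowingSeasonMineralization:
    @pytest.mark.parametrize("total,expected", [(149.2, 298.4), (129.2, 258.4)])
    def test_nue_adjustment(self, total, expected):
        out = growing_season_mineralization(q(total), 0.5)
        assert out.value == pytest.approx(expected)

    def test_nue_one_is_identity(self):
        assert growing_season_mineralization(q(149.2, 16.2), 1.0) == q(149.2, 16.2)

    def test_nonpositive_nue_rejected(self):
        with pytest.raises(ValueError):
            growing_season_mineralization(q(100), 0.0)

    @given(st.floats(0.05, 1.0), st.floats(0.05, 1.0))
    def test_strictly_decreasing_in_nue(self, nue1, nue2):
        v1 = growing_season_mineralization(q(149.2), nue1).value
        v2 = growing_season_mineralization(q(149.2), nue2).value
        assert (nue1 < nue2) == (v1 > v2) or nue1 == nue2


class TestFallowSeason:
    def test_no_residue_change_no_mineralization(self):
        f = FallowMeasurements(q(20.0, 1.0), q(20.0, 1.0), q(10.0))
        assert residue_n_mineralized_fallow(f).value == 0.0

    @pytest.mark.parametrize(
        "fall,spring,expected", [(37.2, 20.3, 16.9), (43.0, 22.0, 21.0)]
    )
    def test_overwinter_residue_release(self, fall, spring, expected):
        f = FallowMeasurements(q(fall), q(spring), q(20.3))
        assert residue_n_mineralized_fallow(f).value == pytest.approx(expected)

    @pytest.mark.parametrize(
        "no3,res,expected", [(20.3, 16.9, 3.4), (42.1, 21.0, 21.1)]
    )
    def test_peat_share_of_fallow_no3(self, no3, res, expected):
        f = FallowMeasurements(q(res), q(0.0), q(no3))
        assert fallow_peat_mineralization(f, q(res)).value == pytest.approx(expected)

    def test_residue_exceeding_no3_warns(self):
        f = FallowMeasurements(q(25.0), q(0.0), q(20.0))
        with pytest.warns(NegativeValueWarning):
            fallow_peat_mineralization(f, q(25.0))


class TestAnnualMineralization:
    @pytest.mark.parametrize(
        "growing,fallow,expected",
        [(298.4, 3.4, 301.8), (258.4, 21.1, 279.5), (0.0, 0.0, 0.0)],
    )
    def test_season_sum(self, growing, fallow, expected):
        assert annual_mineralization(q(growing), q(fallow)).value == pytest.approx(
            expected
        )


class TestAssembleBudget:
    def _fallow(self):
        return FallowMeasurements.from_net_mineralization(q(16.9, 1.3), q(20.3, 0.7))

    def test_full_site1_chain(self):
        b = assemble_budget(
            q(185.0, 10.0), q(1.9, 0.2), q(2.9, 1.3), q(61.7, 9.0), self._fallow()
        )
        assert b.surface_peat_n.value == pytest.approx(87.5)
        assert b.peat_total_n.value == pytest.approx(149.2)
        assert b.nmin_growing.value == pytest.approx(298.4)
        assert b.nmin_fallow.value == pytest.approx(3.4)
        assert b.nmin_total.value == pytest.approx(301.8)

    def test_ledger_closure(self):
        b = assemble_budget(
            q(185.0, 10.0), q(1.9, 0.2), q(2.9, 1.3), q(61.7, 9.0), self._fallow()
        )
        reconstructed = (
            b.ndr.value
            + b.ndsw.value
            + b.ndgw.value
            + b.n_deposition.value
            + b.n_fixation.value
            + b.surface_peat_n.value
        )
        assert reconstructed == pytest.approx(b.uptake_0n.value, abs=1e-9)

    def test_se_modes_agree_on_values_differ_on_se(self):
        args = (q(185.0, 10.0), q(1.9, 0.2), q(2.9, 1.3), q(61.7, 9.0), self._fallow())
        paper = assemble_budget(*args, se_mode="paper")
        consistent = assemble_budget(*args, se_mode="consistent")
        assert paper.peat_total_n.value == pytest.approx(
            consistent.peat_total_n.value
        )
        # paper convention counts the groundwater SE twice; consistent does not
        assert paper.peat_total_n.se == pytest.approx(16.24, abs=0.01)
        assert consistent.peat_total_n.se == pytest.approx(10.09, abs=0.01)

    def test_unknown_se_mode_rejected(self):
        with pytest.raises(ValueError):
            assemble_budget(
                q(185.0), q(1.9), q(2.9), q(61.7), self._fallow(), se_mode="bogus"
            )

    def test_constants_validation(self):
        with pytest.raises(ValueError):
            BudgetConstants(nue=0.0)
        with pytest.raises(ValueError):
            BudgetConstants(n_deposition=-1)
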