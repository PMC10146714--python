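import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thmrisk import risk


class TestSurfaceArea:
    def test_hand_values(self):
        assert risk.surface_area(65.0) == pytest.approx(267.0 / 155.0, rel=1e-12)
        assert risk.surface_area(55.0) == pytest.approx(227.0 / 145.0, rel=1e-12)

    def test_monotone_with_supremum(self):
        bws = np.linspace(40, 5000, 200)
        sas = risk.surface_area(bws)
        assert np.all(np.diff(sas) > 0)
        assert np.all(sas < 4.0)
        assert risk.surface_area(1e9) == pytest.approx(4.0, rel=1e-6)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            risk.surface_area(0.0)


class TestFormationRate:
    def test_zero_celsius(self):
        assert risk.formation_rate(0.0) == pytest.approx(0.0011, rel=1e-15)

    def test_forty_celsius(self):
        assert risk.formation_rate(40.0) == pytest.approx(0.0011 * math.exp(1.628), rel=1e-12)
        assert risk.formation_rate(40.0) == pytest.approx(0.0056030, rel=1e-4)

    def test_hot_cold_ratio(self):
        ratio = risk.formation_rate(40.0) / risk.formation_rate(15.0)
        assert ratio == pytest.approx(math.exp(0.0407 * 25.0), rel=1e-12)
        assert ratio == pytest.approx(2.7663, rel=1e-4)

    def test_out_of_range_guard(self):
        with pytest.raises(ValueError):
            risk.formation_rate(-5.0)
        with pytest.raises(ValueError):
            risk.formation_rate(150.0)


class TestHeatedConcentration:
    def test_zero_duration(self):
        assert risk.heated_concentration(10.0, 0.0, 40.0, 15.0) == pytest.approx(10.0)

    def test_equal_temperatures(self):
        assert risk.heated_concentration(10.0, 10.0, 25.0, 25.0) == pytest.approx(10.0)

    def test_hand_value(self):
        kh = 0.0011 * math.exp(0.0407 * 40)
        kc = 0.0011 * math.exp(0.0407 * 15)
        expected = 10.0 * math.exp((kh - kc) * 10.0)
        got = risk.heated_concentration(10.0, 10.0, 40.0, 15.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(10.3642, rel=1e-4)

    @settings(max_examples=50, deadline=None)
    @given(
        cw=st.floats(0, 100),
        t=st.floats(0, 60),
        cold=st.floats(0, 30),
        bump=st.floats(0, 50),
    )
    def test_property_heating_monotone(self, cw, t, cold, bump):
        hot = min(cold + bump, 100.0)
        chw = risk.heated_concentration(cw, t, hot, cold)
        assert chw >= cw - 1e-12
        if cw > 0 and t > 1e-6 and hot > cold + 1e-6:
            assert chw > cw


class TestOralDoses:
    def test_ingestion_hand_value(self):
        expected = 30.22 * 2 * 350 * 72 * 0.001 / (55 * 26280)
        got = risk.cdi_ingestion(30.22, 2.0, 350.0, 72.0, 55.0, 26280.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.0537e-3, rel=1e-4)

    def test_ingestion_zero_and_linear(self):
        assert risk.cdi_ingestion(0.0, 2.0, 350.0, 72.0, 55.0, 26280.0) == 0.0
        one = risk.cdi_ingestion(10.0, 2.0, 350.0, 72.0, 55.0, 26280.0)
        two = risk.cdi_ingestion(20.0, 2.0, 350.0, 72.0, 55.0, 26280.0)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_ingestion_invalid(self):
        with pytest.raises(ValueError):
            risk.cdi_ingestion(10.0, 2.0, 350.0, 72.0, 0.0, 26280.0)

    def test_dermal_hand_value(self):
        expected = 30.22 * 1.644 * 3.057e-5 * 10 * 0.74 * 331.67 * 72 / (60 * 25550)
        got = risk.cdi_dermal(
            30.22, 1.644, 3.057e-5, 10.0, 0.74, 331.67, 72.0, 60.0, 25550.0
        )
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.750e-4, rel=1e-3)

    def test_dermal_impermeable_and_linear_in_t(self):
        args = (30.22, 1.644, 0.0, 10.0, 0.74, 331.67, 72.0, 60.0, 25550.0)
        assert risk.cdi_dermal(*args) == 0.0
        base = risk.cdi_dermal(30.22, 1.644, 3e-5, 10.0, 0.74, 331.67, 72.0, 60.0, 25550.0)
        double = risk.cdi_dermal(30.22, 1.644, 3e-5, 20.0, 0.74, 331.67, 72.0, 60.0, 25550.0)
        assert double == pytest.approx(2 * base, rel=1e-12)


class TestInhalationExposure:
    def test_exposure_time(self):
        assert risk.exposure_time(10.0, 0.74) == pytest.approx(0.123333, rel=1e-4)
        assert risk.exposure_time(10.0, 0.0) == 0.0
        assert risk.exposure_time(60.0, 1.0) == pytest.approx(1.0, rel=1e-15)

    def test_exposure_concentration_hand_value(self):
        expected = 100 * 0.1233 * 330 * 72 / 630720
        got = risk.exposure_concentration(100.0, 0.1233, 330.0, 72.0, 630720.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.46449, rel=1e-3)

    def test_zero_exposure_time(self):
        assert risk.exposure_concentration(100.0, 0.0, 330.0, 72.0, 630720.0) == 0.0

    def test_continuous_exposure_identity(self):
        # round-the-clock exposure over the full averaging period: EC == Cair
        ed = 10.0
        at_hours = ed * 365.0 * 24.0
        got = risk.exposure_concentration(123.0, 24.0, 365.0, ed, at_hours)
        assert got == pytest.approx(123.0, rel=1e-12)

    def test_invalid_at(self):
        with pytest.raises(ValueError):
            risk.exposure_concentration(1.0, 1.0, 330.0, 72.0, 0.0)


class TestRiskConversion:
    def test_oral_product(self):
        assert risk.cancer_risk_oral(3.55e-4, 0.084) == pytest.approx(2.982e-5, rel=1e-3)
        assert risk.cancer_risk_oral(0.0, 0.084) == 0.0
        assert risk.cancer_risk_oral(1.7e-4, 1.0) == pytest.approx(1.7e-4)

    def test_inhalation_product(self):
        assert risk.cancer_risk_inhalation(0.1, 2.3e-5) == pytest.approx(2.3e-6, rel=1e-12)
        assert risk.cancer_risk_inhalation(0.1, 0.0) == 0.0
        one = risk.cancer_risk_inhalation(1.0, 3.7e-5)
        assert risk.cancer_risk_inhalation(2.0, 3.7e-5) == pytest.approx(2 * one)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            risk.cancer_risk_oral(-1.0, 0.05)
        with pytest.raises(ValueError):
            risk.cancer_risk_inhalation(-1.0, 1e-5)


class TestTotalRisk:
    @staticmethod
    def _grid(ing, der, inh):
        # per-route totals split arbitrarily across species; sums must agree
        def split(total):
            return {"tcm": 0.1 * total, "bdcm": 0.4 * total, "dbcm": 0.45 * total, "tbm": 0.05 * total}

        return {"ingestion": split(ing), "dermal": split(der), "inhalation": split(inh)}

    def test_route_sum_reproduces_printed_total(self):
        grid = self._grid(48.73e-6, 8.69e-6, 1.11e-6)
        totals = risk.total_risk(grid)
        assert totals.grand_total == pytest.approx(58.53e-6, rel=1e-12)
        assert totals.by_route["ingestion"] == pytest.approx(48.73e-6, rel=1e-12)

    def test_all_zero(self):
        totals = risk.total_risk(self._grid(0.0, 0.0, 0.0))
        assert totals.grand_total == 0.0

    def test_conservation(self):
        totals = risk.total_risk(self._grid(1e-5, 2e-6, 5e-7))
        assert sum(totals.by_route.values()) == pytest.approx(totals.grand_total, rel=1e-12)
        assert sum(totals.by_species.values()) == pytest.approx(totals.grand_total, rel=1e-12)

    def test_missing_cells_rejected(self):
        grid = self._grid(1e-5, 2e-6, 5e-7)
        del grid["dermal"]
        with pytest.raises(KeyError, match="dermal"):
            risk.total_risk(grid)
        grid = self._grid(1e-5, 2e-6, 5e-7)
        del grid["inhalation"]["tbm"]
        with pytest.raises(KeyError, match="tbm"):
            risk.total_risk(grid)

    def test_permutation_invariance(self):
        grid = self._grid(1e-5, 2e-6, 5e-7)
        reordered = {route: dict(reversed(list(cells.items()))) for route, cells in reversed(list(grid.items()))}
        a = risk.total_risk(grid)
        b = risk.total_risk(reordered)
        assert a.grand_total == pytest.approx(b.grand_total, rel=1e-15)


class TestHandOracle:
    """Every equation matches an independent inline evaluation on random tuples."""

    def test_twenty_random_tuples(self):
        rng = np.random.default_rng(2718)
        for _ in range(20):
            cw = rng.uniform(0.1, 60)
            ir = rng.uniform(0.5, 4)
            ef = rng.uniform(250, 365)
            ed = rng.uniform(30, 80)
            bw = rng.uniform(40, 90)
            at = rng.uniform(10_000, 30_000)
            t = rng.uniform(2, 30)
            f = rng.uniform(0.3, 1.5)
            sa = rng.uniform(1.2, 2.2)
            pd_skin = rng.uniform(1e-5, 5e-5)
            hot = rng.uniform(30, 50)
            cold = rng.uniform(5, 25)
            cair = rng.uniform(1, 500)
            iur = rng.uniform(1e-7, 5e-5)
            csf = rng.uniform(1e-3, 0.2)

            assert risk.surface_area(bw) == pytest.approx((4 * bw + 7) / (bw + 90), rel=1e-10)
            kh = 0.0011 * math.exp(0.0407 * hot)
            kc = 0.0011 * math.exp(0.0407 * cold)
            assert risk.heated_concentration(cw, t, hot, cold) == pytest.approx(
                cw * math.exp((kh - kc) * t), rel=1e-10
            )
            assert risk.cdi_ingestion(cw, ir, ef, ed, bw, at) == pytest.approx(
                cw * ir * ef * ed * 0.001 / (bw * at), rel=1e-10
            )
            assert risk.cdi_dermal(cw, sa, pd_skin, t, f, ef, ed, bw, at) == pytest.approx(
                cw * sa * pd_skin * t * f * ef * ed / (bw * at), rel=1e-10
            )
            et = t * f / 60.0
            assert risk.exposure_time(t, f) == pytest.approx(et, rel=1e-10)
            assert risk.exposure_concentration(cair, et, ef, ed, at * 24) == pytest.approx(
                cair * et * ef * ed / (at * 24), rel=1e-10
            )
            cdi = cw * ir * ef * ed * 0.001 / (bw * at)
            assert risk.cancer_risk_oral(cdi, csf) == pytest.approx(cdi * csf, rel=1e-10)
            ec = cair * et * ef * ed / (at * 24)
            assert risk.cancer_risk_inhalation(ec, iur) == pytest.approx(ec * iur, rel=1e-10)
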