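"""Region integration, internal-standard quantitation, LOQ and histograms."""

import numpy as np
import pytest

import honeynmr as h
from honeynmr.exceptions import CalibrationError
from honeynmr.panel import IntegrationRegion


def _unit_spectrum(n=101, lo=0.0, hi=10.0, value=1.0):
    return h.Spectrum(np.linspace(lo, hi, n), np.full(n, value), referenced=True)


class TestIntegrateRegion:
    def test_zero_spectrum(self):
        s = _unit_spectrum(value=0.0)
        assert h.integrate_region(s, IntegrationRegion("x", 2.0, 4.0, 1.0)) == 0.0

    def test_point_count_inclusive_endpoints(self):
        # grid 0,0.1,...,10; region [2.0, 3.6] covers points 2.0..3.6 -> 17 points
        s = _unit_spectrum(n=101, lo=0.0, hi=10.0)
        area = h.integrate_region(s, IntegrationRegion("x", 2.0, 3.6, 1.0))
        assert area == 17.0

    def test_lorentzian_riemann_sum_matches_analytic(self):
        amp, gamma = 3.0, 0.02
        ppm = np.linspace(-5, 5, 20001)
        delta = ppm[1] - ppm[0]
        s = h.Spectrum(ppm, amp * gamma**2 / (ppm**2 + gamma**2), referenced=True)
        area = h.integrate_region(s, IntegrationRegion("x", -4.0, 4.0, 1.0))
        assert area == pytest.approx(np.pi * amp * gamma / delta, rel=0.01)

    def test_unreferenced_or_out_of_axis_errors(self):
        s = _unit_spectrum()
        s.referenced = False
        with pytest.raises(CalibrationError):
            h.integrate_region(s, IntegrationRegion("x", 2.0, 4.0, 1.0))
        s.referenced = True
        with pytest.raises(ValueError, match="outside"):
            h.integrate_region(s, IntegrationRegion("x", 9.0, 11.0, 1.0))


class TestQuantify:
    def test_proline_worked_example(self, panel):
        """1 umol in 1 mL over 50 mg honey: 1 mM x 115.13 g/mol x 20 = 2302.6 mg/kg."""
        s = h.simulate_spectrum(panel, {"proline": 1.0}, h.LineshapeParams(), seed=0)
        q = h.quantify(s, panel)
        assert q.concentrations["proline"] == pytest.approx(2302.6, rel=0.01)

    def test_glucose_worked_example(self, panel):
        s = h.simulate_spectrum(panel, {"glucose": 10.0}, h.LineshapeParams(), seed=0)
        q = h.quantify(s, panel)
        assert q.units["glucose"] == "g_per_100g"
        assert q.concentrations["glucose"] == pytest.approx(3.60, rel=0.01)

    def test_tmsp_only_all_below_loq(self, panel):
        s = h.simulate_spectrum(panel, {}, h.LineshapeParams(), seed=0)
        q = h.quantify(s, panel)
        assert all(q.loq_flags.values())

    def test_scale_invariance(self, panel, rng):
        conc = {a.analyte_id: float(rng.uniform(1, 20)) for a in panel.analytes}
        s = h.simulate_spectrum(panel, conc, h.LineshapeParams(), seed=0)
        q1 = h.quantify(s, panel)
        s2 = s.copy()
        s2.intensity *= 123.456
        q2 = h.quantify(s2, panel)
        for aid in conc:
            assert q2.raw_mM[aid] == pytest.approx(q1.raw_mM[aid], rel=1e-10)

    def test_linearity_with_fixed_tmsp(self, panel):
        conc = {"proline": 1.5, "fructose": 30.0, "maltose": 4.0}
        q1 = h.quantify(h.simulate_spectrum(panel, conc, h.LineshapeParams(), seed=0), panel)
        q2 = h.quantify(
            h.simulate_spectrum(panel, {k: 2 * v for k, v in conc.items()},
                                h.LineshapeParams(), seed=0),
            panel,
        )
        for aid in conc:
            assert q2.raw_mM[aid] == pytest.approx(2 * q1.raw_mM[aid], rel=1e-3)

    def test_unit_identity(self, panel):
        """g/100 g is exactly mg/kg / 1e4 for the same underlying molarity."""
        s = h.simulate_spectrum(panel, {"fructose": 50.0}, h.LineshapeParams(), seed=0)
        q = h.quantify(s, panel)
        fru = panel.analyte("fructose")
        mgkg = q.raw_mM["fructose"] * fru.molecular_weight * 20.0
        assert q.concentrations["fructose"] == pytest.approx(mgkg / 1e4, rel=1e-12)

    def test_zero_tmsp_is_calibration_error(self, panel):
        s = h.Spectrum(np.linspace(-0.5, 9.5, 2048), np.zeros(2048), referenced=True)
        with pytest.raises(CalibrationError):
            h.quantify(s, panel)

    def test_nominal2_round_trip_self_consistent(self):
        """Fructose recovery holds under either proton-count convention."""
        p2 = h.default_panel(fructose_proton_mode="nominal2")
        s = h.simulate_spectrum(p2, {"fructose": 25.0}, h.LineshapeParams(), seed=0)
        q = h.quantify(s, p2)
        assert q.raw_mM["fructose"] == pytest.approx(25.0, rel=5e-3)


class TestAverageTriplicates:
    def _result(self, panel, value, sample="A"):
        aid = "proline"
        return h.QuantResult(
            sample_id=sample,
            concentrations={aid: value},
            raw_mM={aid: value / (115.13 * 20)},
            loq_flags={aid: value < 230.0},
            tmsp_area=100.0,
            units={aid: "mg_per_kg"},
        )

    def test_identical_replicates(self, panel):
        rs = [self._result(panel, 500.0) for _ in range(3)]
        avg = h.average_triplicates(rs, panel)
        assert avg.concentrations["proline"] == 500.0
        assert avg.per_analyte_sd["proline"] == 0.0

    def test_hand_mean_and_sd(self, panel):
        rs = [self._result(panel, v) for v in (1.0, 2.0, 3.0)]
        avg = h.average_triplicates(rs, panel)
        assert avg.concentrations["proline"] == pytest.approx(2.0)
        assert avg.per_analyte_sd["proline"] == pytest.approx(1.0)
        assert avg.loq_flags["proline"]  # mean 2 mg/kg < 230 mg/kg LOQ

    def test_single_replicate_has_no_sd(self, panel):
        avg = h.average_triplicates([self._result(panel, 500.0)], panel)
        assert avg.per_analyte_sd is None

    def test_mixed_sample_ids_rejected(self, panel):
        with pytest.raises(ValueError, match="mixed"):
            h.average_triplicates(
                [self._result(panel, 1.0, "A"), self._result(panel, 1.0, "B")], panel
            )


class TestLOQ:
    def test_hand_example(self):
        assert h.loq_mgkg(0.01, 1, 1, 115.13) == pytest.approx(23.026)

    def test_doubling_protons_halves_loq(self):
        one = h.loq_mgkg(0.01, 1, 1, 100.0)
        two = h.loq_mgkg(0.01, 2, 1, 100.0)
        assert two == pytest.approx(one / 2)

    def test_nonpositive_penalty_rejected(self):
        with pytest.raises(Exception, match="multiplicity_penalty"):
            h.loq_mgkg(0.01, 1, 0, 100.0)


class TestFrequencyDistribution:
    def test_uniform_values_conserve_counts(self, rng):
        vals = rng.uniform(0, 100, size=500)
        table = h.frequency_distribution(vals, bin_width=0.01)
        assert len(table) == 100
        assert table["count"].sum() == 500

    def test_degenerate_all_equal(self):
        with pytest.warns(UserWarning, match="single bin"):
            table = h.frequency_distribution([1.0, 1.0, 1.0])
        assert len(table) == 1
        assert table["count"].iloc[0] == 3

    def test_loq_flag_matches_brute_force(self, rng):
        vals = rng.lognormal(3.0, 0.8, size=400)
        loq = float(np.median(vals))
        table = h.frequency_distribution(vals, bin_width=0.01, loq=loq)
        brute = sum(1 for hi in table["bin_high"] if hi <= loq)
        assert int(table["below_loq"].sum()) == brute
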