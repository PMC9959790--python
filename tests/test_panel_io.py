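"""Panel model, spectrum I/O and TMSP referencing."""

import importlib.resources

import numpy as np
import pytest

import honeynmr as h
from honeynmr.exceptions import PanelValidationError, SpectrumFormatError
from honeynmr.panel import AnalyteDefinition, IntegrationRegion, write_panel


class TestPanel:
    def test_default_panel_structure(self, panel):
        assert len(panel.analytes) == 33
        assert sorted(a.numbering for a in panel.analytes) == list(range(1, 34))
        fru = panel.analyte("fructose")
        assert fru.combine_rule == "sum_regions"
        assert len(fru.regions) == 3
        # tautomer-weighted proton equivalents of the three fructose regions
        assert panel.effective_protons(fru) == pytest.approx(2.618, abs=1e-9)
        ist = panel.internal_standard
        assert ist.regions[0].n_protons_effective == 9
        assert ist.regions[0].ppm_min < 0.0 < ist.regions[0].ppm_max

    def test_minor_sugar_anomeric_windows(self, panel):
        # H-1alpha windows of the minor sugars sit inside 5.15-5.55 ppm
        for aid in ("maltose", "sucrose", "kojibiose", "nigerose", "turanose", "trehalose"):
            r = panel.analyte(aid).regions[0]
            assert 5.15 <= r.ppm_min < r.ppm_max <= 5.55

    def test_regions_disjoint(self, panel):
        # required for the forward simulator round trip to be well-posed
        spans = sorted(
            (r.ppm_min, r.ppm_max, r.analyte_id)
            for a in [panel.internal_standard, *panel.analytes]
            for r in a.regions
        )
        for (_, hi, aid1), (lo, _, aid2) in zip(spans, spans[1:]):
            if aid1 == aid2:
                continue  # fructose regions are contiguous by design
            assert hi < lo, f"{aid1} overlaps {aid2}"

    def test_proline_loq_default(self, panel):
        assert panel.analyte("proline").loq == pytest.approx(230.0)

    def test_duplicate_analyte_id_rejected(self, panel):
        a = panel.analytes[0]
        with pytest.raises(PanelValidationError, match="duplicate"):
            h.AnalytePanel(
                analytes=[a, a], internal_standard=panel.internal_standard
            )

    def test_bad_tautomer_fractions_rejected(self, panel):
        with pytest.raises(PanelValidationError, match="sum to 1"):
            h.AnalytePanel(
                analytes=list(panel.analytes),
                internal_standard=panel.internal_standard,
                tautomer_fractions={"a": 0.5, "b": 0.5, "c": 0.0, "d": 0.1},
            )

    def test_region_invariants(self):
        with pytest.raises(PanelValidationError):
            IntegrationRegion("x", 2.0, 1.0, 1.0)
        with pytest.raises(PanelValidationError):
            IntegrationRegion("x", 1.0, 2.0, -1.0)
        with pytest.raises(PanelValidationError):
            AnalyteDefinition("x", "X", 1, 100.0, (), loq=1.0)

    @pytest.mark.parametrize("fmt", ["structured_config", "delimited_table"])
    def test_panel_round_trip(self, panel, tmp_path, fmt):
        ext = "yaml" if fmt == "structured_config" else "csv"
        path = tmp_path / f"panel.{ext}"
        write_panel(panel, path, fmt)
        assert h.load_panel(path, fmt) == panel

    def test_shipped_panel_file_matches_builder(self, panel):
        path = importlib.resources.files("honeynmr") / "data" / "default_panel.yaml"
        assert h.load_panel(str(path)) == panel

    def test_missing_field_names_the_field(self, tmp_path):
        (tmp_path / "p.yaml").write_text("analytes: []\n")
        with pytest.raises(PanelValidationError, match="internal_standard"):
            h.load_panel(tmp_path / "p.yaml")

    def test_nominal2_mode_rescales_fructose(self):
        p = h.default_panel(fructose_proton_mode="nominal2")
        assert p.effective_protons(p.analyte("fructose")) == pytest.approx(2.0)
        # other analytes untouched
        assert p.effective_protons(p.analyte("glucose")) == pytest.approx(1.0)


class TestSpectrumIO:
    def test_two_column_parse(self, tmp_path):
        rows = "\n".join(f"{x}\t{x * 2.0}" for x in range(10))
        path = tmp_path / "s.tsv"
        path.write_text(rows)
        s = h.read_spectrum(path)
        assert s.ppm.size == 10
        assert not s.referenced
        assert s.intensity[3] == 6.0

    def test_duplicate_ppm_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("1.0\t1\n1.0\t2\n2.0\t3\n")
        with pytest.raises(SpectrumFormatError, match="duplicated"):
            h.read_spectrum(path)

    def test_nan_intensity_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("1.0\t1\n2.0\tnan\n")
        with pytest.raises(SpectrumFormatError):
            h.read_spectrum(path)

    def test_descending_axis_stored_ascending(self):
        s = h.Spectrum(np.array([3.0, 2.0, 1.0]), np.array([30.0, 20.0, 10.0]))
        assert list(s.ppm) == [1.0, 2.0, 3.0]
        assert list(s.intensity) == [10.0, 20.0, 30.0]

    @pytest.mark.parametrize("dialect", ["two_column_text", "jcamp_dx"])
    def test_write_read_round_trip(self, tmp_path, dialect, rng):
        ppm = np.linspace(-0.5, 9.5, 512)
        s = h.Spectrum(ppm, rng.normal(size=512))
        path = tmp_path / "s.dx"
        h.write_spectrum(s, path, dialect)
        s2 = h.read_spectrum(path, dialect)
        np.testing.assert_allclose(s2.ppm, s.ppm, rtol=1e-9)
        np.testing.assert_allclose(s2.intensity, s.intensity, rtol=1e-9)


class TestReferencing:
    def test_offset_tmsp_peak_recentred(self, panel):
        s = h.simulate_spectrum(panel, {"proline": 1.0}, h.LineshapeParams(), seed=0)
        shifted = h.Spectrum(s.ppm + 0.02, s.intensity, referenced=False, meta=s.meta)
        ref = h.reference_spectrum(shifted)
        apex = ref.ppm[np.argmax(ref.intensity * ((ref.ppm > -0.1) & (ref.ppm < 0.1)))]
        assert abs(apex) <= ref.grid_step
        assert ref.referenced

    def test_idempotent_within_grid_step(self, panel):
        s = h.simulate_spectrum(panel, {}, h.LineshapeParams(), seed=0)
        r1 = h.reference_spectrum(s)
        r2 = h.reference_spectrum(r1)
        assert abs(r2.ppm[0] - r1.ppm[0]) <= r1.grid_step

    def test_flat_window_tie_breaks_with_warning(self):
        s = h.Spectrum(np.linspace(-0.2, 0.2, 41), np.zeros(41))
        with pytest.warns(UserWarning, match="tie"):
            ref = h.reference_spectrum(s)
        assert ref.referenced

    def test_window_outside_axis_errors(self):
        s = h.Spectrum(np.linspace(1.0, 2.0, 11), np.ones(11))
        with pytest.raises(ValueError, match="window"):
            h.reference_spectrum(s, search_window=(-0.1, 0.1))
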