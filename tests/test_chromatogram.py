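"""SEC trace rendering, integration, S/N statistic and detection limit."""

import numpy as np
import pytest

from fabsec.chromatogram import (NOT_DETECTED, Chromatogram, SpeciesWindow,
                                 default_calibration, detect_lod,
                                 integrate_window, percent_complex,
                                 read_calibration_yaml, read_chromatogram_csv,
                                 render_chromatogram, snr,
                                 write_calibration_yaml,
                                 write_chromatogram_csv)
from fabsec.species import ComplexSpecies, SpeciesClass
from fabsec.synth import GeneratorConfig, gen_titration


def gaussian_trace(center, sigma, area, t0=8.0, t1=22.0, dt=0.02):
    t = np.arange(t0, t1 + dt / 2, dt)
    y = area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return Chromatogram(t, y)


class TestIntegrateWindow:
    def test_flat_zero_trace(self):
        t = np.arange(8, 22, 0.02)
        q = integrate_window(Chromatogram(t, np.zeros_like(t)),
                             SpeciesWindow(SpeciesClass.DRUG_FAB, 14, 16))
        assert q.area == 0.0

    def test_unit_gaussian_fully_inside_window(self):
        chrom = gaussian_trace(15.0, 0.15, 1.0)
        q = integrate_window(chrom, SpeciesWindow(SpeciesClass.DRUG_FAB, 14, 16))
        assert q.area == pytest.approx(1.0, abs=1e-3)

    def test_whole_trace_window_is_total(self):
        chrom = gaussian_trace(15.0, 0.15, 2.5)
        q = integrate_window(chrom, SpeciesWindow(SpeciesClass.DRUG_FAB, 8.0, 22.0))
        assert q.percent_of_total == pytest.approx(1.0, abs=1e-9)

    def test_empty_window_rejected(self):
        chrom = gaussian_trace(15.0, 0.15, 1.0)
        with pytest.raises(ValueError):
            integrate_window(chrom, SpeciesWindow(SpeciesClass.DRUG_FAB, 30.0, 31.0))


class TestRender:
    def test_single_species_conserves_area(self, calibration):
        chrom = render_chromatogram([ComplexSpecies(1, 0, 2, 5.0)], calibration)
        w = next(w for w in calibration if w.species_class == SpeciesClass.DRUG_FAB)
        assert chrom.total_area() == pytest.approx(10.0, rel=1e-6)
        assert integrate_window(chrom, w).area == pytest.approx(10.0, rel=1e-2)

    def test_equal_fab_weighted_abundance_gives_equal_areas(self, calibration):
        chrom = render_chromatogram(
            [ComplexSpecies(1, 0, 2, 5.0), ComplexSpecies.free_fab(10.0)],
            calibration)
        wd = next(w for w in calibration if w.species_class == SpeciesClass.DRUG_FAB)
        wf = next(w for w in calibration if w.species_class == SpeciesClass.FAB488)
        # equal-width windows around each peak centre for an exact comparison
        a1 = integrate_window(chrom, SpeciesWindow(wd.species_class,
                                                   15.0 - 0.7, 15.0 + 0.7)).area
        a2 = integrate_window(chrom, SpeciesWindow(wf.species_class,
                                                   18.0 - 0.7, 18.0 + 0.7)).area
        assert a1 == pytest.approx(a2, rel=1e-6)

    def test_fab_count_weighting(self, calibration):
        """A 2-drug/1-ADA species with 4 Fabs at 1 nM fluoresces like the
        binary complex (2 Fabs) at 2 nM."""
        c1 = render_chromatogram([ComplexSpecies(2, 1, 4, 1.0)], calibration)
        c2 = render_chromatogram([ComplexSpecies(1, 0, 2, 2.0)], calibration)
        assert c1.total_area() == pytest.approx(c2.total_area(), rel=1e-9)

    def test_area_conservation_mixture(self, calibration):
        species = [ComplexSpecies.free_dye(30), ComplexSpecies.free_fab(100),
                   ComplexSpecies(1, 0, 2, 50), ComplexSpecies(1, 1, 2, 10),
                   ComplexSpecies(2, 1, 4, 5), ComplexSpecies(4, 3, 8, 2)]
        chrom = render_chromatogram(species, calibration)
        expected = sum(s.fluorescence_abundance for s in species)
        assert chrom.total_area() == pytest.approx(expected, rel=1e-6)

    def test_uncalibrated_species_rejected(self, calibration):
        cal = [w for w in calibration if w.species_class != SpeciesClass.FREE_DYE]
        with pytest.raises(ValueError):
            render_chromatogram([ComplexSpecies.free_dye(10)], cal)

    def test_overlapping_windows_rejected(self):
        cal = [SpeciesWindow(SpeciesClass.DRUG_FAB, 14, 16),
               SpeciesWindow(SpeciesClass.FAB488, 15, 18)]
        with pytest.raises(ValueError):
            render_chromatogram([], cal)

    def test_render_quantify_roundtrip(self, calibration):
        """Relative abundances recovered within 2 percentage points at
        default noise, over 5 seeds."""
        species = [ComplexSpecies.free_dye(30), ComplexSpecies.free_fab(400),
                   ComplexSpecies(1, 0, 2, 120)]
        total = sum(s.fluorescence_abundance for s in species)
        truth = {s.species_class: s.fluorescence_abundance / total for s in species}
        for seed in range(5):
            chrom = render_chromatogram(species, calibration, noise_sd=1.0,
                                        seed=seed)
            for w in calibration:
                if w.species_class in truth:
                    rec = integrate_window(chrom, w).percent_of_total
                    assert abs(rec - truth[w.species_class]) < 0.02


class TestSnr:
    def test_identical_traces_give_unity(self, complex_window):
        chrom = gaussian_trace(15.0, 0.18, 5.0)
        assert snr(chrom, chrom, complex_window) == pytest.approx(1.0)

    def test_percentage_ratio_arithmetic(self, complex_window):
        # sample: 3% of area in window; blank: 1.5% -> S/N = 2
        blank = gaussian_trace(18.0, 0.18, 98.5)
        blank.signal += gaussian_trace(15.0, 0.18, 1.5).signal
        sample = gaussian_trace(18.0, 0.18, 97.0)
        sample.signal += gaussian_trace(15.0, 0.18, 3.0).signal
        assert snr(sample, blank, complex_window) == pytest.approx(2.0, rel=1e-2)

    def test_scale_invariance(self, complex_window):
        sample = gaussian_trace(15.0, 0.18, 5.0)
        sample.signal += gaussian_trace(18.0, 0.18, 50.0).signal
        blank = gaussian_trace(15.0, 0.18, 1.0)
        blank.signal += gaussian_trace(18.0, 0.18, 50.0).signal
        base = snr(sample, blank, complex_window)
        scaled = snr(Chromatogram(sample.time, sample.signal * 37.2),
                     Chromatogram(blank.time, blank.signal * 0.004),
                     complex_window)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_mismatched_grids_rejected(self, complex_window):
        a = gaussian_trace(15, 0.18, 1.0)
        b = gaussian_trace(15, 0.18, 1.0, dt=0.05)
        with pytest.raises(ValueError):
            snr(a, b, complex_window)


class TestDetectLod:
    def _series(self, snr_values, concs, window):
        blank = gaussian_trace(window.center, 0.18, 1.0)
        blank.signal += gaussian_trace(18.0, 0.18, 99.0).signal
        pb = integrate_window(blank, window).percent_of_total
        out = []
        for s, c in zip(snr_values, concs):
            # build a sample whose window share is s times the blank's
            area = 99.0 * s * pb / (1 - s * pb)
            samp = gaussian_trace(window.center, 0.18, area)
            samp.signal += gaussian_trace(18.0, 0.18, 99.0).signal
            out.append((c, samp))
        return out, blank

    def test_first_crossing(self, complex_window):
        series, blank = self._series([1.1, 1.6, 4.0], [5, 10, 50], complex_window)
        assert detect_lod(series, blank, complex_window) == 10

    def test_not_detected_sentinel(self, complex_window):
        series, blank = self._series([1.05, 1.1, 1.2], [5, 10, 50], complex_window)
        assert detect_lod(series, blank, complex_window) == NOT_DETECTED

    def test_unsorted_rejected(self, complex_window):
        series, blank = self._series([1.1, 1.6], [10, 5], complex_window)
        with pytest.raises(ValueError):
            detect_lod(series, blank, complex_window)

    def test_default_titration_lod_is_10_nM(self, complex_window):
        data = gen_titration(GeneratorConfig(seed=123))
        assert detect_lod(data.samples, data.blank, complex_window) == 10.0


class TestPercentComplex:
    def test_no_ada_signal_gives_zero(self, calibration):
        chrom = render_chromatogram([ComplexSpecies.free_fab(100)], calibration)
        assert percent_complex(chrom, calibration) == pytest.approx(0.0, abs=1e-6)

    def test_all_signal_in_large_complex(self, calibration):
        chrom = render_chromatogram([ComplexSpecies(4, 3, 8, 10)], calibration)
        assert percent_complex(chrom, calibration) == pytest.approx(1.0, abs=1e-2)

    def test_thirty_percent_mixture(self, calibration):
        """30% of Fab-weighted signal in ADA species recovers 0.30 +/- 0.02."""
        species = [ComplexSpecies.free_fab(350), ComplexSpecies(1, 0, 2, 100),
                   ComplexSpecies(1, 1, 2, 60), ComplexSpecies(2, 1, 4, 28.75)]
        ada_w = sum(s.fluorescence_abundance for s in species
                    if s.species_class in (SpeciesClass.ADA1_DRUG1,
                                           SpeciesClass.ADA1_DRUG2))
        total = sum(s.fluorescence_abundance for s in species)
        assert ada_w / total == pytest.approx(0.30, abs=1e-3)
        chrom = render_chromatogram(species, calibration, noise_sd=1.0, seed=9)
        assert percent_complex(chrom, calibration) == pytest.approx(0.30, abs=0.02)

    def test_zero_trace_rejected(self, calibration):
        t = np.arange(8, 22, 0.02)
        with pytest.raises(ValueError):
            percent_complex(Chromatogram(t, np.zeros_like(t)), calibration)


def test_chromatogram_csv_roundtrip(tmp_path):
    chrom = gaussian_trace(15.0, 0.18, 5.0)
    path = tmp_path / "trace.csv"
    write_chromatogram_csv(chrom, path)
    back = read_chromatogram_csv(path)
    np.testing.assert_allclose(back.signal, chrom.signal)


def test_calibration_yaml_roundtrip(tmp_path, calibration):
    path = tmp_path / "cal.yaml"
    write_calibration_yaml(calibration, path)
    back = read_calibration_yaml(path)
    assert [(w.species_class, w.t_start, w.t_end) for w in back] == \
           [(w.species_class, w.t_start, w.t_end) for w in calibration]
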