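"""Windowed charge-series quantification and zero-charge projection."""

import numpy as np
import pytest

from photocascade.instrument import render_spectrum
from photocascade.quant import (
    ChargeSeries,
    integrate_series,
    integrate_series_set,
    ratio_trace,
    relative_abundance,
    zero_charge_project,
)
from photocascade.spectra import PROTON_MASS, LightSchedule, SpeciesDef, Spectrum, SpectrumSeries

from tests.conftest import make_instrument


def gaussian_spectrum(center, sigma, area=1.0, lo=900.0, hi=1100.0, step=0.02):
    mz = np.arange(lo, hi, step)
    inten = area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((mz - center) / sigma) ** 2)
    return Spectrum(mz, inten)


class TestIntegrateSeries:
    def test_zero_spectrum_integrates_to_zero(self):
        sp = SpeciesDef("x", 9990.0, 0.0, 10, 10, peak_fwhm=5.0)
        spec = Spectrum(np.arange(900.0, 1100.0), np.zeros(200))
        assert integrate_series(spec, ChargeSeries(sp)) == 0.0

    def test_unit_gaussian_in_3_sigma_window(self):
        """A ±3σ window captures 99.7% of a unit-area peak."""
        sigma = 2.0
        sp = SpeciesDef("x", 9990.0, 0.0, 10, 10, peak_fwhm=5.0)
        center = (9990.0 + 10 * PROTON_MASS) / 10
        spec = gaussian_spectrum(center, sigma)
        series = ChargeSeries(sp, windows=[(center, 3 * sigma)])
        assert integrate_series(spec, series) == pytest.approx(0.9973, abs=1e-3)

    def test_two_disjoint_species_areas(self):
        """Disjoint windows recover the 2:1 generating areas exactly."""
        a = SpeciesDef("a", 9990.0, 0.0, 10, 10, peak_fwhm=5.0)
        b = SpeciesDef("b", 10490.0, 0.0, 10, 10, peak_fwhm=5.0)
        ca, cb = (9990.0 + 10 * PROTON_MASS) / 10, (10490.0 + 10 * PROTON_MASS) / 10
        mz = np.arange(900.0, 1200.0, 0.02)
        inten = (2.0 / (2.0 * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((mz - ca) / 2.0) ** 2)
                 + 1.0 / (2.0 * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((mz - cb) / 2.0) ** 2))
        spec = Spectrum(mz, inten)
        sums = integrate_series_set(spec, [ChargeSeries(a, [(ca, 8.0)]), ChargeSeries(b, [(cb, 8.0)])])
        assert sums[0] == pytest.approx(2.0, abs=5e-3)
        assert sums[1] == pytest.approx(1.0, abs=5e-3)

    def test_additive_over_disjoint_window_sets(self):
        sp = SpeciesDef("x", 9990.0, 0.0, 10, 10, peak_fwhm=5.0)
        center = (9990.0 + 10 * PROTON_MASS) / 10
        spec = gaussian_spectrum(center, 2.0)
        w1 = ChargeSeries(sp, [(center - 3.0, 2.9)])
        w2 = ChargeSeries(sp, [(center + 3.0, 2.9)])
        both = ChargeSeries(sp, [(center - 3.0, 2.9), (center + 3.0, 2.9)])
        assert integrate_series(spec, both) == pytest.approx(
            integrate_series(spec, w1) + integrate_series(spec, w2), rel=1e-12)

    def test_overlapping_windows_within_species_rejected(self):
        sp = SpeciesDef("x", 9990.0, 0.0, 10, 10, peak_fwhm=5.0)
        with pytest.raises(ValueError, match="overlap"):
            ChargeSeries(sp, [(1000.0, 3.0), (1004.0, 3.0)])

    def test_out_of_range_window_warns_and_contributes_zero(self):
        sp = SpeciesDef("x", 9990.0, 0.0, 10, 10, peak_fwhm=5.0)
        spec = Spectrum(np.arange(2000.0, 2100.0), np.ones(100))
        with pytest.warns(UserWarning, match="outside the spectrum range"):
            total = integrate_series(spec, ChargeSeries(sp))
        assert total == 0.0


class TestRelativeAbundance:
    def test_three_to_one(self, rho_opsin_registry, rho_opsin_series):
        spec = render_spectrum({"rho": 0.75, "opsin": 0.25}, rho_opsin_registry, make_instrument())
        fractions = relative_abundance(spec, rho_opsin_series)
        np.testing.assert_allclose(fractions, [0.75, 0.25], atol=1e-7)

    def test_single_species_present(self, rho_opsin_registry, rho_opsin_series):
        spec = render_spectrum({"rho": 1.0, "opsin": 0.0}, rho_opsin_registry, make_instrument())
        fractions = relative_abundance(spec, rho_opsin_series)
        assert fractions[0] == pytest.approx(1.0, abs=1e-7)

    def test_rescaling_invariance(self, rho_opsin_registry, rho_opsin_series):
        """Fractions are unchanged by global intensity rescaling."""
        spec = render_spectrum({"rho": 0.6, "opsin": 0.4}, rho_opsin_registry, make_instrument())
        scaled = Spectrum(spec.mz, spec.intensity * 37.5, spec.scan_time, spec.light_on)
        np.testing.assert_allclose(relative_abundance(spec, rho_opsin_series),
                                   relative_abundance(scaled, rho_opsin_series), rtol=1e-12)

    def test_all_zero_flags_missing(self, rho_opsin_series):
        spec = Spectrum(np.arange(3900.0, 7000.0), np.zeros(3100))
        with pytest.warns(UserWarning, match="flagged missing"):
            fractions = relative_abundance(spec, rho_opsin_series)
        assert np.all(np.isnan(fractions))

    def test_dark_state_recovered_with_noise(self, rho_opsin_registry, rho_opsin_series,
                                             continuous_light):
        """The 73:27 dark-adapted rho:opsin composition is recovered within 1%."""
        from photocascade.instrument import render_series
        from photocascade.quant import abundance_trace
        from photocascade.spectra import AbundanceTrace

        times = np.arange(0.0, 20.0, 2.0)
        truth = AbundanceTrace(times, np.tile([0.73, 0.27], (times.size, 1)), ["rho", "opsin"])
        series = render_series(truth, rho_opsin_registry, make_instrument(0.01),
                               continuous_light, seed=11)
        tr = abundance_trace(series, rho_opsin_series)
        assert np.nanmean(tr.column("rho")) == pytest.approx(0.73, abs=0.01)
        assert np.nanmean(tr.column("opsin")) == pytest.approx(0.27, abs=0.01)


class TestRatioTrace:
    def _series(self, registry, values, times=None):
        from photocascade.instrument import render_series
        from photocascade.spectra import AbundanceTrace

        times = np.arange(float(len(values))) if times is None else times
        truth = AbundanceTrace(times, np.asarray(values, dtype=float), list(registry))
        return render_series(truth, registry, make_instrument(), LightSchedule.dark(), seed=0)

    def test_constant_one_to_one(self, rho_opsin_registry, rho_opsin_series):
        series = self._series(rho_opsin_registry, [[0.5, 0.5]] * 4)
        _, ratios = ratio_trace(series, rho_opsin_series[0], rho_opsin_series[1])
        np.testing.assert_allclose(ratios, 1.0, atol=1e-6)

    def test_growing_denominator_gives_decreasing_trace(self, rho_opsin_registry, rho_opsin_series):
        vals = [[1 - f, f] for f in np.linspace(0.5, 0.9, 6)]
        series = self._series(rho_opsin_registry, vals)
        _, ratios = ratio_trace(series, rho_opsin_series[0], rho_opsin_series[1])
        assert np.all(np.diff(ratios) < 0)

    def test_absent_denominator_is_inf(self, rho_opsin_registry, rho_opsin_series):
        series = self._series(rho_opsin_registry, [[1.0, 0.0]])
        _, ratios = ratio_trace(series, rho_opsin_series[0], rho_opsin_series[1])
        assert np.isinf(ratios[0])


class TestZeroCharge:
    def test_flat_zero_spectrum(self):
        spec = Spectrum(np.arange(2000.0, 4000.0), np.zeros(2000))
        zc = zero_charge_project(spec, (20000.0, 30000.0), 5.0, range(7, 12))
        assert np.all(zc.score == 0)

    def test_single_envelope_peaks_at_true_mass(self):
        mass = 25000.0
        sp = SpeciesDef("x", mass, 0.0, 8, 12, peak_fwhm=4.0)
        inst = make_instrument(mz_min=1800.0, mz_max=3500.0,
                               charge_envelope={"x": (10.0, 1.0)})
        spec = render_spectrum({"x": 1.0}, {"x": sp}, inst)
        zc = zero_charge_project(spec, (24000.0, 26000.0), 1.0, range(8, 13))
        assert abs(zc.peak_mass - mass) <= 0.5  # within step/2

    def test_rho_opsin_mixture_separates_by_266(self, rho_opsin_registry):
        spec = render_spectrum({"rho": 0.6, "opsin": 0.4}, rho_opsin_registry, make_instrument())
        zc = zero_charge_project(spec, (39500.0, 40700.0), 2.0, range(6, 11))
        peaks = zc.peaks(rel_threshold=0.3)
        assert peaks.size == 2
        assert np.diff(peaks)[0] == pytest.approx(266.42, abs=2.0)

    def test_mass_error_below_grid_step_randomized(self):
        """Noiseless envelopes project to within one grid step of the true mass."""
        rng = np.random.default_rng(20260919)
        step = 1.0
        for _ in range(20):
            mass = rng.uniform(20000.0, 80000.0)
            zlo = int(rng.integers(6, 14))
            zhi = zlo + int(rng.integers(3, 6))
            sp = SpeciesDef("x", mass, 0.0, zlo, zhi, peak_fwhm=6.0)
            inst = make_instrument(mz_min=mass / zhi - 300.0, mz_max=mass / zlo + 300.0,
                                   charge_envelope={"x": ((zlo + zhi) / 2, 1.0)})
            spec = render_spectrum({"x": 1.0}, {"x": sp}, inst)
            zc = zero_charge_project(spec, (mass - 1500.0, mass + 1500.0), step,
                                     range(zlo, zhi + 1))
            assert abs(zc.peak_mass - mass) <= step

    def test_empty_charge_range_rejected(self):
        spec = Spectrum(np.arange(2000.0, 2100.0), np.ones(100))
        with pytest.raises(ValueError, match="empty"):
            zero_charge_project(spec, (20000.0, 21000.0), 1.0, [])

    def test_unreachable_mass_range_rejected(self):
        spec = Spectrum(np.arange(2000.0, 2100.0), np.ones(100))
        with pytest.raises(ValueError, match="outside the spectrum"):
            zero_charge_project(spec, (500.0, 600.0), 1.0, range(20, 25))


class TestScanAveraging:
    def test_scans_per_point_groups_and_averages(self, rho_opsin_registry, rho_opsin_series,
                                                 continuous_light):
        """Summing N consecutive scans per point keeps fractions and shortens the trace."""
        from photocascade.instrument import render_series
        from photocascade.quant import abundance_trace
        from photocascade.spectra import AbundanceTrace

        times = np.arange(0.0, 12.0, 2.0)
        truth = AbundanceTrace(times, np.tile([0.6, 0.4], (times.size, 1)), ["rho", "opsin"])
        series = render_series(truth, rho_opsin_registry, make_instrument(0.01),
                               continuous_light, seed=8)
        tr = abundance_trace(series, rho_opsin_series, scans_per_point=3)
        assert tr.times.size == 2
        np.testing.assert_allclose(tr.column("rho"), 0.6, atol=0.01)
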