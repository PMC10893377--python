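"""Welch PSD, STFT, narrowband SNR, ANOVA peak test, alpha ratio."""

import numpy as np
import pytest
from scipy import stats

from earval.core import Recording
from earval.spectral import (
    Psd,
    alpha_modulation,
    find_spectral_peaks,
    harmonic_scan,
    narrowband_snr,
    spectral_peak_ftest,
    stft_spectrogram,
    welch_psd,
)
from earval.synthetic import square_wave

FS = 500.0


def _rec(x, fs=FS, label="c"):
    return Recording(np.atleast_2d(x), fs, [label])


class TestWelch:
    def test_segment_count_formula(self, rng):
        rec = _rec(rng.normal(size=int(240 * FS)))
        psd = welch_psd(rec, window_s=8.0, overlap=0.5)
        n, win = rec.n_samples, int(8 * FS)
        assert psd.segment_count == (n - win) // (win // 2) + 1 == 59
        assert psd.df == pytest.approx(0.125)

    def test_white_noise_integral_matches_variance(self, rng):
        rec = _rec(rng.standard_normal(int(240 * FS)))
        psd = welch_psd(rec)
        total = np.trapezoid(psd.power[0], psd.freqs)
        assert total == pytest.approx(1.0, rel=0.10)

    def test_sinusoid_band_power_is_a_squared_over_two(self):
        a = 3.0
        t = np.arange(int(60 * FS)) / FS
        psd = welch_psd(_rec(a * np.sin(2 * np.pi * 40.0 * t)))
        band = (psd.freqs >= 39.5) & (psd.freqs <= 40.5)
        peak_power = np.trapezoid(psd.power[0, band], psd.freqs[band])
        assert peak_power == pytest.approx(a * a / 2.0, rel=0.02)

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            welch_psd(_rec(np.zeros(100)), window_s=8.0)


class TestStft:
    def test_frame_count(self, rng):
        rec = _rec(rng.normal(size=int(240 * FS)))
        spec = stft_spectrogram(rec, window_s=2.0, overlap=0.5)
        assert spec.power.shape[2] == 239
        # hop = window * (1 - overlap) = 1 s
        assert np.diff(spec.times)[0] == pytest.approx(1.0)

    def test_stationary_sinusoid_constant_over_time(self):
        t = np.arange(int(60 * FS)) / FS
        spec = stft_spectrogram(_rec(np.sin(2 * np.pi * 10.0 * t)))
        row = spec.power[0, np.argmin(np.abs(spec.freqs - 10.0)), :]
        assert row.min() > 0.9 * row.max()

    def test_zero_signal_zero_power(self):
        spec = stft_spectrogram(_rec(np.zeros(int(10 * FS))))
        assert np.all(spec.power == 0)


def _psd_from_values(freqs, power):
    return Psd(freqs=np.asarray(freqs, dtype=float),
               power=np.atleast_2d(np.asarray(power, dtype=float)),
               segment_count=1, window_s=8.0, overlap=0.5,
               channel_labels=["c"])


class TestNarrowbandSnr:
    def test_flat_spectrum_gives_unity(self):
        freqs = np.arange(30.0, 50.0, 0.125)
        psd = _psd_from_values(freqs, np.ones_like(freqs))
        res = narrowband_snr(psd, "c", 40.0, (35.0, 45.0))
        assert res.snr_linear == pytest.approx(1.0)
        assert res.snr_db == pytest.approx(0.0)

    def test_direct_bin_arithmetic(self):
        freqs = np.arange(35.0, 45.125, 0.125)
        power = np.full(freqs.size, 10.0)
        power[np.argmin(np.abs(freqs - 40.0))] = 100.0
        psd = _psd_from_values(freqs, power)
        res = narrowband_snr(psd, "c", 40.0, (35.0, 45.0))
        assert res.snr_linear == pytest.approx(10.0)
        assert res.snr_db == pytest.approx(10.0)

    def test_invariant_to_spectrum_scaling(self, rng):
        freqs = np.arange(30.0, 50.0, 0.125)
        power = rng.uniform(1.0, 5.0, size=freqs.size)
        a = narrowband_snr(_psd_from_values(freqs, power), "c", 40, (35, 45))
        b = narrowband_snr(_psd_from_values(freqs, 37.5 * power), "c",
                           40, (35, 45))
        assert b.snr_db == pytest.approx(a.snr_db, abs=1e-9)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(100):
            freqs = np.arange(30.0, 50.0, 0.125)
            power = rng.uniform(0.1, 10.0, size=freqs.size)
            psd = _psd_from_values(freqs, power)
            res = narrowband_snr(psd, "c", 40.0, (35.0, 45.0))
            # brute force: enumerate bins explicitly (f0 bin plus the
            # one-bin mainlobe guard on each side excluded)
            f0_bin = int(np.argmin(np.abs(freqs - 40.0)))
            acc, count = 0.0, 0
            for i, f in enumerate(freqs):
                if 35.0 <= f <= 45.0 and abs(i - f0_bin) > 1:
                    acc += power[i]
                    count += 1
            expected = power[f0_bin] / (acc / count)
            assert res.snr_linear == pytest.approx(expected, rel=1e-12)

    def test_band_validation(self):
        freqs = np.arange(30.0, 50.0, 0.125)
        psd = _psd_from_values(freqs, np.ones_like(freqs))
        with pytest.raises(ValueError, match="outside band"):
            narrowband_snr(psd, "c", 40.0, (41.0, 45.0))
        with pytest.raises(ValueError, match="outside frequency range"):
            narrowband_snr(psd, "c", 40.0, (20.0, 60.0))


class TestPeakFtest:
    def test_identical_groups_f_zero_p_one(self):
        freqs = np.arange(35.0, 45.1, 1.0)
        seg = np.full((freqs.size, 4), 2.5)
        f, p = spectral_peak_ftest(freqs, seg, 40.0, (35.0, 45.0))
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_anova(self, rng):
        freqs = np.arange(35.0, 45.1, 1.0)
        for _ in range(100):
            seg = rng.uniform(0.5, 4.0, size=(freqs.size, 6))
            f, p = spectral_peak_ftest(freqs, seg, 40.0, (35.0, 45.0))
            f0_bin = int(np.argmin(np.abs(freqs - 40.0)))
            a = seg[f0_bin]
            b = np.concatenate([seg[i] for i in range(freqs.size)
                                if abs(i - f0_bin) > 1])
            # textbook one-way ANOVA from sums of squares
            grand = np.concatenate([a, b]).mean()
            ssb = len(a) * (a.mean() - grand) ** 2 \
                + len(b) * (b.mean() - grand) ** 2
            ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            df_b, df_w = 1, len(a) + len(b) - 2
            f_ref = (ssb / df_b) / (ssw / df_w)
            p_ref = stats.f.sf(f_ref, df_b, df_w)
            assert f == pytest.approx(f_ref, rel=1e-9)
            assert p == pytest.approx(p_ref, rel=1e-9)

    def test_strong_peak_is_significant(self, assr_session):
        rec, markers, gt = assr_session
        psd = welch_psd(rec.pick(["P4"]))
        res = narrowband_snr(psd, "P4", 40.0, (35.0, 45.0))
        assert res.p_value < 0.05


class TestAlphaModulation:
    def _spectrogram(self, closed_power, open_power):
        t = np.arange(int(120 * FS)) / FS
        x = np.where(t < 60.0, np.sqrt(closed_power), np.sqrt(open_power)) \
            * np.sqrt(2) * np.sin(2 * np.pi * 10.0 * t)
        return stft_spectrogram(_rec(x))

    def test_identical_conditions_give_zero_db(self):
        spec = self._spectrogram(4.0, 4.0)
        am = alpha_modulation(spec, "c", [(5.0, 55.0)], [(65.0, 115.0)])
        assert am.ram_db == pytest.approx(0.0, abs=0.2)

    def test_four_to_one_power_ratio_is_six_db(self):
        spec = self._spectrogram(4.0, 1.0)
        am = alpha_modulation(spec, "c", [(5.0, 55.0)], [(65.0, 115.0)])
        assert am.ram_db == pytest.approx(10 * np.log10(4.0), abs=0.2)
        assert am.ram_linear == pytest.approx(am.power_closed / am.power_open)

    def test_swapping_conditions_negates_db(self):
        spec = self._spectrogram(4.0, 1.0)
        fwd = alpha_modulation(spec, "c", [(5.0, 55.0)], [(65.0, 115.0)])
        rev = alpha_modulation(spec, "c", [(65.0, 115.0)], [(5.0, 55.0)])
        assert rev.ram_db == pytest.approx(-fwd.ram_db, abs=1e-9)

    def test_empty_interval_set_rejected(self):
        spec = self._spectrogram(4.0, 1.0)
        with pytest.raises(ValueError, match="non-empty"):
            alpha_modulation(spec, "c", [], [(65.0, 115.0)])


class TestHarmonics:
    def test_square_wave_peaks_at_odd_harmonics_only(self):
        x = square_wave(10.0, FS, int(60 * FS))
        psd = welch_psd(_rec(x))
        peaks = find_spectral_peaks(psd, "c")
        np.testing.assert_allclose(peaks, np.arange(10.0, 250.0, 20.0))

    def test_harmonic_scan_flags_odd_not_even(self, rng):
        x = square_wave(10.0, FS, int(60 * FS)) \
            + 0.05 * rng.standard_normal(int(60 * FS))
        psd = welch_psd(_rec(x))
        scan = harmonic_scan(psd, "c", 10.0, 80.0, alpha=0.01)
        flags = {k: sig for k, _, sig in scan}
        assert all(flags[k] for k in (1, 3, 5, 7))
        assert not any(flags[k] for k in (2, 4, 6, 8))

    def test_pure_sinusoid_only_fundamental(self, rng):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t) + 0.05 * rng.standard_normal(t.size)
        psd = welch_psd(_rec(x))
        scan = harmonic_scan(psd, "c", 10.0, 80.0, alpha=0.01)
        assert scan[0][2] is True
        assert not any(sig for k, _, sig in scan[1:])

    def test_zero_signal_no_peaks(self):
        psd = welch_psd(_rec(np.zeros(int(20 * FS))))
        assert find_spectral_peaks(psd, "c").size == 0
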