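"""Spectral analysis: Welch PSD, STFT, narrowband SNR, alpha blocking.

Steady-state responses (a 40 Hz auditory steady-state response, a
10 Hz steady-state visual evoked potential, or a simulated phantom
signal) are quantified as the ratio of power at the stimulation
frequency to the average power of the surrounding bins:

    SNR(f0) = P(f0) / mean(P(band)), band excluding the f0 bin

reported both linear and as 10*log10 dB.  The default bands follow
common practice: 35-45 Hz around a 40 Hz response and 5-15 Hz around
a 10 Hz response.  Peak significance is assessed with a one-way ANOVA
comparing the per-Welch-segment power at the f0 bin against the
per-segment powers at the neighbor bins.

Alpha blocking is quantified as the ratio of 8-12 Hz power between the
eyes-closed and eyes-open conditions, R_AM = P_closed / P_open, in dB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from earval.core import Recording

__all__ = [
    "Psd",
    "Spectrogram",
    "SnrResult",
    "AlphaModulation",
    "welch_psd",
    "stft_spectrogram",
    "narrowband_snr",
    "spectral_peak_ftest",
    "alpha_modulation",
    "harmonic_scan",
    "find_spectral_peaks",
]

ALPHA_BAND = (8.0, 12.0)


@dataclass
class Psd:
    """Welch power spectral density.

    ``power`` is channels x frequencies in µV²/Hz; ``segment_powers``
    (channels x frequencies x segments) keeps the per-segment
    periodograms whose mean is ``power``, for segment-level statistics.
    """

    freqs: np.ndarray
    power: np.ndarray
    segment_count: int
    window_s: float
    overlap: float
    channel_labels: list[str]
    segment_powers: np.ndarray | None = None

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in PSD") from None

    @property
    def df(self) -> float:
        """Frequency resolution in Hz."""
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class Spectrogram:
    """STFT power: channels x frequencies x time frames (µV²/Hz)."""

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray
    window_s: float
    overlap: float
    channel_labels: list[str]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in spectrogram") from None


@dataclass
class SnrResult:
    """Narrowband SNR at ``f0`` against the mean of ``band`` bins."""

    f0: float
    band: tuple[float, float]
    snr_linear: float
    snr_db: float
    f_statistic: float
    p_value: float


@dataclass
class AlphaModulation:
    """Eyes-closed over eyes-open alpha-band power ratio."""

    ram_linear: float
    ram_db: float
    power_closed: float
    power_open: float
    alpha_band: tuple[float, float] = ALPHA_BAND


def _segment_psd(rec: Recording, window_s: float, overlap: float):
    """Hann-windowed per-segment one-sided periodograms (density)."""
    nperseg = int(round(window_s * rec.fs))
    if rec.n_samples < nperseg:
        raise ValueError(
            f"recording of {rec.duration:.1f} s shorter than the "
            f"{window_s} s analysis window")
    noverlap = int(round(nperseg * overlap))
    freqs, times, sxx = signal.spectrogram(
        rec.data, fs=rec.fs, window="hann", nperseg=nperseg,
        noverlap=noverlap, detrend="constant", scaling="density",
        mode="psd", axis=1)
    # sxx is channels x freqs x segments
    return freqs, times, sxx


def welch_psd(rec: Recording, window_s: float = 8.0, overlap: float = 0.5
              ) -> Psd:
    """Welch PSD: mean of Hann-windowed overlapping periodograms.

    Defaults (8 s window, 50% overlap) give 0.125 Hz resolution and,
    for an N-sample recording with L-sample window,
    ``floor((N - L) / (L/2)) + 1`` segments.
    """
    freqs, _, sxx = _segment_psd(rec, window_s, overlap)
    return Psd(
        freqs=freqs,
        power=sxx.mean(axis=2),
        segment_count=sxx.shape[2],
        window_s=window_s,
        overlap=overlap,
        channel_labels=list(rec.channel_labels),
        segment_powers=sxx,
    )


def stft_spectrogram(rec: Recording, window_s: float = 2.0,
                     overlap: float = 0.5) -> Spectrogram:
    """Short-time Fourier transform power (2 s window, 50% overlap)."""
    freqs, times, sxx = _segment_psd(rec, window_s, overlap)
    return Spectrogram(
        times=times,
        freqs=freqs,
        power=sxx,
        window_s=window_s,
        overlap=overlap,
        channel_labels=list(rec.channel_labels),
    )


#: Bins on each side of the f0 bin excluded from the neighbor average,
#: in addition to the f0 bin itself.  The Hann taper spreads a
#: bin-centered line over the two adjacent bins (a quarter of the peak
#: each), so counting them as "noise" would contaminate the reference
#: level and cap the measurable SNR; guarding the mainlobe keeps
#: SNR proportional to signal power.
MAINLOBE_GUARD_BINS = 1


def _band_bins(freqs: np.ndarray, f0: float, band: tuple[float, float],
               guard_bins: int = MAINLOBE_GUARD_BINS):
    lo, hi = band
    if not lo <= f0 <= hi:
        raise ValueError(f"f0 {f0} Hz outside band {band}")
    if lo < freqs[0] or hi > freqs[-1]:
        raise ValueError(f"band {band} outside frequency range "
                         f"({freqs[0]}, {freqs[-1]}) Hz")
    in_band = np.nonzero((freqs >= lo) & (freqs <= hi))[0]
    f0_bin = int(np.argmin(np.abs(freqs - f0)))
    neighbors = in_band[np.abs(in_band - f0_bin) > guard_bins]
    if neighbors.size == 0:
        raise ValueError(f"band {band} contains no bins besides f0")
    return f0_bin, neighbors


def spectral_peak_ftest(freqs: np.ndarray, segment_powers: np.ndarray,
                        f0: float, band: tuple[float, float]
                        ) -> tuple[float, float]:
    """One-way ANOVA of per-segment f0-bin power vs neighbor-bin powers.

    ``segment_powers`` is frequencies x segments for one channel.
    Group A holds the power at the bin nearest ``f0`` in each segment;
    group B pools the per-segment powers of the other bins inside
    ``band`` (outside the mainlobe guard).  Returns ``(F, p)``.
    """
    segment_powers = np.asarray(segment_powers, dtype=float)
    if segment_powers.ndim != 2 or segment_powers.shape[1] < 2:
        raise ValueError("need per-segment powers with >= 2 segments")
    f0_bin, neighbors = _band_bins(np.asarray(freqs, dtype=float), f0, band)
    group_a = segment_powers[f0_bin]
    group_b = segment_powers[neighbors].ravel()
    if np.ptp(group_a) == 0 and np.ptp(group_b) == 0:
        # degenerate: no within-group variance
        if group_a[0] == (group_b[0] if group_b.size else group_a[0]):
            return 0.0, 1.0
        return float("inf"), 0.0
    result = stats.f_oneway(group_a, group_b)
    return float(result.statistic), float(result.pvalue)


def narrowband_snr(psd: Psd, channel: str, f0: float,
                   band: tuple[float, float]) -> SnrResult:
    """Power at the bin nearest ``f0`` over the mean of the other bins
    inside ``band`` (the f0 bin and its mainlobe-guard neighbors
    excluded), with ANOVA peak significance when the PSD carries
    per-segment powers."""
    ch = psd.channel_index(channel)
    f0_bin, neighbors = _band_bins(psd.freqs, f0, band)
    p_f0 = float(psd.power[ch, f0_bin])
    p_neigh = float(psd.power[ch, neighbors].mean())
    if p_neigh <= 0:
        snr_linear = np.inf if p_f0 > 0 else 1.0
    else:
        snr_linear = p_f0 / p_neigh
    snr_db = 10.0 * np.log10(snr_linear) if 0 < snr_linear < np.inf else (
        np.inf if snr_linear == np.inf else -np.inf)
    if psd.segment_powers is not None and psd.segment_powers.shape[2] >= 2:
        f_stat, p_val = spectral_peak_ftest(
            psd.freqs, psd.segment_powers[ch], f0, band)
    else:
        f_stat, p_val = float("nan"), float("nan")
    return SnrResult(f0=float(psd.freqs[f0_bin]), band=band,
                     snr_linear=float(snr_linear), snr_db=float(snr_db),
                     f_statistic=f_stat, p_value=p_val)


def alpha_modulation(spec, channel: str,
                     closed_intervals=None, open_intervals=None,
                     alpha_band: tuple[float, float] = ALPHA_BAND
                     ) -> AlphaModulation:
    """Alpha-band power ratio between eyes-closed and eyes-open data.

    ``spec`` is either a :class:`Spectrogram` (power averaged over the
    STFT frames whose centers fall in the respective condition
    intervals, given in seconds on the recording's relative time axis)
    or a pair ``(psd_closed, psd_open)`` of :class:`Psd` computed per
    condition.
    """
    if isinstance(spec, Spectrogram):
        if not closed_intervals or not open_intervals:
            raise ValueError("condition intervals must be non-empty")
        ch = spec.channel_index(channel)
        band_mask = (spec.freqs >= alpha_band[0]) & (spec.freqs <= alpha_band[1])
        if not band_mask.any():
            raise ValueError(f"alpha band {alpha_band} not resolved by "
                             "spectrogram frequency grid")

        def mean_power(intervals):
            tmask = np.zeros(spec.times.size, dtype=bool)
            for lo, hi in intervals:
                tmask |= (spec.times >= lo) & (spec.times <= hi)
            if not tmask.any():
                raise ValueError(f"no STFT frames inside intervals {intervals}")
            return float(spec.power[ch][np.ix_(band_mask, tmask)].mean())

        p_closed = mean_power(closed_intervals)
        p_open = mean_power(open_intervals)
    else:
        psd_closed, psd_open = spec
        p_closed = _band_power(psd_closed, channel, alpha_band)
        p_open = _band_power(psd_open, channel, alpha_band)
    ram = p_closed / p_open
    return AlphaModulation(
        ram_linear=float(ram),
        ram_db=float(10.0 * np.log10(ram)),
        power_closed=p_closed,
        power_open=p_open,
        alpha_band=alpha_band,
    )


def _band_power(psd: Psd, channel: str, band: tuple[float, float]) -> float:
    ch = psd.channel_index(channel)
    mask = (psd.freqs >= band[0]) & (psd.freqs <= band[1])
    if not mask.any():
        raise ValueError(f"band {band} not resolved by PSD frequency grid")
    return float(psd.power[ch, mask].mean())


def harmonic_scan(psd: Psd, channel: str, fundamental: float,
                  max_hz: float, neighbor_halfwidth: float = 5.0,
                  alpha: float = 0.05) -> list[tuple[int, float, bool]]:
    """Narrowband SNR at every harmonic of ``fundamental`` up to
    ``max_hz``.

    Each harmonic k*fundamental is assessed against a band of
    ``+-neighbor_halfwidth`` Hz clipped to the valid frequency range;
    ``significant`` means the ANOVA peak test rejects at ``alpha``.
    Returns ``[(k, snr_db, significant), ...]``.
    """
    if fundamental <= 0:
        raise ValueError("fundamental must be positive")
    results = []
    for k in range(1, int(np.floor(max_hz / fundamental)) + 1):
        f0 = k * fundamental
        band = (max(psd.freqs[0], f0 - neighbor_halfwidth),
                min(psd.freqs[-1], f0 + neighbor_halfwidth))
        res = narrowband_snr(psd, channel, f0, band)
        significant = bool(np.isfinite(res.p_value) and res.p_value < alpha)
        results.append((k, res.snr_db, significant))
    return results


def find_spectral_peaks(psd: Psd, channel: str,
                        rel_height: float = 1e-6) -> np.ndarray:
    """Frequencies of local PSD maxima above ``rel_height`` x max power.

    Intended for clean bench spectra (e.g. locating the harmonics of a
    played-back square wave); returns frequencies in ascending order.
    """
    power = psd.power[psd.channel_index(channel)]
    peak = power.max()
    if peak <= 0:
        return np.array([])
    idx, _ = signal.find_peaks(power, height=rel_height * peak)
    return psd.freqs[idx]
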