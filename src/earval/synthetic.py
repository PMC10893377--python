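"""Seeded generators of paradigm sessions and phantom recordings.

These stand in for subjects and hardware: every recording is built
from a known ground truth (injected oscillation amplitudes, ERP
templates, blink/saccade amplitudes, marker-to-stimulus delays, noise
spectral density), so the analysis chain can be validated by parameter
recovery instead of against human data.

Session structure follows the standard test battery: 4 min continuous
recordings for resting state, alpha blocking (1 min eyes-closed/open
blocks), a 40 Hz amplitude-modulated-tone steady-state response and a
10 Hz flicker steady-state response; 200-trial transient blocks (AEP:
200 ms tones, 1.2-1.8 s inter-stimulus interval; VEP: 500 ms pattern
reversals, 500 ms ISI; auditory and visual oddballs); and an 80-trial
electro-oculography block.  Sampling is 500 Hz on a 12-channel scalp
plus 2x8 in-ear montage.

Background activity is pink (1/f) noise — the dominant character of
resting EEG spectra — with an optional 50 Hz line component.  Ear
channels see cortical effects attenuated relative to scalp (gain 0.3)
and horizontal eye movements amplified (gain 1.5, by proximity);
these projection constants are emulation choices, not measurements.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from earval.core import (
    DEFAULT_EAR_LABELS,
    DEFAULT_SCALP_LABELS,
    MarkerStream,
    Montage,
    Recording,
)
from earval.io import write_recording

__all__ = [
    "EffectSpec",
    "SessionSpec",
    "GroundTruth",
    "generate_session",
    "generate_phantom_recording",
    "generate_latency_recording",
    "make_fixture_suite",
    "pink_noise",
    "erp_template",
]

PARADIGMS = ("resting", "alpha_block", "assr", "ssvep", "aep", "vep",
             "aep_oddball", "vep_oddball", "eog")

#: Measured bench latencies of the reference delivery chain, by
#: modality: (mean s, jitter s).
DEFAULT_LATENCY = {"auditory": (0.0, 0.0022), "visual": (0.021, 0.0028)}

_PARADIGM_MODALITY = {
    "aep": "auditory", "aep_oddball": "auditory",
    "vep": "visual", "vep_oddball": "visual", "eog": "visual",
}

# (n_trials, stimulus_duration_s, isi range) or duration for continuous
_TRIAL_DEFAULTS = {
    "aep": (200, 0.2, (1.2, 1.8)),
    "vep": (200, 0.5, (0.5, 0.5)),
    "aep_oddball": (200, 0.1, (1.2, 1.8)),
    "vep_oddball": (200, 0.5, (0.6, 0.7)),
    "eog": (80, 0.5, (1.0, 1.6)),
}
_CONTINUOUS_DURATION_S = 240.0
_ALPHA_BLOCK_S = 60.0
_LEAD_S = 5.0          # silent lead-in/lead-out around each session
_BLINK_ISI = (2.5, 3.5)  # slower pacing so 3 s blink windows never overlap

#: Scalp gain maps per paradigm family — stylized topographies of the
#: injected effects (occipital alpha/SSVEP, centro-parietal ASSR,
#: fronto-central AEP, occipital VEP).  Unlisted scalp channels get
#: 0.3; ear channels get ``EffectSpec.ear_gain``.
_TOPOGRAPHY = {
    "alpha": {"Oz": 1.0, "Pz": 0.8, "P3": 0.7, "P4": 0.7, "C3": 0.4,
              "C4": 0.4, "Cz": 0.3, "T7": 0.45, "T8": 0.45,
              "F3": 0.2, "Fz": 0.2, "F4": 0.2},
    "assr": {"P4": 1.0, "Pz": 0.9, "P3": 0.85, "Cz": 0.2, "C3": 0.5,
             "C4": 0.5, "T7": 0.6, "T8": 0.6, "Fz": 0.3, "F3": 0.3,
             "F4": 0.3, "Oz": 0.6},
    "ssvep": {"Oz": 1.0, "Pz": 0.8, "P3": 0.7, "P4": 0.7, "T7": 0.5,
              "T8": 0.5, "Cz": 0.2, "C3": 0.3, "C4": 0.3,
              "Fz": 0.15, "F3": 0.15, "F4": 0.15},
    "aep": {"Fz": 1.0, "Cz": 1.0, "C3": 0.9, "C4": 0.9, "F3": 0.8,
            "F4": 0.8, "T7": 0.6, "T8": 0.6, "Pz": 0.7, "P3": 0.6,
            "P4": 0.6, "Oz": 0.4},
    "vep": {"Oz": 1.0, "Pz": 0.8, "P3": 0.6, "P4": 0.6, "T7": 0.3,
            "T8": 0.3, "Cz": 0.4, "C3": 0.3, "C4": 0.3,
            "Fz": 0.2, "F3": 0.2, "F4": 0.2},
}
_TOPOGRAPHY["alpha_block"] = _TOPOGRAPHY["resting"] = _TOPOGRAPHY["alpha"]
_TOPOGRAPHY["aep_oddball"] = _TOPOGRAPHY["aep"]
_TOPOGRAPHY["vep_oddball"] = _TOPOGRAPHY["vep"]


@dataclass
class EffectSpec:
    """Ground-truth effect sizes injected by the generator.

    Amplitudes are in microvolts on scalp channels; ``ear_gain``
    scales cortical effects on ear channels.  ERP components are
    ``(name, latency_s, width_s, amplitude_uv)`` Gaussians.
    """

    # alpha blocking
    alpha_freq: float = 10.0
    alpha_amplitude_uv: float = 30.0          # eyes-closed amplitude
    alpha_modulation_ratio: float = 4.0       # closed/open power ratio
    # steady-state responses
    assr_freq: float = 40.0
    assr_amplitude_uv: float = 1.0
    ssvep_freq: float = 10.0
    ssvep_amplitude_uv: float = 2.0
    ssvep_harmonic_decay: float = 0.5         # amplitude factor per harmonic
    ssvep_n_harmonics: int = 8
    # transient templates
    aep_components: tuple = (("P1", 0.050, 0.015, 2.0),
                             ("N1", 0.100, 0.020, -5.0),
                             ("P2", 0.200, 0.030, 3.9))
    vep_components: tuple = (("P1", 0.090, 0.020, 3.0),
                             ("P2", 0.200, 0.040, 15.0))
    mmn_delta: tuple = (("MMN", 0.200, 0.035, -2.0),)
    p300_delta: tuple = (("P300", 0.280, 0.050, 6.0),)
    # electro-oculography
    blink_p2p_hard_uv: float = 8000.0
    blink_p2p_soft_uv: float = 1500.0
    blink_latency_s: float = 0.30
    blink_width_s: float = 0.15
    saccade_step_uv: dict = field(default_factory=lambda: {
        "horizontal": 5.0, "vertical": 1.0})
    saccade_latency_s: float = 0.15
    # background
    noise_rms_uv: float = 10.0
    noise_f_lo: float = 1.0
    line_50hz_uv: float = 0.0
    # projection
    ear_gain: float = 0.3
    ear_eog_horizontal_gain: float = 1.5
    # marker timing, per modality
    marker_latency: dict = field(
        default_factory=lambda: dict(DEFAULT_LATENCY))


@dataclass
class SessionSpec:
    """One paradigm session to synthesize."""

    paradigm: str
    fs: float = 500.0
    montage: Montage = field(default_factory=Montage)
    n_trials: int | None = None
    duration_s: float | None = None
    isi: tuple[float, float] | None = None
    stimulus_duration_s: float | None = None
    oddball_fraction: float = 0.2
    effect: EffectSpec = field(default_factory=EffectSpec)
    seed: int = 0

    def __post_init__(self):
        if self.paradigm not in PARADIGMS:
            raise ValueError(
                f"unknown paradigm {self.paradigm!r}; choose from {PARADIGMS}")
        if self.isi is not None and self.isi[0] > self.isi[1]:
            raise ValueError(f"isi range {self.isi} must be (min, max)")
        if not 0 < self.oddball_fraction <= 0.5:
            raise ValueError(
                "oddball_fraction must be in (0, 0.5] so that deviants "
                "never have to be consecutive")


@dataclass
class GroundTruth:
    """Everything the generator injected, for parameter-recovery tests."""

    paradigm: str
    params: dict


# ------------------------------------------------------------- noise

def square_wave(f0: float, fs: float, n_samples: int) -> np.ndarray:
    """Unit-amplitude 50% duty-cycle square wave starting high.

    When the period is a whole number of samples the wave is built
    from integer arithmetic, so the duty cycle is exact over any
    length (a naive ``sign(sin(...))`` accumulates floating-point
    phase error that randomly displaces transition samples and raises
    a broadband spectral floor).
    """
    period = fs / f0
    n = np.arange(n_samples)
    if abs(period - round(period)) < 1e-9 and round(period) % 2 == 0:
        half = round(period) // 2
        return np.where((n % (2 * half)) < half, 1.0, -1.0)
    phase = (n * (f0 / fs)) % 1.0
    return np.where(phase < 0.5, 1.0, -1.0)


def pink_noise(rng: np.random.Generator, n_samples: int, fs: float,
               rms_uv: float, f_lo: float = 1.0
               ) -> tuple[np.ndarray, float]:
    """1/f noise with one-sided density S(f) = K/f on [f_lo, fs/2].

    K is set so the expected total power equals ``rms_uv**2``;
    returns ``(samples, K)``.  Synthesized in the frequency domain
    from complex Gaussian coefficients, hence exactly band-limited.
    """
    if rms_uv == 0:
        return np.zeros(n_samples), 0.0
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    k_density = rms_uv ** 2 / math.log((fs / 2.0) / f_lo)
    s_f = np.where(freqs >= f_lo, k_density / np.maximum(freqs, f_lo), 0.0)
    scale = np.sqrt(s_f * fs * n_samples) / 2.0
    coeffs = scale * (rng.standard_normal(freqs.size)
                      + 1j * rng.standard_normal(freqs.size))
    return np.fft.irfft(coeffs, n=n_samples), k_density


def _background(rng, n_channels, n_samples, fs, effect: EffectSpec
                ) -> tuple[np.ndarray, float]:
    data = np.empty((n_channels, n_samples))
    k_density = 0.0
    for ch in range(n_channels):
        data[ch], k_density = pink_noise(
            rng, n_samples, fs, effect.noise_rms_uv, effect.noise_f_lo)
    if effect.line_50hz_uv > 0:
        t = np.arange(n_samples) / fs
        data += effect.line_50hz_uv * np.sin(2 * np.pi * 50.0 * t)
    return data, k_density


# ---------------------------------------------------------- templates

def erp_template(times: np.ndarray, components) -> np.ndarray:
    """Sum-of-Gaussians waveform on ``times`` (s since stimulus onset)."""
    wave = np.zeros_like(times, dtype=float)
    for _name, latency, width, amplitude in components:
        wave += amplitude * np.exp(-0.5 * ((times - latency) / width) ** 2)
    return wave


def _blink_wave(times: np.ndarray, p2p_uv: float, latency: float,
                width: float) -> np.ndarray:
    # single positive lobe: peak-to-peak equals the peak amplitude
    return p2p_uv * np.exp(-0.5 * ((times - latency) / width) ** 2)


def _saccade_wave(times: np.ndarray, step_uv: float, latency: float,
                  rise_s: float = 0.02, hold_s: float = 0.5) -> np.ndarray:
    """Gaze shift and return: a step at ``latency`` held for ``hold_s``
    (the return saccade brings the potential back to baseline, so
    consecutive trials do not accumulate)."""
    up = 1.0 / (1.0 + np.exp(-(times - latency) / rise_s))
    down = 1.0 / (1.0 + np.exp(-(times - latency - hold_s) / rise_s))
    return step_uv * (up - down)


# ------------------------------------------------------ trial timing

def _draw_trial_times(rng, n_trials, stim_s, isi, fs):
    spacings = stim_s + rng.uniform(isi[0], isi[1], size=n_trials - 1) \
        if n_trials > 1 else np.array([])
    onsets = _LEAD_S + np.concatenate([[0.0], np.cumsum(spacings)])
    return onsets


def _oddball_labels(rng, n_trials, fraction, standard, deviant):
    """Deviant placement without consecutive deviants.

    Uniform over all placements with no two adjacent deviants and a
    standard first trial, via the gap construction: draw sorted
    distinct slots and spread them by their rank.
    """
    n_dev = int(round(fraction * n_trials))
    n_slots = n_trials - n_dev   # slots 1..n_slots keep trial 0 standard
    if n_dev > 0 and n_slots < n_dev:
        raise ValueError(
            f"cannot place {n_dev} non-consecutive deviants in "
            f"{n_trials} trials")
    slots = np.sort(rng.choice(np.arange(1, n_slots + 1), size=n_dev,
                               replace=False))
    pos = slots + np.arange(n_dev)
    labels = [standard] * n_trials
    for p in pos:
        labels[p] = deviant
    return labels, [int(p) for p in pos]


def _cortical_gains(spec: SessionSpec) -> np.ndarray:
    """Signed per-channel projection of the paradigm's cortical effect."""
    topo = _TOPOGRAPHY[spec.paradigm]
    m = spec.montage
    return np.array([topo.get(lb, 0.3) if lb in m.scalp_labels
                     else spec.effect.ear_gain for lb in m.all_labels])


def _eog_gains(spec: SessionSpec, kind: str, direction: str | None
               ) -> np.ndarray:
    """Signed per-channel projection of eye-movement potentials."""
    e = spec.effect
    gains = []
    for lb in spec.montage.all_labels:
        if kind == "blink":
            if lb in ("F3", "Fz", "F4"):
                g = 1.0
            elif lb in spec.montage.scalp_labels:
                g = 0.3
            else:
                g = 0.2
        elif direction in ("left", "right"):
            sign = 1.0 if direction == "left" else -1.0
            if lb == "T7":
                g = sign
            elif lb == "T8":
                g = -sign
            elif lb in ("F3", "F4"):
                g = sign * (0.5 if lb == "F3" else -0.5)
            elif lb.startswith("EL"):
                g = sign * e.ear_eog_horizontal_gain
            elif lb.startswith("ER"):
                g = -sign * e.ear_eog_horizontal_gain
            else:
                g = 0.2 * sign
        else:  # vertical
            sign = 1.0 if direction == "up" else -1.0
            if lb in ("F3", "Fz", "F4"):
                g = sign
            elif lb in spec.montage.scalp_labels:
                g = 0.4 * sign
            else:
                g = 0.5 * sign
        gains.append(g)
    return np.array(gains)


# ------------------------------------------------------- generators

def generate_session(spec: SessionSpec
                     ) -> tuple[Recording, MarkerStream, GroundTruth]:
    """Synthesize one paradigm session.

    Returns the recording, its marker stream and a :class:`GroundTruth`
    carrying every injected parameter (per-trial physical onsets,
    marker-to-stimulus delays, templates, noise density).  Identical
    specs (including seed) produce bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.paradigm in _TRIAL_DEFAULTS:
        return _generate_trial_session(spec, rng)
    return _generate_continuous_session(spec, rng)


def _finish(spec, rng, n_samples, signal_per_channel, events, gt_params
            ) -> tuple[Recording, MarkerStream, GroundTruth]:
    noise, k_density = _background(
        rng, len(spec.montage.all_labels), n_samples, spec.fs, spec.effect)
    rec = Recording(
        data=noise + signal_per_channel,
        fs=spec.fs,
        channel_labels=list(spec.montage.all_labels),
        t0=0.0,
        reference_label="FCz",
    )
    gt_params.update({
        "fs": spec.fs,
        "seed": spec.seed,
        "noise_rms_uv": spec.effect.noise_rms_uv,
        "noise_density_k": k_density,
        "noise_f_lo": spec.effect.noise_f_lo,
    })
    return rec, MarkerStream(events), GroundTruth(spec.paradigm, gt_params)


def _generate_continuous_session(spec: SessionSpec, rng):
    e = spec.effect
    duration = spec.duration_s or _CONTINUOUS_DURATION_S
    n = int(round((duration + 2 * _LEAD_S) * spec.fs))
    t = np.arange(n) / spec.fs
    active = (t >= _LEAD_S) & (t < _LEAD_S + duration)
    gains = _cortical_gains(spec)
    signal = np.zeros(n)
    events: list[tuple[float, str]] = []
    gt: dict = {"duration_s": duration, "lead_s": _LEAD_S,
                "ear_gain": e.ear_gain}

    if spec.paradigm == "resting":
        events = [(_LEAD_S, "resting_start"), (_LEAD_S + duration,
                                               "resting_stop")]
    elif spec.paradigm == "assr":
        phase = rng.uniform(0, 2 * np.pi)
        signal[active] = e.assr_amplitude_uv * np.sin(
            2 * np.pi * e.assr_freq * t[active] + phase)
        events = [(_LEAD_S, "assr_start"), (_LEAD_S + duration, "assr_stop")]
        gt.update(amplitude_uv=e.assr_amplitude_uv, f0=e.assr_freq)
    elif spec.paradigm == "ssvep":
        amplitudes = [e.ssvep_amplitude_uv * e.ssvep_harmonic_decay ** (k - 1)
                      for k in range(1, e.ssvep_n_harmonics + 1)]
        for k, amp in enumerate(amplitudes, start=1):
            if k * e.ssvep_freq >= spec.fs / 2:
                amplitudes = amplitudes[:k - 1]
                break
            phase = rng.uniform(0, 2 * np.pi)
            signal[active] += amp * np.sin(
                2 * np.pi * k * e.ssvep_freq * t[active] + phase)
        events = [(_LEAD_S, "ssvep_start"), (_LEAD_S + duration, "ssvep_stop")]
        gt.update(amplitudes_uv=amplitudes, f0=e.ssvep_freq)
    elif spec.paradigm == "alpha_block":
        # four alternating blocks (closed/open x2); 60 s each at the
        # default 4 min duration
        n_blocks = 4
        block_s = duration / n_blocks
        amp_closed = e.alpha_amplitude_uv
        amp_open = amp_closed / math.sqrt(e.alpha_modulation_ratio)
        phase = rng.uniform(0, 2 * np.pi)
        alpha = np.sin(2 * np.pi * e.alpha_freq * t + phase)
        envelope = np.zeros(n)
        blocks = []
        for b in range(n_blocks):
            condition = "eyes_closed" if b % 2 == 0 else "eyes_open"
            start = _LEAD_S + b * block_s
            stop = start + block_s
            envelope[(t >= start) & (t < stop)] = (
                amp_closed if condition == "eyes_closed" else amp_open)
            events.append((start, condition))
            blocks.append({"condition": condition, "start_s": start,
                           "stop_s": stop})
        events.append((_LEAD_S + n_blocks * block_s, "alpha_stop"))
        signal = envelope * alpha
        gt.update(amplitude_closed_uv=amp_closed, amplitude_open_uv=amp_open,
                  modulation_ratio=e.alpha_modulation_ratio,
                  alpha_freq=e.alpha_freq, blocks=blocks)
    gt["channel_gains"] = dict(zip(spec.montage.all_labels,
                                   gains.tolist()))
    per_channel = gains[:, np.newaxis] * signal[np.newaxis, :]
    return _finish(spec, rng, n, per_channel, events, gt)


def _generate_trial_session(spec: SessionSpec, rng):
    e = spec.effect
    n_trials, stim_default, isi_default = _TRIAL_DEFAULTS[spec.paradigm]
    n_trials = spec.n_trials or n_trials
    stim_s = (spec.stimulus_duration_s if spec.stimulus_duration_s is not None
              else stim_default)
    isi = spec.isi or isi_default
    if stim_s < 0 or isi[0] < 0:
        raise ValueError("stimulus duration and ISI must be non-negative")
    modality = _PARADIGM_MODALITY[spec.paradigm]
    lat_mean, lat_jitter = e.marker_latency[modality]

    if spec.paradigm == "eog":
        return _generate_eog_session(spec, rng, n_trials, stim_s, isi)

    if spec.paradigm == "aep":
        labels = ["tone"] * n_trials
        base = e.aep_components
        delta = ()
        deviant_positions = []
    elif spec.paradigm == "vep":
        labels = ["reversal"] * n_trials
        base = e.vep_components
        delta = ()
        deviant_positions = []
    elif spec.paradigm == "aep_oddball":
        labels, deviant_positions = _oddball_labels(
            rng, n_trials, spec.oddball_fraction, "standard", "deviant")
        base = e.aep_components
        delta = e.mmn_delta
    else:  # vep_oddball
        labels, deviant_positions = _oddball_labels(
            rng, n_trials, spec.oddball_fraction, "standard", "target")
        base = e.vep_components
        delta = e.p300_delta

    marker_times = _draw_trial_times(rng, n_trials, stim_s, isi, spec.fs)
    delays = rng.normal(lat_mean, lat_jitter, size=n_trials)
    onsets = marker_times + delays
    epoch_len = 0.8
    n = int(round((onsets[-1] + epoch_len + _LEAD_S) * spec.fs))

    template_times = np.arange(0.0, epoch_len, 1.0 / spec.fs)
    base_wave = erp_template(template_times, base)
    delta_wave = erp_template(template_times, delta) if delta else None

    signal = np.zeros(n)
    deviant_set = set(deviant_positions)
    for i, onset in enumerate(onsets):
        start = int(np.floor(onset * spec.fs + 0.5))
        wave = base_wave if i not in deviant_set else base_wave + delta_wave
        stop = min(n, start + wave.size)
        signal[start:stop] += wave[:stop - start]

    gains = _cortical_gains(spec)
    per_channel = gains[:, np.newaxis] * signal[np.newaxis, :]
    events = [(float(tm), lb) for tm, lb in zip(marker_times, labels)]
    gt = {
        "n_trials": n_trials,
        "stimulus_duration_s": stim_s,
        "isi": list(isi),
        "marker_times": marker_times.tolist(),
        "onsets": onsets.tolist(),
        "delays": delays.tolist(),
        "latency_mean_s": lat_mean,
        "latency_jitter_s": lat_jitter,
        "labels": labels,
        "deviant_positions": deviant_positions,
        "n_deviants": len(deviant_positions),
        "template_times": template_times.tolist(),
        "template": base_wave.tolist(),
        "delta_template": (delta_wave.tolist() if delta_wave is not None
                           else None),
        "ear_gain": e.ear_gain,
        "channel_gains": dict(zip(spec.montage.all_labels, gains.tolist())),
    }
    return _finish(spec, rng, n, per_channel, events, gt)


def _generate_eog_session(spec: SessionSpec, rng, n_trials, stim_s, isi):
    """Saccade trials in four directions plus hard/soft blink blocks.

    ``n_trials`` counts the dot-movement (saccade) trials; an
    instructed blink section of ``n_trials // 2`` extra trials (half
    intentional/hard, half regular/soft, in blocks) follows.
    """
    e = spec.effect
    n_blinks = n_trials // 2
    n_hard = n_blinks // 2
    directions = list(np.tile(["up", "down", "left", "right"],
                              math.ceil(n_trials / 4))[:n_trials])
    rng.shuffle(directions)
    trial_kinds = ([("saccade", d) for d in directions]
                   + [("blink", "hard")] * n_hard
                   + [("blink", "soft")] * (n_blinks - n_hard))

    lat_mean, lat_jitter = e.marker_latency["visual"]
    times, events, kinds = [], [], []
    t_cursor = _LEAD_S
    for kind, sub in trial_kinds:
        times.append(t_cursor)
        events.append((t_cursor, f"{kind}_{sub}"))
        kinds.append((kind, sub))
        trial_isi = _BLINK_ISI if kind == "blink" else isi
        t_cursor += stim_s + rng.uniform(*trial_isi)
    marker_times = np.array(times)
    delays = rng.normal(lat_mean, lat_jitter, size=len(times))
    onsets = marker_times + delays

    epoch_len = 2.5
    n = int(round((onsets[-1] + epoch_len + _LEAD_S) * spec.fs))
    wave_times = np.arange(0.0, epoch_len, 1.0 / spec.fs)
    blink_hard = _blink_wave(wave_times, e.blink_p2p_hard_uv,
                             e.blink_latency_s, e.blink_width_s)
    blink_soft = _blink_wave(wave_times, e.blink_p2p_soft_uv,
                             e.blink_latency_s, e.blink_width_s)
    n_ch = len(spec.montage.all_labels)
    data = np.zeros((n_ch, n))
    for (kind, sub), onset in zip(kinds, onsets):
        start = int(np.floor(onset * spec.fs + 0.5))
        if kind == "blink":
            wave = blink_hard if sub == "hard" else blink_soft
            gains = _eog_gains(spec, "blink", None)
        else:
            amp = e.saccade_step_uv[
                "horizontal" if sub in ("left", "right") else "vertical"]
            wave = _saccade_wave(wave_times, amp, e.saccade_latency_s)
            gains = _eog_gains(spec, "saccade", sub)
        stop = min(n, start + wave.size)
        data[:, start:stop] += gains[:, np.newaxis] * wave[:stop - start]

    gt = {
        "n_trials": len(kinds),
        "marker_times": marker_times.tolist(),
        "onsets": onsets.tolist(),
        "delays": delays.tolist(),
        "labels": [f"{k}_{s}" for k, s in kinds],
        "blink_p2p_hard_uv": e.blink_p2p_hard_uv,
        "blink_p2p_soft_uv": e.blink_p2p_soft_uv,
        "blink_ratio": e.blink_p2p_hard_uv / e.blink_p2p_soft_uv,
        "saccade_step_uv": dict(e.saccade_step_uv),
        "latency_mean_s": e.marker_latency["visual"][0],
        "latency_jitter_s": e.marker_latency["visual"][1],
    }
    return _finish(spec, rng, n, data,
                   [(float(t), lb) for t, lb in events], gt)


def generate_phantom_recording(
    square_amp_mv: float = 100.0,
    f0: float = 10.0,
    contact_quality: dict[str, str] | None = None,
    noise_floor_uvrms: dict[str, float] | None = None,
    duration_s: float = 20.0,
    fs: float = 250.0,
    attenuation: float = 1e-3,
    contact_gain: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[Recording, GroundTruth]:
    """Synthesize a phantom playback recording.

    A square wave of ``square_amp_mv`` millivolts at ``f0`` is played
    through the phantom; each electrode sees it scaled by the material
    ``attenuation`` and its contact gain (good contact 1.0, bad 0.02
    by default), plus white noise at the per-class noise floor (good
    0.5 µVrms, bad 300 µVrms — bad contacts are dominated by noise on
    the order of hundreds of µVrms).
    """
    if square_amp_mv < 0:
        raise ValueError("square-wave amplitude must be non-negative")
    if contact_quality is None:
        contact_quality = {f"ER{i}": "good" for i in range(1, 9)}
    for label, quality in contact_quality.items():
        if quality not in ("good", "bad"):
            raise KeyError(
                f"contact quality for {label!r} must be 'good' or 'bad'")
    noise_map = {"good": 0.5, "bad": 300.0}
    if noise_floor_uvrms:
        noise_map.update(noise_floor_uvrms)
    gain_map = {"good": 1.0, "bad": 0.02}
    if contact_gain:
        gain_map.update(contact_gain)

    rng = np.random.default_rng(seed)
    labels = list(contact_quality)
    n = int(round(duration_s * fs))
    wave = square_wave(f0, fs, n) if square_amp_mv > 0 else np.zeros(n)
    amp_uv = square_amp_mv * 1000.0 * attenuation
    # electrodes further along the earpiece sit further from the
    # antennas' midpoint and pick up more of the played-back signal,
    # so per-electrode amplitudes differ (0.6x-1.3x by sensor number)
    def position_gain(label: str) -> float:
        digits = "".join(ch for ch in label if ch.isdigit())
        return 0.5 + 0.1 * int(digits) if digits else 1.0
    data = np.empty((len(labels), n))
    per_channel = {}
    for i, label in enumerate(labels):
        quality = contact_quality[label]
        channel_amp = amp_uv * gain_map[quality] * position_gain(label)
        sigma = noise_map[quality]
        data[i] = channel_amp * wave + rng.normal(0.0, sigma, size=n)
        per_channel[label] = {"quality": quality,
                              "signal_amp_uv": channel_amp,
                              "noise_uvrms": sigma}
    rec = Recording(data=data, fs=fs, channel_labels=labels, t0=0.0)
    gt = GroundTruth("phantom", {
        "square_amp_mv": square_amp_mv, "f0": f0, "fs": fs,
        "duration_s": duration_s, "attenuation": attenuation,
        "channels": per_channel, "seed": seed,
    })
    return rec, gt


def generate_latency_recording(
    n_events: int = 1000,
    mean_delay_s: float = 0.021,
    jitter_s: float = 0.0028,
    fs: float = 500.0,
    pulse_s: float = 0.05,
    spacing_s: float = 0.3,
    seed: int = 0,
) -> tuple[Recording, MarkerStream, GroundTruth]:
    """Bench trace for the latency estimator: one pulse per marker.

    Each marker is followed by a rectangular unit pulse whose leading
    edge is delayed by Normal(mean, jitter); the step lands between
    two samples so sub-sample onset interpolation is exercised.
    """
    rng = np.random.default_rng(seed)
    marker_times = _LEAD_S + np.arange(n_events) * spacing_s \
        + rng.uniform(0, 1.0 / fs, size=n_events)
    delays = rng.normal(mean_delay_s, jitter_s, size=n_events)
    onsets = marker_times + delays
    n = int(round((marker_times[-1] + 1.0) * fs))
    trace = np.zeros(n)
    for onset in onsets:
        start = int(np.ceil(onset * fs))
        stop = min(n, start + int(round(pulse_s * fs)))
        trace[start:stop] = 1.0
    rec = Recording(trace[np.newaxis, :], fs=fs, channel_labels=["stim"])
    markers = MarkerStream([(float(t), "stim") for t in marker_times])
    gt = GroundTruth("latency", {
        "n_events": n_events, "mean_delay_s": mean_delay_s,
        "jitter_s": jitter_s, "delays": delays.tolist(), "seed": seed,
    })
    return rec, markers, gt


# ------------------------------------------------------ fixture suite

def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def make_fixture_suite(out_dir, seed: int = 0, scale: float = 1.0) -> dict:
    """Write one XDF fixture per paradigm plus phantom and latency
    cases, with a JSON manifest of file hashes and ground truth.

    ``scale`` < 1 shrinks durations and trial counts proportionally
    (minimum 8 trials / 30 s) for quick smoke suites; 1.0 reproduces
    the full session structure.  Deterministic for a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "scale": scale, "files": {}}
    for i, paradigm in enumerate(PARADIGMS):
        spec = SessionSpec(paradigm=paradigm, seed=seed + i)
        if scale != 1.0:
            if paradigm in _TRIAL_DEFAULTS:
                spec.n_trials = max(8, int(_TRIAL_DEFAULTS[paradigm][0] * scale))
            else:
                spec.duration_s = max(30.0, _CONTINUOUS_DURATION_S * scale)
        rec, markers, gt = generate_session(spec)
        path = out_dir / f"{paradigm}.xdf"
        write_recording(rec, markers, path)
        manifest["files"][path.name] = {
            "sha256": _sha256(path),
            "paradigm": paradigm,
            "ground_truth": _compact_gt(gt),
        }
    for offset, (name, contacts) in enumerate([
        ("phantom_wet.xdf", {f"ER{i}": "good" for i in range(1, 9)}),
        ("phantom_dry.xdf", {**{f"ER{i}": "good" for i in range(1, 9)},
                             "ER3": "bad", "ER7": "bad"}),
    ]):
        rec, gt = generate_phantom_recording(
            contact_quality=contacts, seed=seed + 50 + offset)
        path = out_dir / name
        write_recording(rec, MarkerStream([]), path)
        manifest["files"][path.name] = {
            "sha256": _sha256(path), "paradigm": "phantom",
            "ground_truth": _jsonable(gt.params),
        }
    rec, markers, gt = generate_latency_recording(
        n_events=max(50, int(1000 * scale)), seed=seed + 99)
    path = out_dir / "latency.xdf"
    write_recording(rec, markers, path)
    manifest["files"][path.name] = {
        "sha256": _sha256(path), "paradigm": "latency",
        "ground_truth": {k: v for k, v in gt.params.items() if k != "delays"},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _compact_gt(gt: GroundTruth) -> dict:
    drop = {"marker_times", "onsets", "delays", "template",
            "delta_template", "template_times", "labels"}
    return _jsonable({k: v for k, v in gt.params.items() if k not in drop})


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
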