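"""Per-paradigm orchestration: file in, metric table out.

:func:`run_analysis` runs the full chain for one recorded session —
filter, re-reference, epoch/transform, quantify — and returns a tidy
metrics table with columns ``paradigm, channel, reference, metric,
value, p``.  :func:`compare_references` repeats an analysis under a
list of re-referencing schemes and ranks them, the procedure used to
pick the best in-ear reference electrode.

Analysis defaults (filter bands, windows, corrections) are the
conventional ones for each paradigm and can be overridden per
:class:`AnalysisConfig` field or via a YAML file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from earval.core import MarkerStream, Recording, estimate_marker_latency
from earval.eog import blink_metrics, direction_separation, saccade_profiles
from earval.erp import (
    COMPONENT_WINDOWS,
    average_erp,
    component_metrics,
    oddball_difference,
)
from earval.io import read_recording
from earval.preprocess import (
    FilterSpec,
    ReferenceScheme,
    apply_filter_chain,
    baseline_correct,
    extract_epochs,
)
from earval.preprocess import rereference as _rereference
from earval.spectral import (
    alpha_modulation,
    narrowband_snr,
    stft_spectrogram,
    welch_psd,
)

__all__ = [
    "AnalysisConfig",
    "run_analysis",
    "compare_references",
    "alpha_condition_intervals",
    "ANALYSES",
]

log = logging.getLogger("earval")

ANALYSES = ("resting", "alpha", "assr", "ssvep", "aep", "vep", "mmn",
            "p300", "eog", "latency")

#: Defaults per analysis: filter band, notch, epoch window, baseline,
#: event labels, latency correction (s), headline channel.
_DEFAULTS = {
    "resting": dict(band=(1.0, 100.0), notch=50.0),
    "alpha": dict(band=(1.0, 100.0), notch=50.0),
    "assr": dict(band=(1.0, 100.0), notch=50.0, f0=40.0,
                 snr_band=(35.0, 45.0)),
    "ssvep": dict(band=(1.0, 100.0), notch=50.0, f0=10.0,
                  snr_band=(5.0, 15.0)),
    "aep": dict(band=(1.0, 20.0), notch=None, window=(-0.1, 0.5),
                labels=("tone",), correction=0.0,
                components=(("P1", "positive"), ("N1", "negative"),
                            ("P2", "positive"))),
    "vep": dict(band=(1.0, 20.0), notch=None, window=(-0.1, 0.5),
                labels=("reversal",), correction=0.021,
                components=(("P2", "positive"),)),
    "mmn": dict(band=(1.0, 20.0), notch=None, window=(-0.1, 0.5),
                standard="standard", deviant="deviant", correction=0.0,
                components=(("MMN", "negative"),)),
    "p300": dict(band=(1.0, 20.0), notch=None, window=(-0.1, 0.8),
                 standard="standard", deviant="target", correction=0.021,
                 components=(("P300", "positive"),)),
    "eog": dict(blink_band=(0.2, 3.0), saccade_band=(1.0, 20.0),
                blink_window=(-1.0, 2.0), saccade_window=(-0.1, 0.5),
                correction=0.021),
    "latency": dict(),
}


@dataclass
class AnalysisConfig:
    """Parameters for one paradigm analysis.

    ``None`` fields fall back to the per-paradigm defaults; the exact
    values used are echoed next to the outputs as JSON.
    """

    paradigm: str
    reference: str | None = "Cz"
    highpass_hz: float | None = None
    lowpass_hz: float | None = None
    notch_hz: float | None = None
    epoch_window: tuple[float, float] | None = None
    baseline: tuple[float, float] = (-0.1, 0.0)
    latency_correction: float | None = None
    alpha_level: float = 0.05
    channels: list[str] | None = None
    settle_discard_s: float = 2.0
    out_dir: str | None = None

    def __post_init__(self):
        if self.paradigm not in ANALYSES:
            raise ValueError(
                f"unknown analysis {self.paradigm!r}; choose from {ANALYSES}")

    @classmethod
    def from_yaml(cls, path, paradigm: str | None = None) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if paradigm is not None:
            raw["paradigm"] = paradigm
        for key in ("epoch_window", "baseline"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def resolved(self) -> dict:
        """Defaults merged with explicit overrides."""
        base = dict(_DEFAULTS[self.paradigm])
        if self.highpass_hz is not None or self.lowpass_hz is not None:
            lo, hi = base.get("band", (1.0, 100.0))
            base["band"] = (self.highpass_hz or lo, self.lowpass_hz or hi)
        if self.notch_hz is not None:
            base["notch"] = self.notch_hz
        if self.epoch_window is not None:
            base["window"] = self.epoch_window
        if self.latency_correction is not None:
            base["correction"] = self.latency_correction
        return base


def _prepare(rec: Recording, config: AnalysisConfig, band, notch) -> Recording:
    spec = FilterSpec(highpass_hz=band[0], lowpass_hz=band[1], notch_hz=notch)
    rec = apply_filter_chain(rec, spec)
    if config.reference:
        rec = _rereference(rec, ReferenceScheme("channel", config.reference))
    return rec


def _channels(rec: Recording, config: AnalysisConfig) -> list[str]:
    if config.channels:
        return list(config.channels)
    return list(rec.channel_labels)


def alpha_condition_intervals(
    markers: MarkerStream, t0: float = 0.0, discard_s: float = 2.0
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Eyes-closed / eyes-open intervals from block markers.

    Blocks run from each ``eyes_closed``/``eyes_open`` marker to the
    next marker of any label; the first ``discard_s`` seconds after
    each transition are dropped to skip the settling response.  Times
    are returned relative to ``t0``.
    """
    closed, opened = [], []
    events = list(zip(markers.times, markers.labels))
    for (t, label), nxt in zip(events, events[1:] + [(None, None)]):
        if label not in ("eyes_closed", "eyes_open"):
            continue
        stop = nxt[0] if nxt[0] is not None else None
        if stop is None:
            continue
        interval = (t - t0 + discard_s, stop - t0)
        if interval[1] <= interval[0]:
            continue
        (closed if label == "eyes_closed" else opened).append(interval)
    if not closed or not opened:
        raise ValueError(
            "alpha-block analysis needs both eyes_closed and eyes_open "
            f"blocks; marker labels seen: {sorted(set(markers.labels))}")
    return closed, opened


def _crop_between(rec: Recording, markers: MarkerStream, start_label, stop_label
                  ) -> Recording:
    """Restrict to the span between two markers when both are present."""
    times = dict(zip(markers.labels, markers.times))
    if start_label not in times or stop_label not in times:
        return rec
    lo = max(0, int((times[start_label] - rec.t0) * rec.fs))
    hi = min(rec.n_samples, int((times[stop_label] - rec.t0) * rec.fs))
    data = rec.data[:, lo:hi]
    return replace_data(rec, data, rec.t0 + lo / rec.fs)


def replace_data(rec: Recording, data, t0) -> Recording:
    return Recording(data=data, fs=rec.fs,
                     channel_labels=list(rec.channel_labels),
                     t0=t0, reference_label=rec.reference_label)


def run_analysis(path, config: AnalysisConfig) -> pd.DataFrame:
    """Run one paradigm analysis on a recorded session file.

    Deterministic given file and config.  When ``config.out_dir`` is
    set, writes ``<paradigm>_metrics.csv`` and a JSON echo of every
    parameter actually used next to it.
    """
    rec, markers = read_recording(path)
    rows = _analyze(rec, markers, config)
    table = pd.DataFrame(rows, columns=["paradigm", "channel", "reference",
                                        "metric", "value", "p"])
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / f"{config.paradigm}_metrics.csv", index=False)
        echo = {"config": asdict(config), "resolved": _echoable(config)}
        with open(out / f"{config.paradigm}_config.json", "w") as fh:
            json.dump(echo, fh, indent=1, sort_keys=True, default=str)
        log.info("wrote %s metrics to %s", config.paradigm, out)
    return table


def _echoable(config: AnalysisConfig) -> dict:
    return {k: (list(v) if isinstance(v, tuple) else v)
            for k, v in config.resolved().items()}


def _analyze(rec, markers, config) -> list[dict]:
    p = config.paradigm
    d = config.resolved()
    ref = config.reference or (rec.reference_label or "recorded")

    def row(channel, metric, value, pval=np.nan):
        return dict(paradigm=p, channel=channel, reference=ref,
                    metric=metric, value=float(value), p=float(pval))

    if p == "latency":
        est = estimate_marker_latency(rec.pick([rec.channel_labels[0]]),
                                      markers)
        return [row("stim", "mean_delay_ms", est.mean_delay * 1e3),
                row("stim", "jitter_ms", est.jitter * 1e3),
                row("stim", "n_events", est.n_events)]

    if p == "resting":
        filtered = _prepare(rec, config, d["band"], d["notch"])
        psd = welch_psd(filtered)
        bands = {"delta": (1, 4), "theta": (4, 8), "alpha": (8, 12),
                 "beta": (13, 30)}
        rows = []
        for ch in _channels(filtered, config):
            idx = psd.channel_index(ch)
            for name, (lo, hi) in bands.items():
                mask = (psd.freqs >= lo) & (psd.freqs <= hi)
                rows.append(row(ch, f"bandpower_{name}_uv2hz",
                                psd.power[idx, mask].mean()))
        return rows

    if p == "alpha":
        filtered = _prepare(rec, config, d["band"], d["notch"])
        closed, opened = alpha_condition_intervals(
            markers, t0=filtered.t0, discard_s=config.settle_discard_s)
        spec = stft_spectrogram(filtered)
        return [row(ch, "ram_db",
                    alpha_modulation(spec, ch, closed, opened).ram_db)
                for ch in _channels(filtered, config)
                if ch != config.reference]

    if p in ("assr", "ssvep"):
        cropped = _crop_between(rec, markers, f"{p}_start", f"{p}_stop")
        filtered = _prepare(cropped, config, d["band"], d["notch"])
        psd = welch_psd(filtered, window_s=min(8.0, filtered.duration))
        rows = []
        for ch in _channels(filtered, config):
            if ch == config.reference:
                continue
            res = narrowband_snr(psd, ch, d["f0"], d["snr_band"])
            rows.append(row(ch, "snr_db", res.snr_db, res.p_value))
        return rows

    if p in ("aep", "vep"):
        filtered = _prepare(rec, config, d["band"], d["notch"])
        ep = extract_epochs(filtered, markers, set(d["labels"]),
                            d["window"], d["correction"])
        ep = baseline_correct(ep, config.baseline)
        erp = average_erp(ep, config.alpha_level)
        rows = []
        comps = [(name, COMPONENT_WINDOWS[name], pol)
                 for name, pol in d["components"]]
        p2p = ("N1", "P2") if p == "aep" else None
        for ch in _channels(filtered, config):
            if ch == config.reference:
                continue
            for metric in component_metrics(erp, ch, comps, peak_to_peak=p2p):
                rows.append(row(ch, f"{metric.name}_amplitude_uv",
                                metric.peak_amplitude))
                rows.append(row(ch, f"{metric.name}_latency_s",
                                metric.peak_latency))
                if metric.peak_to_peak is not None:
                    rows.append(row(ch, f"{metric.name}_p2p_uv",
                                    metric.peak_to_peak))
        return rows

    if p in ("mmn", "p300"):
        filtered = _prepare(rec, config, d["band"], d["notch"])
        ep = extract_epochs(filtered, markers,
                            {d["standard"], d["deviant"]},
                            d["window"], d["correction"])
        ep = baseline_correct(ep, config.baseline)
        diff = oddball_difference(ep, d["standard"], d["deviant"],
                                  config.alpha_level)
        comps = [(name, COMPONENT_WINDOWS[name], pol)
                 for name, pol in d["components"]]
        rows = []
        for ch in _channels(filtered, config):
            if ch == config.reference:
                continue
            for metric in component_metrics(diff, ch, comps):
                rows.append(row(ch, f"{metric.name}_amplitude_uv",
                                metric.peak_amplitude))
                rows.append(row(ch, f"{metric.name}_latency_s",
                                metric.peak_latency))
            idx = diff.channel_index(ch)
            rows.append(row(ch, "sig_fraction",
                            diff.sig_mask[idx].mean()))
        return rows

    if p == "eog":
        rows = []
        blink_rec = _prepare(rec, config, d["blink_band"], None)
        ep_hard = extract_epochs(blink_rec, markers, {"blink_hard"},
                                 d["blink_window"], d["correction"])
        ep_soft = extract_epochs(blink_rec, markers, {"blink_soft"},
                                 d["blink_window"], d["correction"])
        sacc_rec = _prepare(rec, config, d["saccade_band"], None)
        sacc_labels = {f"saccade_{dd}" for dd in
                       ("up", "down", "left", "right")}
        ep_sacc = extract_epochs(sacc_rec, markers, sacc_labels,
                                 d["saccade_window"], d["correction"])
        ep_sacc = baseline_correct(ep_sacc, config.baseline)
        for ch in _channels(rec, config):
            if ch == config.reference:
                continue
            bm = blink_metrics(ep_hard, ep_soft, ch)
            rows.append(row(ch, "blink_ratio", bm.ratio))
            rows.append(row(ch, "blink_p2p_hard_uv", bm.p2p_hard))
            rows.append(row(ch, "blink_p2p_soft_uv", bm.p2p_soft))
            profiles = saccade_profiles(ep_sacc, ch)
            for direction, prof in profiles.items():
                rows.append(row(ch, f"saccade_{direction}_uv",
                                prof.amplitude_at_t))
            for axis in ("horizontal", "vertical"):
                rows.append(row(ch, f"saccade_sep_{axis}_uv",
                                direction_separation(profiles, axis)))
        return rows

    raise AssertionError(f"unhandled paradigm {p}")  # pragma: no cover


_HEADLINE = {"assr": "snr_db", "ssvep": "snr_db", "alpha": "ram_db",
             "eog": "blink_ratio"}


def compare_references(path, config: AnalysisConfig, references: list[str]
                       ) -> pd.DataFrame:
    """Re-run one analysis under several reference schemes and rank.

    The ranking metric is the paradigm's headline quantity (SNR in dB
    for steady-state paradigms, modulation ratio for alpha blocking,
    blink ratio for EOG) averaged over the channels of interest,
    excluding whichever channel serves as the reference.  Deltas are
    reported against the first listed reference.
    """
    metric = _HEADLINE.get(config.paradigm)
    if metric is None:
        raise ValueError(
            f"no reference-comparison metric for {config.paradigm!r}")
    rows = []
    for ref in references:
        table = run_analysis(path, replace(config, reference=ref,
                                           out_dir=None))
        sub = table[(table.metric == metric) & (table.channel != ref)]
        rows.append({"reference": ref, "metric": metric,
                     "value": float(sub.value.mean()),
                     "n_channels": int(len(sub))})
    out = pd.DataFrame(rows)
    out["delta_vs_first"] = out["value"] - out["value"].iloc[0]
    return out.sort_values("value", ascending=False).reset_index(drop=True)
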