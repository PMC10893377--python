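"""Core domain containers and the trigger-latency estimator.

A :class:`Recording` is a uniformly sampled channels x samples matrix in
microvolts; a :class:`MarkerStream` is the ordered list of timestamped
string labels that delimit paradigms and stimuli.  Marker timestamps
live on the recording clock once aligned (an explicit ``clock_offset``
carries any residual offset between the two acquisition clocks).

The latency estimator quantifies the delay between a software marker and
the physical stimulus it announces, measured on a bench trace (audio
loopback or photodiode).  Stimulus-delivery chains introduce a roughly
constant delay plus jitter — for example a few tens of milliseconds for
a visual chain limited by monitor refresh — and downstream epoching
corrects event onsets by the measured mean delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Recording",
    "MarkerStream",
    "Montage",
    "LatencyEstimate",
    "estimate_marker_latency",
    "DEFAULT_SCALP_LABELS",
    "DEFAULT_EAR_LABELS",
]

#: 12-channel scalp montage used for benchmark recordings.
DEFAULT_SCALP_LABELS = (
    "F3", "Fz", "F4", "T7", "C3", "Cz", "C4", "T8", "P3", "Pz", "P4", "Oz",
)

#: Two 8-electrode earpieces, left (EL) and right (ER), numbered 1-8.
DEFAULT_EAR_LABELS = tuple(f"EL{i}" for i in range(1, 9)) + tuple(
    f"ER{i}" for i in range(1, 9)
)


@dataclass
class Recording:
    """Uniformly sampled multichannel recording.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array of amplitudes in microvolts.
    fs
        Sampling rate in Hz (typically 500).
    channel_labels
        Ordered unique channel names, one per data row.
    t0
        Start timestamp in seconds (recording clock).
    reference_label
        Name of the electrode the data are currently referenced to
        (e.g. the amplifier's hardware reference, or a channel after
        software re-referencing).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    t0: float = 0.0
    reference_label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[np.newaxis, :]
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Absolute sample timestamps in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not found; available: {self.channel_labels}"
            ) from None

    def get_channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def pick(self, labels: list[str]) -> "Recording":
        """Return a copy restricted to ``labels`` in the given order."""
        idx = [self.channel_index(lb) for lb in labels]
        return replace(self, data=self.data[idx].copy(),
                       channel_labels=list(labels))

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(),
                       channel_labels=list(self.channel_labels))


@dataclass
class MarkerStream:
    """Ordered timestamped string labels.

    ``clock_offset`` is the offset of the marker clock relative to the
    recording clock: an event stamped ``t`` occurred at
    ``t + clock_offset`` on the recording clock.
    """

    events: list[tuple[float, str]] = field(default_factory=list)
    clock_offset: float = 0.0

    def __post_init__(self) -> None:
        self.events = [(float(t), str(lb)) for t, lb in self.events]
        times = [t for t, _ in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("marker timestamps must be non-decreasing")
        if any(not lb for _, lb in self.events):
            raise ValueError("marker labels must be non-empty")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def times(self) -> np.ndarray:
        """Event times on the recording clock (offset applied)."""
        return np.array([t for t, _ in self.events]) + self.clock_offset

    @property
    def labels(self) -> list[str]:
        return [lb for _, lb in self.events]

    def select(self, labels) -> "MarkerStream":
        """Sub-stream with only the given label set (offset preserved)."""
        labels = set(labels)
        return MarkerStream(
            [(t, lb) for t, lb in self.events if lb in labels],
            clock_offset=self.clock_offset,
        )


@dataclass
class Montage:
    """Electrode layout: scalp labels, ear labels and electrode roles."""

    scalp_labels: tuple[str, ...] = DEFAULT_SCALP_LABELS
    ear_labels: tuple[str, ...] = DEFAULT_EAR_LABELS
    role_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.scalp_labels) & set(self.ear_labels)
        if overlap:
            raise ValueError(f"labels in both scalp and ear groups: {overlap}")
        unknown = set(self.role_map) - set(self.all_labels)
        if unknown:
            raise ValueError(f"role_map keys not in montage: {unknown}")
        bad_roles = set(self.role_map.values()) - {
            "recording", "reference", "ground"}
        if bad_roles:
            raise ValueError(f"unknown electrode roles: {bad_roles}")

    @property
    def all_labels(self) -> tuple[str, ...]:
        return tuple(self.scalp_labels) + tuple(self.ear_labels)

    def __contains__(self, label: str) -> bool:
        return label in self.all_labels


@dataclass
class LatencyEstimate:
    """Mean delay and jitter between markers and physical onsets."""

    mean_delay: float
    jitter: float
    n_events: int
    n_missed: int = 0

    def __post_init__(self) -> None:
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        if self.n_events < 1:
            raise ValueError("need at least one detected event")


class LatencyEstimationError(RuntimeError):
    """No physical onset could be matched to any marker."""


def _detect_onset(
    trace: np.ndarray,
    fs: float,
    start: int,
    stop: int,
    threshold_frac: float,
) -> float | None:
    """First threshold crossing of the rectified trace in [start, stop).

    Returns the crossing time in samples (float, sub-sample precision by
    linear interpolation between the last sub-threshold and first
    supra-threshold sample), or ``None`` if no crossing exists.
    """
    seg = np.abs(trace[start:stop])
    if seg.size == 0:
        return None
    peak = seg.max()
    if peak <= 0:
        return None
    thresh = threshold_frac * peak
    above = np.nonzero(seg >= thresh)[0]
    if above.size == 0:
        return None
    k = int(above[0])
    if k == 0:
        return float(start)
    y0, y1 = seg[k - 1], seg[k]
    # linear interpolation of the crossing between samples k-1 and k
    frac = (thresh - y0) / (y1 - y0) if y1 > y0 else 1.0
    return start + (k - 1) + float(frac)


def estimate_marker_latency(
    stim_trace: Recording,
    markers: MarkerStream,
    onset_threshold: float = 0.5,
    search_window: float = 0.2,
) -> LatencyEstimate:
    """Estimate marker-to-stimulus delay and jitter from a bench trace.

    For every marker, the rectified single-channel ``stim_trace`` is
    scanned over ``[marker, marker + search_window]`` for its first
    crossing of ``onset_threshold`` x the window's rectified maximum;
    the crossing time (sub-sample, linearly interpolated) is taken as
    the physical stimulus onset.  The estimate is the mean and standard
    deviation of onset minus marker time.  Markers with no detectable
    onset are excluded and counted in ``n_missed``.

    Parameters
    ----------
    stim_trace
        Single-channel recording of the physical stimulus (photodiode
        or audio loopback).
    markers
        Software markers, aligned to the recording clock.
    onset_threshold
        Fraction of the in-window rectified maximum that defines the
        onset crossing (default 0.5).
    search_window
        Post-marker search span in seconds (default 0.2).
    """
    if stim_trace.n_channels != 1:
        raise ValueError("stim_trace must have exactly one channel")
    if len(markers) < 1:
        raise ValueError("need at least one marker")
    trace = stim_trace.data[0]
    fs = stim_trace.fs
    delays = []
    n_missed = 0
    for t_marker in markers.times:
        rel = t_marker - stim_trace.t0
        start = max(0, int(np.ceil(rel * fs)))
        stop = min(stim_trace.n_samples, int(np.floor((rel + search_window) * fs)) + 1)
        if start >= stop:
            n_missed += 1
            continue
        onset_sample = _detect_onset(trace, fs, start, stop, onset_threshold)
        if onset_sample is None:
            n_missed += 1
            continue
        delays.append(stim_trace.t0 + onset_sample / fs - t_marker)
    if not delays:
        raise LatencyEstimationError(
            f"no detectable stimulus onset for any of {len(markers)} markers"
        )
    delays = np.asarray(delays)
    return LatencyEstimate(
        mean_delay=float(delays.mean()),
        jitter=float(delays.std(ddof=1)) if delays.size > 1 else 0.0,
        n_events=int(delays.size),
        n_missed=n_missed,
    )
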