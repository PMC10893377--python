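"""Electro-oculography: blink amplitude ratios and saccade profiles.

Blinks are quantified as the mean across trials of the within-epoch
peak-to-peak amplitude (after 0.2-3 Hz band-limiting, done upstream),
and the "blink ratio" is intentional (hard) over regular (soft) blink
peak-to-peak — a practical effect-size measure for blink-driven BCI
switches.  Saccades are quantified on their per-direction average
waves at a fixed assessment time (~200 ms after the cue, where the
directions separate most); horizontal saccades invert polarity between
left- and right-hemisphere sensing electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from earval.preprocess import Epochs

__all__ = [
    "BlinkMetrics",
    "SaccadeProfile",
    "blink_metrics",
    "saccade_profiles",
    "direction_separation",
    "SACCADE_DIRECTIONS",
]

SACCADE_DIRECTIONS = ("up", "down", "left", "right")

_AXES = {"horizontal": ("left", "right"), "vertical": ("up", "down")}


@dataclass
class BlinkMetrics:
    """Peak-to-peak amplitudes of hard vs soft blinks and their ratio."""

    p2p_hard: float
    p2p_soft: float
    ratio: float
    n_hard: int
    n_soft: int


@dataclass
class SaccadeProfile:
    """Average wave of one saccade direction on one channel."""

    direction: str
    wave: np.ndarray
    times: np.ndarray
    amplitude_at_t: float
    assessment_time: float


def _mean_p2p(ep: Epochs, channel: str) -> float:
    data = ep.data[:, ep.channel_index(channel), :]
    return float((data.max(axis=1) - data.min(axis=1)).mean())


def blink_metrics(ep_hard: Epochs, ep_soft: Epochs, channel: str
                  ) -> BlinkMetrics:
    """Hard/soft blink peak-to-peak amplitudes and their ratio.

    Expects blink-band (0.2-3 Hz) filtered, marker-locked epochs; the
    peak-to-peak is taken over the full epoch window (no additional
    blink search).
    """
    if ep_hard.n_trials < 1 or ep_soft.n_trials < 1:
        raise ValueError("both blink conditions need at least one trial")
    p2p_hard = _mean_p2p(ep_hard, channel)
    p2p_soft = _mean_p2p(ep_soft, channel)
    if p2p_soft <= 0:
        raise ValueError("soft-blink peak-to-peak is zero; ratio undefined")
    return BlinkMetrics(
        p2p_hard=p2p_hard,
        p2p_soft=p2p_soft,
        ratio=p2p_hard / p2p_soft,
        n_hard=ep_hard.n_trials,
        n_soft=ep_soft.n_trials,
    )


def saccade_profiles(ep: Epochs, channel: str,
                     assessment_time: float = 0.2,
                     directions=SACCADE_DIRECTIONS
                     ) -> dict[str, SaccadeProfile]:
    """Per-direction average saccade waves on one channel.

    ``ep.event_labels`` must contain every direction in ``directions``
    (labels may be bare directions or suffixed like ``saccade_left``).
    The amplitude is read at the sample nearest ``assessment_time``.
    """
    tmin, tmax = ep.window
    if not tmin <= assessment_time <= tmax:
        raise ValueError(f"assessment time {assessment_time} outside "
                         f"epoch window {ep.window}")
    ch = ep.channel_index(channel)
    times = ep.times
    at = int(np.argmin(np.abs(times - assessment_time)))
    profiles: dict[str, SaccadeProfile] = {}
    for direction in directions:
        idx = [i for i, lb in enumerate(ep.event_labels)
               if lb == direction or lb.endswith(f"_{direction}")]
        if not idx:
            raise ValueError(f"no trials for saccade direction {direction!r}")
        wave = ep.data[idx, ch, :].mean(axis=0)
        profiles[direction] = SaccadeProfile(
            direction=direction,
            wave=wave,
            times=times,
            amplitude_at_t=float(wave[at]),
            assessment_time=float(times[at]),
        )
    return profiles


def direction_separation(profiles: dict[str, SaccadeProfile],
                         axis: str) -> float:
    """|amplitude difference| between the two directions of an axis
    (``horizontal``: left vs right; ``vertical``: up vs down) at the
    assessment time."""
    try:
        a, b = _AXES[axis]
    except KeyError:
        raise ValueError(f"axis must be one of {sorted(_AXES)}") from None
    missing = {a, b} - set(profiles)
    if missing:
        raise ValueError(f"missing saccade directions: {sorted(missing)}")
    return abs(profiles[a].amplitude_at_t - profiles[b].amplitude_at_t)
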