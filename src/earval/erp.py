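"""Event-related potentials: averaging, difference waves, components.

Trial averages carry a per-timepoint significance mask from one-sample
two-tailed t-tests of the trial amplitudes against zero (p < alpha,
deliberately uncorrected for multiple comparisons, as is conventional
for descriptive ERP plots).  Oddball difference waves (mismatch
negativity, P300) subtract the average of the standards that
immediately precede a deviant from the average of the deviants, and
are masked with per-timepoint Welch two-sample t-tests.

Component metrics pick the signed extremum of the stated polarity in a
search window (e.g. N1 as the most negative deflection in 80-150 ms)
and optionally the peak-to-peak span between two components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from earval.preprocess import Epochs

__all__ = [
    "ErpResult",
    "DifferenceWave",
    "ComponentMetric",
    "average_erp",
    "oddball_difference",
    "component_metrics",
    "standards_before_deviants",
    "COMPONENT_WINDOWS",
]

#: Default component search windows in seconds (configurable; typical
#: adult latency ranges).
COMPONENT_WINDOWS = {
    "P1": (0.03, 0.08),
    "N1": (0.08, 0.15),
    "P2": (0.15, 0.30),
    "MMN": (0.10, 0.30),
    "P300": (0.25, 0.50),
}


@dataclass
class ErpResult:
    """Across-trial average with per-timepoint significance."""

    times: np.ndarray
    mean_wave: np.ndarray       # channels x samples, µV
    per_trial: np.ndarray       # trials x channels x samples
    sig_mask: np.ndarray        # channels x samples, bool
    alpha: float
    n_trials: int
    channel_labels: list[str]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in ERP") from None


@dataclass
class DifferenceWave:
    """Deviant-minus-standard average wave with significance mask."""

    times: np.ndarray
    wave: np.ndarray            # channels x samples, µV
    n_pairs: int
    sig_mask: np.ndarray
    alpha: float
    channel_labels: list[str]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in difference wave") from None


@dataclass
class ComponentMetric:
    """Peak amplitude/latency of one named ERP component."""

    name: str
    peak_amplitude: float
    peak_latency: float
    search_window: tuple[float, float]
    peak_to_peak: float | None = None


def _ttest_mask(trials: np.ndarray, alpha: float) -> np.ndarray:
    """Per-timepoint one-sample two-tailed t-test mask vs 0.

    Zero-variance timepoints take the limit behavior of t: mask true
    when the (constant) mean is nonzero, false when it is zero.
    """
    import warnings

    mean = trials.mean(axis=0)
    sd = trials.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"), \
            warnings.catch_warnings():
        # constant timepoints are handled by the explicit rule below
        warnings.simplefilter("ignore", RuntimeWarning)
        result = stats.ttest_1samp(trials, 0.0, axis=0)
        mask = result.pvalue < alpha
    degenerate = sd == 0
    mask[degenerate] = mean[degenerate] != 0
    return mask


def average_erp(ep: Epochs, alpha: float = 0.05) -> ErpResult:
    """Across-trial mean with uncorrected per-timepoint significance."""
    if ep.n_trials < 2:
        raise ValueError("averaging requires at least 2 trials")
    return ErpResult(
        times=ep.times,
        mean_wave=ep.data.mean(axis=0),
        per_trial=ep.data,
        sig_mask=_ttest_mask(ep.data, alpha),
        alpha=alpha,
        n_trials=ep.n_trials,
        channel_labels=list(ep.channel_labels),
    )


def standards_before_deviants(labels, standard: str, deviant: str
                              ) -> tuple[list[int], list[int]]:
    """Indices of deviant trials and of the standards immediately
    preceding a deviant in presentation order."""
    deviants = [i for i, lb in enumerate(labels) if lb == deviant]
    used_standards = [i - 1 for i in deviants
                      if i > 0 and labels[i - 1] == standard]
    return deviants, used_standards


def oddball_difference(ep: Epochs, standard: str = "standard",
                       deviant: str = "deviant", alpha: float = 0.05
                       ) -> DifferenceWave:
    """Deviant average minus the average of immediately-preceding
    standards.

    Only standards directly followed by a deviant enter the standard
    average (balancing slow drifts between the two classes); all
    deviants enter the deviant average.  Significance is a Welch
    two-sample two-tailed t-test per timepoint at ``alpha``,
    uncorrected.
    """
    deviants, used_standards = standards_before_deviants(
        ep.event_labels, standard, deviant)
    if len(deviants) < 2:
        raise ValueError(f"need >= 2 {deviant!r} trials, got {len(deviants)}")
    if not used_standards:
        raise ValueError(
            f"no {standard!r} trial immediately precedes a {deviant!r}")
    dev = ep.data[deviants]
    std = ep.data[used_standards]
    with np.errstate(divide="ignore", invalid="ignore"):
        result = stats.ttest_ind(dev, std, axis=0, equal_var=False)
        mask = np.nan_to_num(result.pvalue, nan=1.0) < alpha
    return DifferenceWave(
        times=ep.times,
        wave=dev.mean(axis=0) - std.mean(axis=0),
        n_pairs=min(len(deviants), len(used_standards)),
        sig_mask=mask,
        alpha=alpha,
        channel_labels=list(ep.channel_labels),
    )


def component_metrics(erp, channel: str, components,
                      peak_to_peak: tuple[str, str] | None = None
                      ) -> list[ComponentMetric]:
    """Quantify named components on one channel of an average wave.

    ``components`` is a list of ``(name, (tmin, tmax), polarity)``
    with polarity ``"positive"`` or ``"negative"``; the metric is the
    signed extremum in the window plus its latency (ties resolved to
    the earliest sample).  If ``peak_to_peak`` names two listed
    components, their absolute amplitude difference is attached to the
    second one.
    """
    ch = erp.channel_index(channel)
    wave = erp.mean_wave[ch] if hasattr(erp, "mean_wave") else erp.wave[ch]
    times = erp.times
    metrics: dict[str, ComponentMetric] = {}
    for name, window, polarity in components:
        lo, hi = window
        if lo < times[0] or hi > times[-1]:
            raise ValueError(
                f"window {window} for {name} outside epoch span "
                f"({times[0]:.3f}, {times[-1]:.3f})")
        mask = np.nonzero((times >= lo) & (times <= hi))[0]
        seg = wave[mask]
        pick = int(np.argmax(seg)) if polarity == "positive" else int(np.argmin(seg))
        metrics[name] = ComponentMetric(
            name=name,
            peak_amplitude=float(seg[pick]),
            peak_latency=float(times[mask[pick]]),
            search_window=(lo, hi),
        )
    if peak_to_peak is not None:
        a, b = peak_to_peak
        if a not in metrics or b not in metrics:
            raise ValueError(f"peak-to-peak components {peak_to_peak} "
                             "not among quantified components")
        metrics[b].peak_to_peak = abs(
            metrics[a].peak_amplitude - metrics[b].peak_amplitude)
    return list(metrics.values())
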