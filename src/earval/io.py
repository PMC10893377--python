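"""Reading and writing recordings with synchronized markers.

Two dialects, selected by file suffix:

``.xdf``
    The LSL session format: one numeric EEG stream (regular rate,
    channel labels in the stream header) plus zero or one string
    marker stream (irregular).  Irregular acquisition timestamps are
    regularized on read by anchoring the first timestamp and assuming
    the nominal rate — the standard offline treatment for
    regular-rate streams.

``.csv``
    A plain-text fallback for fixtures: a data table (``time`` column
    followed by one column per channel) with a ``# fs=... t0=...``
    metadata comment line, and a sibling ``<stem>.events.csv`` with
    ``timestamp,label`` rows.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from earval.core import MarkerStream, Recording
from earval.xdf import XdfFormatError, XdfStream, read_xdf, write_xdf

__all__ = ["read_recording", "write_recording",
           "XdfFormatError", "AmbiguousStreamsError"]


class AmbiguousStreamsError(ValueError):
    """File contains more than one candidate EEG stream."""


def read_recording(path) -> tuple[Recording, MarkerStream]:
    """Read a recording plus its marker stream.

    Returns the EEG data on a uniform grid at the nominal rate, with
    marker timestamps already expressed on the recording clock
    (``clock_offset`` 0).  Raises :class:`XdfFormatError` when no EEG
    stream is present and :class:`AmbiguousStreamsError` when several
    are.
    """
    path = Path(path)
    if path.suffix.lower() == ".xdf":
        return _read_xdf_recording(path)
    return _read_csv_recording(path)


def write_recording(rec: Recording, markers: MarkerStream, path) -> None:
    """Write ``rec`` and ``markers`` so that :func:`read_recording`
    recovers labels/fs losslessly and data within float tolerance.

    Marker times are materialized on the recording clock (any
    ``clock_offset`` is applied before writing).
    """
    path = Path(path)
    if path.suffix.lower() == ".xdf":
        _write_xdf_recording(rec, markers, path)
    else:
        _write_csv_recording(rec, markers, path)


# ---------------------------------------------------------------- XDF

def _read_xdf_recording(path) -> tuple[Recording, MarkerStream]:
    streams = read_xdf(path)
    eeg = [s for s in streams
           if s.channel_format != "string" and s.nominal_srate > 0]
    marker = [s for s in streams if s.channel_format == "string"]
    if not eeg:
        raise XdfFormatError(f"{path}: no regular-rate EEG stream found")
    if len(eeg) > 1:
        names = ", ".join(repr(s.name) for s in eeg)
        raise AmbiguousStreamsError(
            f"{path}: more than one EEG stream ({names}); "
            "this reader supports exactly one")
    stream = eeg[0]
    labels = stream.channel_labels or [
        f"ch{i}" for i in range(stream.channel_count)]
    t0 = float(stream.timestamps[0]) if len(stream.timestamps) else 0.0
    rec = Recording(
        data=np.asarray(stream.samples).T,
        fs=stream.nominal_srate,
        channel_labels=labels,
        t0=t0,
        reference_label=None,
    )
    events: list[tuple[float, str]] = []
    if marker:
        ms = marker[0]
        for ts, values in zip(ms.timestamps, ms.samples):
            events.append((float(ts), values[0]))
    return rec, MarkerStream(events)


def _write_xdf_recording(rec: Recording, markers: MarkerStream, path) -> None:
    eeg = XdfStream(
        stream_id=1,
        name="EEG",
        type="EEG",
        channel_count=rec.n_channels,
        nominal_srate=rec.fs,
        channel_format="double64",
        channel_labels=list(rec.channel_labels),
        samples=rec.data.T,
        timestamps=rec.times,
    )
    mk = XdfStream(
        stream_id=2,
        name="Markers",
        type="Markers",
        channel_count=1,
        nominal_srate=0.0,
        channel_format="string",
        samples=[[lb] for lb in markers.labels],
        timestamps=markers.times,
    )
    write_xdf(path, [eeg, mk])


# ---------------------------------------------------------------- CSV

def _events_path(path: Path) -> Path:
    return path.with_name(path.stem + ".events.csv")


def _write_csv_recording(rec: Recording, markers: MarkerStream, path) -> None:
    frame = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    frame.insert(0, "time", rec.times)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs!r} t0={rec.t0!r} "
                 f"reference={rec.reference_label or ''}\n")
        frame.to_csv(fh, index=False, float_format="%.8g")
    pd.DataFrame(
        {"timestamp": markers.times, "label": markers.labels}
    ).to_csv(_events_path(Path(path)), index=False)


def _read_csv_recording(path) -> tuple[Recording, MarkerStream]:
    path = Path(path)
    with open(path) as fh:
        meta_line = fh.readline()
    if not meta_line.startswith("#"):
        raise XdfFormatError(f"{path}: missing '# fs=...' metadata line")
    meta = dict(item.split("=", 1)
                for item in meta_line[1:].split() if "=" in item)
    frame = pd.read_csv(path, comment="#")
    if "time" not in frame.columns:
        raise XdfFormatError(f"{path}: missing 'time' column")
    labels = [c for c in frame.columns if c != "time"]
    rec = Recording(
        data=frame[labels].to_numpy().T,
        fs=float(meta["fs"]),
        channel_labels=labels,
        t0=float(meta.get("t0", 0.0)),
        reference_label=meta.get("reference") or None,
    )
    events_file = _events_path(path)
    events: list[tuple[float, str]] = []
    if events_file.exists():
        table = pd.read_csv(events_file)
        if len(table):
            events = list(zip(table["timestamp"].astype(float),
                              table["label"].astype(str)))
    return rec, MarkerStream(events)
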