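"""Minimal XDF (Extensible Data Format) reader/writer.

Supports the dialect produced by LSL-style recorders for a single
session: one regularly sampled numeric stream (EEG) plus at most one
irregular string-marker stream.  Chunk types handled: FileHeader,
StreamHeader, Samples, StreamFooter; Boundary and ClockOffset chunks
are skipped on read (clock alignment is exposed to callers through
``MarkerStream.clock_offset`` instead of being resolved silently).

Numeric payloads are written as ``double64`` so that round-trips are
lossless to well below 1e-6 microvolt; ``float32`` and the other fixed
integer formats are accepted on read.
"""

from __future__ import annotations

import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np

__all__ = ["XdfStream", "read_xdf", "write_xdf", "XdfFormatError"]

_MAGIC = b"XDF:"

_TAG_FILE_HEADER = 1
_TAG_STREAM_HEADER = 2
_TAG_SAMPLES = 3
_TAG_CLOCK_OFFSET = 4
_TAG_BOUNDARY = 5
_TAG_STREAM_FOOTER = 6

_NUMERIC_FMTS = {
    "float32": ("<f", 4),
    "double64": ("<d", 8),
    "int8": ("<b", 1),
    "int16": ("<h", 2),
    "int32": ("<i", 4),
    "int64": ("<q", 8),
}


class XdfFormatError(ValueError):
    """File is not parseable as the supported XDF dialect."""


@dataclass
class XdfStream:
    """One stream: header metadata plus collected samples."""

    stream_id: int
    name: str
    type: str
    channel_count: int
    nominal_srate: float
    channel_format: str
    channel_labels: list[str] = field(default_factory=list)
    # numeric streams: (n_samples, n_channels) float array
    samples: np.ndarray | list = None
    # per-sample timestamps; NaN where the file omitted them
    timestamps: np.ndarray = None


def _write_varlen(buf: bytearray, value: int) -> None:
    if value < 256:
        buf += struct.pack("<BB", 1, value)
    elif value < 2**32:
        buf += struct.pack("<BI", 4, value)
    else:
        buf += struct.pack("<BQ", 8, value)


def _write_chunk(fh, tag: int, content: bytes) -> None:
    head = bytearray()
    _write_varlen(head, len(content) + 2)
    fh.write(bytes(head))
    fh.write(struct.pack("<H", tag))
    fh.write(content)


def _header_xml(stream: XdfStream) -> bytes:
    info = ET.Element("info")
    for key, val in [
        ("name", stream.name),
        ("type", stream.type),
        ("channel_count", str(stream.channel_count)),
        ("nominal_srate", repr(float(stream.nominal_srate))),
        ("channel_format", stream.channel_format),
    ]:
        ET.SubElement(info, key).text = val
    if stream.channel_labels:
        channels = ET.SubElement(ET.SubElement(info, "desc"), "channels")
        for label in stream.channel_labels:
            ET.SubElement(ET.SubElement(channels, "channel"), "label").text = label
    return ET.tostring(info, encoding="unicode").encode("utf-8")


def write_xdf(path, streams: list[XdfStream]) -> None:
    """Write streams to ``path``.

    Numeric streams must carry ``samples`` as an (n_samples,
    n_channels) array; string streams as a list of per-sample
    ``[value]`` lists.  ``timestamps`` must be per-sample; for regular
    streams only the first timestamp of a chunk is materialized in the
    file (the rest are implied at the nominal rate).
    """
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        _write_chunk(fh, _TAG_FILE_HEADER,
                     b'<info><version>1.0</version></info>')
        for stream in streams:
            content = struct.pack("<I", stream.stream_id) + _header_xml(stream)
            _write_chunk(fh, _TAG_STREAM_HEADER, content)
        for stream in streams:
            if stream.channel_format in _NUMERIC_FMTS:
                _write_numeric_samples(fh, stream)
            elif stream.channel_format == "string":
                _write_string_samples(fh, stream)
            else:
                raise XdfFormatError(
                    f"unsupported channel_format {stream.channel_format!r}")
        for stream in streams:
            footer = struct.pack("<I", stream.stream_id) + (
                b"<info><sample_count>%d</sample_count></info>"
                % _n_samples(stream))
            _write_chunk(fh, _TAG_STREAM_FOOTER, footer)


def _n_samples(stream: XdfStream) -> int:
    if stream.samples is None:
        return 0
    return len(stream.samples)


def _write_numeric_samples(fh, stream: XdfStream) -> None:
    data = np.asarray(stream.samples, dtype=float)
    n = data.shape[0]
    if n == 0:
        return
    fmt, _ = _NUMERIC_FMTS[stream.channel_format]
    ts = np.asarray(stream.timestamps, dtype=float)
    body = bytearray()
    body += struct.pack("<I", stream.stream_id)
    _write_varlen(body, n)
    row_fmt = "<" + fmt[1] * data.shape[1]
    for i in range(n):
        if i == 0:
            body += struct.pack("<Bd", 8, float(ts[0]))
        else:
            body += b"\x00"
        body += struct.pack(row_fmt, *data[i])
    _write_chunk(fh, _TAG_SAMPLES, bytes(body))


def _write_string_samples(fh, stream: XdfStream) -> None:
    n = _n_samples(stream)
    if n == 0:
        return
    ts = np.asarray(stream.timestamps, dtype=float)
    body = bytearray()
    body += struct.pack("<I", stream.stream_id)
    _write_varlen(body, n)
    for i in range(n):
        body += struct.pack("<Bd", 8, float(ts[i]))
        for value in stream.samples[i]:
            raw = str(value).encode("utf-8")
            _write_varlen(body, len(raw))
            body += raw
    _write_chunk(fh, _TAG_SAMPLES, bytes(body))


def _read_varlen(buf: bytes, pos: int) -> tuple[int, int]:
    nbytes = buf[pos]
    pos += 1
    if nbytes == 1:
        return buf[pos], pos + 1
    if nbytes == 4:
        return struct.unpack_from("<I", buf, pos)[0], pos + 4
    if nbytes == 8:
        return struct.unpack_from("<Q", buf, pos)[0], pos + 8
    raise XdfFormatError(f"invalid varlen size byte {nbytes}")


def _parse_header(content: bytes) -> XdfStream:
    stream_id = struct.unpack_from("<I", content)[0]
    root = ET.fromstring(content[4:].decode("utf-8"))
    labels = [el.text or "" for el in root.findall("desc/channels/channel/label")]
    return XdfStream(
        stream_id=stream_id,
        name=root.findtext("name", ""),
        type=root.findtext("type", ""),
        channel_count=int(root.findtext("channel_count", "1")),
        nominal_srate=float(root.findtext("nominal_srate", "0")),
        channel_format=root.findtext("channel_format", "float32"),
        channel_labels=labels,
        samples=[],
        timestamps=None,
    )


def _parse_samples(content: bytes, streams: dict[int, XdfStream],
                   raw_ts: dict[int, list]) -> None:
    stream_id = struct.unpack_from("<I", content)[0]
    if stream_id not in streams:
        raise XdfFormatError(f"samples for undeclared stream {stream_id}")
    stream = streams[stream_id]
    n, pos = _read_varlen(content, 4)
    numeric = stream.channel_format in _NUMERIC_FMTS
    if numeric:
        fmt, size = _NUMERIC_FMTS[stream.channel_format]
        row_fmt = "<" + fmt[1] * stream.channel_count
        row_size = size * stream.channel_count
    for _ in range(n):
        ts_bytes = content[pos]
        pos += 1
        if ts_bytes == 8:
            ts = struct.unpack_from("<d", content, pos)[0]
            pos += 8
        elif ts_bytes == 0:
            ts = np.nan
        else:
            raise XdfFormatError(f"invalid timestamp size byte {ts_bytes}")
        raw_ts[stream_id].append(ts)
        if numeric:
            stream.samples.append(struct.unpack_from(row_fmt, content, pos))
            pos += row_size
        else:
            values = []
            for _ in range(stream.channel_count):
                length, pos = _read_varlen(content, pos)
                values.append(content[pos:pos + length].decode("utf-8"))
                pos += length
            stream.samples.append(values)


def read_xdf(path) -> list[XdfStream]:
    """Read all streams from an XDF file.

    Per-sample timestamps are reconstructed: omitted timestamps are
    filled forward at the stream's nominal rate.  Numeric streams come
    back with ``samples`` as an (n_samples, n_channels) float array.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if blob[:4] != _MAGIC:
        raise XdfFormatError(f"{path}: not an XDF file (bad magic)")
    streams: dict[int, XdfStream] = {}
    raw_ts: dict[int, list] = {}
    pos = 4
    while pos < len(blob):
        length, pos = _read_varlen(blob, pos)
        tag = struct.unpack_from("<H", blob, pos)[0]
        content = blob[pos + 2:pos + length]
        pos += length
        if tag == _TAG_STREAM_HEADER:
            stream = _parse_header(content)
            streams[stream.stream_id] = stream
            raw_ts[stream.stream_id] = []
        elif tag == _TAG_SAMPLES:
            _parse_samples(content, streams, raw_ts)
        elif tag in (_TAG_FILE_HEADER, _TAG_CLOCK_OFFSET, _TAG_BOUNDARY,
                     _TAG_STREAM_FOOTER):
            continue
        else:
            raise XdfFormatError(f"unknown chunk tag {tag}")
    out = []
    for sid, stream in streams.items():
        ts = np.asarray(raw_ts[sid], dtype=float)
        if ts.size and np.isnan(ts).any():
            ts = _fill_timestamps(ts, stream.nominal_srate)
        stream.timestamps = ts
        if stream.channel_format in _NUMERIC_FMTS:
            stream.samples = np.asarray(stream.samples, dtype=float).reshape(
                -1, stream.channel_count)
        out.append(stream)
    return out


def _fill_timestamps(ts: np.ndarray, srate: float) -> np.ndarray:
    if srate <= 0:
        raise XdfFormatError(
            "omitted timestamps in a stream with no nominal rate")
    dt = 1.0 / srate
    filled = ts.copy()
    last = None
    for i, value in enumerate(filled):
        if np.isnan(value):
            if last is None:
                raise XdfFormatError("first sample of a chunk lacks a timestamp")
            filled[i] = last + dt
        last = filled[i]
    return filled
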