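"""Plain-text (TSV/CSV) readers and writers for traces, session logs,
events/annotations and cohort tables.

The on-disk trace format is a TSV with a '#'-prefixed header block (keys:
version, content, sampling_rate_hz, units, protocol fields, meta fields) and
columns ``time_s``, ``voltage_mv``, ``current_na``.  Events and annotations
share a TSV with columns ``time_s``, ``kind``, ``value``.  Chosen over binary
containers for diffability; vendor formats (ABF, HEKA) and NWB are
deliberately out of scope.

The estimated tip-offset potential (default -14 mV for a K-gluconate
solution) is applied to the voltage exactly once: the header flag
``tip_offset_applied`` records whether the stored column already includes it.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    ANNOTATION_KINDS,
    EVENT_KINDS,
    Annotation,
    CurrentClampTrace,
    Event,
    PulseTrain,
    SessionLog,
    StepProtocol,
)

FORMAT_VERSION = 1
_FLOAT_FMT = "%.6f"  # declared numeric precision of the text format

_META_STR_KEYS = {"cell_id", "species", "protocol_role", "endpoint_true"}


def _header_lines(content, sampling_rate, protocol, meta):
    lines = [
        f"# touchzap_tsv_version: {FORMAT_VERSION}",
        f"# content: {content}",
        f"# sampling_rate_hz: {sampling_rate:.10g}",
        "# units: time_s=s voltage_mv=mV current_na=nA",
    ]
    if isinstance(protocol, StepProtocol):
        lines += [
            "# protocol: step",
            f"# protocol_onset_s: {protocol.onset_s:.10g}",
            f"# protocol_duration_s: {protocol.duration_s:.10g}",
            f"# protocol_amplitude_na: {protocol.amplitude_na:.10g}",
            f"# protocol_inter_sweep_s: {protocol.inter_sweep_s:.10g}",
        ]
    elif isinstance(protocol, PulseTrain):
        lines += [
            "# protocol: pulse_train",
            f"# protocol_frequency_hz: {protocol.frequency_hz:.10g}",
            f"# protocol_duty: {protocol.duty:.10g}",
            f"# protocol_amplitude_na: {protocol.amplitude_na:.10g}",
            f"# protocol_start_s: {protocol.start_s:.10g}",
        ]
        if protocol.stop_s is not None:
            lines.append(f"# protocol_stop_s: {protocol.stop_s:.10g}")
    else:
        lines.append("# protocol: none")
    for key in sorted(meta):
        val = meta[key]
        if val is None:
            continue
        if isinstance(val, bool):
            val = str(val).lower()
        lines.append(f"# meta_{key}: {val}")
    return lines


def _parse_header(path):
    header = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                header[key.strip()] = val.strip()
    return header, n_header


def _parse_protocol(header):
    kind = header.get("protocol", "none")
    try:
        if kind == "step":
            return StepProtocol(
                onset_s=float(header["protocol_onset_s"]),
                duration_s=float(header["protocol_duration_s"]),
                amplitude_na=float(header["protocol_amplitude_na"]),
                inter_sweep_s=float(header.get("protocol_inter_sweep_s", 1.0)),
            )
        if kind == "pulse_train":
            stop = header.get("protocol_stop_s")
            return PulseTrain(
                frequency_hz=float(header["protocol_frequency_hz"]),
                duty=float(header["protocol_duty"]),
                amplitude_na=float(header["protocol_amplitude_na"]),
                start_s=float(header.get("protocol_start_s", 0.0)),
                stop_s=float(stop) if stop is not None else None,
            )
    except KeyError as exc:
        raise ValueError(f"incomplete {kind} protocol header: missing {exc}") from exc
    return None


def _parse_meta(header):
    meta = {}
    for key, val in header.items():
        if not key.startswith("meta_"):
            continue
        name = key[5:]
        if val in ("true", "false"):
            meta[name] = val == "true"
        elif name in _META_STR_KEYS:
            meta[name] = val
        else:
            try:
                meta[name] = float(val)
            except ValueError:
                meta[name] = val
    return meta


def _read_columns(path, n_header):
    data = pd.read_csv(path, sep="\t", skiprows=n_header)
    for col in ("time_s", "voltage_mv", "current_na"):
        if col not in data.columns:
            raise ValueError(f"trace file missing required column {col!r}")
    if data[["voltage_mv", "current_na"]].isna().any().any():
        raise ValueError("voltage and current columns differ in length (missing values found)")
    return data


def _require(header, key):
    if key not in header:
        raise ValueError(f"file header is missing required field {key!r}")
    return header[key]


def write_trace(trace: CurrentClampTrace, path) -> None:
    """Write a trace as headered TSV at the declared numeric precision."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write("\n".join(_header_lines("trace", trace.sampling_rate, trace.protocol, trace.meta)))
    buf.write("\ntime_s\tvoltage_mv\tcurrent_na\n")
    cols = np.column_stack([trace.times, trace.voltage, trace.current])
    np.savetxt(buf, cols, fmt=_FLOAT_FMT, delimiter="\t")
    path.write_text(buf.getvalue())


def read_trace(path) -> CurrentClampTrace:
    """Read a trace TSV; applies the tip offset exactly once (idempotent)."""
    header, n_header = _parse_header(path)
    _require(header, "units")
    rate = float(_require(header, "sampling_rate_hz"))
    data = _read_columns(path, n_header)
    meta = _parse_meta(header)
    voltage = data["voltage_mv"].to_numpy()
    tip = meta.get("tip_offset_mv")
    if tip is not None and not meta.get("tip_offset_applied", False):
        voltage = voltage + tip
        meta["tip_offset_applied"] = True
    return CurrentClampTrace(
        sampling_rate=rate,
        voltage=voltage,
        current=data["current_na"].to_numpy(),
        protocol=_parse_protocol(header),
        meta=meta,
    )


def write_session(log: SessionLog, path, annotations_path=None) -> None:
    """Write a session log as headered TSV; annotations go to a sibling
    ``<stem>.annotations.tsv`` (or ``annotations_path``)."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write("\n".join(_header_lines("session", log.sampling_rate, log.pulse_train, log.meta)))
    buf.write("\ntime_s\tvoltage_mv\tcurrent_na\n")
    cols = np.column_stack([log.times, log.voltage, log.current])
    np.savetxt(buf, cols, fmt=_FLOAT_FMT, delimiter="\t")
    path.write_text(buf.getvalue())
    if annotations_path is None:
        annotations_path = path.with_suffix(".annotations.tsv")
    write_events(log.annotations, annotations_path)


def read_session(path, annotations_path=None) -> SessionLog:
    """Read a session TSV (+ optional annotation TSV) back into a SessionLog."""
    header, n_header = _parse_header(path)
    _require(header, "units")
    rate = float(_require(header, "sampling_rate_hz"))
    data = _read_columns(path, n_header)
    protocol = _parse_protocol(header)
    annotations = []
    if annotations_path is None:
        candidate = Path(path).with_suffix(".annotations.tsv")
        if candidate.exists():
            annotations_path = candidate
    if annotations_path is not None:
        annotations = [a for a in read_events(annotations_path) if isinstance(a, Annotation)]
    return SessionLog(
        sampling_rate=rate,
        voltage=data["voltage_mv"].to_numpy(),
        current=data["current_na"].to_numpy(),
        pulse_train=protocol if isinstance(protocol, PulseTrain) else None,
        annotations=annotations,
        meta=_parse_meta(header),
    )


def write_events(items: Sequence[Union[Event, Annotation]], path) -> None:
    """Write events and/or annotations as TSV ordered by time."""
    path = Path(path)
    lines = [
        f"# touchzap_tsv_version: {FORMAT_VERSION}",
        "# content: events",
        "time_s\tkind\tvalue",
    ]
    for item in sorted(items, key=lambda x: x.time_s):
        val = item.value
        if val is None:
            sval = ""
        elif isinstance(val, float):
            sval = f"{val:.6f}"
        else:
            sval = str(val)
        lines.append(f"{item.time_s:.6f}\t{item.kind}\t{sval}")
    path.write_text("\n".join(lines) + "\n")


def read_events(path) -> List[Union[Event, Annotation]]:
    """Read an event/annotation TSV.  Unknown kinds are rejected; unsorted
    input is sorted on read with a warning; duplicate timestamps are fine."""
    path = Path(path)
    items: List[Union[Event, Annotation]] = []
    times = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("time_s"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed event line: {line!r}")
            t = float(parts[0])
            kind = parts[1].strip()
            sval = parts[2].strip() if len(parts) > 2 else ""
            if kind in EVENT_KINDS:
                if kind == "zap" and not sval:
                    raise ValueError("zap event is missing its V_zap value")
                items.append(Event(t, kind, float(sval) if sval else None))
            elif kind in ANNOTATION_KINDS:
                items.append(Annotation(t, kind, sval))
            else:
                raise ValueError(
                    f"unknown kind {kind!r}; expected one of {sorted(EVENT_KINDS | ANNOTATION_KINDS)}"
                )
            times.append(t)
    if any(b < a for a, b in zip(times, times[1:])):
        warnings.warn(f"{path.name}: events were not time-ordered; sorted on read", stacklevel=2)
        items.sort(key=lambda x: x.time_s)
    return items


def write_records(records: pd.DataFrame, path) -> None:
    """Write a cohort table (one row per cell) as CSV."""
    pd.DataFrame(records).to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path)


__all__ = [
    "FORMAT_VERSION",
    "read_trace",
    "write_trace",
    "read_session",
    "write_session",
    "read_events",
    "write_events",
    "read_records",
    "write_records",
]
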