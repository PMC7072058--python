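"""Readers and writers: pulse-trace CSV, FCS 3.1 listmode, and report files.

Two on-disk dialects carry event data:

* a documented long-format **pulse CSV** holding the full per-channel traces
  (the stand-in for the instrument's native profile export), and
* **FCS 3.1** listmode files holding the derived per-event features, one
  float parameter per (channel x feature), for interoperability with the
  wider cytometry tool ecosystem.  FCS has no standard encoding for full
  traces, so only feature tables travel as FCS.

All writers are atomic (write to a temp file, then rename) and all readers
reject malformed input rather than silently coercing it.
"""

from __future__ import annotations

import io as _io
import json
import os
import struct
import tempfile
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .pulse import (
    CHANNELS,
    MORPHOLOGY_LABELS,
    POPULATION_LABELS,
    EventFeatureTable,
    ParameterError,
    PulseEvent,
    feature_columns,
)


class FormatError(ValueError):
    """Input file does not conform to the expected dialect."""


# ---------------------------------------------------------------------------
# atomic writes

def _atomic_write_bytes(path: str | Path, payload: bytes) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_text(path: str | Path, text: str) -> None:
    _atomic_write_bytes(path, text.encode("utf-8"))


# ---------------------------------------------------------------------------
# pulse CSV dialect
#
#   # cytogate-pulse-csv v1
#   # sample_spacing_um: 0.5
#   # adc_max: 65535
#   event_id,channel,sample_index,value
#   0,FSC,0,12.0
#   ...

PULSE_CSV_MAGIC = "# cytogate-pulse-csv v1"


def write_pulse_csv(events: Sequence[PulseEvent], path: str | Path) -> None:
    """Serialize pulse events to the documented long-format CSV dialect."""
    events = list(events)
    if not events:
        raise ParameterError("cannot write an empty event collection")
    spacing = events[0].sample_spacing
    adc_max = events[0].adc_max
    buf = _io.StringIO()
    buf.write(f"{PULSE_CSV_MAGIC}\n")
    buf.write(f"# sample_spacing_um: {float(spacing)!r}\n")
    buf.write(f"# adc_max: {float(adc_max)!r}\n")
    buf.write("event_id,channel,sample_index,value\n")
    for ev in events:
        for channel in CHANNELS:
            trace = ev.channel_traces[channel]
            for i, v in enumerate(trace):
                buf.write(f"{ev.event_id},{channel},{i},{float(v)!r}\n")
    _atomic_write_text(path, buf.getvalue())


def read_pulse_csv(path: str | Path) -> list[PulseEvent]:
    """Read pulse events from the long-format CSV dialect.

    Raises :class:`FormatError` naming the offending event for a missing
    channel, or the offending line for a non-numeric value.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    header: dict[str, float] = {}
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                try:
                    header[key.strip()] = float(val)
                except ValueError:
                    pass
            continue
        data_start = i
        break
    else:
        raise FormatError(f"{path}: no data rows")
    if "sample_spacing_um" not in header or "adc_max" not in header:
        raise FormatError(f"{path}: header must declare sample_spacing_um and adc_max")

    df = pd.read_csv(_io.StringIO("".join(lines[data_start:])), dtype=str)
    expected_cols = ["event_id", "channel", "sample_index", "value"]
    if list(df.columns) != expected_cols:
        raise FormatError(f"{path}: expected columns {expected_cols}, got {list(df.columns)}")
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        bad = int(values.isna().idxmax())
        raise FormatError(
            f"{path}: non-numeric value {df['value'].iloc[bad]!r} at line "
            f"{data_start + 2 + bad}"
        )
    for col in ("event_id", "sample_index"):
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            bad = int(converted.isna().idxmax())
            raise FormatError(
                f"{path}: non-numeric {col} {df[col].iloc[bad]!r} at line "
                f"{data_start + 2 + bad}"
            )
        df[col] = converted.astype(int)
    df["value"] = values.astype(float)

    events: list[PulseEvent] = []
    for event_id, grp in df.groupby("event_id", sort=True):
        traces: dict[str, np.ndarray] = {}
        for channel in CHANNELS:
            sub = grp[grp["channel"] == channel]
            if sub.empty:
                raise FormatError(f"{path}: event {event_id} missing channel {channel}")
            sub = sub.sort_values("sample_index")
            traces[channel] = sub["value"].to_numpy()
        lengths = {len(t) for t in traces.values()}
        if len(lengths) != 1:
            raise FormatError(f"{path}: event {event_id} has unequal trace lengths")
        events.append(
            PulseEvent(
                event_id=int(event_id),
                channel_traces=traces,
                sample_spacing=header["sample_spacing_um"],
                adc_max=header["adc_max"],
            )
        )
    return events


def write_labels_csv(labels: pd.DataFrame, path: str | Path) -> None:
    """Write a ground-truth label sidecar (event_id, label, morphology)."""
    _atomic_write_text(path, labels.to_csv(index=False))


# ---------------------------------------------------------------------------
# FCS 3.1 listmode

_LABEL_CODES = {name: i for i, name in enumerate(POPULATION_LABELS)}
_MORPH_CODES = {name: i for i, name in enumerate(MORPHOLOGY_LABELS)}
_HEADER_LEN = 58


def _fcs_parameters(table: EventFeatureTable) -> list[str]:
    params = ["EVENT_ID", *[c.upper() for c in feature_columns()]]
    if "label" in table.data.columns:
        params.append("LABEL_CODE")
    if "morphology" in table.data.columns:
        params.append("MORPH_CODE")
    return params


def write_fcs_listmode(table: EventFeatureTable, path: str | Path) -> None:
    """Write an :class:`EventFeatureTable` as an FCS 3.1 float listmode file.

    One float32 parameter per (channel x feature) plus ``EVENT_ID`` and, when
    present, integer-coded ``LABEL_CODE`` / ``MORPH_CODE`` parameters whose
    code maps are recorded as custom TEXT keywords.
    """
    if len(table) == 0:
        raise ParameterError("cannot write an empty feature table to FCS")
    params = _fcs_parameters(table)
    df = table.data
    mat = np.empty((len(df), len(params)), dtype="<f4")
    for j, name in enumerate(params):
        if name == "EVENT_ID":
            col = df["event_id"].to_numpy(dtype=float)
        elif name == "LABEL_CODE":
            col = df["label"].map(_LABEL_CODES).to_numpy(dtype=float)
        elif name == "MORPH_CODE":
            col = df["morphology"].map(_MORPH_CODES).to_numpy(dtype=float)
        else:
            col = df[name.lower()].to_numpy(dtype=float)
        mat[:, j] = col

    delim = "/"
    n_bytes = mat.nbytes

    def build_text(begin_data: int, end_data: int) -> str:
        kv: list[tuple[str, str]] = [
            ("$BEGINANALYSIS", "0"),
            ("$ENDANALYSIS", "0"),
            ("$BEGINSTEXT", "0"),
            ("$ENDSTEXT", "0"),
            ("$BEGINDATA", f"{begin_data:010d}"),
            ("$ENDDATA", f"{end_data:010d}"),
            ("$BYTEORD", "1,2,3,4"),
            ("$DATATYPE", "F"),
            ("$MODE", "L"),
            ("$NEXTDATA", "0"),
            ("$PAR", str(len(params))),
            ("$TOT", str(len(df))),
            # the TEXT delimiter ('/') must not appear inside values: encode it
            ("CYTOGATE_LABEL_MAP",
             "|".join(f"{v}:{k.replace('/', '%2F')}" for k, v in _LABEL_CODES.items())),
            ("CYTOGATE_MORPH_MAP",
             "|".join(f"{v}:{k.replace('/', '%2F')}" for k, v in _MORPH_CODES.items())),
        ]
        for j, name in enumerate(params, start=1):
            kv += [
                (f"$P{j}N", name),
                (f"$P{j}B", "32"),
                (f"$P{j}E", "0,0"),
                (f"$P{j}R", "262144"),
            ]
        return delim + delim.join(f"{k}{delim}{v}" for k, v in kv) + delim

    # offsets depend on TEXT length; the fixed-width $BEGINDATA/$ENDDATA
    # values make the length independent of the actual offsets
    text_len = len(build_text(0, 0))
    text_begin = _HEADER_LEN
    text_end = text_begin + text_len - 1
    data_begin = text_end + 1
    data_end = data_begin + n_bytes - 1
    text = build_text(data_begin, data_end)
    assert len(text) == text_len

    def hdr_off(x: int) -> bytes:
        s = str(x) if x <= 99_999_999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + b"".join(
        hdr_off(x) for x in (text_begin, text_end, data_begin, data_end, 0, 0)
    )
    assert len(header) == _HEADER_LEN
    _atomic_write_bytes(path, header + text.encode("ascii") + mat.tobytes())


def read_fcs_listmode(path: str | Path) -> EventFeatureTable:
    """Read a float-mode FCS 3.1 listmode file back into an :class:`EventFeatureTable`."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_LEN:
        raise FormatError(f"{path}: truncated FCS header")
    version = raw[:6].decode("ascii", errors="replace")
    if version != "FCS3.1":
        raise FormatError(f"{path}: unsupported FCS version {version!r}")
    offs = [raw[10 + 8 * i : 18 + 8 * i].decode("ascii").strip() for i in range(6)]
    text_begin, text_end = int(offs[0]), int(offs[1])
    text = raw[text_begin : text_end + 1].decode("ascii")
    delim, body = text[0], text[1:]
    if body.endswith(delim):
        body = body[:-1]
    fields = body.split(delim)
    if len(fields) % 2:
        raise FormatError(f"{path}: malformed TEXT segment")
    kw = {fields[i]: fields[i + 1] for i in range(0, len(fields), 2)}

    if kw.get("$DATATYPE") != "F" or kw.get("$MODE") != "L":
        raise FormatError(f"{path}: only float list-mode FCS is supported")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord == "1,2,3,4" else ">"
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    data_begin = int(kw.get("$BEGINDATA") or offs[2])
    data_end = int(kw.get("$ENDDATA") or offs[3])
    n_bytes = data_end - data_begin + 1
    if n_bytes != 4 * n_par * n_tot:
        raise FormatError(f"{path}: DATA segment size mismatch")
    mat = np.frombuffer(raw[data_begin : data_end + 1], dtype=f"{endian}f4").reshape(
        n_tot, n_par
    )
    names = [kw.get(f"$P{j}N", f"P{j}") for j in range(1, n_par + 1)]
    df = pd.DataFrame(mat.astype(float), columns=names)

    out = pd.DataFrame({"event_id": df["EVENT_ID"].round().astype(int)})
    for col in feature_columns():
        name = col.upper()
        if name not in df.columns:
            raise FormatError(f"{path}: missing feature parameter {name}")
        if col.endswith("_saturated"):
            out[col] = df[name] > 0.5
        else:
            out[col] = df[name]
    if "LABEL_CODE" in df.columns:
        rev = {v: k for k, v in _LABEL_CODES.items()}
        out["label"] = df["LABEL_CODE"].round().astype(int).map(rev)
    if "MORPH_CODE" in df.columns:
        rev = {v: k for k, v in _MORPH_CODES.items()}
        out["morphology"] = df["MORPH_CODE"].round().astype(int).map(rev)
    return EventFeatureTable(out)


# ---------------------------------------------------------------------------
# result reports

def _jsonable(obj: Any) -> Any:
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(result: Any, path: str | Path, format: str = "json") -> None:
    """Serialize a classification/calibration/monitoring result losslessly.

    ``format="json"`` writes the nested structure directly; ``format="csv"``
    writes two columns (``field,value``) with nested values JSON-encoded, so
    the CSV form round-trips too.
    """
    payload = _jsonable(result)
    fmt = format.lower()
    if fmt == "json":
        _atomic_write_text(path, json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif fmt == "csv":
        if not isinstance(payload, Mapping):
            raise ParameterError("csv reports require a mapping-like result")
        rows = ["field,value"]
        for k, v in payload.items():
            rows.append(f"{k},{json.dumps(v)}" if not isinstance(v, str) else f"{k},{json.dumps(v)}")
        _atomic_write_text(path, "\n".join(rows) + "\n")
    else:
        raise ParameterError(f"unknown report format {format!r}; use 'json' or 'csv'")


def read_report(path: str | Path, format: str = "json") -> dict[str, Any]:
    """Read a report written by :func:`write_report` back into a dict."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "json":
        return json.loads(path.read_text())
    if fmt == "csv":
        out: dict[str, Any] = {}
        lines = path.read_text().splitlines()
        if not lines or lines[0] != "field,value":
            raise FormatError(f"{path}: not a cytogate csv report")
        for line in lines[1:]:
            key, _, val = line.partition(",")
            out[key] = json.loads(val)
        return out
    raise ParameterError(f"unknown report format {format!r}")
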