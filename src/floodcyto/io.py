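"""Event-level cytometry I/O: FCS 3.0 and delimited text.

The FCS support is a deliberately small dialect: list-mode floating-point
data ($MODE L, $DATATYPE F or D), single data set, written as FCS 3.0 and
read back from FCS 2.0/3.0/3.1 headers. Raw stored intensities are the
canonical unit; no compensation or transform is applied at I/O time —
preprocessing belongs to the response-model stage so that every step of it
is auditable.
"""

from __future__ import annotations

import struct
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EventMatrix, SampleRecord
from .panel import PanelDef

_HEADER_VERSIONS = (b"FCS2.0", b"FCS3.0", b"FCS3.1")
# record-separator delimiter: legal per the standard and cannot collide
# with channel names containing "/" (e.g. CBRM1/5)
_DELIM = "\x1e"


class FormatError(ValueError):
    """File does not parse under the requested format."""


# --------------------------------------------------------------------------
# FCS
# --------------------------------------------------------------------------

def _build_text_segment(keywords: dict[str, str]) -> bytes:
    parts = [_DELIM]
    for k, v in keywords.items():
        if _DELIM in k or _DELIM in str(v):
            raise ValueError(f"keyword {k!r} contains the TEXT delimiter")
        parts.append(f"{k}{_DELIM}{v}{_DELIM}")
    return "".join(parts).encode("ascii")


def write_fcs(events: EventMatrix, path: str | Path) -> None:
    """Write an event matrix as an FCS 3.0 list-mode file.

    Data are stored as little-endian 32-bit floats; $PnN carries the
    channel names, and $TOT/$PAR the event/parameter counts.
    """
    path = Path(path)
    values = np.ascontiguousarray(events.values, dtype="<f4")
    n_events, n_par = values.shape
    data = values.tobytes()

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, ch in enumerate(events.panel.channels, start=1):
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}N"] = ch
        keywords[f"$P{i}R"] = str(int(max(1, np.ceil(values[:, i - 1].max()))))

    # Offsets depend on the TEXT length, which depends on the offsets;
    # fixed-width offset fields make a single two-pass layout sufficient.
    keywords["$BEGINDATA"] = "0" * 10
    keywords["$ENDDATA"] = "0" * 10
    text = _build_text_segment(keywords)
    text_begin = 58
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(data) - 1
    keywords["$BEGINDATA"] = str(data_begin).rjust(10, "0")
    keywords["$ENDDATA"] = str(data_end).rjust(10, "0")
    text = _build_text_segment(keywords)

    def fmt(off: int) -> bytes:
        s = str(off)
        if len(s) > 8:
            s = "0"  # out-of-range offsets fall back to the TEXT keywords
        return s.rjust(8).encode("ascii")

    header = (
        b"FCS3.0    "
        + fmt(text_begin)
        + fmt(text_end)
        + fmt(data_begin if data_end < 10**8 else 0)
        + fmt(data_end if data_end < 10**8 else 0)
        + fmt(0)
        + fmt(0)
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data)


def _parse_text_segment(raw: bytes, offset: int) -> dict[str, str]:
    if not raw:
        raise FormatError(f"empty TEXT segment at offset {offset}")
    delim = chr(raw[0])
    tokens = raw.decode("ascii", errors="replace").split(delim)[1:]
    if tokens and tokens[-1] == "":
        tokens = tokens[:-1]
    if len(tokens) % 2 != 0:
        raise FormatError(f"unbalanced TEXT segment at offset {offset}")
    return {tokens[i].strip(): tokens[i + 1] for i in range(0, len(tokens), 2)}


def read_fcs(path: str | Path, panel: PanelDef | None = None) -> EventMatrix:
    """Read an FCS 2.0/3.0/3.1 list-mode file into an :class:`EventMatrix`.

    Channel names are taken from the $PnN (falling back to $PnS) keywords.
    If ``panel`` is given and the file's channel set differs, a warning is
    emitted and the file's own channels are kept (pass-through).
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 58:
        raise FormatError(f"file too short for an FCS header (got {len(blob)} bytes)")
    version = blob[:6]
    if version not in _HEADER_VERSIONS:
        raise FormatError(f"unsupported FCS version {version!r} at offset 0")

    def header_off(i: int) -> int:
        field = blob[10 + 8 * i : 18 + 8 * i].strip()
        try:
            return int(field) if field else 0
        except ValueError:
            raise FormatError(f"corrupt header offset field at offset {10 + 8 * i}")

    text_begin, text_end = header_off(0), header_off(1)
    if not (0 < text_begin <= text_end < len(blob)):
        raise FormatError(f"TEXT segment offsets out of range at offset 10")
    kw = _parse_text_segment(blob[text_begin : text_end + 1], text_begin)

    data_begin, data_end = header_off(2), header_off(3)
    if data_begin == 0 or data_end == 0:
        try:
            data_begin = int(kw["$BEGINDATA"])
            data_end = int(kw["$ENDDATA"])
        except (KeyError, ValueError):
            raise FormatError("missing or corrupt $BEGINDATA/$ENDDATA keywords")
    if not (0 < data_begin <= data_end < len(blob)):
        raise FormatError(f"DATA segment offsets out of range ({data_begin}, {data_end})")

    try:
        n_par = int(kw["$PAR"])
        n_tot = int(kw["$TOT"])
    except (KeyError, ValueError):
        raise FormatError("missing or corrupt $PAR/$TOT keywords")
    datatype = kw.get("$DATATYPE", "F").strip().upper()
    if datatype not in ("F", "D"):
        raise FormatError(f"unsupported $DATATYPE {datatype!r} (float data expected)")
    byteord = kw.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    itemsize = 4 if datatype == "F" else 8

    expected = n_par * n_tot * itemsize
    raw = blob[data_begin : data_end + 1]
    if len(raw) < expected:
        raise FormatError(
            f"DATA segment at offset {data_begin} holds {len(raw)} bytes, "
            f"expected {expected}"
        )
    values = np.frombuffer(
        raw[:expected], dtype=f"{endian}f{itemsize}"
    ).reshape(n_tot, n_par).astype(float)

    channels = []
    for i in range(1, n_par + 1):
        name = kw.get(f"$P{i}N") or kw.get(f"$P{i}S") or f"P{i}"
        channels.append(name.strip())
    file_panel = PanelDef(channels=tuple(channels))
    if panel is not None:
        if tuple(panel.channels) == tuple(file_panel.channels):
            file_panel = panel
        else:
            warnings.warn(
                f"{path.name}: channel set {file_panel.channels} differs from "
                f"the expected panel; keeping the file's channels",
                stacklevel=2,
            )
    return EventMatrix(values=values, panel=file_panel)


# --------------------------------------------------------------------------
# Delimited text
# --------------------------------------------------------------------------

def write_delimited(events: EventMatrix, path: str | Path, sep: str = "\t") -> None:
    """One row per event, one column per channel, header row of names."""
    df = pd.DataFrame(events.values, columns=list(events.panel.channels))
    df.to_csv(path, sep=sep, index=False)


def read_delimited(
    path: str | Path, panel: PanelDef | None = None, sep: str = "\t"
) -> EventMatrix:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pandas raises several parser error types
        raise FormatError(f"cannot parse delimited file {path}: {exc}") from exc
    file_panel = PanelDef(channels=tuple(str(c) for c in df.columns))
    if panel is not None and tuple(panel.channels) != tuple(file_panel.channels):
        warnings.warn(
            f"{path.name}: channel set differs from the expected panel; "
            "keeping the file's channels",
            stacklevel=2,
        )
    elif panel is not None:
        file_panel = panel
    return EventMatrix(values=df.to_numpy(dtype=float), panel=file_panel)


def read_events(
    path: str | Path, format: str = "fcs", panel: PanelDef | None = None
) -> EventMatrix:
    """Read events from ``path`` in the named format (``fcs``/``delimited``)."""
    if format == "fcs":
        return read_fcs(path, panel=panel)
    if format == "delimited":
        return read_delimited(path, panel=panel)
    raise ValueError(f"unknown format {format!r}")


def write_events(events: EventMatrix, path: str | Path, format: str = "fcs") -> None:
    if format == "fcs":
        write_fcs(events, path)
    elif format == "delimited":
        write_delimited(events, path)
    else:
        raise ValueError(f"unknown format {format!r}")


# --------------------------------------------------------------------------
# Cohort persistence
# --------------------------------------------------------------------------

METADATA_COLUMNS = ("subject", "day", "session", "group", "counter_concentration", "path")


def write_cohort(
    records: list[SampleRecord], out_dir: str | Path, format: str = "fcs"
) -> Path:
    """Write every sample plus a metadata table; returns the table path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "fcs" if format == "fcs" else "tsv"
    rows = []
    for rec in records:
        fname = f"{rec.subject}_{rec.session}_d{rec.day}.{ext}"
        write_events(rec.events, out_dir / fname, format=format)
        rows.append(
            {
                "subject": rec.subject,
                "day": rec.day,
                "session": rec.session,
                "group": rec.group,
                "counter_concentration": rec.counter_concentration,
                "path": fname,
            }
        )
    table_path = out_dir / "cohort_metadata.tsv"
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(
        table_path, sep="\t", index=False
    )
    return table_path


def read_cohort(
    table_path: str | Path, format: str = "fcs", panel: PanelDef | None = None
) -> list[SampleRecord]:
    """Load a cohort previously written by :func:`write_cohort`."""
    table_path = Path(table_path)
    meta = pd.read_csv(table_path, sep="\t")
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise FormatError(f"cohort metadata table missing columns {sorted(missing)}")
    records = []
    for _, row in meta.iterrows():
        events = read_events(table_path.parent / row["path"], format=format, panel=panel)
        records.append(
            SampleRecord(
                subject=str(row["subject"]),
                day=int(row["day"]),
                session=str(row["session"]),
                group=str(row["group"]),
                events=events,
                counter_concentration=float(row["counter_concentration"]),
            )
        )
    return records
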