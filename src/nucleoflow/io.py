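"""Reading and writing event tables and cohort datasets.

Two on-disk dialects are supported:

* ``tabular`` — TSV with header columns ``fs, ch_7aad, ch_neun, ch_olig2``
  and (optionally) ``truth_label``.  Lossless for synthetic data.
* ``fcs`` — FCS 3.1 list-mode files with float32 data and channel names
  ($PnN) ``FS, 7AAD, NeuN, OLIG2``.  A deliberately small writer/reader pair
  covering the keywords this pipeline needs; truth labels are not carried.

Demographics travel as a TSV mirroring a brain-bank sample sheet.
"""

from __future__ import annotations

import os
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .simulate import CohortDataset

FCS_CHANNEL_NAMES = ("FS", "7AAD", "NeuN", "OLIG2")
TABULAR_CHANNELS = ("fs", "ch_7aad", "ch_neun", "ch_olig2")

_CHANNEL_MAP = dict(zip(FCS_CHANNEL_NAMES, TABULAR_CHANNELS))


# ---------------------------------------------------------------------------
# FCS 3.1
# ---------------------------------------------------------------------------

def write_fcs(path, events: pd.DataFrame) -> None:
    """Write an event table as a minimal FCS 3.1 file (float32, list mode)."""
    _require_channels(events, TABULAR_CHANNELS, str(path))
    n = len(events)
    if n == 0:
        raise DataError(f"refusing to write empty event table to {path}")
    data = np.ascontiguousarray(
        events.loc[:, list(TABULAR_CHANNELS)].to_numpy(dtype="<f4")
    )
    payload = data.tobytes()

    delim = "/"
    keywords = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BEGINDATA", "%012d"),  # placeholder, fixed width
        ("$ENDDATA", "%012d"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", "4"),
        ("$TOT", str(n)),
    ]
    for i, name in enumerate(FCS_CHANNEL_NAMES, start=1):
        keywords += [
            (f"$P{i}N", name),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", "1024" if name == "FS" else "1048576"),
        ]

    def render(begin: int, end: int) -> bytes:
        parts = [delim]
        for key, val in keywords:
            if val == "%012d":
                val = "%012d" % (begin if key == "$BEGINDATA" else end)
            parts.append(f"{key}{delim}{val}{delim}")
        return "".join(parts).encode("ascii")

    header_len = 58
    text = render(0, 0)  # fixed-width placeholders: length is final
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + len(payload) - 1
    text = render(data_start, data_end)

    header = b"FCS3.1    " + b"".join(
        b"%8d" % v
        for v in (text_start, text_end,
                  data_start if data_start <= 99_999_999 else 0,
                  data_end if data_end <= 99_999_999 else 0,
                  0, 0)
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload)


def read_fcs(path) -> pd.DataFrame:
    """Read a minimal FCS 3.0/3.1 list-mode file into an event table."""
    raw = Path(path).read_bytes()
    if len(raw) < 58:
        raise DataError(f"{path}: not an FCS file (too short)")
    if not raw[:6] in (b"FCS3.1", b"FCS3.0"):
        raise DataError(f"{path}: unsupported FCS version {raw[:6]!r}")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_start : text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    fields = text[1:].split(delim)
    kw = {
        fields[i].strip(): fields[i + 1]
        for i in range(0, len(fields) - 1, 2)
        if fields[i].strip()
    }

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    dtype = kw.get("$DATATYPE", "F").upper()
    if dtype != "F":
        raise DataError(f"{path}: only $DATATYPE F supported, got {dtype}")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    data_start = int(kw.get("$BEGINDATA") or raw[26:34])
    data_end = int(kw.get("$ENDDATA") or raw[34:42])
    payload = raw[data_start : data_end + 1]
    expect = n_par * n_tot * 4
    if len(payload) < expect:
        raise DataError(f"{path}: truncated DATA segment")
    arr = np.frombuffer(payload[:expect], dtype=f"{endian}f4").reshape(n_tot, n_par)

    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    missing = [c for c in FCS_CHANNEL_NAMES if c not in names]
    if missing:
        raise DataError(
            f"{path}: missing required channels {missing}; found {names}"
        )
    table = {}
    for fcs_name, col in _CHANNEL_MAP.items():
        table[col] = arr[:, names.index(fcs_name)].astype(np.float64)
    out = pd.DataFrame(table)
    out["fs"] = np.clip(np.rint(out["fs"]), 0, 1023).astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------

def write_tabular(path, events: pd.DataFrame) -> None:
    _require_channels(events, TABULAR_CHANNELS, str(path))
    cols = list(TABULAR_CHANNELS)
    if "truth_label" in events.columns:
        cols.append("truth_label")
    events.loc[:, cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_tabular(path) -> pd.DataFrame:
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path}: empty event file") from exc
    _require_channels(table, TABULAR_CHANNELS, str(path))
    if len(table) == 0:
        raise DataError(f"{path}: event file has a header but no events")
    table["fs"] = np.clip(table["fs"].round(), 0, 1023).astype(np.int64)
    return table


def _require_channels(table: pd.DataFrame, channels, where: str) -> None:
    missing = [c for c in channels if c not in table.columns]
    if missing:
        raise DataError(f"{where}: missing required channels {missing}")


# ---------------------------------------------------------------------------
# dataset-level I/O
# ---------------------------------------------------------------------------

def read_events(path, format: str = "auto") -> pd.DataFrame:
    """Read one event table; ``format`` is ``fcs``, ``tabular`` or ``auto``."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"event file not found: {path}")
    if format == "auto":
        format = "fcs" if path.suffix.lower() == ".fcs" else "tabular"
    if format == "fcs":
        return read_fcs(path)
    if format == "tabular":
        return read_tabular(path)
    raise DataError(f"unsupported event format {format!r}")


def write_dataset(dataset: CohortDataset, directory, format: str = "tabular") -> list:
    """Write demographics + per-sample event files; returns written paths."""
    if format not in ("fcs", "tabular"):
        raise DataError(f"unsupported format {format!r}")
    if len(dataset) == 0 or not dataset.events:
        raise DataError("refusing to write an empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    demo_path = directory / "demographics.tsv"
    dataset.demographics.to_csv(
        demo_path, sep="\t", index=False, float_format="%.10g"
    )
    written.append(demo_path)
    ext = ".fcs" if format == "fcs" else ".events.tsv"
    for sample_id, events in dataset.events.items():
        path = directory / f"{sample_id}{ext}"
        if format == "fcs":
            write_fcs(path, events)
        else:
            write_tabular(path, events)
        written.append(path)
    return written


def read_demographics(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"demographics file not found: {path}")
    demo = pd.read_csv(path, sep="\t")
    if "sample_id" not in demo.columns:
        raise DataError(f"{path}: demographics must have a sample_id column")
    return demo.set_index("sample_id", drop=False)


def read_dataset(directory, format: str = "auto") -> CohortDataset:
    """Load a cohort written by :func:`write_dataset`."""
    directory = Path(directory)
    demo = read_demographics(directory / "demographics.tsv")
    events = {}
    for sample_id in demo["sample_id"]:
        candidates = [
            directory / f"{sample_id}.events.tsv",
            directory / f"{sample_id}.fcs",
        ]
        found = [p for p in candidates if p.exists()]
        if not found:
            raise DataError(f"no event file found for sample {sample_id}")
        events[sample_id] = read_events(found[0], format)
    return CohortDataset(demographics=demo, events=events)
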