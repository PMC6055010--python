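"""Reading and writing the on-disk text formats.

Chart-recorder software exports triggered sweeps as delimited text; two
layouts are supported:

* ``wide`` — a header row, an optional leading time column, then one voltage
  column per sweep;
* ``long`` — three columns ``(sweep_index, time, voltage)``, one row per
  sample, rows in any order.

The field separator is auto-detected among comma, tab and semicolon; the
decimal mark must be a point. A time column, when present, is validated
against the metadata sampling rate (to within half a sample period, in ms or
s) and then discarded — the time base is always reconstructed as
``t = i / sampling_rate``.

Proprietary binary formats are deliberately not parsed; convert them to text
with the acquisition software and ingest the export here.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import RecordingMeta, Sweep, SweepSet
from .errors import (
    ConfigError,
    MetadataConflictError,
    ParseError,
    StructureError,
)

__all__ = [
    "TwoGroupTable",
    "read_sweeps",
    "write_sweeps",
    "write_summary_csv",
    "read_summary_csv",
    "read_two_group_csv",
    "load_meta",
    "save_meta",
]

_TIME_NAMES = {"t", "time", "ms", "s", "sec", "time_ms", "time_s", "t_ms", "t_s"}

SUMMARY_COLUMNS = [
    "subject",
    "group",
    "stimulus_intensity_mA",
    "amplitude_mV",
    "latency_ms",
    "duration_ms",
    "flags",
]


class TwoGroupTable:
    """Two independent numeric samples with group labels.

    The on-disk convention is a two-column CSV whose first row holds the two
    group names; shorter columns are padded with blanks.
    """

    def __init__(self, group_names, values):
        if len(group_names) != 2 or len(values) != 2:
            raise StructureError("a TwoGroupTable holds exactly two groups")
        self.group_names = (str(group_names[0]), str(group_names[1]))
        self.values = tuple(np.asarray(v, dtype=np.float64) for v in values)
        for name, v in zip(self.group_names, self.values):
            if v.ndim != 1 or len(v) < 1:
                raise StructureError(f"group {name!r} needs at least one value")
            if not np.all(np.isfinite(v)):
                raise StructureError(f"group {name!r} contains non-finite values")

    @property
    def n(self):
        return (len(self.values[0]), len(self.values[1]))

    def swapped(self) -> "TwoGroupTable":
        return TwoGroupTable(self.group_names[::-1], self.values[::-1])


def _sniff_sep(first_line: str) -> str:
    counts = {sep: first_line.count(sep) for sep in (",", "\t", ";")}
    sep = max(counts, key=counts.get)
    return sep if counts[sep] > 0 else ","


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    with open(path, "r", newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise ParseError(f"{path}: empty file or blank header line (line 1)")
        sep = _sniff_sep(first)
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: could not parse delimited text: {exc}") from exc
    if df.columns.duplicated().any() or any(
        str(c).startswith("Unnamed") for c in df.columns
    ):
        raise ParseError(f"{path}: malformed header row (line 1): {list(df.columns)}")
    return df


def _to_float_column(series: pd.Series, path, colname) -> np.ndarray:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna() & (series.astype(str).str.strip() != "")
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ParseError(
            f"{path}: non-numeric value {series[bad.idxmax()]!r} in column "
            f"{colname!r} at line {row}"
        )
    return out.to_numpy(dtype=np.float64)


def _validate_time_column(t: np.ndarray, meta: RecordingMeta, path) -> None:
    """Check a time column against the metadata rate; accepts ms or s units."""
    dt = meta.dt_ms
    n = len(t)
    expected = np.arange(n) * dt
    for scale in (1.0, 1000.0):  # column in ms, or in seconds
        if np.max(np.abs(t * scale - expected)) <= dt / 2 + 1e-12:
            return
    raise MetadataConflictError(
        f"{path}: time column is inconsistent with sampling_rate="
        f"{meta.sampling_rate:g} Hz (expected step {dt:g} ms)"
    )


def read_sweeps(path, meta: RecordingMeta, dialect: str = "wide") -> SweepSet:
    """Read a delimited-text sweep export into a :class:`SweepSet`.

    Parameters
    ----------
    path : path-like
        Text file with a header row; comma, tab or semicolon separated.
    meta : RecordingMeta
        Expected acquisition metadata. The per-sweep sample count must equal
        ``meta.n_samples``; stored values are multiplied by
        ``meta.voltage_scale`` to yield mV.
    dialect : {"wide", "long"}
        File layout (see module docstring).
    """
    df = _read_table(path)
    if dialect == "wide":
        cols = list(df.columns)
        if str(cols[0]).strip().lower() in _TIME_NAMES:
            t = _to_float_column(df[cols[0]], path, cols[0])
            _validate_time_column(t, meta, path)
            cols = cols[1:]
        if not cols:
            raise StructureError(f"{path}: no voltage columns found")
        traces = [_to_float_column(df[c], path, c) for c in cols]
    elif dialect == "long":
        if df.shape[1] < 3:
            raise StructureError(
                f"{path}: long dialect needs (sweep_index, time, voltage) columns"
            )
        c_idx, c_t, c_v = df.columns[:3]
        idx = _to_float_column(df[c_idx], path, c_idx)
        t = _to_float_column(df[c_t], path, c_t)
        v = _to_float_column(df[c_v], path, c_v)
        order = np.lexsort((t, idx))
        idx, t, v = idx[order], t[order], v[order]
        traces = []
        for k in np.unique(idx):
            sel = idx == k
            _validate_time_column(t[sel], meta, path)
            traces.append(v[sel])
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'wide' or 'long'")

    lengths = {len(tr) for tr in traces}
    if len(lengths) != 1:
        raise StructureError(f"{path}: inconsistent sweep lengths {sorted(lengths)}")
    if lengths.pop() != meta.n_samples:
        raise StructureError(
            f"{path}: sweeps have {len(traces[0])} samples but metadata implies "
            f"{meta.n_samples}"
        )
    return SweepSet([Sweep(tr * meta.voltage_scale, meta) for tr in traces])


def write_sweeps(sweepset: SweepSet, path, include_time: bool = True) -> None:
    """Write a sweep set as a wide-dialect CSV (full float precision).

    Columns are ``t_ms`` (optional) followed by ``sweep_1 .. sweep_n``.
    Reading the file back with the same metadata reproduces the samples
    bit for bit.
    """
    path = Path(path)
    meta = sweepset.meta
    mat = sweepset.to_matrix()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        names = [f"sweep_{i + 1}" for i in range(len(sweepset))]
        if include_time:
            w.writerow(["t_ms"] + names)
            t = meta.times_ms()
            for i in range(mat.shape[1]):
                w.writerow([repr(float(t[i]))] + [repr(float(x)) for x in mat[:, i]])
        else:
            w.writerow(names)
            for i in range(mat.shape[1]):
                w.writerow([repr(float(x)) for x in mat[:, i]])


def write_summary_csv(records: Sequence[tuple], path) -> None:
    """Write one summary row per measured recording.

    ``records`` is a sequence of ``(meta, measurement)`` pairs where ``meta``
    is a :class:`RecordingMeta` (supplying subject/group/intensity labels) and
    ``measurement`` a :class:`cmapkit.measure.CmapMeasurement`. Column order
    is fixed: subject, group, stimulus_intensity_mA, amplitude_mV,
    latency_ms, duration_ms, flags.
    """
    if len(records) == 0:
        raise ValueError("refusing to write an empty summary table")
    rows = []
    for meta, m in records:
        rows.append(
            {
                "subject": meta.subject_id,
                "group": meta.group,
                "stimulus_intensity_mA": meta.stimulus_intensity,
                "amplitude_mV": m.amplitude,
                "latency_ms": m.latency,
                "duration_ms": m.duration,
                "flags": ";".join(sorted(m.flags)),
            }
        )
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6g")


def read_summary_csv(path) -> pd.DataFrame:
    """Read a summary table written by :func:`write_summary_csv`."""
    df = _read_table(path)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise StructureError(f"{path}: summary table missing columns {missing}")
    df["flags"] = df["flags"].fillna("")
    return df


def read_two_group_csv(path) -> TwoGroupTable:
    """Read a two-column CSV: group names on the first row, values below.

    Blank cells are dropped per column, so the two groups may have unequal n.
    """
    df = _read_table(path)
    if df.shape[1] != 2:
        raise StructureError(
            f"{path}: expected exactly 2 columns (two groups), found {df.shape[1]}"
        )
    names = [str(c) for c in df.columns]
    cols = []
    for c in df.columns:
        v = _to_float_column(df[c], path, c)
        cols.append(v[~np.isnan(v)])
    return TwoGroupTable(names, cols)


_META_FIELDS = [
    "sampling_rate",
    "sweep_duration",
    "stimulus_intensity",
    "artifact_onset",
    "polarity_inverted",
    "subject_id",
    "group",
    "voltage_scale",
]


def load_meta(path, **overrides) -> RecordingMeta:
    """Load recording metadata from a YAML config, applying defaults.

    Keys not present in the file fall back to :class:`RecordingMeta`
    defaults; keyword ``overrides`` take precedence over the file (so a CLI
    flag can override a config value).
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping of field: value")
    unknown = set(data) - set(_META_FIELDS)
    if unknown:
        raise ConfigError(f"{path}: unknown config fields {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RecordingMeta(**data)


def save_meta(meta: RecordingMeta, path) -> None:
    """Write recording metadata as a YAML config."""
    data = {k: getattr(meta, k) for k in _META_FIELDS}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
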