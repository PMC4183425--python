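"""Trajectory-table file format and converters.

The native interchange format is a delimited text table (CSV or TSV,
auto-detected): optional ``#``-prefixed metadata lines, then a header row
``time, synapse 1, synapse 2, ...`` and one row per time point.  Times are
hours; empty cells mark missing values (before birth / after elimination).

A converter for the spreadsheet-grid layout used by published supplementary
datasets (one sheet per figure, rows/columns titled "time" and
"synapse #") is provided as a utility.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import Ensemble

__all__ = [
    "read_trajectory_table",
    "write_trajectory_table",
    "ensemble_from_frame",
    "read_spreadsheet_grid",
]


class FormatError(ValueError):
    """The file does not conform to the trajectory-table format."""


_META_KEYS = ("dt_minutes", "normalization", "filtered", "seed")


def write_trajectory_table(ens: Ensemble, path) -> None:
    """Write an ensemble deterministically (ascending synapse id, fixed format)."""
    ens.validate()
    delim = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    lines = []
    for key in _META_KEYS:
        if key in ens.tags:
            lines.append(f"# {key} = {ens.tags[key]}")
    header = ["time"] + [f"synapse {i + 1}" for i in range(ens.n_synapses)]
    lines.append(delim.join(header))
    for j in range(ens.n_times):
        cells = [f"{ens.times_hours[j]:.10g}"]
        for i in range(ens.n_synapses):
            v = ens.sizes[i, j]
            cells.append(f"{v:.10g}" if np.isfinite(v) else "")
        lines.append(delim.join(cells))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_meta(path) -> dict:
    tags = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key, val = key.strip(), val.strip()
                if key in ("dt_minutes",):
                    tags[key] = float(val)
                elif key in ("seed", "filtered") and val.isdigit():
                    tags[key] = int(val)
                else:
                    tags[key] = val
    return tags


def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if "\t" in line else ","
    raise FormatError(f"{path}: empty file")


def read_trajectory_table(path) -> Ensemble:
    """Parse a trajectory table into an :class:`Ensemble`.

    Trailing runs of empty cells are interpreted as elimination (the
    trajectory ended); interior gaps are kept as isolated missing
    measurements and do not mark the synapse as eliminated.
    """
    tags = _parse_meta(path)
    delim = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, comment="#", sep=delim)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a time column plus >= 1 synapse column")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise FormatError(
                f"{path}: non-numeric cell(s) in column {col!r}, data row(s) "
                f"{list(bad[:5])}"
            )
    return ensemble_from_frame(df, tags=tags, source=str(path))


def ensemble_from_frame(df: pd.DataFrame, tags: dict | None = None,
                        source: str = "<frame>") -> Ensemble:
    """Build an Ensemble from a time-by-synapse DataFrame (first column = time)."""
    times = df.iloc[:, 0].to_numpy(dtype=float)
    if times.size > 1:
        diffs = np.diff(times)
        if np.any(diffs <= 0):
            rows = list(np.flatnonzero(diffs <= 0) + 1)
            raise FormatError(f"{source}: time not strictly increasing at row(s) {rows}")
        if np.any(np.abs(diffs - diffs[0]) > 1e-9):
            rows = list(np.flatnonzero(np.abs(diffs - diffs[0]) > 1e-9) + 1)
            raise FormatError(f"{source}: non-uniform time grid at row(s) {rows}")
    sizes = df.iloc[:, 1:].to_numpy(dtype=float).T  # synapse x time
    alive = np.isfinite(sizes)
    n, n_t = sizes.shape
    elim = np.full(n, -1, dtype=int)
    for i in range(n):
        finite = np.flatnonzero(alive[i])
        if finite.size and finite[-1] < n_t - 1:
            elim[i] = finite[-1] + 1  # trailing gap = elimination
    full_tags = {"normalization": "none", "filtered": "none"}
    full_tags.update(tags or {})
    ens = Ensemble(times, sizes, alive, elim, tags=full_tags)
    ens.validate()
    return ens


def read_spreadsheet_grid(path, sheet=0, tags: dict | None = None) -> Ensemble:
    """Convert a spreadsheet grid (Excel) to an Ensemble.

    Expects one worksheet holding a synapse-by-time or time-by-synapse grid
    whose first row/column carries the time axis (header containing "time").
    The orientation is detected from the headers.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    first = str(df.columns[0]).strip().lower()
    if "time" not in first:
        # assume synapse-by-time: first column synapse ids, header row = times
        df = df.set_index(df.columns[0]).T.reset_index()
        df.rename(columns={df.columns[0]: "time"}, inplace=True)
    df["time"] = pd.to_numeric(df["time"], errors="coerce")
    df = df.dropna(subset=["time"])
    return ensemble_from_frame(df, tags=tags, source=str(path))
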