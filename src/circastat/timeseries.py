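"""Time-series containers and the grouped-CSV dialect.

Input files are plain CSV: an index column whose header is ``Time`` (hours),
followed by one column per sample.  Sample labels sit in the first header row
and need not be unique -- samples sharing a label form a group.  Up to three
files can be loaded jointly; the first file's labels define the groups and
unmatched labels in later files are dropped.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CSVFormatError,
    CSVParseError,
    EmptyStudyError,
    TimeOrderError,
)

__all__ = [
    "TimeSeries",
    "GroupedStudy",
    "load_csv",
    "align_groups",
    "write_results",
    "read_results",
]

#: default palette for group colors (matplotlib "tab10")
_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)

RESULT_COLUMNS = ("label", "METHOD", "PER", "AMP", "ACROPHASE", "P", "ADJ.P", "BH.Q")


@dataclass(frozen=True)
class TimeSeries:
    """One sample's measurements over time.

    Parameters
    ----------
    times : array-like
        Observation times in hours, strictly increasing. Regular or irregular
        spacing is allowed.
    values : array-like
        Measurements, same length as ``times``.
    label : str
        Sample identifier (group membership key).
    source_slot : int
        File slot (1-3) the series was read from.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    source_slot: int = 1

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if t.size < 4:
            raise ValueError(
                f"series {self.label!r} has {t.size} points; at least 4 required"
            )
        if not np.all(np.diff(t) > 0):
            raise TimeOrderError(
                f"series {self.label!r}: times must be strictly increasing"
            )
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError(f"series {self.label!r}: non-finite entries")
        if not (1 <= int(self.source_slot) <= 3):
            raise ValueError("source_slot must be 1, 2 or 3")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    # -- convenience ---------------------------------------------------
    @property
    def n(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def median_interval(self) -> float:
        return float(np.median(np.diff(self.times)))

    def is_regular(self, rel_tol: float = 0.01) -> bool:
        """True when sampling intervals are constant within ``rel_tol``."""
        dt = np.diff(self.times)
        return bool(np.all(np.abs(dt - dt.mean()) <= rel_tol * dt.mean()))

    def with_values(self, values, times=None) -> "TimeSeries":
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            times=self.times if times is None else np.asarray(times, dtype=float),
        )


@dataclass
class GroupedStudy:
    """Samples grouped by identical label, aligned across up to three files.

    ``groups`` maps group label -> list of per-slot member lists
    (``groups[label][slot_index]`` holds the slot's series with that label).
    Group order follows first appearance in slot 1 (the reference slot).
    """

    groups: "dict[str, list[list[TimeSeries]]]"
    colors: "dict[str, str]" = field(default_factory=dict)
    n_slots: int = 1
    reference_slot: int = 1

    def __post_init__(self):
        for label, slots in self.groups.items():
            for members in slots:
                for ts in members:
                    if ts.label != label:
                        raise ValueError(
                            f"series labelled {ts.label!r} placed in group {label!r}"
                        )
        if not self.colors:
            self.colors = {
                lab: _PALETTE[i % len(_PALETTE)] for i, lab in enumerate(self.groups)
            }

    @property
    def labels(self) -> "list[str]":
        return list(self.groups)

    def members(self, label: str, slot: int = 1) -> "list[TimeSeries]":
        return self.groups[label][slot - 1]

    def all_series(self) -> "list[TimeSeries]":
        out = []
        for slots in self.groups.values():
            for members in slots:
                out.extend(members)
        return out

    def averaged(self, label: str, slot: int = 1) -> TimeSeries:
        """Pointwise mean of a group's members in one slot.

        Members must share identical time grids; use per-series analysis
        otherwise.
        """
        members = self.members(label, slot)
        if not members:
            raise EmptyStudyError(f"group {label!r} has no members in slot {slot}")
        t0 = members[0].times
        for ts in members[1:]:
            if ts.n != members[0].n or not np.allclose(ts.times, t0):
                raise ValueError(
                    f"group {label!r}: members have differing time grids; "
                    "cannot average"
                )
        mean = np.mean([ts.values for ts in members], axis=0)
        return TimeSeries(t0, mean, label=label, source_slot=slot)


# ---------------------------------------------------------------------------
# CSV input
# ---------------------------------------------------------------------------

def load_csv(path, time_label: str = "Time", source_slot: int = 1) -> "list[TimeSeries]":
    """Read one grouped-CSV file into a list of :class:`TimeSeries`.

    The first header cell must equal ``time_label``; every later header cell
    is a sample label (duplicates allowed, preserved in column order).  Empty
    cells are missing values and are dropped pairwise with their time point,
    per series.
    """
    raw = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=True)
    if raw.empty or raw.shape[1] < 2:
        raise CSVFormatError(f"{path}: need an index column plus at least one sample")
    header = raw.iloc[0].tolist()
    found = "" if pd.isna(header[0]) else str(header[0]).strip()
    if found != time_label:
        raise CSVFormatError(
            f"{path}: first header cell is {found!r}; expected index label {time_label!r}"
        )
    labels = []
    for h in header[1:]:
        lab = "" if pd.isna(h) else str(h).strip()
        labels.append(lab)
    # drop trailing unnamed columns (spreadsheet artefacts)
    while labels and labels[-1] == "":
        labels.pop()
    if not labels:
        raise CSVFormatError(f"{path}: no sample columns found")

    body = raw.iloc[1:].reset_index(drop=True)

    def _numeric(col_idx: int, col_name: str) -> np.ndarray:
        cells = body.iloc[:, col_idx]
        stripped = cells.fillna("").astype(str).str.strip()
        out = pd.to_numeric(stripped.replace("", np.nan), errors="coerce")
        bad = out.isna() & (stripped != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CSVParseError(
                f"{path}: non-numeric cell {stripped.iloc[row]!r} at data row "
                f"{row + 1}, column {col_name!r}"
            )
        return out.to_numpy(dtype=float)

    times = _numeric(0, time_label)
    if np.isnan(times).any():
        row = int(np.flatnonzero(np.isnan(times))[0])
        raise CSVParseError(f"{path}: empty time cell at data row {row + 1}")
    if not np.all(np.diff(times) > 0):
        raise TimeOrderError(f"{path}: time index must be strictly increasing")

    series = []
    for j, lab in enumerate(labels, start=1):
        vals = _numeric(j, lab)
        keep = ~np.isnan(vals)
        series.append(
            TimeSeries(times[keep], vals[keep], label=lab, source_slot=source_slot)
        )
    return series


def align_groups(*file_series: Sequence[TimeSeries]) -> GroupedStudy:
    """Group series by identical label across up to three file slots.

    Slot 1 is the reference: its distinct labels define the group set and
    their order; labels appearing only in later slots are dropped.  The
    result is independent of the order of slots 2 and 3 and idempotent.
    """
    slots = [list(s) for s in file_series if s is not None]
    if not slots or len(slots) > 3:
        raise EmptyStudyError("between 1 and 3 file slots required")
    if not slots[0]:
        raise EmptyStudyError("slot 1 is empty; it defines the groups")
    labels: "list[str]" = []
    for ts in slots[0]:
        if ts.label not in labels:
            labels.append(ts.label)
    groups = {
        lab: [
            [replace(ts, source_slot=i + 1) for ts in slot if ts.label == lab]
            for i, slot in enumerate(slots)
        ]
        for lab in labels
    }
    return GroupedStudy(groups=groups, n_slots=len(slots))


# ---------------------------------------------------------------------------
# Results CSV
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return format(float(x), ".10g")


def write_results(results: Iterable, path) -> None:
    """Write rhythm results to CSV (columns label,METHOD,PER,AMP,ACROPHASE,P,ADJ.P,BH.Q).

    Unset optional fields (e.g. BH.Q) become empty cells.  Numeric fields
    round-trip through :func:`read_results` to better than 6 significant
    digits.
    """
    rows = list(results)
    if not rows:
        raise ValueError("no results to write")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(RESULT_COLUMNS)
        for r in rows:
            w.writerow(
                [
                    r.label,
                    r.method,
                    _fmt(r.period),
                    _fmt(r.amplitude),
                    _fmt(r.acrophase),
                    _fmt(r.p_raw),
                    _fmt(r.adj_p),
                    _fmt(r.bh_q),
                ]
            )


def read_results(path) -> "list":
    """Read a results CSV written by :func:`write_results`."""
    from .base import RhythmResult  # local import: avoids a cycle

    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if tuple(reader.fieldnames or ()) != RESULT_COLUMNS:
            raise CSVFormatError(f"{path}: not a circastat results file")
        for row in reader:
            def num(key, default=math.nan):
                cell = (row[key] or "").strip()
                return float(cell) if cell else default

            out.append(
                RhythmResult(
                    label=row["label"],
                    method=row["METHOD"],
                    period=num("PER"),
                    amplitude=num("AMP"),
                    acrophase=num("ACROPHASE"),
                    p_raw=num("P"),
                    adj_p=num("ADJ.P"),
                    bh_q=num("BH.Q", None) if (row["BH.Q"] or "").strip() else None,
                )
            )
    return out
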