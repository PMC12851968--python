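"""File formats: beat-interval recordings, immune tables, CAS tables.

Two text layouts are accepted for recordings: a single column of
intervals in ms (one beat per line, beat times reconstructed by
cumulative summation from zero) and a two-column CSV ``time_min,rri_ms``
with a header.  Recordings are written in the two-column form with an
optional JSON sidecar holding ground-truth parameters.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .params import CAS_PARAM_NAMES, CASParameters
from .recording import MS_PER_MIN, RRiRecording

__all__ = [
    "RRiParseError",
    "read_rri_file",
    "write_rri_file",
    "read_immune_table",
    "write_immune_table",
    "write_cas_table",
    "read_cas_table",
]

IMMUNE_COLUMNS = [
    "subject_id",
    "lymphocytes",
    "b_total",
    "cd21p_cd11cn",
    "cd21p_cd11cp",
    "cd21n_cd11cp",
    "cd21n_cd11cn",
    "age",
    "sex",
    "fat_pct",
    "muscle_kg",
]

CAS_COLUMNS = ["subject_id", *CAS_PARAM_NAMES, "sigma", "loss", "converged", "n_beats_used"]


class RRiParseError(ValueError):
    """Typed parse failure carrying the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


def read_rri_file(path: Union[str, Path], subject_id: Optional[str] = None) -> RRiRecording:
    """Read a beat-interval file in either supported layout.

    Raises :class:`RRiParseError` with a line number on nonpositive
    intervals, nonmonotone times, or an empty/garbled file.
    """
    path = Path(path)
    sid = subject_id if subject_id is not None else path.stem
    lines = path.read_text().splitlines()
    rows = [
        (i + 1, ln.strip()) for i, ln in enumerate(lines) if ln.strip()
    ]
    if not rows:
        raise RRiParseError(f"empty recording file: {path}")

    first = rows[0][1]
    two_col = "," in first
    if two_col and not _is_number(first.split(",")[0]):
        rows = rows[1:]  # header
        if not rows:
            raise RRiParseError(f"recording file has a header but no data: {path}")

    times, intervals = [], []
    for lineno, ln in rows:
        parts = [p.strip() for p in ln.split(",")] if two_col else [ln]
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            raise RRiParseError(f"could not parse {ln!r}", lineno) from None
        if two_col:
            if len(vals) < 2:
                raise RRiParseError("expected two columns time_min,rri_ms", lineno)
            t, rri = vals[0], vals[1]
        else:
            t, rri = None, vals[0]
        if rri <= 0:
            raise RRiParseError(f"nonpositive interval {rri}", lineno)
        if t is not None:
            if times and t <= times[-1]:
                raise RRiParseError(f"nonmonotone beat time {t}", lineno)
            times.append(t)
        intervals.append(rri)

    intervals = np.asarray(intervals)
    if times:
        return RRiRecording(np.asarray(times), intervals, subject_id=sid)
    return RRiRecording.from_intervals(intervals, subject_id=sid)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_rri_file(
    rec: RRiRecording,
    path: Union[str, Path],
    truth: Optional[CASParameters] = None,
) -> None:
    """Write the two-column CSV; ``truth`` adds a JSON sidecar ``<path>.json``."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time_min,rri_ms\n")
        for t, rri in zip(rec.beat_times, rec.intervals):
            fh.write(f"{t:.9f},{rri:.6f}\n")
    if truth is not None:
        sidecar = {k: getattr(truth, k) for k in (*CAS_PARAM_NAMES, "sigma")}
        sidecar["subject_id"] = rec.subject_id
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_immune_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in IMMUNE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"immune table missing columns: {missing}")
    neg = [
        c
        for c in IMMUNE_COLUMNS[1:7]
        if (df[c].to_numpy(float) < 0).any()
    ]
    if neg:
        raise ValueError(f"negative cell counts in columns: {neg}")
    return df


def write_immune_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, index=False, columns=[c for c in IMMUNE_COLUMNS if c in df.columns])


def write_cas_table(rows: list, path: Union[str, Path]) -> pd.DataFrame:
    """Write per-subject CAS fit rows (dicts from ``CASFit.as_row``)."""
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, columns=[c for c in CAS_COLUMNS if c in df.columns])
    return df


def read_cas_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", *CAS_PARAM_NAMES) if c not in df.columns]
    if missing:
        raise ValueError(f"CAS table missing columns: {missing}")
    return df
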