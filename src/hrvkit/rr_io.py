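"""RR-interval recording and study-table I/O.

RR recordings are plain text files with one inter-beat interval in
milliseconds per line; blank lines and lines starting with ``#`` are
ignored. Study tables (per-subject characteristics and per-subject HRV
metrics under both stimulation conditions) are CSV files; transcriptions
of the 22-patient study tables ship with the package and can be loaded
with :func:`load_patient_table` / :func:`load_hrv_table`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "RRRecording",
    "CohortTable",
    "read_rr_text",
    "write_rr_text",
    "select_segment",
    "read_cohort_table",
    "load_patient_table",
    "load_hrv_table",
    "write_metrics_table",
    "read_metrics_table",
]


class RRParseError(ValueError):
    """A line of an RR text file could not be parsed."""


@dataclass(frozen=True)
class RRRecording:
    """A sequence of inter-beat (RR) intervals in milliseconds.

    ``sampling_resolution`` is the device timer resolution in ms per
    tick (1 ms for a 1000 Hz beat detector); it is carried as metadata
    and does not quantize the stored intervals.
    """

    intervals: np.ndarray
    subject_id: Optional[str] = None
    condition: Optional[str] = None  # "off" | "on"
    sampling_resolution: float = 1.0

    def __post_init__(self):
        arr = np.asarray(self.intervals, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("an RR recording needs at least 2 intervals")
        if np.any(arr <= 0):
            bad = int(np.flatnonzero(arr <= 0)[0])
            raise ValueError(f"non-positive RR interval at beat {bad}: {arr[bad]}")
        if self.condition not in (None, "off", "on"):
            raise ValueError(f"condition must be 'off' or 'on', got {self.condition!r}")
        object.__setattr__(self, "intervals", arr)

    @property
    def n_beats(self) -> int:
        return int(self.intervals.size)

    @property
    def beat_times_s(self) -> np.ndarray:
        """Cumulative beat times in seconds (end of each interval)."""
        return np.cumsum(self.intervals) / 1000.0

    @property
    def duration_s(self) -> float:
        return float(self.intervals.sum() / 1000.0)


@dataclass(frozen=True)
class CohortTable:
    """Per-subject study table, rows keyed by subject id.

    Wraps a :class:`pandas.DataFrame` indexed by ``subject_id``. Depending
    on provenance it carries patient characteristics (sex, age,
    medication flags, VAS pain scores off/on) and/or per-condition HRV
    metrics (mean IBI, HR, normalized LF/HF power, rLF/HF).
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if df.index.name != "subject_id":
            raise ValueError("CohortTable must be indexed by subject_id")
        vas_cols = [c for c in df.columns if c.startswith("vas_")]
        for c in vas_cols:
            vals = df[c].dropna()
            if ((vals < 0) | (vals > 10)).any():
                raise ValueError(f"VAS column {c!r} outside [0, 10]")
        for cond in ("off", "on"):
            nlf, nhf = f"nlf_{cond}", f"nhf_{cond}"
            if nlf in df.columns and nhf in df.columns:
                s = (df[nlf] + df[nhf]).dropna()
                if ((s < 0.999) | (s > 1.001)).any():
                    raise ValueError(
                        f"normalized LF + HF must sum to 1 within 0.001 ({cond})"
                    )

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def paired(self, variable: str) -> tuple[np.ndarray, np.ndarray]:
        """Off/on value pairs for ``variable``, subjects with either
        condition missing excluded pairwise."""
        off_col, on_col = f"{variable}_off", f"{variable}_on"
        for c in (off_col, on_col):
            if c not in self.data.columns:
                raise KeyError(f"missing column {c!r}")
        sub = self.data[[off_col, on_col]].dropna()
        return sub[off_col].to_numpy(float), sub[on_col].to_numpy(float)

    def paired_variables(self) -> list[str]:
        """Variables present with both _off and _on columns."""
        stems = []
        for c in self.data.columns:
            if c.endswith("_off") and c[:-4] + "_on" in self.data.columns:
                stems.append(c[:-4])
        return stems


def read_rr_text(
    path: str | Path,
    subject_id: Optional[str] = None,
    condition: Optional[str] = None,
) -> RRRecording:
    """Read an RR recording from a one-interval-per-line text file."""
    values = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                v = float(line)
            except ValueError:
                raise RRParseError(
                    f"{path}: line {lineno}: not a number: {line!r}"
                ) from None
            if v <= 0:
                raise ValueError(
                    f"{path}: line {lineno}: non-positive RR interval {v}"
                )
            values.append(v)
    if not values:
        raise ValueError(f"{path}: no intervals")
    if len(values) < 2:
        raise ValueError(f"{path}: need at least 2 intervals, got {len(values)}")
    return RRRecording(
        intervals=np.array(values), subject_id=subject_id, condition=condition
    )


def write_rr_text(rec: RRRecording, path: str | Path) -> None:
    """Write a recording in the same one-ms-value-per-line dialect."""
    with open(path, "w") as fh:
        if rec.subject_id is not None:
            fh.write(f"# subject: {rec.subject_id}\n")
        if rec.condition is not None:
            fh.write(f"# condition: {rec.condition}\n")
        for v in rec.intervals:
            v = float(v)
            fh.write(f"{int(v)}\n" if v.is_integer() else f"{v!r}\n")


def select_segment(
    rec: RRRecording, duration_s: float, offset_s: float = 0.0
) -> RRRecording:
    """Select the run of consecutive beats inside a time window.

    Returns the maximal run of intervals whose cumulative (end) time lies
    in ``(offset, offset + duration]`` seconds from the recording start,
    so a recording of constant 1000 ms beats trimmed to 300 s keeps
    exactly 300 intervals. Selection is idempotent.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    available = rec.duration_s
    if available + 1e-9 < offset_s + duration_s:
        raise ValueError(
            f"recording spans {available:.3f} s, need "
            f"{offset_s + duration_s:.3f} s (offset {offset_s} + duration {duration_s})"
        )
    ends = np.cumsum(rec.intervals) / 1000.0
    mask = (ends > offset_s) & (ends <= offset_s + duration_s + 1e-9)
    idx = np.flatnonzero(mask)
    if idx.size < 2:
        raise ValueError("selected window contains fewer than 2 beats")
    return replace(rec, intervals=rec.intervals[idx[0] : idx[-1] + 1])


_PATIENT_COLUMNS = {
    "subject_id", "sex", "age", "opioids", "beta_blockers",
    "vas_back_off", "vas_back_on", "vas_leg_off", "vas_leg_on",
}
_HRV_COLUMNS = {
    "subject_id",
    "mean_ibi_off", "mean_ibi_on", "hr_off", "hr_on",
    "nlf_off", "nlf_on", "nhf_off", "nhf_on", "rlfhf_off", "rlfhf_on",
}


def read_cohort_table(path: str | Path | io.IOBase) -> CohortTable:
    """Read a per-subject study table (CSV with header).

    The header must contain the full column set of either the patient
    characteristics table or the per-subject HRV metrics table (a merged
    table with both is accepted).
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if not (_PATIENT_COLUMNS <= cols or _HRV_COLUMNS <= cols):
        missing_p = sorted(_PATIENT_COLUMNS - cols)
        missing_h = sorted(_HRV_COLUMNS - cols)
        raise ValueError(
            "table header matches neither study schema; "
            f"patient table lacks {missing_p}, HRV table lacks {missing_h}"
        )
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id rows")
    return CohortTable(df.set_index("subject_id"))


def _packaged(name: str) -> CohortTable:
    ref = resources.files("hrvkit.data").joinpath(name)
    with resources.as_file(ref) as p:
        return read_cohort_table(p)


def load_patient_table() -> CohortTable:
    """Packaged 22-patient characteristics table (sex, age, medication,
    VAS back/leg pain with stimulation off/on)."""
    return _packaged("table1_patients.csv")


def load_hrv_table() -> CohortTable:
    """Packaged per-subject HRV metrics table (mean IBI, HR, normalized
    LF/HF, rLF/HF; stimulation off/on) for the 22-patient cohort."""
    return _packaged("table2_hrv.csv")


def write_metrics_table(profiles: Iterable, path: str | Path) -> None:
    """Write computed per-recording metric profiles as CSV.

    One row per (subject, condition); undefined metrics become empty
    cells rather than zeros.
    """
    rows = [p.to_row() for p in profiles]
    if not rows:
        raise ValueError("no profiles to write")
    pd.DataFrame(rows).to_csv(path, index=False, na_rep="")


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    """Read back a metrics table written by :func:`write_metrics_table`."""
    return pd.read_csv(path)
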