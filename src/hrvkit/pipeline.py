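"""End-to-end orchestration: recording → preprocessing → four-domain
metrics → cohort statistics.

:func:`analyze_recording` turns one RR recording into an
:class:`HRVProfile` spanning the time, frequency, time-frequency and
nonlinear domains. :func:`run_study` aggregates paired off/on profiles
(or a precomputed per-subject metric table) into the study report:
descriptives, routed paired tests, and optionally a Simes-corrected
significance column.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Mapping, Optional, Sequence, Union

import pandas as pd

from .config import AnalysisConfig, DEFAULT_CONFIG
from .freq_domain import BandPowers, spectral_profile
from .nonlinear import NonlinearMetrics, nonlinear_metrics
from .preprocess import preprocess_pipeline
from .rr_io import CohortTable, RRRecording, read_rr_text, select_segment
from .study_stats import StudyRow, build_study_table, study_table_frame
from .time_domain import TimeDomainMetrics, time_metrics
from .time_freq import TFSummary, tf_summary, windowed_burg

logger = logging.getLogger(__name__)

__all__ = ["HRVProfile", "analyze_recording", "run_study", "StudyReport"]


def _none_to_nan(v) -> float:
    return math.nan if v is None else float(v)


@dataclass(frozen=True)
class HRVProfile:
    """Per-recording metric set across the four HRV domains."""

    subject_id: Optional[str]
    condition: Optional[str]
    time: TimeDomainMetrics
    freq: BandPowers
    tf: TFSummary
    nonlinear: NonlinearMetrics
    fraction_flagged: float

    def to_row(self) -> dict:
        """Flatten to one table row (undefined metrics become NaN →
        empty CSV cells)."""
        t, f, w, n = self.time, self.freq, self.tf, self.nonlinear
        return {
            "subject_id": self.subject_id,
            "condition": self.condition,
            "mean_ibi": t.mean_ibi,
            "hr": t.mean_hr,
            "sdnn": t.sdnn,
            "rmssd": t.rmssd,
            "ti": _none_to_nan(t.ti),
            "tinn": _none_to_nan(t.tinn),
            "lf": f.lf,
            "hf": f.hf,
            "nlf": f.nlf,
            "nhf": f.nhf,
            "lf_hf": f.lf_hf,
            "tf_lf": w.lf_abs,
            "tf_hf": w.hf_abs,
            "tf_nlf": w.nlf,
            "tf_nhf": w.nhf,
            "rlfhf": w.rlfhf,
            "sd1": n.sd1,
            "sd2": n.sd2,
            "sampen": _none_to_nan(n.sampen),
            "dfa_alpha": _none_to_nan(n.dfa_alpha),
            "dfa_alpha1": _none_to_nan(n.dfa_alpha1),
            "dfa_alpha2": _none_to_nan(n.dfa_alpha2),
            "fraction_flagged": self.fraction_flagged,
        }


def analyze_recording(
    source: Union[str, Path, RRRecording],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> HRVProfile:
    """Full four-domain analysis of one RR recording.

    Accepts a path to an RR text file or an in-memory recording. The
    analysis segment (300 s from offset 0 by default) is selected first;
    beat-domain metrics come from the corrected series, spectral metrics
    from the detrended 2 Hz tachogram. Degenerate inputs (for example a
    constant recording) yield a profile with NaN/None markers rather
    than failing.
    """
    rec = source if isinstance(source, RRRecording) else read_rr_text(source)
    who = f"{rec.subject_id or '?'}/{rec.condition or '?'}"
    if rec.duration_s >= config.segment_offset_s + config.segment_duration_s:
        rec = select_segment(rec, config.segment_duration_s, config.segment_offset_s)
    else:
        logger.warning(
            "%s: recording spans %.1f s < requested segment %.1f s; using all of it",
            who, rec.duration_s, config.segment_duration_s,
        )
    clean, tach = preprocess_pipeline(rec, config)
    try:
        td = time_metrics(clean)
    except Exception as exc:
        raise RuntimeError(f"{who}: time-domain stage failed: {exc}") from exc
    try:
        fd = spectral_profile(tach, config)
    except Exception as exc:
        raise RuntimeError(f"{who}: frequency-domain stage failed: {exc}") from exc
    try:
        spectro = windowed_burg(
            tach, config.tf_window_s, config.tf_overlap_s,
            config.spectrum_order, config.spectrum_n_freq,
        )
        tf = tf_summary(spectro, config)
    except Exception as exc:
        raise RuntimeError(f"{who}: time-frequency stage failed: {exc}") from exc
    try:
        nl = nonlinear_metrics(clean, config)
    except Exception as exc:
        raise RuntimeError(f"{who}: nonlinear stage failed: {exc}") from exc
    return HRVProfile(
        subject_id=rec.subject_id,
        condition=rec.condition,
        time=td,
        freq=fd,
        tf=tf,
        nonlinear=nl,
        fraction_flagged=clean.fraction_flagged,
    )


@dataclass(frozen=True)
class StudyReport:
    rows: List[StudyRow]
    table: pd.DataFrame
    n_subjects: int

    def summary_text(self) -> str:
        lines = [f"Paired study report ({self.n_subjects} subjects)", ""]
        for r in self.rows:
            stat = r.test
            if stat.method == "paired_t":
                head = f"t({stat.df}) = {stat.statistic:.2f}"
            else:
                head = f"V = {stat.statistic:g}"
            lines.append(
                f"{r.variable:>12}: off {r.off.formatted()}  on {r.on.formatted()}  "
                f"{head}, p = {stat.p_value:.3g}"
            )
        return "\n".join(lines)


def _profiles_to_cohort(profiles: Iterable[HRVProfile]) -> pd.DataFrame:
    long = pd.DataFrame([p.to_row() for p in profiles])
    if long.empty:
        raise ValueError("no profiles")
    metric_cols = [
        c for c in long.columns if c not in ("subject_id", "condition", "fraction_flagged")
    ]
    wide = long.pivot(index="subject_id", columns="condition", values=metric_cols)
    wide.columns = [f"{metric}_{cond}" for metric, cond in wide.columns]
    return wide


def run_study(
    source: Union[CohortTable, pd.DataFrame, Iterable[HRVProfile], str, Path],
    config: AnalysisConfig = DEFAULT_CONFIG,
    variables: Optional[Sequence[str]] = None,
    overrides: Optional[Mapping[str, str]] = None,
    simes_alpha: Optional[float] = None,
    output_csv: Optional[Union[str, Path]] = None,
) -> StudyReport:
    """Build the paired study report.

    ``source`` may be a cohort metric table (computed or transcribed), a
    collection of :class:`HRVProfile`, or a directory of RR text files
    named ``<subject>_<condition>.txt`` that will be analyzed first.
    Unpaired subjects are excluded with a warning. ``simes_alpha``
    appends a multiple-testing-corrected significance column.
    """
    if isinstance(source, (str, Path)):
        directory = Path(source)
        if not directory.is_dir():
            raise ValueError(f"{source} is not a directory of recordings")
        profiles = []
        for path in sorted(directory.glob("*.txt")):
            stem = path.stem
            if "_" not in stem:
                raise ValueError(
                    f"{path.name}: expected <subject>_<condition>.txt naming"
                )
            sid, cond = stem.rsplit("_", 1)
            rec = read_rr_text(path, subject_id=sid, condition=cond)
            profiles.append(analyze_recording(rec, config))
        source = profiles
    if isinstance(source, (CohortTable, pd.DataFrame)):
        cohort = source
        if isinstance(cohort, CohortTable):
            n_subjects = cohort.n_subjects
        else:
            n_subjects = len(cohort)
    else:
        cohort = _profiles_to_cohort(source)
        n_subjects = len(cohort)
    rows = build_study_table(
        cohort if not isinstance(cohort, CohortTable) else cohort,
        variables=variables,
        overrides=overrides,
    )
    table = study_table_frame(rows, simes_alpha=simes_alpha)
    if output_csv is not None:
        table.to_csv(output_csv, index=False)
    report = StudyReport(rows=rows, table=table, n_subjects=n_subjects)
    return report
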