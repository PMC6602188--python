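"""Paired on/off study statistics.

The study design is a within-subject crossover: each variable is
measured in every subject with the intervention off and on, and the
off − on contrast is tested with a Wilcoxon signed-rank test or a
paired t-test, routed by Shapiro–Wilk normality of the differences
(with per-variable manual overrides). The signed-rank statistic is V,
the sum of the ranks of positive differences after dropping zero
differences and assigning average ranks to ties — the convention of
mainstream statistical software. Descriptive quantiles use linear
interpolation of order statistics at h = (n − 1)p. The Simes step-up
procedure is available for multiple-testing control across variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .rr_io import CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "PairedTestResult",
    "Descriptives",
    "StudyRow",
    "wilcoxon_signed_rank",
    "paired_t",
    "route_test",
    "mann_whitney_u",
    "levene_test",
    "describe",
    "simes_adjust",
    "build_study_table",
    "study_table_frame",
    "TABLE_TEST_OVERRIDES",
]


@dataclass(frozen=True)
class PairedTestResult:
    variable: str
    method: str  # "wilcoxon_signed_rank" | "paired_t"
    statistic: float  # V (sum of positive ranks) or t
    p_value: float
    n_eff: int
    df: Optional[int] = None
    direction: int = 0  # sign of the off - on central tendency


@dataclass(frozen=True)
class Descriptives:
    mean: float
    sd: Optional[float]
    median: float
    q1: float
    q3: float
    presentation: str = "median_iqr"  # or "mean_sd"

    def formatted(self, digits: int = 2) -> str:
        if self.presentation == "mean_sd":
            return f"{self.mean:.{digits}f} ± {self.sd:.{digits}f}"
        return f"{self.median:.{digits}f} ({self.q1:.{digits}f}–{self.q3:.{digits}f})"


def wilcoxon_signed_rank(x, y, variable: str = "") -> PairedTestResult:
    """Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; tied absolute differences receive
    average ranks; V is the sum of ranks of positive differences. The
    p-value is exact when there are no ties or zeros and n_eff ≤ 25,
    otherwise a tie-corrected normal approximation with continuity
    correction is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 pairs")
    d = x - y
    nz = d != 0
    if not nz.any():
        raise ValueError("degenerate pairing: all differences are zero")
    d_eff = d[nz]
    n_eff = d_eff.size
    ranks = stats.rankdata(np.abs(d_eff))
    V = float(ranks[d_eff > 0].sum())
    has_ties = np.unique(np.abs(d_eff)).size < n_eff
    had_zeros = n_eff < d.size
    if not has_ties and not had_zeros and n_eff <= 25:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(x, y, zero_method="wilcox", correction=True, method=method)
    direction = int(np.sign(np.median(d_eff))) or int(np.sign(d_eff.mean()))
    return PairedTestResult(
        variable=variable,
        method="wilcoxon_signed_rank",
        statistic=V,
        p_value=float(res.pvalue),
        n_eff=n_eff,
        df=None,
        direction=direction,
    )


def paired_t(x, y, variable: str = "") -> PairedTestResult:
    """Two-sided paired t-test on off − on differences."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    if d.std(ddof=1) == 0:
        raise ValueError("zero-variance differences: t undefined")
    res = stats.ttest_rel(x, y)
    return PairedTestResult(
        variable=variable,
        method="paired_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_eff=x.size,
        df=x.size - 1,
        direction=int(np.sign(d.mean())),
    )


def route_test(
    x,
    y,
    variable: str = "",
    alpha_normality: float = 0.05,
    overrides: Optional[Mapping[str, str]] = None,
) -> PairedTestResult:
    """Choose and run the paired test.

    The Shapiro–Wilk test on the differences routes to the paired t-test
    when normality is not rejected (p > ``alpha_normality``) and to the
    Wilcoxon signed-rank test otherwise. ``overrides`` maps variable
    names to ``"paired_t"`` or ``"wilcoxon_signed_rank"`` and bypasses
    routing — used to reproduce a published test assignment exactly.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    choice = (overrides or {}).get(variable)
    if choice is None:
        sw_p = stats.shapiro(x - y).pvalue
        choice = "paired_t" if sw_p > alpha_normality else "wilcoxon_signed_rank"
    if choice == "paired_t":
        return paired_t(x, y, variable)
    if choice == "wilcoxon_signed_rank":
        return wilcoxon_signed_rank(x, y, variable)
    raise ValueError(f"unknown test {choice!r}")


def mann_whitney_u(values, groups) -> Tuple[float, float]:
    """Unpaired two-group rank test (Mann-Whitney U).

    Returns (W, p) with W the U statistic of the first group. The
    p-value is exact for small tie-free samples, otherwise a
    tie-corrected normal approximation.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if labels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {labels.size}")
    g1 = values[groups == labels[0]]
    g2 = values[groups == labels[1]]
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def levene_test(*samples) -> Tuple[float, float]:
    """Levene's test (mean-centered) for equality of variances."""
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for s in samples:
        if len(s) < 2:
            raise ValueError("each group needs at least 2 values")
    arrays = [np.asarray(s, float) for s in samples]
    if all(a.std() == 0 for a in arrays):
        raise ValueError("all groups constant: Levene degenerate")
    res = stats.levene(*arrays, center="mean")
    return float(res.statistic), float(res.pvalue)


def describe(values, presentation: str = "median_iqr") -> Descriptives:
    """Descriptive statistics with h = (n − 1)p interpolated quantiles."""
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no values")
    sd = float(v.std(ddof=1)) if v.size > 1 else None
    return Descriptives(
        mean=float(v.mean()),
        sd=sd,
        median=float(np.quantile(v, 0.5)),
        q1=float(np.quantile(v, 0.25)),
        q3=float(np.quantile(v, 0.75)),
        presentation=presentation,
    )


def simes_adjust(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Simes step-up rejection flags at familywise level ``alpha``.

    Sorting the m p-values ascending, all hypotheses with rank up to
    max{i : p_(i) ≤ i·alpha/m} are rejected.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    crit = np.arange(1, m + 1) * alpha / m
    passing = np.flatnonzero(sorted_p <= crit)
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing.max() + 1]] = True
    return reject


# Published per-variable test assignment for the packaged study tables:
# normalized powers and the two metrics with near-normal differences use
# the paired t-test, everything else the signed-rank test.
TABLE_TEST_OVERRIDES: Dict[str, str] = {
    "mean_ibi": "wilcoxon_signed_rank",
    "hr": "wilcoxon_signed_rank",
    "sdnn": "wilcoxon_signed_rank",
    "rmssd": "wilcoxon_signed_rank",
    "ti": "paired_t",
    "tinn": "wilcoxon_signed_rank",
    "lf": "wilcoxon_signed_rank",
    "hf": "wilcoxon_signed_rank",
    "nlf": "paired_t",
    "nhf": "paired_t",
    "lf_hf": "wilcoxon_signed_rank",
    "tf_lf": "wilcoxon_signed_rank",
    "tf_hf": "wilcoxon_signed_rank",
    "tf_nlf": "paired_t",
    "tf_nhf": "paired_t",
    "rlfhf": "wilcoxon_signed_rank",
    "sd1": "wilcoxon_signed_rank",
    "sd2": "wilcoxon_signed_rank",
    "sampen": "wilcoxon_signed_rank",
    "dfa_alpha": "wilcoxon_signed_rank",
    "dfa_alpha1": "paired_t",
    "dfa_alpha2": "wilcoxon_signed_rank",
    "vas_back": "wilcoxon_signed_rank",
    "vas_leg": "wilcoxon_signed_rank",
}


@dataclass(frozen=True)
class StudyRow:
    variable: str
    off: Descriptives
    on: Descriptives
    test: PairedTestResult


def build_study_table(
    cohort: CohortTable | pd.DataFrame,
    variables: Optional[Sequence[str]] = None,
    overrides: Optional[Mapping[str, str]] = None,
    alpha_normality: float = 0.05,
) -> List[StudyRow]:
    """Paired off/on contrasts and descriptives per variable.

    Accepts a :class:`CohortTable` (or a raw frame with ``<var>_off`` /
    ``<var>_on`` columns). Subjects missing either condition for a
    variable are excluded pairwise. Variables routed to the t-test
    present mean ± SD descriptives, Wilcoxon variables median (IQR),
    mirroring the convention of mixed-normality study reports.
    """
    if isinstance(cohort, pd.DataFrame):
        df = cohort
        if df.index.name != "subject_id" and "subject_id" in df.columns:
            df = df.set_index("subject_id")
        cohort = CohortTable(df)
    if variables is None:
        variables = cohort.paired_variables()
    if overrides is None:
        overrides = TABLE_TEST_OVERRIDES
    rows: List[StudyRow] = []
    n_subjects = cohort.n_subjects
    for var in variables:
        off, on = cohort.paired(var)
        if off.size < n_subjects:
            logger.warning(
                "%s: %d of %d subjects lack a condition; excluded pairwise",
                var, n_subjects - off.size, n_subjects,
            )
        result = route_test(off, on, var, alpha_normality, overrides)
        pres = "mean_sd" if result.method == "paired_t" else "median_iqr"
        rows.append(
            StudyRow(
                variable=var,
                off=describe(off, pres),
                on=describe(on, pres),
                test=result,
            )
        )
    return rows


def study_table_frame(
    rows: Iterable[StudyRow], simes_alpha: Optional[float] = None
) -> pd.DataFrame:
    """Flatten study rows into a report table.

    With ``simes_alpha`` set, a Simes-corrected significance column is
    appended across the listed contrasts.
    """
    rows = list(rows)
    frame = pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "off": [r.off.formatted() for r in rows],
            "on": [r.on.formatted() for r in rows],
            "method": [r.test.method for r in rows],
            "statistic": [r.test.statistic for r in rows],
            "df": [r.test.df if r.test.df is not None else "" for r in rows],
            "n_eff": [r.test.n_eff for r in rows],
            "p_value": [r.test.p_value for r in rows],
        }
    )
    if simes_alpha is not None:
        frame["simes_significant"] = simes_adjust(
            frame["p_value"].to_numpy(), simes_alpha
        )
    return frame
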