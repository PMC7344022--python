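"""Group-level statistics for ROI entropy tables.

The inferential battery: Pearson correlation matrices across scans,
paired t-tests with Bonferroni correction, balanced two-factor ANOVA with
interaction, ICC(3,1) test-retest reliability, and scan-1 vs scan-2
consistency summaries.

Conventions pinned here:

* Correlation matrices drop rows listwise (never pairwise-complete), so
  every entry uses the same scan set and the matrix stays positive
  semidefinite.
* Rest-vs-task pairing is by (subject_id, scan_index).
* ICC(3,1) is the two-way mixed, single-measure, *consistency* form
  (BMS - EMS) / (BMS + (k - 1) EMS) with k = 2 scans, insensitive to a
  fixed shift between scans.
* Bonferroni adjustment is min(1, p * family size); raw and adjusted
  p-values are always reported together.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import (
    ConstantInputError,
    OutOfRangeError,
    SubjectMismatchError,
    TooFewScansError,
    TooFewSubjectsError,
    UnbalancedDesignError,
)
from .parcellation import RoiEntropyTable


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation and two-tailed p (t-transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson needs two equal-length 1D series")
    if x.size < 3:
        raise TooFewScansError("pearson needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("constant input to pearson")
    res = scipy.stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationMatrix:
    """Symmetric ROI x ROI correlation with the scan count used."""

    values: pd.DataFrame
    n_scans: int

    @property
    def roi_names(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index=True, index_label="roi")

    @classmethod
    def from_csv(cls, path, n_scans: int = 0) -> "CorrelationMatrix":
        return cls(values=pd.read_csv(path, index_col="roi"), n_scans=n_scans)


def correlation_matrix(
    table: RoiEntropyTable,
    columns: Optional[Sequence[str]] = None,
    condition: Optional[str] = None,
) -> CorrelationMatrix:
    """Pearson correlation between ROI mean-entropy columns across scans.

    Rows are restricted to ``condition`` (if given) and any row with a
    missing cell in the selected columns is dropped entirely.
    """
    tab = table.select(condition) if condition else table
    cols = list(columns) if columns is not None else tab.roi_names
    data = tab.mean[cols]
    data = data.dropna(axis=0, how="any")
    n = len(data)
    if n < 3:
        raise TooFewScansError(f"need >= 3 complete scans, have {n}")
    values = np.corrcoef(data.to_numpy(), rowvar=False)
    np.fill_diagonal(values, 1.0)
    return CorrelationMatrix(values=pd.DataFrame(values, index=cols, columns=cols), n_scans=n)


@dataclass(frozen=True)
class PairedTestResult:
    t_stat: float
    df: int
    p_raw: float
    p_adjusted: float
    mean_diff: float
    n_tests: int = 1
    note: Optional[str] = None  # "zero-variance-diff" when t is undefined

    @property
    def degenerate(self) -> bool:
        return self.note is not None


def paired_ttest(rest, task, n_tests_for_bonferroni: int = 1) -> PairedTestResult:
    """Classical paired t-test on rest - task differences.

    Degenerate input (all differences identical, so the t statistic is
    undefined or infinite) is reported as a sentinel result with NaN
    statistics and ``note='zero-variance-diff'``, never an exception.
    """
    rest = np.asarray(rest, dtype=float)
    task = np.asarray(task, dtype=float)
    if rest.shape != task.shape or rest.ndim != 1:
        raise ValueError("paired series must be equal-length 1D")
    if rest.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = rest - task
    n = diff.size
    if np.ptp(diff) == 0:
        return PairedTestResult(
            t_stat=np.nan,
            df=n - 1,
            p_raw=np.nan,
            p_adjusted=np.nan,
            mean_diff=float(diff.mean()),
            n_tests=n_tests_for_bonferroni,
            note="zero-variance-diff",
        )
    res = scipy.stats.ttest_rel(rest, task)
    p_raw = float(res.pvalue)
    return PairedTestResult(
        t_stat=float(res.statistic),
        df=n - 1,
        p_raw=p_raw,
        p_adjusted=min(1.0, p_raw * n_tests_for_bonferroni),
        mean_diff=float(diff.mean()),
        n_tests=n_tests_for_bonferroni,
    )


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni family adjustment: p -> min(1, p * family size)."""
    ps = [float(p) for p in p_values]
    if any(not 0.0 <= p <= 1.0 for p in ps):
        raise OutOfRangeError("p-values must lie in [0, 1]")
    k = len(ps)
    return [min(1.0, p * k) for p in ps]


@dataclass
class AnovaTable:
    """Classical balanced two-way ANOVA decomposition with interaction."""

    table: pd.DataFrame  # rows factor_a, factor_b, interaction, error, total

    def row(self, source: str) -> pd.Series:
        return self.table.set_index("source").loc[source]


def two_factor_anova(values, factor_a, factor_b, names=("factor_a", "factor_b")) -> AnovaTable:
    """Balanced two-way ANOVA with interaction via SS partitioning.

    Requires a fully crossed design with equal cell counts (the classical
    setting where Type I/II/III sums of squares coincide); anything else
    raises UnbalancedDesignError rather than silently re-weighting.  With
    one observation per cell the error stratum is empty and F is NaN; a
    zero-variance response reports 0/0 F ratios as NaN.
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.shape == fa.shape == fb.shape) or y.ndim != 1:
        raise ValueError("values and factor labels must be equal-length 1D")
    a_levels = np.unique(fa)
    b_levels = np.unique(fb)
    a, b = len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise UnbalancedDesignError("each factor needs at least 2 levels")
    cell_n = np.zeros((a, b), dtype=int)
    cell_sum = np.zeros((a, b))
    ai = {lev: i for i, lev in enumerate(a_levels)}
    bi = {lev: i for i, lev in enumerate(b_levels)}
    for yi, la, lb in zip(y, fa, fb):
        cell_n[ai[la], bi[lb]] += 1
        cell_sum[ai[la], bi[lb]] += yi
    r = cell_n.flat[0]
    if r < 1 or np.any(cell_n != r):
        raise UnbalancedDesignError(f"cell counts {sorted(set(cell_n.ravel()))} are not all equal")
    grand = y.mean()
    cell_mean = cell_sum / r
    mean_a = cell_mean.mean(axis=1)
    mean_b = cell_mean.mean(axis=0)
    ss_a = r * b * float(((mean_a - grand) ** 2).sum())
    ss_b = r * a * float(((mean_b - grand) ** 2).sum())
    ss_ab = r * float(
        ((cell_mean - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum()
    )
    ss_tot = float(((y - grand) ** 2).sum())
    ss_err = max(ss_tot - ss_a - ss_b - ss_ab, 0.0)
    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_err = a * b * (r - 1)
    df_tot = y.size - 1
    ms_err = ss_err / df_err if df_err > 0 else np.nan

    def f_and_p(ss, df):
        ms = ss / df
        if df_err == 0 or not np.isfinite(ms_err) or ms_err == 0.0:
            return ms, np.nan, np.nan
        f = ms / ms_err
        return ms, f, float(scipy.stats.f.sf(f, df, df_err))

    rows = []
    for src, ss, df in ((names[0], ss_a, df_a), (names[1], ss_b, df_b), ("interaction", ss_ab, df_ab)):
        ms, f, p = f_and_p(ss, df)
        rows.append({"source": src, "sum_sq": ss, "df": df, "mean_sq": ms, "F": f, "p": p})
    rows.append(
        {
            "source": "error",
            "sum_sq": ss_err,
            "df": df_err,
            "mean_sq": ms_err,
            "F": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {"source": "total", "sum_sq": ss_tot, "df": df_tot, "mean_sq": np.nan, "F": np.nan, "p": np.nan}
    )
    return AnovaTable(table=pd.DataFrame(rows))


@dataclass(frozen=True)
class IccResult:
    icc: float
    between_subject_ms: float
    error_ms: float
    n_subjects: int
    k: int = 2


def icc_3_1(scan1, scan2) -> IccResult:
    """ICC(3,1): two-way mixed, single measure, consistency.

    Computed from the subjects x scans ANOVA decomposition as
    (BMS - EMS) / (BMS + (k - 1) EMS) with k = 2.  Identical scans give
    ICC = 1; so does scan2 = scan1 + constant, because the consistency
    form removes the fixed scan effect.
    """
    s1 = np.asarray(scan1, dtype=float)
    s2 = np.asarray(scan2, dtype=float)
    if s1.shape != s2.shape or s1.ndim != 1:
        raise ValueError("scan series must be equal-length 1D")
    n = s1.size
    if n < 3:
        raise TooFewSubjectsError(f"ICC needs >= 3 subjects, have {n}")
    k = 2
    y = np.stack([s1, s2], axis=1)  # subjects x scans
    grand = y.mean()
    subj_mean = y.mean(axis=1)
    scan_mean = y.mean(axis=0)
    ss_subj = k * float(((subj_mean - grand) ** 2).sum())
    ss_scan = n * float(((scan_mean - grand) ** 2).sum())
    ss_tot = float(((y - grand) ** 2).sum())
    ss_err = max(ss_tot - ss_subj - ss_scan, 0.0)
    bms = ss_subj / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    denom = bms + (k - 1) * ems
    icc = (bms - ems) / denom if denom > 0 else np.nan
    return IccResult(icc=float(icc), between_subject_ms=bms, error_ms=ems, n_subjects=n, k=k)


def scan_consistency(
    table_scan1: RoiEntropyTable, table_scan2: RoiEntropyTable
) -> tuple[pd.DataFrame, float]:
    """Scan-1 vs scan-2 consistency per ROI, plus a group-level summary.

    Both tables must cover the same subjects (one row each) and ROI
    columns.  Per ROI: ICC(3,1) and Pearson r across subjects, and a
    two-tailed paired-t p comparing the scan-1 and scan-2 means.  The
    group-level value is the Pearson correlation between the two
    length-K vectors of ROI means.
    """
    t1, t2 = table_scan1, table_scan2
    subj1 = list(t1.meta["subject_id"])
    subj2 = list(t2.meta["subject_id"])
    if subj1 != subj2 or len(subj1) != len(set(subj1)):
        raise SubjectMismatchError("tables must list the same subjects exactly once each")
    if t1.roi_names != t2.roi_names:
        raise SubjectMismatchError("tables must share ROI columns")
    rows = []
    for name in t1.roi_names:
        x = t1.mean[name].to_numpy(dtype=float)
        y = t2.mean[name].to_numpy(dtype=float)
        icc = icc_3_1(x, y).icc
        r, _ = pearson(x, y)
        tt = paired_ttest(x, y, 1)
        rows.append({"roi": name, "icc": icc, "r": r, "p_two_tail": tt.p_raw})
    means1 = t1.mean.mean(axis=0).to_numpy()
    means2 = t2.mean.mean(axis=0).to_numpy()
    if means1.size >= 3:
        group_r, _ = pearson(means1, means2)
    else:  # correlation across <3 ROI means is not meaningful
        group_r = np.nan
    return pd.DataFrame(rows), float(group_r)
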