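"""Cohort-level statistics: Yates chi-square, two-sample t, permutation and
paired-t/Bonferroni method comparison.

The chi-square uses the clamped continuity correction
``max(|O - E| - 0.5, 0)`` so a zero-deviation table scores exactly 0; the
two-sample t defaults to the pooled-variance form (Welch available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats as sstats

from .containers import CohortTable


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic_name: str  # "X2" or "T"
    statistic: float
    df: float
    p: float

    def rounded(self, ndigits: int = 2) -> float:
        return round(self.statistic, ndigits)


def yates_chi2(table: np.ndarray) -> TestResult:
    """Chi-square on a 2x2 contingency table with clamped Yates correction."""
    O = np.asarray(table, dtype=np.float64)
    if O.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {O.shape}")
    if np.any(O < 0):
        raise ValueError("counts must be nonnegative")
    rows = O.sum(axis=1)
    cols = O.sum(axis=0)
    n = O.sum()
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("chi-square undefined: zero marginal in the table")
    E = np.outer(rows, cols) / n
    adj = np.maximum(np.abs(O - E) - 0.5, 0.0)
    chi2 = float((adj ** 2 / E).sum())
    p = float(sstats.chi2.sf(chi2, df=1))
    return TestResult("chi2", "X2", chi2, 1, p)


def two_sample_t(n1: int, mean1: float, sd1: float,
                 n2: int, mean2: float, sd2: float,
                 equal_var: bool = True) -> TestResult:
    """Two-sample t from summary statistics (pooled variance by default)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    res = sstats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=equal_var)
    df = n1 + n2 - 2 if equal_var else float(res.df) if hasattr(res, "df") else np.nan
    return TestResult("t", "T", float(res.statistic), float(df), float(res.pvalue))


def cohort_stats(table: CohortTable, equal_var: bool = True):
    """Group-comparison tests over a cohort table, one row per characteristic.

    Categorical rows (site, sex) get the Yates chi-square; continuous rows
    (age, education, MMSE, recording duration) get the two-sample t.
    Returns a list of :class:`TestResult`.
    """
    df = table.to_dataframe()
    hc = df[df.group == "HC"]
    mci = df[df.group == "MCI"]
    if len(hc) < 2 or len(mci) < 2:
        raise ValueError("need at least 2 subjects per group")
    results = []
    for name, col, levels in [("site", "site", ("CBU", "CTB")),
                              ("sex", "sex", ("M", "F"))]:
        counts = np.array([
            [(hc[col] == levels[0]).sum(), (hc[col] == levels[1]).sum()],
            [(mci[col] == levels[0]).sum(), (mci[col] == levels[1]).sum()],
        ])
        r = yates_chi2(counts)
        results.append(TestResult(name, r.statistic_name, r.statistic, r.df, r.p))
    for name in ["age", "education", "mmse", "recording_duration"]:
        a, b = hc[name].to_numpy(), mci[name].to_numpy()
        r = two_sample_t(len(a), a.mean(), a.std(ddof=1),
                         len(b), b.mean(), b.std(ddof=1), equal_var=equal_var)
        results.append(TestResult(name, r.statistic_name, r.statistic, r.df, r.p))
    return results


class PairedTTest(NamedTuple):
    t: float
    p_raw: float
    p_adjusted: float
    df: int
    degenerate: bool


def paired_ttest_bonferroni(metric_a, metric_b, m: int = 1) -> PairedTTest:
    """Paired t-test on fold-wise metric differences with Bonferroni factor m.

    All-zero differences give p = 1 (no evidence); constant nonzero
    differences have zero variance and are flagged degenerate.
    """
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors of at least 2 folds")
    if m < 1:
        raise ValueError("number of comparisons m must be >= 1")
    d = a - b
    df = d.size - 1
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return PairedTTest(0.0, 1.0, 1.0, df, False)
        t = np.inf if d.mean() > 0 else -np.inf
        return PairedTTest(float(t), 0.0, 0.0, df, True)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
    p = 2.0 * float(sstats.t.sf(abs(t), df))
    return PairedTTest(float(t), p, min(1.0, m * p), df, False)


def permutation_pvalue(values, labels, n_perm: int = 1000, seed: int = 0) -> float:
    """Two-sided label-permutation p-value for a difference in group means."""
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    obs = abs(values[labels == 1].mean() - values[labels == 0].mean())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        stat = abs(values[perm == 1].mean() - values[perm == 0].mean())
        if stat >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)
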