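"""Group-level nonparametric statistics for cohort tables.

The cohort table is tidy: one row per subject x metric, with the subject's
age group and sex carried along.  Two-group comparisons use the rank-sum
(Mann-Whitney) test, within-subject comparisons the paired Wilcoxon
signed-rank test; both use an exact permutation reference distribution at
small sample sizes (computed on the observed, possibly tied, mid-ranked
data) and the normal approximation otherwise.  Sex-by-age association uses
Fisher's exact test.  Bonferroni correction is applied across declared
comparison families.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "make_cohort_table",
    "compare_groups",
    "wilcoxon_paired",
    "fisher_association",
    "bonferroni",
    "summarize",
    "EXACT_MAX_N",
]

#: largest per-group (or pair-count) size for which the exact permutation
#: distribution is enumerated
EXACT_MAX_N = 10
EXACT_MAX_PAIRS = 14


@dataclass(frozen=True)
class TestResult:
    metric: str
    test: str  # mann_whitney | wilcoxon_paired | fisher_exact
    n1: int
    n2: int
    statistic: float
    p_raw: float
    p_adjusted: float
    adjust: str = "none"
    alpha: float = 0.05
    exact: bool = True

    @property
    def significant(self) -> bool:
        return self.p_adjusted < self.alpha


def make_cohort_table(records: pd.DataFrame | list[dict]) -> pd.DataFrame:
    """Validate and return a tidy cohort table (one value per subject x metric)."""
    df = pd.DataFrame(records)
    required = {"subject_id", "age_group", "metric", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["subject_id", "metric"])
    if dup.any():
        raise ValueError("cohort table has duplicate subject x metric rows")
    return df


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided permutation p for the rank-sum statistic (mid-ranks)."""
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_obs = ranks[:n1].sum()
    total = 0
    n_le = 0
    n_ge = 0
    eps = 1e-9
    for idx in combinations(range(len(pooled)), n1):
        r = ranks[list(idx)].sum()
        total += 1
        if r <= r_obs + eps:
            n_le += 1
        if r >= r_obs - eps:
            n_ge += 1
    p = min(1.0, 2.0 * min(n_le, n_ge) / total)
    u_obs = r_obs - n1 * (n1 + 1) / 2.0
    return float(u_obs), p


def _exact_signedrank_p(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided permutation p for the signed-rank statistic."""
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    total = 2 ** n
    # distribution of W+ over all 2^n sign assignments
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    eps = 1e-9
    n_le = int(np.sum(sums <= w_obs + eps))
    n_ge = int(np.sum(sums >= w_obs - eps))
    p = min(1.0, 2.0 * min(n_le, n_ge) / total)
    return float(w_obs), p


def compare_groups(table: pd.DataFrame, metric: str, paired: bool = False,
                   metric2: str | None = None, group: str | None = None,
                   group_col: str = "age_group") -> TestResult:
    """Compare a metric between the two age groups, or two metrics within one.

    Unpaired (default): Mann-Whitney rank-sum of ``metric`` between the two
    levels of ``group_col``.  Paired: Wilcoxon signed-rank of ``metric`` vs
    ``metric2`` paired by subject (optionally restricted to one ``group``).
    """
    if paired:
        if metric2 is None:
            raise ValueError("paired comparison needs metric2")
        sub = table if group is None else table[table[group_col] == group]
        a = sub[sub["metric"] == metric].set_index("subject_id")["value"]
        b = sub[sub["metric"] == metric2].set_index("subject_id")["value"]
        common = a.index.intersection(b.index)
        if len(common) < 3:
            raise ValueError("need at least 3 pairs")
        return wilcoxon_paired(a[common].to_numpy(), b[common].to_numpy(),
                               metric=f"{metric} vs {metric2}")
    sub = table[table["metric"] == metric]
    levels = sorted(sub[group_col].unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, found {levels}")
    x = sub[sub[group_col] == levels[0]]["value"].to_numpy(dtype=float)
    y = sub[sub[group_col] == levels[1]]["value"].to_numpy(dtype=float)
    if min(len(x), len(y)) < 3:
        raise ValueError("need at least 3 subjects per group")
    if max(len(x), len(y)) <= EXACT_MAX_N:
        stat, p = _exact_ranksum_p(x, y)
        exact = True
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        stat, p, exact = float(res.statistic), float(res.pvalue), False
    return TestResult(metric=metric, test="mann_whitney", n1=len(x), n2=len(y),
                      statistic=stat, p_raw=p, p_adjusted=p, exact=exact)


def wilcoxon_paired(a: np.ndarray, b: np.ndarray, metric: str = "") -> TestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    if np.all(d == 0):
        return TestResult(metric=metric, test="wilcoxon_paired", n1=len(a),
                          n2=len(b), statistic=0.0, p_raw=1.0, p_adjusted=1.0)
    if len(d) <= EXACT_MAX_PAIRS:
        stat, p = _exact_signedrank_p(d)
        exact = True
    else:
        res = sps.wilcoxon(a, b, alternative="two-sided", method="approx")
        stat, p, exact = float(res.statistic), float(res.pvalue), False
    return TestResult(metric=metric, test="wilcoxon_paired", n1=len(a), n2=len(b),
                      statistic=stat, p_raw=p, p_adjusted=p, exact=exact)


def fisher_association(counts: np.ndarray | list, metric: str = "sex x age"
                       ) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 contingency table."""
    counts = np.asarray(counts, dtype=int)
    if counts.shape != (2, 2) or np.any(counts < 0):
        raise ValueError("counts must be a non-negative 2x2 table")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("contingency table has an empty margin")
    odds, p = sps.fisher_exact(counts, alternative="two-sided")
    return TestResult(metric=metric, test="fisher_exact",
                      n1=int(counts[0].sum()), n2=int(counts[1].sum()),
                      statistic=float(odds), p_raw=float(p), p_adjusted=float(p))


def bonferroni(results: list[TestResult], m: int | None = None) -> list[TestResult]:
    """Bonferroni-adjust a family of results: p_adj = min(1, m * p_raw)."""
    if m is None:
        m = len(results)
    if m < 1:
        raise ValueError("family size must be >= 1")
    return [replace(r, p_adjusted=min(1.0, m * r.p_raw), adjust="bonferroni")
            for r in results]


def summarize(table: pd.DataFrame, group_col: str = "age_group") -> pd.DataFrame:
    """Per metric x group summary: n, mean, SD (SD is NaN and flagged at n=1)."""
    if table.empty:
        raise ValueError("empty cohort table")
    rows = []
    for (metric, grp), sub in table.groupby(["metric", group_col], sort=True):
        vals = sub["value"].to_numpy(dtype=float)
        n = len(vals)
        rows.append({
            "metric": metric, group_col: grp, "n": n,
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if n > 1 else float("nan"),
            "sd_defined": n > 1,
        })
    return pd.DataFrame(rows)
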