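"""Exact nonparametric tests, Bonferroni, and cohort summaries."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cranioflow.stats import (bonferroni, compare_groups, fisher_association,
                              make_cohort_table, summarize, wilcoxon_paired)


def _table(values_by_group, metric="m"):
    rows = []
    for grp, values in values_by_group.items():
        for i, v in enumerate(values):
            rows.append({"subject_id": f"{grp}{i}", "age_group": grp,
                         "metric": metric, "value": v})
    return make_cohort_table(rows)


def brute_force_ranksum_p(x, y):
    """Independent oracle: enumerate every group split of the pooled ranks."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    obs = ranks[: len(x)].sum()
    sums = [ranks[list(idx)].sum() for idx in combinations(range(len(pooled)), len(x))]
    sums = np.asarray(sums)
    n_le = np.sum(sums <= obs + 1e-9)
    n_ge = np.sum(sums >= obs - 1e-9)
    return min(1.0, 2.0 * min(n_le, n_ge) / len(sums))


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        res = compare_groups(_table({"YA": [1, 2, 3], "OA": [1, 2, 3]}), "m")
        assert res.p_raw == 1.0

    def test_complete_separation_3v3(self):
        """{1,2,3} vs {10,11,12}: exact two-sided p = 2/20 = 0.1."""
        res = compare_groups(_table({"YA": [1, 2, 3], "OA": [10, 11, 12]}), "m")
        assert res.p_raw == pytest.approx(0.1)
        assert res.exact

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(0)
        for n1, n2 in [(4, 4), (5, 7), (8, 8), (3, 6)]:
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.8, 1, n2)
            res = compare_groups(_table({"YA": x, "OA": y}), "m")
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res.p_raw == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_matches_brute_force_with_ties(self):
        """Mid-rank exact p equals full enumeration on tied data, n <= 8."""
        rng = np.random.default_rng(1)
        for n1, n2 in [(4, 5), (6, 6), (8, 7)]:
            x = rng.integers(0, 4, n1).astype(float)
            y = rng.integers(1, 5, n2).astype(float)
            res = compare_groups(_table({"YA": x, "OA": y}), "m")
            assert res.p_raw == pytest.approx(brute_force_ranksum_p(x, y), abs=1e-12)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 6), rng.normal(1, 1, 7)
        p1 = compare_groups(_table({"YA": x, "OA": y}), "m").p_raw
        p2 = compare_groups(_table({"YA": y, "OA": x}), "m").p_raw
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(_table({"YA": [1, 2], "OA": [3, 4, 5]}), "m")


class TestWilcoxon:
    def test_constant_positive_differences_n5(self):
        """All-equal positive differences, n=5: exact p = 2/32 = 0.0625."""
        a = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        res = wilcoxon_paired(a, a - 1.0)
        assert res.p_raw == pytest.approx(0.0625)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        for n in (6, 9, 12):
            a = rng.normal(0, 1, n)
            b = a + rng.normal(0.5, 1, n)
            res = wilcoxon_paired(a, b)
            ref = sps.wilcoxon(a, b, alternative="two-sided", method="exact")
            assert res.p_raw == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_matches_brute_force_sign_enumeration(self):
        """Signed-rank exact p equals enumeration of all sign patterns."""
        d = np.array([1.0, -2.0, 2.0, 3.0, -1.0, 4.0])
        ranks = sps.rankdata(np.abs(d))
        obs = ranks[d > 0].sum()
        sums = [sum(r for r, s in zip(ranks, signs) if s)
                for signs in product([False, True], repeat=len(d))]
        sums = np.asarray(sums, float)
        expected = min(1.0, 2.0 * min((sums <= obs + 1e-9).sum(),
                                      (sums >= obs - 1e-9).sum()) / len(sums))
        res = wilcoxon_paired(d, np.zeros_like(d))
        assert res.p_raw == pytest.approx(expected, abs=1e-12)

    def test_paired_via_cohort_table(self):
        rows = []
        for i, (a, b) in enumerate([(1, 2), (2, 4), (3, 5), (4, 7), (5, 8)]):
            rows.append({"subject_id": f"s{i}", "age_group": "YA",
                         "metric": "peak_BT", "value": float(a)})
            rows.append({"subject_id": f"s{i}", "age_group": "YA",
                         "metric": "peak_RC", "value": float(b)})
        res = compare_groups(make_cohort_table(rows), "peak_BT", paired=True,
                             metric2="peak_RC")
        assert res.test == "wilcoxon_paired"
        assert res.p_raw == pytest.approx(0.0625)


class TestFisher:
    def test_balanced_table(self):
        assert fisher_association([[5, 5], [5, 5]]).p_raw == 1.0

    def test_diagonal_matches_hypergeometric_enumeration(self):
        """[[10,0],[0,10]]: sum hypergeometric probabilities <= observed."""
        counts = [[10, 0], [0, 10]]
        dist = sps.hypergeom(20, 10, 10)
        p_obs = dist.pmf(10)
        oracle = sum(dist.pmf(k) for k in range(11) if dist.pmf(k) <= p_obs + 1e-12)
        res = fisher_association(counts)
        assert res.p_raw == pytest.approx(oracle, rel=1e-9)

    def test_cohort_sex_balance_not_significant(self):
        """6/4 vs 5/4 males/females between age groups: p is comfortably
        non-significant (>= 0.4)."""
        assert fisher_association([[6, 4], [5, 4]]).p_raw >= 0.4

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_association([[0, 0], [3, 4]])


class TestBonferroni:
    def test_never_lowers_and_caps_at_one(self):
        base = [fisher_association([[5, 5], [5, 5]]),
                fisher_association([[9, 1], [1, 9]])]
        adjusted = bonferroni(base, m=4)
        for raw, adj in zip(base, adjusted):
            assert adj.p_adjusted >= raw.p_raw
            assert adj.p_adjusted <= 1.0
            assert adj.adjust == "bonferroni"
            assert adj.p_adjusted == pytest.approx(min(1.0, 4 * raw.p_raw))


class TestSummarize:
    def test_single_subject_sd_flagged(self):
        table = _table({"YA": [3.0]})
        out = summarize(table)
        assert not out.sd_defined.iloc[0]
        assert np.isnan(out.sd.iloc[0])

    def test_mean_of_sums_equals_sum_of_means(self):
        rng = np.random.default_rng(7)
        bt, rc, lc = rng.random((3, 7)) * 10
        rows = []
        for i in range(7):
            for name, vals in [("BT", bt), ("RC", rc), ("LC", lc),
                               ("total", bt + rc + lc)]:
                rows.append({"subject_id": f"s{i}", "age_group": "YA",
                             "metric": name, "value": vals[i]})
        out = summarize(make_cohort_table(rows)).set_index("metric")["mean"]
        assert out["total"] == pytest.approx(out["BT"] + out["RC"] + out["LC"])

    def test_duplicate_rows_rejected(self):
        rows = [{"subject_id": "a", "age_group": "YA", "metric": "m", "value": 1.0},
                {"subject_id": "a", "age_group": "YA", "metric": "m", "value": 2.0}]
        with pytest.raises(ValueError):
            make_cohort_table(rows)
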