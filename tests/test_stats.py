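"""Chi-square and AMOVA, checked against independent direct-summation
oracles and their distributional properties."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chlorotyping import GroupedDataset, amova, pearson_chisq, within_group_contributions


def amova_oracle(chlorotypes, labels):
    """Textbook AMOVA by explicit double loops (independent of the
    package's vectorised path)."""
    n = len(chlorotypes)
    groups = sorted(set(labels))
    d2 = {}
    for i, j in itertools.combinations(range(n), 2):
        d2[(i, j)] = sum(a != b for a, b in zip(chlorotypes[i], chlorotypes[j]))
    ssd_total = sum(d2.values()) / n
    ssd_within = 0.0
    per_group = {}
    for g in groups:
        idx = [i for i, lab in enumerate(labels) if lab == g]
        s = sum(d2[(i, j)] for i, j in itertools.combinations(idx, 2))
        per_group[g] = s / len(idx)
        ssd_within += s / len(idx)
    ssd_among = ssd_total - ssd_within
    G, df_a, df_w = len(groups), len(groups) - 1, n - len(groups)
    ms_a, ms_w = ssd_among / df_a, ssd_within / df_w
    sizes = [labels.count(g) for g in groups]
    n0 = (n - sum(s * s for s in sizes) / n) / (G - 1)
    s2a, s2w = (ms_a - ms_w) / n0, ms_w
    return dict(
        ssd_among=ssd_among, ssd_within=ssd_within, ssd_total=ssd_total,
        sigma2_among=s2a, sigma2_within=s2w,
        pct_among=100 * s2a / (s2a + s2w),
        contributions={g: 100 * v / ssd_within for g, v in per_group.items()},
    )


class TestChiSquare:
    def test_identical_columns_give_zero(self):
        table = pd.DataFrame({"a": [10, 5, 2], "b": [10, 5, 2]})
        res = pearson_chisq(table)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_association_closed_form(self):
        res = pearson_chisq(pd.DataFrame([[10, 0], [0, 10]]))
        assert res.statistic == pytest.approx(20.0)  # 4 cells of (5)^2/5
        assert res.df == 1

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pearson_chisq(pd.DataFrame([[1, 2]]))

    def test_zero_marginal_rows_dropped(self):
        res = pearson_chisq(pd.DataFrame([[5, 5], [0, 0], [5, 1]]))
        assert res.n_dropped_cells == 2
        assert res.df == 1

    def test_matches_scipy_on_dense_table(self, rng):
        table = pd.DataFrame(rng.integers(1, 30, size=(4, 3)))
        res = pearson_chisq(table)
        stat, p, df, _ = sps.chi2_contingency(table.values, correction=False)
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)
        assert res.df == df


def _dataset(chlorotypes, labels):
    return GroupedDataset(
        [(f"s{i}", g, c) for i, (g, c) in enumerate(zip(labels, chlorotypes))]
    )


class TestAmova:
    toy_chloro = ["0101", "0101", "0111", "1110", "1100", "1110"]
    toy_labels = ["A", "A", "A", "B", "B", "B"]

    def test_components_match_direct_summation_oracle(self):
        res = amova(_dataset(self.toy_chloro, self.toy_labels), n_perm=0)
        exp = amova_oracle(self.toy_chloro, self.toy_labels)
        assert res.ssd_among == pytest.approx(exp["ssd_among"])
        assert res.ssd_within == pytest.approx(exp["ssd_within"])
        assert res.sigma2_among == pytest.approx(exp["sigma2_among"])
        assert res.sigma2_within == pytest.approx(exp["sigma2_within"])
        assert res.pct_among == pytest.approx(exp["pct_among"])

    def test_fixed_group_differences_give_all_among(self):
        res = amova(_dataset(["0101"] * 3 + ["0111"] * 3, ["A"] * 3 + ["B"] * 3), n_perm=0)
        assert res.pct_among == pytest.approx(100.0)
        assert res.pct_within == pytest.approx(0.0)

    def test_split_pool_shows_no_structure(self, rng):
        pool = ["".join(rng.choice(list("01"), 5)) for _ in range(30)]
        res = amova(_dataset(pool + pool, ["A"] * 30 + ["B"] * 30), n_perm=199, seed=5)
        assert res.pct_among < 5.0
        assert res.p_perm > 0.05

    def test_ssd_additivity(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 20))
            chloro = ["".join(rng.choice(list("01a"), 6)) for _ in range(n)]
            labels = list(rng.choice(["A", "B", "C"], n))
            if len(set(labels)) < 2 or min(labels.count(g) for g in set(labels)) < 1:
                continue
            res = amova(_dataset(chloro, labels), n_perm=0)
            assert res.ssd_among + res.ssd_within == pytest.approx(
                res.ssd_total, rel=1e-9
            )

    def test_sample_order_invariance(self, rng):
        chloro = ["".join(rng.choice(list("01"), 4)) for _ in range(12)]
        labels = ["A"] * 6 + ["B"] * 6
        res1 = amova(_dataset(chloro, labels), n_perm=0)
        order = rng.permutation(12)
        res2 = amova(
            GroupedDataset(
                [(f"s{i}", labels[i], chloro[i]) for i in order], groups=["A", "B"]
            ),
            n_perm=0,
        )
        assert res1.pct_among == pytest.approx(res2.pct_among)
        assert res1.ssd_within == pytest.approx(res2.ssd_within)

    def test_permutation_p_on_achievable_grid(self):
        res = amova(_dataset(self.toy_chloro, self.toy_labels), n_perm=99, seed=0)
        assert 1 / 100 <= res.p_perm <= 1.0

    def test_permutation_p_uniform_under_null(self):
        """Kolmogorov-Smirnov check of permutation p-values on label-
        randomised data (199 permutations, 200 replicates)."""
        ps = []
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            chloro = ["".join(rng.choice(list("01"), 5)) for _ in range(16)]
            labels = ["A"] * 8 + ["B"] * 8
            res = amova(_dataset(chloro, labels), n_perm=199, seed=rep)
            ps.append(res.p_perm)
        assert sps.kstest(ps, "uniform").pvalue > 1e-3

    def test_identical_individuals_flagged_not_raised(self):
        res = amova(_dataset(["0101"] * 6, ["A"] * 3 + ["B"] * 3), n_perm=0)
        assert res.undefined
        assert np.isnan(res.pct_among)

    def test_unresolved_chlorotypes_rejected(self):
        with pytest.raises(ValueError, match=r"\?"):
            amova(_dataset(["01?1", "0101", "0111", "1110"], ["A", "A", "B", "B"]))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            amova(_dataset(["01", "11"], ["A", "A"]))


class TestWithinContributions:
    def test_symmetric_groups_split_evenly(self):
        chloro = ["00", "01", "10", "00", "01", "10"]
        labels = ["A", "A", "A", "B", "B", "B"]
        contrib = within_group_contributions(_dataset(chloro, labels))
        assert contrib["A"] == pytest.approx(50.0)
        assert contrib["B"] == pytest.approx(50.0)

    def test_three_groups_match_direct_summation(self, rng):
        chloro = ["".join(rng.choice(list("01"), 4)) for _ in range(15)]
        labels = ["A"] * 5 + ["B"] * 5 + ["C"] * 5
        contrib = within_group_contributions(_dataset(chloro, labels))
        exp = amova_oracle(chloro, labels)["contributions"]
        for g in "ABC":
            assert contrib[g] == pytest.approx(exp[g])
        assert sum(contrib.values()) == pytest.approx(100.0)

    def test_zero_within_variation_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            within_group_contributions(
                _dataset(["01", "01", "11", "11"], ["A", "A", "B", "B"])
            )
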