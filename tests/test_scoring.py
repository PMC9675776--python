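import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gedinet import (
    GroupScore,
    assign_gene_scores,
    gene_t_statistic,
    group_score_analytic,
    group_score_ml,
    rank_groups,
)
from gedinet.grouping import SubDataset

from conftest import make_dataset, random_two_class


def as_subdataset(ds, name="grp"):
    return SubDataset(group_name=name, data=ds)


class TestGeneTStatistic:
    def test_hand_worked_value(self):
        # means 2 vs 1, both sample variances 2 with n=2: T = 1/sqrt(2/2 + 2/2)... = 1/sqrt(2)
        t = gene_t_statistic([1, 3], [0, 2])
        assert t.T == pytest.approx(1 / math.sqrt(2), abs=1e-12)

    def test_identical_classes_give_zero(self):
        assert gene_t_statistic([1, 2, 3], [1, 2, 3]).T == 0.0

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=15),
        st.lists(st.floats(-50, 50), min_size=2, max_size=15),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetry(self, a, b):
        t_ab = gene_t_statistic(a, b).T
        t_ba = gene_t_statistic(b, a).T
        if math.isinf(t_ab):
            assert math.isinf(t_ba) and t_ab == -t_ba
        else:
            assert t_ab == pytest.approx(-t_ba, rel=1e-9, abs=1e-9)

    def test_zero_variance_shifted_means_flagged(self):
        t = gene_t_statistic([2, 2], [1, 1])
        assert math.isinf(t.T) and t.T > 0 and t.flagged


class TestGroupScoreAnalytic:
    def test_matches_brute_force(self, rng):
        """Mean |T| over genes must equal an independent gene-by-gene evaluation."""
        for _ in range(20):
            n_pos = int(rng.integers(2, 20))
            n_neg = int(rng.integers(2, 20))
            n_genes = int(rng.integers(1, 10))
            values = rng.normal(size=(n_pos + n_neg, n_genes))
            ds = make_dataset(values, ["pos"] * n_pos + ["neg"] * n_neg)
            score = group_score_analytic(as_subdataset(ds)).score
            pos, neg = values[:n_pos], values[n_pos:]
            ts = []
            for j in range(n_genes):
                num = pos[:, j].mean() - neg[:, j].mean()
                den = math.sqrt(
                    pos[:, j].var(ddof=1) / n_pos + neg[:, j].var(ddof=1) / n_neg
                )
                ts.append(abs(num / den))
            assert score == pytest.approx(np.mean(ts), abs=1e-10)

    def test_single_gene_group(self):
        ds = make_dataset([[1], [3], [0], [2]], ["pos", "pos", "neg", "neg"])
        score = group_score_analytic(as_subdataset(ds)).score
        assert score == pytest.approx(1 / math.sqrt(2), abs=1e-12)

    def test_signed_mode_cancels(self):
        # two genes with exactly opposite shifts: signed mean T is 0
        values = np.array([[1.0, -1.0], [3.0, -3.0], [0.0, 0.0], [2.0, -2.0]])
        ds = make_dataset(values, ["pos", "pos", "neg", "neg"])
        signed = group_score_analytic(as_subdataset(ds), use_absolute=False).score
        unsigned = group_score_analytic(as_subdataset(ds), use_absolute=True).score
        assert signed == pytest.approx(0.0, abs=1e-12)
        assert unsigned > 0

    def test_infinite_t_clipped_and_flagged(self):
        ds = make_dataset([[2.0], [2.0], [1.0], [1.0]], ["pos", "pos", "neg", "neg"])
        gs = group_score_analytic(as_subdataset(ds), infinite_cap=100.0)
        assert gs.flagged and gs.score == 100.0


class TestGroupScoreMl:
    def test_separable_group_scores_high(self, rng):
        ds = random_two_class(rng, n_pos=30, n_neg=30, n_genes=5, shift=10.0)
        gs = group_score_ml(as_subdataset(ds), r=10, seed=1, n_trees=25)
        assert gs.score >= 0.95

    def test_null_group_scores_near_chance(self, rng):
        ds = random_two_class(rng, n_pos=30, n_neg=30, n_genes=5, shift=0.0)
        gs = group_score_ml(as_subdataset(ds), r=50, seed=2, n_trees=25)
        assert abs(gs.score - 0.5) <= 0.15

    def test_deterministic_under_fixed_seed(self, rng):
        ds = random_two_class(rng, n_pos=12, n_neg=12, n_genes=4, shift=1.0)
        a = group_score_ml(as_subdataset(ds), r=5, seed=7, n_trees=10)
        b = group_score_ml(as_subdataset(ds), r=5, seed=7, n_trees=10)
        assert a.score == b.score

    def test_score_in_unit_interval_and_monotone_in_signal(self, rng):
        means = []
        for shift in (0.0, 1.0, 3.0):
            scores = []
            for seed in range(20):
                local = np.random.default_rng(seed)
                ds = random_two_class(local, n_pos=20, n_neg=20, n_genes=4, shift=shift)
                s = group_score_ml(as_subdataset(ds), r=3, seed=seed, n_trees=10).score
                assert 0.0 <= s <= 1.0
                scores.append(s)
            means.append(np.mean(scores))
        assert means[0] <= means[1] <= means[2]


class TestRankGroups:
    @staticmethod
    def gs(name, score, genes=("a",)):
        return GroupScore(group_name=name, score=score, gene_set=frozenset(genes), method="ml")

    def test_descending_order(self):
        ranked = rank_groups([self.gs("C", 0.94), self.gs("A", 0.98), self.gs("B", 0.96)])
        assert [(g.group_name, g.rank) for g in ranked] == [("A", 1), ("B", 2), ("C", 3)]

    def test_tie_broken_by_size_then_name(self):
        big = self.gs("Z", 0.9, genes=[f"g{i}" for i in range(10)])
        small = self.gs("A", 0.9, genes=["g1", "g2", "g3"])
        ranked = rank_groups([small, big])
        assert ranked[0].group_name == "Z"
        tied_same_size = rank_groups([self.gs("B", 0.9), self.gs("A", 0.9)])
        assert tied_same_size[0].group_name == "A"

    def test_single_group(self):
        assert rank_groups([self.gs("only", 0.5)])[0].rank == 1

    def test_output_is_permutation_with_valid_ranks(self, rng):
        scores = [self.gs(f"d{i}", float(rng.random())) for i in range(25)]
        ranked = rank_groups(scores)
        assert sorted(g.group_name for g in ranked) == sorted(g.group_name for g in scores)
        assert [g.rank for g in ranked] == list(range(1, 26))
        assert all(ranked[i].score >= ranked[i + 1].score for i in range(24))


class TestAssignGeneScores:
    def test_max_rule(self):
        ranked = rank_groups(
            [
                TestRankGroups.gs("hi", 0.9, genes=["shared", "only_hi"]),
                TestRankGroups.gs("lo", 0.7, genes=["shared", "only_lo"]),
            ]
        )
        scores = dict(assign_gene_scores(ranked))
        assert scores == {"shared": 0.9, "only_hi": 0.9, "only_lo": 0.7}

    def test_sorted_descending(self):
        ranked = rank_groups(
            [TestRankGroups.gs("a", 0.6, ["x"]), TestRankGroups.gs("b", 0.8, ["y"])]
        )
        out = assign_gene_scores(ranked)
        assert out == [("y", 0.8), ("x", 0.6)]

    def test_empty(self):
        assert assign_gene_scores([]) == []
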