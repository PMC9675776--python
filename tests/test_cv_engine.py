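import numpy as np
import pytest

from gedinet import (
    GediNetConfig,
    GroupCatalog,
    aggregate_performance,
    mccv_split,
    run_gedinet,
    run_iteration,
    undersample,
)
from gedinet.cv_engine import IterationResult
from gedinet.modeling import PerformanceRecord
from gedinet.synthetic import SyntheticSpec, generate

from conftest import make_dataset, random_two_class

FAST = dict(n_trees=10, scoring_r=2)


class TestUndersample:
    def test_majority_thinned_minority_intact(self, rng):
        ds = random_two_class(rng, n_pos=99, n_neg=41, n_genes=3)
        bal = undersample(ds, seed=1)
        n_pos, n_neg = bal.class_counts()
        assert n_pos == n_neg == 41
        neg_ids = {s for s, l in zip(ds.samples, ds.labels) if l == "neg"}
        assert neg_ids <= set(bal.samples)

    def test_balanced_unchanged(self, rng):
        ds = random_two_class(rng, n_pos=30, n_neg=30, n_genes=2)
        assert undersample(ds, seed=5).samples == ds.samples

    def test_deterministic(self, rng):
        ds = random_two_class(rng, n_pos=50, n_neg=20, n_genes=2)
        assert undersample(ds, seed=3).samples == undersample(ds, seed=3).samples


class TestMccvSplit:
    def test_stratified_sizes(self, rng):
        ds = random_two_class(rng, n_pos=60, n_neg=40, n_genes=2)
        train, test = mccv_split(ds, train_frac=0.9, seed=0)
        assert train.class_counts() == (54, 36)
        assert test.class_counts() == (6, 4)
        assert set(train.samples) | set(test.samples) == set(ds.samples)
        assert not set(train.samples) & set(test.samples)

    def test_same_seed_same_partition(self, rng):
        ds = random_two_class(rng, n_pos=20, n_neg=20, n_genes=2)
        a = mccv_split(ds, 0.9, seed=11)
        b = mccv_split(ds, 0.9, seed=11)
        assert a[0].samples == b[0].samples and a[1].samples == b[1].samples

    def test_different_seeds_differ(self, rng):
        ds = random_two_class(rng, n_pos=30, n_neg=30, n_genes=2)
        differ = sum(
            mccv_split(ds, 0.9, seed=2 * k)[1].samples
            != mccv_split(ds, 0.9, seed=2 * k + 1)[1].samples
            for k in range(10)
        )
        assert differ >= 9


def small_run(iterations=3, seed=0, **spec_kw):
    spec = SyntheticSpec(
        n_pos=25, n_neg=25, n_genes=60, n_groups=5, group_size=10, n_planted=2,
        delta=2.5, seed=seed, **spec_kw,
    )
    ds, catalog, truth = generate(spec)
    config = GediNetConfig(iterations=iterations, seed=seed, max_j=3, **FAST)
    return ds, catalog, truth, config


class TestRunGedinet:
    def test_orchestration_contract(self):
        ds, catalog, truth, config = small_run(iterations=3)
        results = run_gedinet(ds, catalog, config)
        assert len(results) == 3
        for res in results:
            assert [g.rank for g in res.ranked_groups] == list(
                range(1, len(res.ranked_groups) + 1)
            )
            assert [p.j for p in res.performance] == list(
                range(1, min(config.max_j, len(res.ranked_groups)) + 1)
            )
            assert not res.train_ids & res.test_ids

    def test_planted_groups_dominate(self):
        ds, catalog, truth, config = small_run(iterations=5)
        results = run_gedinet(ds, catalog, config)
        top = [res.ranked_groups[0].group_name for res in results]
        assert all(name in truth.planted_groups for name in top)

    def test_all_groups_absent_raises(self, rng):
        ds = random_two_class(rng, n_pos=10, n_neg=10, n_genes=4, shift=2.0)
        catalog = GroupCatalog(groups={"d": frozenset({"absent1", "absent2"})})
        config = GediNetConfig(iterations=4, **FAST)
        with pytest.raises(RuntimeError):
            run_gedinet(ds, catalog, config)

    def test_bit_reproducible(self):
        ds, catalog, _, config = small_run(iterations=2)
        r1 = run_gedinet(ds, catalog, config)
        r2 = run_gedinet(ds, catalog, config)
        for a, b in zip(r1, r2):
            assert [(g.group_name, g.score) for g in a.ranked_groups] == [
                (g.group_name, g.score) for g in b.ranked_groups
            ]
            assert a.performance == b.performance
            assert a.test_ids == b.test_ids

    def test_no_leakage_from_test_labels(self, rng):
        """Flipping every test label must not move anything upstream of evaluation."""
        ds, catalog, _, config = small_run(iterations=1)
        train, test = mccv_split(ds, 0.9, seed=4)
        flipped = make_dataset(
            test.values,
            ["neg" if l == "pos" else "pos" for l in test.labels],
            genes=test.genes,
            samples=test.samples,
        )
        res_a = run_iteration(train, test, catalog, config, seed=9)
        res_b = run_iteration(train, flipped, catalog, config, seed=9)
        assert [(g.group_name, g.score, g.rank) for g in res_a.ranked_groups] == [
            (g.group_name, g.score, g.rank) for g in res_b.ranked_groups
        ]
        # downstream metrics do change, which is exactly the point of the split
        assert [p.n_genes for p in res_a.performance] == [
            p.n_genes for p in res_b.performance
        ]


class TestAggregatePerformance:
    @staticmethod
    def iteration(i, recs):
        return IterationResult(
            iteration=i, ranked_groups=[], performance=recs, split_seed=0,
            train_ids=frozenset(), test_ids=frozenset(),
        )

    def test_mean_of_two_iterations(self):
        r1 = PerformanceRecord(1, 10, 0.8, 0.8, 0.8, 0.9)
        r2 = PerformanceRecord(1, 12, 0.9, 0.9, 0.9, 0.95)
        out = aggregate_performance([self.iteration(0, [r1]), self.iteration(1, [r2])])
        assert out.loc[0, "Accuracy"] == pytest.approx(0.85)
        assert out.loc[0, "#Genes"] == pytest.approx(11.0)

    def test_missing_auc_excluded(self):
        r1 = PerformanceRecord(1, 10, 0.8, 0.8, 0.8, float("nan"))
        r2 = PerformanceRecord(1, 10, 0.9, 0.9, 0.9, 0.7)
        out = aggregate_performance([self.iteration(0, [r1]), self.iteration(1, [r2])])
        assert out.loc[0, "AUC"] == pytest.approx(0.7)

    def test_single_iteration_identity(self):
        r = PerformanceRecord(2, 5, 0.6, 0.5, 0.7, 0.65)
        out = aggregate_performance([self.iteration(0, [r])])
        assert out.loc[0, "Specificity"] == pytest.approx(0.7)

    def test_mean_genes_non_decreasing_in_j(self):
        ds, catalog, _, config = small_run(iterations=3)
        results = run_gedinet(ds, catalog, config)
        out = aggregate_performance(results, descending=False)
        genes = out["#Genes"].to_numpy()
        assert (np.diff(genes) >= 0).all()
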