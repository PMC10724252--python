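import numpy as np
import pandas as pd
import pytest

from cfnet import inference as inf
from cfnet.errors import ConfigError
from cfnet.goldstandard import label_pairs
from cfnet.types import ComplexCatalog, LabeledPairSet
from oracles import auroc_paircount, precision_recount


def pair_index(pairs):
    return pd.Index(pairs, tupleize_cols=False)


def feature_table(pairs, values, experiments=("e1",), measures=("dcor",)):
    cols = pd.MultiIndex.from_product([experiments, measures], names=["experiment", "measure"])
    data = np.tile(np.asarray(values, dtype=float)[:, None], (1, len(cols)))
    return pd.DataFrame(data, index=pair_index(pairs), columns=cols)


def make_labels(n_complexes=4, size=3, prefix="P"):
    proteins = [f"{prefix}{i:03d}" for i in range(n_complexes * size)]
    complexes = {
        f"C{i}": frozenset(proteins[size * i : size * (i + 1)]) for i in range(n_complexes)
    }
    return label_pairs(ComplexCatalog(complexes=complexes))


class TestTieredMeasures:
    @pytest.mark.parametrize(
        "n,measures",
        [
            (12, ["dcor"]),
            (11, ["dcor"]),
            (10, ["dcor", "wcc"]),
            (7, ["dcor", "wcc"]),
            (6, ["dcor", "wcc"]),
            (5, ["dcor", "wcc", "cosine", "mi"]),
            (3, ["dcor", "wcc", "cosine", "mi"]),
            (1, ["dcor", "wcc", "cosine", "mi"]),
        ],
    )
    def test_tier_rule(self, n, measures):
        assert [s.measure for s in inf.tiered_measures(n)] == measures

    @pytest.mark.parametrize("n,total", [(12, 12), (7, 14), (3, 12)])
    def test_total_column_counts(self, n, total):
        assert n * len(inf.tiered_measures(n)) == total


class TestPrecisionCurve:
    def test_hand_computed_sequences(self):
        np.testing.assert_allclose(
            inf.precision_curve([1, 1, 0, 1]), [1, 1, 2 / 3, 3 / 4]
        )
        got = inf.precision_curve([1, np.nan, 0])
        np.testing.assert_allclose(got, [1, 1, 0.5])

    def test_undefined_until_first_labeled(self):
        got = inf.precision_curve([np.nan, np.nan, 1])
        assert np.isnan(got[0]) and np.isnan(got[1]) and got[2] == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_recount(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.choice([1.0, 0.0, np.nan], size=20, p=[0.3, 0.4, 0.3])
        got = inf.precision_curve(labels)
        expected = precision_recount(list(labels))
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestAuroc:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_paircount_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice(np.round(rng.uniform(0, 1, 8), 2), size=30)  # force ties
        labels = rng.integers(0, 2, size=30)
        assert inf.roc_auc(scores, labels) == pytest.approx(
            auroc_paircount(scores, labels), abs=1e-12
        )

    def test_perfect_and_inverted(self):
        assert inf.roc_auc(np.array([3, 2, 1, 0]), np.array([1, 1, 0, 0])) == 1.0
        assert inf.roc_auc(np.array([0, 1, 2, 3]), np.array([1, 1, 0, 0])) == 0.0


class TestThresholding:
    def ranked_from(self, labels):
        n = len(labels)
        pairs = [(f"A{i:02d}", f"B{i:02d}") for i in range(n)]
        scores = np.linspace(1, 0.5, n)
        return inf.RankedNetwork(
            pairs=pairs,
            scores=scores,
            labels=np.asarray(labels, dtype=float),
            precision=inf.precision_curve(labels),
        )

    def test_hand_computed_cutoff(self):
        ranked = self.ranked_from([1, 1, 0, 1, 0, 0, 0, 0])
        # cumulative: 1, 1, 2/3, 3/4, 3/5, 1/2, 3/7, 3/8 -> largest >= 0.5 is rank 6
        net = inf.threshold_network(ranked, 0.5)
        assert len(net) == 6

    def test_target_one_keeps_longest_perfect_prefix(self):
        ranked = self.ranked_from([1, 1, 0, 1])
        net = inf.threshold_network(ranked, 1.0)
        assert len(net) == 2

    def test_unreached_target_gives_empty_network(self):
        ranked = self.ranked_from([0, 0, 1])
        assert len(inf.threshold_network(ranked, 0.9)) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_linear_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.choice([1.0, 0.0, np.nan], size=25, p=[0.4, 0.4, 0.2])
        ranked = self.ranked_from(labels)
        target = 0.6
        k = 0
        prec = precision_recount(list(labels))
        for r, p in enumerate(prec, start=1):
            if not np.isnan(p) and p >= target:
                k = r
        assert len(inf.threshold_network(ranked, target)) == k

    def test_topk_basics_and_overflow(self):
        ranked = self.ranked_from([1, 0, 1, 0, 1])
        assert len(inf.threshold_topk(ranked, 3)) == 3
        assert len(inf.threshold_topk(ranked, 99)) == 5

    def test_topk_tie_break_invariant_to_input_order(self):
        pairs = [("A", "B"), ("A", "C"), ("B", "C"), ("B", "D")]
        scores = {p: 1.0 for p in pairs}  # all tied
        nets = []
        for perm in ([0, 1, 2, 3], [3, 2, 1, 0], [2, 0, 3, 1]):
            ordered = [pairs[i] for i in perm]
            order = inf._rank_order(ordered, np.array([scores[p] for p in ordered]))
            ranked = inf.RankedNetwork(
                pairs=[ordered[i] for i in order],
                scores=np.ones(4),
                labels=np.full(4, np.nan),
                precision=np.full(4, np.nan),
            )
            nets.append(inf.threshold_topk(ranked, 2).edge_set)
        assert nets[0] == nets[1] == nets[2] == {("A", "B"), ("A", "C")}


class TestTrainScoreCV:
    def test_separable_features_rank_positives_first(self):
        labels = make_labels(4, 3)
        pairs = sorted(labels.labels)
        values = [1.0 if labels.labels[p] == 1 else 0.0 for p in pairs]
        table = feature_table(pairs, values)
        ranked = inf.train_score_cv(table, labels, k=2, n_trees=20, seed=0)
        n_pos = len(labels.positives)
        assert set(ranked.pairs[:n_pos]) == labels.positives
        np.testing.assert_allclose(ranked.precision[:n_pos], 1.0)

    def test_same_seed_bit_identical_ranking(self):
        rng = np.random.default_rng(0)
        labels = make_labels(4, 3)
        pairs = sorted(labels.labels)
        values = rng.uniform(0, 1, len(pairs))
        table = feature_table(pairs, values)
        r1 = inf.train_score_cv(table, labels, k=2, n_trees=10, seed=3)
        r2 = inf.train_score_cv(table, labels, k=2, n_trees=10, seed=3)
        assert r1.pairs == r2.pairs
        np.testing.assert_array_equal(r1.scores, r2.scores)

    def test_missing_features_never_reach_learner(self):
        labels = make_labels(4, 3)
        pairs = sorted(labels.labels)
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 1, len(pairs))
        table = feature_table(pairs, values)
        table.iloc[::3, 0] = np.nan  # markers must be zero-filled internally
        ranked = inf.train_score_cv(table, labels, k=2, n_trees=10, seed=0)
        assert np.isfinite(ranked.scores).all()

    def test_median_fill_differs_from_zero_fill_only_with_markers(self):
        labels = make_labels(4, 3)
        pairs = sorted(labels.labels)
        rng = np.random.default_rng(2)
        table = feature_table(pairs, rng.uniform(0.4, 1.0, len(pairs)))
        table.iloc[::4, 0] = np.nan
        zero = inf.train_score_cv(table, labels, k=2, n_trees=10, seed=0)
        med = inf.train_score_cv(table, labels, k=2, n_trees=10, seed=0, missing_fill="median")
        assert zero.pairs != med.pairs or not np.array_equal(zero.scores, med.scores)
        with pytest.raises(ConfigError):
            inf.train_score_cv(table, labels, k=2, n_trees=10, seed=0, missing_fill="mean")

    def test_single_class_fold_is_informative_error(self):
        labels = LabeledPairSet(
            labels={("A", "B"): 1, ("C", "D"): 1},
            origin={("A", "B"): {"C1"}, ("C", "D"): {"C2"}},
        )
        table = feature_table(sorted(labels.labels), [1.0, 1.0])
        with pytest.raises(ConfigError, match="single class"):
            inf.train_score_cv(table, labels, k=2, n_trees=5, seed=0)

    def test_unlabeled_pairs_scored_by_fold_average(self):
        labels = make_labels(4, 3)
        pairs = sorted(labels.labels) + [("ZZZ1", "ZZZ2")]
        values = [float(labels.labels.get(p, 0.5)) for p in pairs]
        table = feature_table(pairs, values)
        ranked = inf.train_score_cv(table, labels, k=2, n_trees=10, seed=0)
        assert ("ZZZ1", "ZZZ2") in ranked.pairs
        assert np.isnan(ranked.labels[ranked.pairs.index(("ZZZ1", "ZZZ2"))])


class TestAugmentation:
    def build(self, n_target_complexes=4, pool_pairs=400):
        labels = make_labels(n_target_complexes, 3)
        pairs = sorted(labels.labels)
        rng = np.random.default_rng(0)
        table = feature_table(pairs, rng.uniform(0, 1, len(pairs)), experiments=("t1", "t2"))
        ext_labels = {}
        ext = {}
        ext_pair_list = []
        for i in range(pool_pairs):
            p = (f"X{i:04d}", f"Y{i:04d}")
            ext_pair_list.append(p)
            ext_labels[p] = int(i % 2)
        for e in range(3):
            ext[f"ext{e}"] = pd.DataFrame(
                {"dcor": rng.uniform(0, 1, pool_pairs)},
                index=pair_index(ext_pair_list),
            )
        pool = inf.ExternalFeaturePool(experiments=ext, labels=ext_labels)
        return table, labels, pool

    def test_injection_count_is_floor_of_proportion(self):
        table, labels, pool = self.build()
        n_labeled = len(labels.labels)
        aug = inf.augment_training(table, labels, pool, proportion=0.33, seed=0)
        assert aug.audit["n_injected"] == int(np.floor(0.33 * n_labeled))
        assert len(aug.features) == aug.audit["n_injected"]

    def test_injection_arithmetic_300_labeled_at_033_gives_99(self):
        labels = make_labels(10, 5)  # 10 complexes of 5 -> 100 positives
        pairs = sorted(labels.labels)[:300]
        sub = labels.restrict(pairs)
        table = feature_table(pairs, np.linspace(0, 1, 300), experiments=("t1",))
        pool = self.build(pool_pairs=400)[2]
        aug = inf.augment_training(table, sub, pool, proportion=0.33, seed=0)
        assert aug.audit["n_injected"] == 99

    def test_scored_output_identical_with_and_without_augmentation(self):
        table, labels, pool = self.build()
        plain = inf.train_score_cv(table, labels, k=2, n_trees=10, seed=1)
        aug = inf.augment_training(table, labels, pool, proportion=0.33, seed=1)
        augmented = inf.train_score_cv(table, labels, k=2, n_trees=10, seed=1, extra_training=aug)
        assert set(plain.pairs) == set(augmented.pairs)
        assert not any(a.startswith("EXT::") for a, _ in augmented.pairs)

    def test_pool_too_small_is_error(self):
        table, labels, pool = self.build(pool_pairs=2)
        with pytest.raises(ConfigError):
            inf.augment_training(table, labels, pool, proportion=0.5, seed=0)

    def test_negative_proportion_is_error(self):
        table, labels, pool = self.build()
        with pytest.raises(ConfigError):
            inf.augment_training(table, labels, pool, proportion=-0.1, seed=0)


class TestTransfer:
    def build_pool(self, n_exps=5, n_pairs=120, seed=0):
        rng = np.random.default_rng(seed)
        pairs = [(f"X{i:04d}", f"Y{i:04d}") for i in range(n_pairs)]
        labels = {p: int(i % 2) for i, p in enumerate(pairs)}
        exps = {}
        for e in range(n_exps):
            # positives get systematically higher dcor
            base = np.array([0.8 if labels[p] else 0.2 for p in pairs])
            exps[f"ext{e}"] = pd.DataFrame(
                {"dcor": np.clip(base + rng.normal(0, 0.1, n_pairs), 0, 1)},
                index=pair_index(pairs),
            )
        return inf.ExternalFeaturePool(experiments=exps, labels=labels)

    def test_training_vector_width_matches_replicates(self):
        pool = self.build_pool()
        model = inf.transfer_train(pool, target_replicate_count=2, n_trees=10, seed=0)
        assert model.model.n_features_in_ == 2  # 2 replicates x 1 measure
        assert model.n_replicates == 2

    def test_random_scores_auroc_near_half(self):
        """Transfer AUROC under random scores stays within 3 sigma of the
        Mann-Whitney null averaged over 100 seeds."""
        n_pos, n_neg = 40, 60
        null_sd = np.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))
        aurocs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            scores = rng.uniform(0, 1, n_pos + n_neg)
            labels = np.array([1] * n_pos + [0] * n_neg)
            aurocs.append(inf.roc_auc(scores, labels))
        assert abs(np.mean(aurocs) - 0.5) < 3 * null_sd / np.sqrt(100)

    def test_fewer_experiments_than_replicates_warns_and_samples(self):
        pool = self.build_pool(n_exps=2)
        model = inf.transfer_train(pool, target_replicate_count=4, n_trees=5, seed=0)
        assert model.audit["with_replacement"]

    def test_scoring_requires_matching_replicate_count(self):
        pool = self.build_pool()
        model = inf.transfer_train(pool, target_replicate_count=3, n_trees=5, seed=0)
        table = feature_table([("A", "B")], [0.5], experiments=("t1", "t2"))
        with pytest.raises(ConfigError):
            inf.transfer_score(model, table)
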