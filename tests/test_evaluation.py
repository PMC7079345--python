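import itertools
import math

import numpy as np
import pytest

from dtilearn.evaluation import (
    ConfusionCounts,
    InteractionDataset,
    MetricsReport,
    SamplingError,
    balanced_negative_sampling,
    compute_auc,
    compute_metrics,
    confusion_from_scores,
    cross_validate,
    evaluate_predictions,
    read_pairs_tsv,
    split_dataset,
    write_pairs_tsv,
)


def small_network(n_drugs=5, n_targets=4, positives=((0, 0), (1, 2), (3, 3))):
    drugs = [f"d{i}" for i in range(n_drugs)]
    targets = [f"t{i}" for i in range(n_targets)]
    pos = [(drugs[a], targets[b]) for a, b in positives]
    return InteractionDataset(drugs, targets, pos)


class TestNegativeSampling:
    def test_nuclear_receptor_scale(self):
        rng = np.random.default_rng(0)
        drugs = [f"d{i}" for i in range(54)]
        targets = [f"t{i}" for i in range(26)]
        all_pairs = list(itertools.product(drugs, targets))
        pos = [all_pairs[i] for i in rng.choice(len(all_pairs), 90, replace=False)]
        ds = balanced_negative_sampling(
            InteractionDataset(drugs, targets, pos), seed=1
        )
        assert len(ds.negatives) == 90
        assert not set(ds.negatives) & set(ds.positives)

    def test_fully_connected_network_fails(self):
        drugs, targets = ["d0", "d1"], ["t0"]
        pos = [("d0", "t0"), ("d1", "t0")]
        with pytest.raises(SamplingError):
            balanced_negative_sampling(InteractionDataset(drugs, targets, pos))

    def test_seed_reproducibility(self):
        ds = small_network()
        n1 = balanced_negative_sampling(ds, seed=9).negatives
        n2 = balanced_negative_sampling(ds, seed=9).negatives
        assert n1 == n2

    def test_never_returns_positive_exhaustive(self):
        # every seed on a small network: negatives disjoint from positives
        ds = small_network()
        for seed in range(25):
            out = balanced_negative_sampling(ds, seed=seed)
            assert not set(out.negatives) & set(out.positives)
            assert len(out.negatives) == len(out.positives)


class TestSplit:
    def test_stated_fractions_at_100(self):
        sp = split_dataset(100, seed=0)
        assert sp.test_idx.size == 10
        assert sp.train_idx.size == 72
        assert sp.val_idx.size == 18

    @pytest.mark.parametrize("n", [10, 37, 100, 1234, 10000])
    def test_partition_property(self, n):
        sp = split_dataset(n, seed=3)
        allv = np.concatenate([sp.train_idx, sp.val_idx, sp.test_idx])
        assert sorted(allv.tolist()) == list(range(n))
        # proportions within rounding of 0.72 / 0.18 / 0.10
        assert abs(sp.test_idx.size - 0.10 * n) <= 1
        assert abs(sp.train_idx.size - 0.72 * n) <= 2
        assert abs(sp.val_idx.size - 0.18 * n) <= 2

    def test_stratification_balanced_labels(self):
        labels = np.array([0, 1] * 25)
        sp = split_dataset(50, seed=1, labels=labels)
        for part in (sp.train_idx, sp.val_idx, sp.test_idx):
            frac = labels[part].mean()
            assert abs(frac - 0.5) <= 1.0 / part.size

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            split_dataset(9)


class TestMetrics:
    def test_perfect_classifier(self):
        r = compute_metrics(ConfusionCounts(TP=5, FP=0, TN=5, FN=0))
        assert (r.ACC, r.TPR, r.SPC, r.PPV, r.MCC) == (1, 1, 1, 1, 1)

    def test_hand_worked_confusion(self):
        r = compute_metrics(ConfusionCounts(TP=3, FN=1, TN=2, FP=2))
        assert r.ACC == pytest.approx(0.625)
        assert r.TPR == pytest.approx(0.75)
        assert r.SPC == pytest.approx(0.5)
        assert r.PPV == pytest.approx(0.6)
        assert r.MCC == pytest.approx(4 / math.sqrt(240))

    def test_inverted_classifier_mcc_minus_one(self):
        r = compute_metrics(ConfusionCounts(TP=0, FP=4, TN=0, FN=4))
        assert r.MCC == pytest.approx(-1.0)

    def test_mcc_symmetric_under_class_swap(self):
        a = compute_metrics(ConfusionCounts(TP=7, FP=2, TN=5, FN=3)).MCC
        b = compute_metrics(ConfusionCounts(TP=5, FP=3, TN=7, FN=2)).MCC
        assert a == pytest.approx(b)

    def test_zero_denominator_reports_undefined(self):
        r = compute_metrics(ConfusionCounts(TP=0, FP=0, TN=4, FN=4))
        assert math.isnan(r.PPV)
        assert not math.isnan(r.ACC)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_confusion_from_scores_threshold(self):
        c = confusion_from_scores([1, 0, 1, 0], [0.9, 0.2, 0.4, 0.6], threshold=0.5)
        assert (c.TP, c.FP, c.TN, c.FN) == (1, 1, 1, 1)


class TestAUC:
    def test_perfect_separation(self):
        assert compute_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_all_ties_half(self):
        assert compute_auc([1, 0, 1, 0], [0.5] * 4) == 0.5

    def test_hand_worked_three_quarters(self):
        assert compute_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == pytest.approx(0.75)

    def test_complement_identity(self, rng):
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        scores = rng.uniform(size=50)  # tie-free almost surely
        assert compute_auc(labels, scores) + compute_auc(labels, -scores) == pytest.approx(1.0)

    def test_matches_pair_enumeration(self, rng):
        labels = np.array([1] * 8 + [0] * 12)
        scores = rng.uniform(size=20)
        conc = sum(
            1.0 if sp > sn else 0.5 if sp == sn else 0.0
            for sp in scores[labels == 1]
            for sn in scores[labels == 0]
        )
        assert compute_auc(labels, scores) == pytest.approx(conc / (8 * 12))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([1, 1], [0.5, 0.6])


class _ConstantModel:
    """Scores equal to the first feature; no fitting needed."""

    def fit(self, X, y):
        return self

    def predict_score(self, X):
        return 1 / (1 + np.exp(-np.asarray(X)[:, 0]))


class TestCrossValidate:
    def test_fold_balance(self, rng):
        X = rng.normal(size=(100, 3))
        y = np.array([0, 1] * 50)
        X[:, 0] = 3.0 * (2 * y - 1) + 0.1 * rng.normal(size=100)
        reports, mean = cross_validate(_ConstantModel, X, y, k=5, seed=0)
        assert len(reports) == 5
        for f in ("ACC", "TPR", "SPC", "PPV", "MCC", "AUC"):
            assert getattr(mean, f) == pytest.approx(
                np.mean([getattr(r, f) for r in reports])
            )

    def test_same_seed_same_folds(self, rng):
        X = rng.normal(size=(60, 2))
        y = np.array([0, 1] * 30)
        r1, m1 = cross_validate(_ConstantModel, X, y, k=3, seed=4)
        r2, m2 = cross_validate(_ConstantModel, X, y, k=3, seed=4)
        assert [r.as_dict() for r in r1] == [r.as_dict() for r in r2]

    def test_too_few_minority_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            cross_validate(_ConstantModel, X, y, k=5, seed=0)


def test_pairs_tsv_roundtrip(tmp_path):
    ds = balanced_negative_sampling(small_network(), seed=0)
    path = tmp_path / "pairs.tsv"
    write_pairs_tsv(ds, path)
    pairs, labels = read_pairs_tsv(path)
    assert len(pairs) == 6
    assert labels.sum() == 3
    assert pairs[: 3] == ds.positives


def test_dataset_invariants():
    with pytest.raises(ValueError, match="overlap"):
        InteractionDataset(["d0"], ["t0", "t1"], [("d0", "t0")], [("d0", "t0")])
    with pytest.raises(ValueError, match="unknown"):
        InteractionDataset(["d0"], ["t0"], [("d1", "t0")])
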