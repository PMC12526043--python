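"""Feature extraction, training sets, information gain, CV, and prediction."""

import itertools

import numpy as np
import pytest

from cpdfingerprint import pipeline
from cpdfingerprint.classify import (
    FeatureSchema,
    TrainingSet,
    build_training_set,
    cross_validate,
    extract_features,
    gcr1_schema,
    hap235_schema,
    information_gain,
    load_model,
    predict_genome,
    rank_attributes_information_gain,
    save_model,
    train,
)
from cpdfingerprint.fingerprint import build_induction_track
from cpdfingerprint.genome_io import (
    GenomeSequence,
    GenomicInterval,
    MotifOccurrence,
    reverse_complement,
    scan_motif,
)
from cpdfingerprint.lesion_map import LesionTrack, NormalizedPair


def zero_track():
    return build_induction_track(
        NormalizedPair(LesionTrack(), LesionTrack(), 1.0), floor=10
    )


class TestFeatureSchema:
    def test_default_schemas_have_expected_widths(self):
        assert hap235_schema().n_attributes == 10
        assert hap235_schema().offsets == (-1.5, 0.5, 2.5, 3.5, 4.5)
        assert gcr1_schema().n_attributes == 8
        assert gcr1_schema().offsets == (-1.5, -0.5, 0.5, 1.5)

    def test_vector_is_channel_major(self):
        genome = GenomeSequence({"c": "A" * 60})
        site = MotifOccurrence("c", "+", 28, 30, "CCAAT")
        ind = {("c", "+", 30.5): 7.0}
        logr = {("c", "+", 30.5): 1.5}
        from cpdfingerprint.fingerprint import InductionTrack

        track = InductionTrack(ind, logr)
        schema = FeatureSchema("CCAAT", (-1.5, 0.5))
        vec = extract_features(track, genome, site, schema)
        assert vec.tolist() == [0.0, 7.0, 0.0, 1.5]

    def test_zero_track_gives_zero_vector(self):
        genome = GenomeSequence({"c": "A" * 60})
        site = MotifOccurrence("c", "+", 28, 30, "CCAAT")
        vec = extract_features(zero_track(), genome, site, hap235_schema())
        assert vec.tolist() == [0.0] * 10

    def test_mirror_twin_yields_identical_vector(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=80))
        L = len(seq)
        genome = GenomeSequence({"c": seq})
        mirror = GenomeSequence({"c": reverse_complement(seq)})
        from cpdfingerprint.fingerprint import InductionTrack

        keys = [("c", "+", 30.5), ("c", "-", 27.5), ("c", "+", 35.5)]
        ind = {k: float(i + 1) for i, k in enumerate(keys)}
        m_ind = {
            ("c", "-" if s == "+" else "+", L - 1 - h): v
            for (c, s, h), v in ind.items()
        }
        site = MotifOccurrence("c", "+", 28, 30, "CCAAT")
        twin = MotifOccurrence("c", "-", L - 33, L - 1 - 30, "CCAAT")
        v1 = extract_features(InductionTrack(ind, dict(ind)), genome, site, hap235_schema())
        v2 = extract_features(InductionTrack(m_ind, dict(m_ind)), mirror, twin, hap235_schema())
        assert v1.tolist() == v2.tolist()

    def test_edge_site_raises(self):
        genome = GenomeSequence({"c": "A" * 10})
        site = MotifOccurrence("c", "+", 0, 1, "CCAAT")
        with pytest.raises(ValueError, match="edge"):
            extract_features(zero_track(), genome, site, hap235_schema())


class TestBuildTrainingSet:
    def _toy(self):
        rng = np.random.default_rng(9)
        seq = list(rng.choice(list("ACGT"), size=3000))
        # one ORF [500, 2500); qualifying motifs well inside the margin
        for s in (700, 900, 1100, 1300, 1500):
            seq[s:s + 5] = "CCAAT"
        seq[599:604] = "CCAAT"   # 99 bp from ORF start: excluded by margin
        seq[100:105] = "CCAAT"   # intergenic positive
        genome = GenomeSequence({"c": "".join(seq)})
        orfs = [GenomicInterval("c", 500, 2500, "+", "orf1")]
        positives = [MotifOccurrence("c", "+", 100, 102, "CCAAT")]
        return genome, orfs, positives

    def test_seeded_sampling_is_reproducible(self):
        genome, orfs, positives = self._toy()
        kwargs = dict(
            positives=positives, orfs=orfs, genome=genome, pattern="CCAAT",
            track=zero_track(), schema=hap235_schema(),
            n_negatives=3, margin=100, anchor_index=2,
        )
        a = build_training_set(seed=4, **kwargs)
        b = build_training_set(seed=4, **kwargs)
        assert a.site_ids == b.site_ids
        assert a.n_positive == 1 and a.n_negative == 3

    def test_margin_rule_excludes_near_boundary_motif(self):
        genome, orfs, positives = self._toy()
        ts = build_training_set(
            positives, orfs, genome, "CCAAT", zero_track(), hap235_schema(),
            n_negatives=5, margin=100, seed=0, anchor_index=2,
        )
        assert "c:601:+" not in ts.site_ids  # anchor of the 99-bp motif

    def test_positive_never_sampled_as_negative(self):
        genome, orfs, _ = self._toy()
        # declare an intragenic motif as positive; it must not reappear
        positives = [MotifOccurrence("c", "+", 700, 702, "CCAAT")]
        ts = build_training_set(
            positives, orfs, genome, "CCAAT", zero_track(), hap235_schema(),
            n_negatives=4, margin=100, seed=1, anchor_index=2,
        )
        assert ts.site_ids.count("c:702:+") == 1

    def test_insufficient_negatives_errors(self):
        genome, orfs, positives = self._toy()
        with pytest.raises(ValueError, match="qualifying"):
            build_training_set(
                positives, orfs, genome, "CCAAT", zero_track(), hap235_schema(),
                n_negatives=50, margin=100, seed=0, anchor_index=2,
            )


def brute_force_best_split_gain(values, y):
    """Oracle: exhaustive single-cut-point enumeration, no MDL recursion."""
    def H(labels):
        _, c = np.unique(labels, return_counts=True)
        p = c / len(labels)
        return -np.sum(p * np.log2(p))

    order = np.argsort(values, kind="stable")
    v, yy = np.asarray(values, float)[order], np.asarray(y)[order]
    n = len(v)
    best = 0.0
    for i in range(1, n):
        if v[i] == v[i - 1]:
            continue
        gain = H(yy) - (i * H(yy[:i]) + (n - i) * H(yy[i:])) / n
        best = max(best, gain)
    return best


class TestInformationGain:
    def test_constant_attribute_has_zero_gain(self):
        assert information_gain(np.ones(10), np.array([0] * 5 + [1] * 5)) == 0.0

    def test_perfect_balanced_separator_gains_one_bit(self):
        values = np.array([0, 1, 2, 3, 4, 5, 10, 11, 12, 13, 14, 15], float)
        y = np.array([0] * 6 + [1] * 6)
        assert information_gain(values, y) == pytest.approx(1.0)

    def test_gain_matches_split_enumeration_on_toy_set(self):
        # separable 6-instance set: one MDL-accepted cut, pure halves
        values = np.array([1.0, 2.0, 3.0, 7.0, 8.0, 9.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        assert information_gain(values, y) == pytest.approx(
            brute_force_best_split_gain(values, y)
        )

    def test_ranking_requires_both_classes_and_orders_descending(self):
        X = np.column_stack([
            np.array([0, 0, 0, 1, 1, 1, 0, 1], float),   # weak
            np.array([1, 2, 3, 4, 10, 11, 12, 13], float),  # uninformative order
            np.array([0, 0, 0, 0, 5, 5, 5, 5], float),   # perfect
            np.ones(8),                                   # constant
        ])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        schema = FeatureSchema("CCAAT", (-1.5, 0.5), ("induction", "log2_floored"))
        ts = TrainingSet(schema, X, y, [f"s{i}" for i in range(8)])
        ranked = rank_attributes_information_gain(ts)
        gains = [g for _, g in ranked]
        assert gains == sorted(gains, reverse=True)
        assert ranked[0][1] == pytest.approx(1.0)
        assert ranked[-1][1] == 0.0
        bad = TrainingSet(schema, X, np.zeros(8, dtype=int), [f"s{i}" for i in range(8)])
        with pytest.raises(ValueError):
            rank_attributes_information_gain(bad)


def pairwise_auc_oracle(y, scores):
    """Mann-Whitney oracle: fraction of correctly ordered (pos, neg) pairs."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


def separable_training_set(n=40, n_features=4, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0, 1, size=(n // 2, n_features))
    X1 = rng.normal(8, 1, size=(n // 2, n_features))
    X = np.vstack([X0, X1])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    schema = FeatureSchema("CCAAT", (-1.5, 0.5))
    return TrainingSet(schema, X, y, [f"s{i}" for i in range(n)])


class TestTrainAndCV:
    @pytest.mark.parametrize(
        "algorithm", ["random_forest", "multilayer_perceptron", "logistic", "naive_bayes"]
    )
    def test_separable_data_fits_perfectly(self, algorithm):
        ts = separable_training_set()
        model = train(ts, algorithm, seed=0)
        proba = model.predict_proba(ts.X)
        assert np.all((proba >= 0.5) == (ts.y == 1))

    def test_same_seed_reproduces_model_predictions(self):
        ts = separable_training_set(seed=3)
        p1 = train(ts, "random_forest", seed=7).predict_proba(ts.X)
        p2 = train(ts, "random_forest", seed=7).predict_proba(ts.X)
        assert np.array_equal(p1, p2)

    def test_label_permutation_yields_chance_auc(self):
        """Permutation null: CV AUC centers on 0.5 over repetitions."""
        rng = np.random.default_rng(42)
        aucs = []
        for rep in range(50):
            ts = separable_training_set(n=24, seed=rep)
            y_perm = rng.permutation(ts.y)
            if y_perm.sum() in (0, len(y_perm)):
                continue
            ts_perm = TrainingSet(ts.schema, ts.X, y_perm, ts.site_ids)
            aucs.append(cross_validate(ts_perm, "naive_bayes", k=2, seed=rep).auc)
        mean = np.mean(aucs)
        se = np.std(aucs) / np.sqrt(len(aucs))
        assert abs(mean - 0.5) < 4 * se + 0.02

    def test_cv_auc_matches_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        n = 60
        X = rng.normal(size=(n, 4))
        y = (X[:, 0] + rng.normal(0, 1.5, n) > 0).astype(int)
        X[:, 0] += y  # some signal
        ts = TrainingSet(FeatureSchema("CCAAT", (-1.5, 0.5)), X, y,
                         [f"s{i}" for i in range(n)])
        report = cross_validate(ts, "logistic", k=5, seed=0)
        assert report.auc == pytest.approx(
            pairwise_auc_oracle(ts.y, report.oof_probabilities)
        )

    def test_k_exceeding_minority_count_errors(self):
        ts = separable_training_set(n=8)
        with pytest.raises(ValueError, match="minority"):
            cross_validate(ts, "logistic", k=5, seed=0)

    def test_confusion_sums_and_roc_monotone(self):
        ts = separable_training_set(n=30, seed=1)
        report = cross_validate(ts, "random_forest", k=3, seed=1)
        assert report.confusion.sum() == len(ts.y)
        fpr = [p[0] for p in report.roc_points]
        tpr = [p[1] for p in report.roc_points]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)


class TestPredictGenome:
    def test_training_positives_recovered_and_threshold_edge(self, default_truth,
                                                             default_induction,
                                                             default_training_set):
        model = train(default_training_set, "random_forest", seed=0)
        candidates = default_truth.bound_sites
        preds = predict_genome(
            model, candidates, default_induction, default_truth.genome
        )
        assert len(preds.bound_sites) == len(candidates)
        none = predict_genome(
            model, candidates, default_induction, default_truth.genome, threshold=1.01
        )
        assert none.bound_sites == []

    def test_calls_sorted_by_probability(self, default_truth, default_induction,
                                         default_training_set):
        model = train(default_training_set, "random_forest", seed=0)
        sites = default_truth.bound_sites[:5] + default_truth.decoy_sites[:20]
        preds = predict_genome(model, sites, default_induction, default_truth.genome)
        probs = [p for _, p, _ in preds.calls]
        assert probs == sorted(probs, reverse=True)

    def test_duplicated_negatives_leave_bound_set_unchanged(self, default_truth,
                                                            default_induction,
                                                            default_training_set):
        """Class-prior robustness: doubling the negatives doesn't flip calls."""
        ts = default_training_set
        neg = ts.y == 0
        X2 = np.vstack([ts.X, ts.X[neg]])
        y2 = np.concatenate([ts.y, ts.y[neg]])
        ids2 = ts.site_ids + [f"{i}_dup" for i in np.flatnonzero(neg)]
        ts2 = TrainingSet(ts.schema, X2, y2, ids2)
        sites = default_truth.bound_sites + default_truth.decoy_sites[:500]
        m1 = train(ts, "random_forest", seed=0)
        m2 = train(ts2, "random_forest", seed=0)
        b1 = {s.site_id for s in predict_genome(m1, sites, default_induction,
                                                default_truth.genome).bound_sites}
        b2 = {s.site_id for s in predict_genome(m2, sites, default_induction,
                                                default_truth.genome).bound_sites}
        assert b1 == b2

    def test_model_round_trip_serialization(self, tmp_path):
        ts = separable_training_set()
        model = train(ts, "logistic", seed=0)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        assert np.array_equal(loaded.predict_proba(ts.X), model.predict_proba(ts.X))
        assert loaded.schema == model.schema
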