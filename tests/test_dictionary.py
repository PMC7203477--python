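"""Dictionary decoding rule and the two evaluation protocols."""

import numpy as np
import pytest

from ptcdecode.comparators import ConstantComparator, FunctionComparator, RandomComparator
from ptcdecode.dictionary import (
    Dictionary,
    DictionaryConfigurationError,
    build_dictionary,
    classify_with_dictionary,
    evaluate_multiclass,
    evaluate_same_different,
    evaluate_scheme,
    pairwise_same_probabilities,
)
from ptcdecode.pairing import CapacityError, build_test_pairs
from .conftest import make_dataset

LABELS = ("face", "scene", "word")


def class_marker_dataset(**kwargs):
    """Dataset whose signals encode their class index in element [0, 0]."""
    ds = make_dataset(labels=LABELS, **kwargs)
    ds.data[:, 0, 0] = [LABELS.index(c) for c in ds.metadata["class_label"]]
    return ds


def oracle_comparator():
    """P(same)=1 iff the two signals carry the same class marker."""
    return FunctionComparator(
        lambda batch: (batch[:, 0, 0, 0] == batch[:, 1, 0, 0]).astype(float)
    )


def brute_force_decision(comparator, query, dictionary):
    """Independent double loop over (class, entry); argmax with low-index ties."""
    best_label, best_score = None, -np.inf
    scores = {}
    for label in dictionary.label_set:
        entries = dictionary.class_entries(label)
        total = 0.0
        for entry in entries:
            pair = np.stack([query, entry])[None]
            total += float(comparator.predict_pair_proba(pair)[0, 0])
        scores[label] = total / len(entries)
        if scores[label] > best_score:
            best_label, best_score = label, scores[label]
    return scores, best_label


class TestBuildDictionary:
    def test_hundred_singles_per_class(self):
        pool = make_dataset(n_subjects=3, trials_per_class=40, labels=LABELS)
        d = build_dictionary(pool, n_per_class=100, entry_kind="single",
                             rng=np.random.default_rng(0))
        assert len(d.signals) == 300
        assert d.n_per_class == {lab: 100 for lab in LABELS}

    def test_single_entry_is_verbatim_trial(self):
        pool = make_dataset(n_subjects=1, trials_per_class=3)
        d = build_dictionary(pool, n_per_class=1, entry_kind="single",
                             rng=np.random.default_rng(1))
        for sig, src in zip(d.signals, d.sources):
            ((subj, tid),) = src
            idx = pool.metadata.query(
                "subject_id == @subj and trial_id == @tid"
            ).index[0]
            np.testing.assert_array_equal(sig, pool.data[idx])

    def test_averaged_entries_have_twenty_sources(self):
        pool = make_dataset(n_subjects=3, trials_per_class=25)
        d = build_dictionary(pool, n_per_class=4, entry_kind="average", k=20,
                             rng=np.random.default_rng(2))
        for src in d.sources:
            assert len(src) == 20

    def test_capacity_error_names_class(self):
        pool = make_dataset(n_subjects=1, trials_per_class=3)
        with pytest.raises(CapacityError, match="face"):
            build_dictionary(pool, n_per_class=10, entry_kind="single")


class TestClassifyWithDictionary:
    @pytest.fixture
    def pool(self):
        return class_marker_dataset(n_subjects=3, trials_per_class=10)

    def test_oracle_stub_always_correct(self, pool):
        d = build_dictionary(pool, n_per_class=6, rng=np.random.default_rng(3))
        comp = oracle_comparator()
        for i in range(0, pool.n_trials, 7):
            dec = classify_with_dictionary(comp, pool.data[i], d)
            assert dec.predicted_class == pool.metadata["class_label"][i]

    def test_matches_brute_force_exactly(self, pool):
        """The rule is exact: no approximation relative to a double loop."""
        rng = np.random.default_rng(4)
        for dict_seed in range(3):
            d = build_dictionary(pool, n_per_class=5,
                                 rng=np.random.default_rng(100 + dict_seed))
            comp = FunctionComparator(
                lambda batch: 1 / (1 + np.exp(-batch[:, 0].mean(axis=(1, 2))
                                              * batch[:, 1].mean(axis=(1, 2))))
            )
            for _ in range(50):
                q = pool.data[rng.integers(pool.n_trials)]
                dec = classify_with_dictionary(comp, q, d)
                bf_scores, bf_label = brute_force_decision(comp, q, d)
                assert dec.predicted_class == bf_label
                for lab in LABELS:
                    assert dec.scores[lab] == pytest.approx(bf_scores[lab], abs=1e-12)

    def test_uninformative_stub_near_chance(self, pool):
        d = build_dictionary(pool, n_per_class=8, rng=np.random.default_rng(5))
        comp = RandomComparator(6)
        correct = []
        for _ in range(34):  # balanced queries: every trial once, ~3000 pairs total
            for i in range(pool.n_trials):
                dec = classify_with_dictionary(comp, pool.data[i], d)
                correct.append(dec.predicted_class == pool.metadata["class_label"][i])
            if len(correct) >= 3000:
                break
        acc = np.mean(correct)
        se = np.sqrt((1 / 3) * (2 / 3) / len(correct))
        assert abs(acc - 1 / 3) < 3 * se

    def test_tie_breaks_to_lowest_class_index(self, pool):
        d = build_dictionary(pool, n_per_class=4, rng=np.random.default_rng(7))
        dec = classify_with_dictionary(ConstantComparator(0.5), pool.data[0], d)
        assert dec.predicted_class == d.label_set[0]

    def test_empty_class_rejected(self, pool):
        d = build_dictionary(pool, n_per_class=4, rng=np.random.default_rng(8))
        empty = Dictionary(
            signals=d.signals[d.classes != "word"],
            classes=d.classes[d.classes != "word"],
            sources=[s for s, c in zip(d.sources, d.classes) if c != "word"],
            label_set=d.label_set, entry_kind="single", k=1,
        )
        with pytest.raises(DictionaryConfigurationError):
            classify_with_dictionary(ConstantComparator(1.0), pool.data[0], empty)

    def test_query_shape_mismatch_rejected(self, pool):
        d = build_dictionary(pool, n_per_class=4, rng=np.random.default_rng(9))
        with pytest.raises(ValueError, match="shape"):
            classify_with_dictionary(ConstantComparator(1.0), pool.data[0][:, :3], d)


class TestEvaluateSameDifferent:
    def make_pairs(self, seed=0):
        test = class_marker_dataset(n_subjects=1, trials_per_class=10, seed=seed)
        known = class_marker_dataset(n_subjects=2, trials_per_class=12, seed=seed + 1)
        return build_test_pairs(test, known, "single_single", n_known_per_class=10,
                                rng=np.random.default_rng(seed))

    def test_perfect_comparator_identity_confusion(self):
        pairs = self.make_pairs()
        res = evaluate_same_different(oracle_comparator(), pairs)
        assert res.accuracy == pytest.approx(100.0)
        np.testing.assert_allclose(res.confusion, [[100, 0], [0, 100]])

    def test_uninformative_stub_near_fifty(self):
        pairs = self.make_pairs(seed=2)
        res = evaluate_same_different(RandomComparator(3), pairs)
        se = 50 / np.sqrt(pairs.n_pairs / 2)
        assert abs(res.accuracy - 50.0) < 3 * se

    def test_rows_sum_to_hundred(self):
        pairs = self.make_pairs(seed=4)
        res = evaluate_same_different(RandomComparator(5), pairs)
        np.testing.assert_allclose(res.confusion.sum(axis=1), [100, 100], atol=0.01)

    def test_empty_set_rejected(self):
        test = make_dataset(n_subjects=1, trials_per_class=2).select(
            np.array([], dtype=int)
        )
        known = make_dataset(n_subjects=2, trials_per_class=8)
        pairs = build_test_pairs(test, known, "single_single", n_known_per_class=4)
        with pytest.raises(ValueError, match="empty"):
            evaluate_same_different(RandomComparator(0), pairs)


class TestEvaluateMulticlass:
    def test_oracle_stub_diagonal_confusion(self):
        test = class_marker_dataset(n_subjects=1, trials_per_class=8, seed=1)
        known = class_marker_dataset(n_subjects=2, trials_per_class=12, seed=2)
        d = build_dictionary(known, n_per_class=6, rng=np.random.default_rng(0))
        res = evaluate_multiclass(oracle_comparator(), test, d)
        assert res.accuracy == pytest.approx(100.0)
        np.testing.assert_allclose(res.confusion, np.eye(3))

    def test_uninformative_stub_near_third(self):
        test = class_marker_dataset(n_subjects=1, trials_per_class=40, seed=3)
        known = class_marker_dataset(n_subjects=2, trials_per_class=45, seed=4)
        d = build_dictionary(known, n_per_class=30, rng=np.random.default_rng(1))
        res = evaluate_multiclass(RandomComparator(2), test, d)
        se = 100 * np.sqrt((1 / 3) * (2 / 3) / res.n_queries)
        assert abs(res.accuracy - 100 / 3) < 3 * se

    def test_confusion_rows_sum_to_one(self):
        test = class_marker_dataset(n_subjects=1, trials_per_class=6, seed=5)
        known = class_marker_dataset(n_subjects=2, trials_per_class=10, seed=6)
        d = build_dictionary(known, n_per_class=5, rng=np.random.default_rng(2))
        res = evaluate_multiclass(RandomComparator(7), test, d)
        np.testing.assert_allclose(res.confusion.sum(axis=1), 1.0, atol=1e-9)

    def test_average_scheme_queries_built_from_test_pool(self):
        test = class_marker_dataset(n_subjects=1, trials_per_class=30, seed=7)
        known = class_marker_dataset(n_subjects=2, trials_per_class=30, seed=8)
        d = build_dictionary(known, n_per_class=5, entry_kind="average", k=10,
                             rng=np.random.default_rng(3))
        res = evaluate_multiclass(
            oracle_comparator(), test, d, scheme="average_average",
            n_test_averages_per_class=12, average_k=10,
            rng=np.random.default_rng(4),
        )
        assert res.n_queries == 36
        assert res.accuracy == pytest.approx(100.0)

    def test_insufficient_trials_for_averaging_rejected(self):
        test = make_dataset(n_subjects=1, trials_per_class=5)
        known = make_dataset(n_subjects=2, trials_per_class=30)
        d = build_dictionary(known, n_per_class=5, rng=np.random.default_rng(5))
        with pytest.raises(CapacityError):
            evaluate_multiclass(
                RandomComparator(0), test, d, scheme="average_average", average_k=20
            )


class TestEvaluateScheme:
    def test_consistent_with_separate_protocols(self):
        """One shared P(same) matrix reproduces both separately computed metrics."""
        test = class_marker_dataset(n_subjects=1, trials_per_class=6, seed=9)
        known = class_marker_dataset(n_subjects=2, trials_per_class=10, seed=10)
        pairs = build_test_pairs(test, known, "single_single", n_known_per_class=5,
                                 rng=np.random.default_rng(6))
        comp = oracle_comparator()
        sd, mc = evaluate_scheme(comp, pairs, LABELS)
        sd_alone = evaluate_same_different(comp, pairs)
        assert sd.accuracy == pytest.approx(sd_alone.accuracy)
        assert mc.accuracy == pytest.approx(100.0)

    def test_matrix_matches_per_pair_calls(self):
        test = class_marker_dataset(n_subjects=1, trials_per_class=3, seed=11)
        known = class_marker_dataset(n_subjects=2, trials_per_class=5, seed=12)
        comp = FunctionComparator(
            lambda b: 1 / (1 + np.exp(-(b[:, 0] - b[:, 1]).mean(axis=(1, 2))))
        )
        mat = pairwise_same_probabilities(comp, test.data, known.data, batch_size=7)
        for qi in (0, 4, 8):
            for mi in (0, 3, 11):
                pair = np.stack([test.data[qi], known.data[mi]])[None]
                assert mat[qi, mi] == pytest.approx(
                    float(comp.predict_pair_proba(pair)[0, 0])
                )


class TestSerialization:
    def test_pair_set_round_trip(self, tmp_path):
        from ptcdecode.io import load_pair_set, save_pair_set

        test = class_marker_dataset(n_subjects=1, trials_per_class=4, seed=20)
        known = class_marker_dataset(n_subjects=2, trials_per_class=8, seed=21)
        pairs = build_test_pairs(test, known, "single_average", n_known_per_class=3,
                                 average_k=4, rng=np.random.default_rng(0))
        path = tmp_path / "pairs.h5"
        save_pair_set(pairs, path)
        back = load_pair_set(path)
        np.testing.assert_array_equal(back.queries, pairs.queries)
        np.testing.assert_array_equal(back.knowns, pairs.knowns)
        assert list(back.known_classes) == list(pairs.known_classes)
        assert back.known_sources == pairs.known_sources
        assert back.scheme == pairs.scheme

    def test_dictionary_round_trip(self, tmp_path):
        from ptcdecode.io import load_dictionary, save_dictionary

        pool = class_marker_dataset(n_subjects=2, trials_per_class=10, seed=22)
        d = build_dictionary(pool, n_per_class=4, entry_kind="average", k=5,
                             rng=np.random.default_rng(1), source_pool_id="known")
        path = tmp_path / "dict.h5"
        save_dictionary(d, path)
        back = load_dictionary(path)
        np.testing.assert_array_equal(back.signals, d.signals)
        assert back.sources == d.sources
        assert back.label_set == d.label_set and back.k == 5
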