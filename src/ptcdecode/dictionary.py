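"""Dictionary decoding: from pairwise same/different to multiclass.

An unknown signal is compared (via a trained pair comparator) against a
*dictionary* of known-class entries — raw trials or k-trial averages
drawn from the training/validation pools.  Each comparison yields a
softmaxed P(same); the per-class score is the mean P(same) over that
class's entries, and the predicted class is the argmax (ties broken by
the lowest class index, deterministically).

This module also hosts the two evaluation protocols: same/different
accuracy with its 2×2 confusion matrix, and dictionary (multiclass)
accuracy with its K×K confusion matrix.  Both are computed from the same
query × known P(same) matrix, so a single pass over the comparator
serves both metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import EpochDataset
from .pairing import (
    CapacityError,
    TestPairSet,
    _PoolIndex,
    make_trial_average,
)


class DictionaryConfigurationError(ValueError):
    """Raised for unusable dictionaries (e.g. an empty class)."""


@dataclass
class Dictionary:
    """Per-class corpus of known signals with provenance.

    ``signals`` is ``(n_classes * n_per_class, channels, bins)`` stacked
    in label order; ``classes`` names each entry's class; ``sources``
    holds each entry's contributing (subject_id, trial_id) set.
    """

    signals: np.ndarray
    classes: np.ndarray  # object array of labels, aligned with signals
    sources: list  # frozensets, aligned with signals
    label_set: tuple
    entry_kind: str  # "single" | "average"
    k: int  # trials per averaged entry (1 for singles)
    source_pool_id: str = ""

    @property
    def n_per_class(self) -> dict:
        return {lab: int((self.classes == lab).sum()) for lab in self.label_set}

    def class_entries(self, label) -> np.ndarray:
        return self.signals[self.classes == label]

    def all_sources(self) -> frozenset:
        out = set()
        for s in self.sources:
            out |= s
        return frozenset(out)


@dataclass
class DictionaryDecision:
    """Per-class mean P(same) scores and the argmax decision."""

    scores: dict
    predicted_class: object
    per_comparison: dict | None = None


def build_dictionary(
    known_pool: EpochDataset,
    n_per_class: int = 100,
    entry_kind: str = "single",
    k: int = 20,
    rng: np.random.Generator | None = None,
    source_pool_id: str = "",
) -> Dictionary:
    """Naive (uniform random) dictionary selection from the known pool.

    Singles are drawn without replacement within a class; averaged
    entries are independent k-trial within-class averages drawn across
    subjects.
    """
    if entry_kind not in ("single", "average"):
        raise ValueError(f"unknown entry_kind {entry_kind!r}")
    rng = rng or np.random.default_rng()
    index = _PoolIndex(known_pool)
    sigs, classes, sources = [], [], []
    for lab in known_pool.label_set:
        idx = index.by_class[lab]
        if entry_kind == "single":
            if len(idx) < n_per_class:
                raise CapacityError(
                    f"class {lab!r}: need {n_per_class} trials for the dictionary,"
                    f" have {len(idx)}"
                )
            chosen = rng.choice(idx, size=n_per_class, replace=False)
            for i in chosen:
                sigs.append(known_pool.data[i])
                classes.append(lab)
                sources.append(frozenset([index.sources[i]]))
        else:
            for _ in range(n_per_class):
                s, src = make_trial_average(known_pool, lab, k, frozenset(), rng, index)
                sigs.append(s)
                classes.append(lab)
                sources.append(src)
    return Dictionary(
        signals=np.stack(sigs),
        classes=np.asarray(classes, dtype=object),
        sources=sources,
        label_set=known_pool.label_set,
        entry_kind=entry_kind,
        k=1 if entry_kind == "single" else k,
        source_pool_id=source_pool_id,
    )


def pairwise_same_probabilities(
    comparator,
    queries: np.ndarray,
    knowns: np.ndarray,
    batch_size: int = 128,
) -> np.ndarray:
    """P(same) for every (query, known) pair, shape (Q, M).

    Pairs are stacked query-first (slot A = unknown, slot B = known) to
    match the training convention.
    """
    q_n, m_n = len(queries), len(knowns)
    out = np.empty((q_n, m_n))
    total = q_n * m_n
    for start in range(0, total, batch_size):
        idx = np.arange(start, min(start + batch_size, total))
        qi, mi = idx // m_n, idx % m_n
        x = np.stack([queries[qi], knowns[mi]], axis=1)
        out.ravel()[idx] = comparator.predict_pair_proba(x)[:, 0]
    return out


def classify_with_dictionary(
    comparator,
    query: np.ndarray,
    dictionary: Dictionary,
    batch_size: int = 128,
    keep_comparisons: bool = False,
) -> DictionaryDecision:
    """Classify one unknown signal against the dictionary.

    The class score is the mean softmaxed P(same) over that class's
    entries; the decision is the argmax, ties going to the lowest class
    index in label-set order.
    """
    counts = dictionary.n_per_class
    empty = [lab for lab in dictionary.label_set if counts[lab] == 0]
    if empty:
        raise DictionaryConfigurationError(f"dictionary classes without entries: {empty}")
    if query.shape != dictionary.signals.shape[1:]:
        raise ValueError(
            f"query shape {query.shape} does not match dictionary entries"
            f" {dictionary.signals.shape[1:]}"
        )
    p_same = pairwise_same_probabilities(
        comparator, query[None], dictionary.signals, batch_size
    )[0]
    scores = {}
    for lab in dictionary.label_set:
        scores[lab] = float(p_same[dictionary.classes == lab].mean())
    best = max(range(len(dictionary.label_set)),
               key=lambda i: (scores[dictionary.label_set[i]], -i))
    per_comp = None
    if keep_comparisons:
        per_comp = {"p_same": p_same, "classes": dictionary.classes.copy()}
    return DictionaryDecision(scores, dictionary.label_set[best], per_comp)


# ---------------------------------------------------------------------------
# Evaluation protocols
# ---------------------------------------------------------------------------

@dataclass
class SameDifferentResult:
    """Binary protocol outcome: accuracy and row-normalized confusion (%)."""

    accuracy: float  # percent
    confusion: np.ndarray  # 2x2, rows actual (same, different), percent
    n_pairs: int

    @property
    def p_different_given_same(self) -> float:
        return self.confusion[0, 1]

    @property
    def p_same_given_different(self) -> float:
        return self.confusion[1, 0]


@dataclass
class MulticlassResult:
    """Dictionary protocol outcome: accuracy and K×K confusion proportions."""

    accuracy: float  # percent
    confusion: np.ndarray  # rows actual class, proportions summing to 1
    label_set: tuple
    n_queries: int


def _same_different_from_matrix(
    p_same: np.ndarray, same_mask: np.ndarray
) -> SameDifferentResult:
    pred_same = (p_same >= 0.5).ravel()
    actual_same = same_mask.ravel()
    n_same, n_diff = int(actual_same.sum()), int((~actual_same).sum())
    conf = np.zeros((2, 2))
    conf[0, 0] = (pred_same & actual_same).sum()
    conf[0, 1] = (~pred_same & actual_same).sum()
    conf[1, 0] = (pred_same & ~actual_same).sum()
    conf[1, 1] = (~pred_same & ~actual_same).sum()
    row_sums = conf.sum(axis=1, keepdims=True)
    conf_pct = np.divide(conf, row_sums, out=np.zeros_like(conf), where=row_sums > 0) * 100
    if n_same == n_diff:
        acc = float((pred_same == actual_same).mean()) * 100
    else:  # balanced accuracy: mean of the two row accuracies
        acc = float((conf_pct[0, 0] + conf_pct[1, 1]) / 2)
    return SameDifferentResult(acc, conf_pct, len(actual_same))


def evaluate_same_different(comparator, pairs: TestPairSet,
                            batch_size: int = 128) -> SameDifferentResult:
    """Same/different accuracy over an evaluation pair set.

    Each pair is decided by argmax over the comparator's two outputs.
    Confusion rows are normalized to percent; with unequal numbers of
    same and different pairs the accuracy is the balanced mean of the
    two row accuracies (chance 50% either way).
    """
    if pairs.n_pairs == 0:
        raise ValueError("empty evaluation pair set")
    p_same = pairwise_same_probabilities(comparator, pairs.queries, pairs.knowns, batch_size)
    return _same_different_from_matrix(p_same, pairs.pair_labels())


def _multiclass_from_matrix(
    p_same: np.ndarray,
    query_classes: np.ndarray,
    known_classes: np.ndarray,
    label_set: tuple,
) -> MulticlassResult:
    k = len(label_set)
    class_scores = np.stack(
        [p_same[:, known_classes == lab].mean(axis=1) for lab in label_set], axis=1
    )
    # argmax with ties to the lowest class index
    pred_idx = class_scores.argmax(axis=1)
    truth_idx = np.array([label_set.index(c) for c in query_classes])
    conf = np.zeros((k, k))
    for t, p in zip(truth_idx, pred_idx):
        conf[t, p] += 1
    row_sums = conf.sum(axis=1, keepdims=True)
    conf_prop = np.divide(conf, row_sums, out=np.zeros_like(conf), where=row_sums > 0)
    acc = float((pred_idx == truth_idx).mean()) * 100
    return MulticlassResult(acc, conf_prop, label_set, len(truth_idx))


def evaluate_multiclass(
    comparator,
    test_pool: EpochDataset,
    dictionary: Dictionary,
    scheme: str = "single_single",
    n_test_averages_per_class: int = 80,
    average_k: int = 20,
    rng: np.random.Generator | None = None,
    batch_size: int = 128,
) -> MulticlassResult:
    """Multiclass accuracy of the dictionary rule on a held-out subject.

    Queries are the test pool's raw trials for single-query schemes, or
    ``n_test_averages_per_class`` k-trial averages per class built from
    the test pool for ``average_average``.
    """
    if scheme == "average_average":
        rng = rng or np.random.default_rng()
        index = _PoolIndex(test_pool)
        sigs, labs = [], []
        for lab in test_pool.label_set:
            for _ in range(n_test_averages_per_class):
                s, _src = make_trial_average(test_pool, lab, average_k, frozenset(), rng, index)
                sigs.append(s)
                labs.append(lab)
        queries = np.stack(sigs)
        query_classes = np.asarray(labs, dtype=object)
    else:
        queries = test_pool.data
        query_classes = test_pool.metadata["class_label"].to_numpy(dtype=object)
    p_same = pairwise_same_probabilities(comparator, queries, dictionary.signals, batch_size)
    return _multiclass_from_matrix(
        p_same, query_classes, dictionary.classes, dictionary.label_set
    )


def evaluate_scheme(
    comparator, pairs: TestPairSet, label_set: tuple, batch_size: int = 128
) -> tuple[SameDifferentResult, MulticlassResult]:
    """Both protocols from one comparator pass.

    When the evaluation pair set's known side doubles as the dictionary
    (the standard protocol), the same P(same) matrix yields the binary
    metric (per pair) and the multiclass metric (per query row).
    """
    p_same = pairwise_same_probabilities(comparator, pairs.queries, pairs.knowns, batch_size)
    sd = _same_different_from_matrix(p_same, pairs.pair_labels())
    mc = _multiclass_from_matrix(
        p_same, pairs.query_classes, pairs.known_classes, label_set
    )
    return sd, mc
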