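"""Construction of same/different trial pairs.

Pair comparison turns ``n`` trials into Θ(n²) training examples: every
ordered pair of trials is a labelled example of "same class" or
"different class".  Three schemes are supported, named for what each side
of the pair is:

* ``single_single`` — two raw trials;
* ``single_average`` — a raw trial (the query, slot A) against a k-trial
  within-class average (slot B, the "known" side; k = 20 by default);
* ``average_average`` — two disjoint k-trial averages.

Slot semantics are fixed: signal A is the unknown/query side, signal B the
known/dictionary side.  Training minibatches balance same vs different by
weighting each of the K same types twice as much as each of the K(K−1)
different types, and averages never share a source trial with the other
side of their pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .epochs import EpochDataset

SCHEMES = ("single_single", "single_average", "average_average")

Source = tuple  # (subject_id, trial_id)


class CapacityError(ValueError):
    """Raised when a pool has too few eligible trials for a request."""


@dataclass(frozen=True)
class PairType:
    """One ordered (class_a, class_b) combination."""

    class_a: str
    class_b: str

    @property
    def same(self) -> bool:
        return self.class_a == self.class_b


def enumerate_pair_types(labels_or_k) -> list[PairType]:
    """All K² ordered class pairs: K "same" and K(K−1) "different" types.

    Accepts either a class count (labels become ``0..K-1`` as strings) or
    an explicit label sequence.
    """
    if isinstance(labels_or_k, int):
        if labels_or_k < 1:
            raise ValueError(f"need K >= 1 classes, got {labels_or_k}")
        labels = [str(i) for i in range(labels_or_k)]
    else:
        labels = list(labels_or_k)
        if len(labels) < 1:
            raise ValueError("need at least one class label")
    return [PairType(a, b) for a in labels for b in labels]


@dataclass
class PairExample:
    """An ordered pair of signals with its same/different label.

    ``sources_*`` record every (subject_id, trial_id) that went into each
    side, enabling disjointness and leakage audits downstream.
    """

    signal_a: np.ndarray
    signal_b: np.ndarray
    class_a: str
    class_b: str
    sources_a: frozenset
    sources_b: frozenset
    scheme: str

    @property
    def same(self) -> bool:
        return self.class_a == self.class_b

    @property
    def label(self) -> str:
        return "same" if self.same else "different"

    def check_invariants(self) -> None:
        """Raise AssertionError on any label/disjointness violation."""
        assert self.scheme in SCHEMES
        if self.scheme == "average_average":
            assert not (self.sources_a & self.sources_b), "averages share sources"
        elif self.scheme == "single_average":
            assert not (self.sources_a & self.sources_b), "single trial inside its average"


@dataclass
class PairSamplingPlan:
    """How training pairs are drawn: scheme, balance weights, averaging k."""

    scheme: str = "single_single"
    batch_size: int = 144
    average_k: int = 20
    same_weight: float = 2.0
    different_weight: float = 1.0
    allow_self_pair: bool = False  # pair a single trial with itself
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.same_weight <= 0 or self.different_weight <= 0:
            raise ValueError("weights must be positive")
        if self.average_k < 1:
            raise ValueError("average_k must be >= 1")

    def type_probabilities(self, labels) -> tuple[list[PairType], np.ndarray]:
        """Normalized sampling probability for each ordered pair type."""
        types = enumerate_pair_types(labels)
        w = np.array(
            [self.same_weight if t.same else self.different_weight for t in types]
        )
        return types, w / w.sum()


class _PoolIndex:
    """Per-class trial indices and source ids for fast repeated sampling."""

    def __init__(self, pool: EpochDataset):
        self.pool = pool
        subj = pool.metadata["subject_id"].to_numpy()
        tid = pool.metadata["trial_id"].to_numpy()
        self.sources = [(s, int(t)) for s, t in zip(subj, tid)]
        self.by_class = {
            lab: pool.class_indices(lab) for lab in pool.label_set
        }

    def eligible(self, label: str, exclude: frozenset) -> np.ndarray:
        idx = self.by_class[label]
        if not exclude:
            return idx
        keep = [i for i in idx if self.sources[i] not in exclude]
        return np.asarray(keep, dtype=np.intp)


def make_trial_average(
    pool: EpochDataset,
    class_label: str,
    k: int,
    exclude: frozenset = frozenset(),
    rng: np.random.Generator | None = None,
    index: _PoolIndex | None = None,
) -> tuple[np.ndarray, frozenset]:
    """Unweighted mean of ``k`` distinct same-class trials.

    Trials are sampled without replacement from ``pool`` among trials of
    ``class_label`` whose (subject_id, trial_id) is not in ``exclude``.
    Returns the averaged signal and the set of k sources used.
    """
    rng = rng or np.random.default_rng()
    index = index or _PoolIndex(pool)
    eligible = index.eligible(class_label, exclude)
    if len(eligible) < k:
        raise CapacityError(
            f"class {class_label!r}: need {k} eligible trials, have {len(eligible)}"
            f" (short by {k - len(eligible)})"
        )
    chosen = rng.choice(eligible, size=k, replace=False)
    signal = pool.data[chosen].mean(axis=0)
    return signal, frozenset(index.sources[i] for i in chosen)


def _draw_side(
    index: _PoolIndex,
    label: str,
    single: bool,
    k: int,
    exclude: frozenset,
    rng: np.random.Generator,
) -> tuple[np.ndarray, frozenset]:
    if single:
        eligible = index.eligible(label, exclude)
        if len(eligible) < 1:
            raise CapacityError(f"class {label!r}: no eligible trial outside exclusions")
        i = int(rng.choice(eligible))
        return index.pool.data[i], frozenset([index.sources[i]])
    return make_trial_average(index.pool, label, k, exclude, rng, index)


def sample_pair_minibatch(
    train_pool: EpochDataset,
    plan: PairSamplingPlan,
    rng: np.random.Generator | None = None,
) -> list[PairExample]:
    """Draw ``plan.batch_size`` pairs with balanced type sampling.

    Each example's ordered class pair is drawn from the weighted type
    distribution (same types weighted ``same_weight``, different types
    ``different_weight``); signals are then sampled from all subjects in
    the pool under the scheme's disjointness rules.
    """
    rng = rng or np.random.default_rng(plan.seed)
    index = _PoolIndex(train_pool)
    types, probs = plan.type_probabilities(train_pool.label_set)
    a_single = plan.scheme in ("single_single", "single_average")
    b_single = plan.scheme == "single_single"
    k = plan.average_k

    out: list[PairExample] = []
    type_draws = rng.choice(len(types), size=plan.batch_size, p=probs)
    for ti in type_draws:
        t = types[ti]
        sig_a, src_a = _draw_side(index, t.class_a, a_single, k, frozenset(), rng)
        # B must not reuse A's sources when they could collide:
        # averages never contain the paired single/average's trials, and
        # a same-class single is (by default) never paired with itself.
        if not b_single:
            exclude = src_a
        elif t.same and not plan.allow_self_pair:
            exclude = src_a
        else:
            exclude = frozenset()
        sig_b, src_b = _draw_side(index, t.class_b, b_single, k, exclude, rng)
        out.append(
            PairExample(sig_a, sig_b, t.class_a, t.class_b, src_a, src_b, plan.scheme)
        )
    return out


@dataclass
class TestPairSet:
    """Cross-product evaluation pair set: every query × every known signal.

    Stored factored (queries and knowns separately) rather than as
    materialized pairs; :meth:`iter_batches` yields stacked
    ``(B, 2, channels, bins)`` inputs with same/different labels.
    """

    queries: np.ndarray  # (Q, channels, bins)
    query_classes: np.ndarray  # (Q,) str
    query_sources: list  # per query: frozenset of sources
    knowns: np.ndarray  # (M, channels, bins)
    known_classes: np.ndarray  # (M,) str
    known_sources: list
    scheme: str

    @property
    def n_pairs(self) -> int:
        return len(self.queries) * len(self.knowns)

    def pair_labels(self) -> np.ndarray:
        """Boolean (Q, M) matrix: True where query and known class agree."""
        return self.query_classes[:, None] == self.known_classes[None, :]

    def iter_batches(self, batch_size: int = 512) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        """Yield (inputs, same_mask) over the flattened Q × M pair grid."""
        q_n, m_n = len(self.queries), len(self.knowns)
        same = self.pair_labels().ravel()
        for start in range(0, q_n * m_n, batch_size):
            idx = np.arange(start, min(start + batch_size, q_n * m_n))
            qi, mi = idx // m_n, idx % m_n
            x = np.stack([self.queries[qi], self.knowns[mi]], axis=1)
            yield x, same[idx]


def _sample_known_signals(
    known_pool: EpochDataset,
    n_per_class: int,
    single: bool,
    k: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Known-side signals: ``n_per_class`` singles or k-averages per class."""
    index = _PoolIndex(known_pool)
    sigs, classes, sources = [], [], []
    for lab in known_pool.label_set:
        if single:
            idx = index.by_class[lab]
            if len(idx) < n_per_class:
                raise CapacityError(
                    f"class {lab!r}: need {n_per_class} trials, have {len(idx)}"
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
    return np.stack(sigs), np.asarray(classes, dtype=object), sources


def build_test_pairs(
    test_pool: EpochDataset,
    known_pool: EpochDataset,
    scheme: str,
    n_known_per_class: int = 100,
    n_test_averages_per_class: int = 80,
    average_k: int = 20,
    rng: np.random.Generator | None = None,
) -> TestPairSet:
    """Evaluation pairs for one held-out subject.

    For single-query schemes every test trial is compared against
    ``n_known_per_class`` known signals per class (raw trials for
    ``single_single``, k-averages otherwise).  For ``average_average``,
    ``n_test_averages_per_class`` averages per class are built from the
    test pool (each internally without replacement; reuse across averages
    is allowed) and compared against known-side averages.

    Pools must be subject-disjoint; this is audited downstream.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = rng or np.random.default_rng()

    if scheme == "average_average":
        index = _PoolIndex(test_pool)
        q_sigs, q_classes, q_sources = [], [], []
        for lab in test_pool.label_set:
            for _ in range(n_test_averages_per_class):
                s, src = make_trial_average(
                    test_pool, lab, average_k, frozenset(), rng, index
                )
                q_sigs.append(s)
                q_classes.append(lab)
                q_sources.append(src)
        queries = np.stack(q_sigs) if q_sigs else np.empty((0, *test_pool.data.shape[1:]))
        query_classes = np.asarray(q_classes, dtype=object)
    else:
        queries = test_pool.data.copy()
        query_classes = test_pool.metadata["class_label"].to_numpy(dtype=object)
        q_sources = [
            frozenset([(s, int(t))])
            for s, t in zip(
                test_pool.metadata["subject_id"], test_pool.metadata["trial_id"]
            )
        ]

    knowns, known_classes, known_sources = _sample_known_signals(
        known_pool,
        n_known_per_class,
        single=(scheme == "single_single"),
        k=average_k,
        rng=rng,
    )
    return TestPairSet(
        queries, query_classes, q_sources, knowns, known_classes, known_sources, scheme
    )
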