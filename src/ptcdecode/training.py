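"""Leave-one-subject-out training orchestration.

Each cross-validation fold holds out every trial of one subject for
testing; the remaining subjects are split 80/20 into training and
validation *by subject*, so no subject contributes to more than one of
the three pools.  Training minibatches of pairs are generated dynamically
each step; a validation pair set is sampled once per fold and frozen so
the early-stopping signal is stable.  Training stops when validation loss
has not improved for ``patience_epochs`` epochs and the weights from the
best-validation-loss epoch are restored.

Because pairs are generated dynamically there is no natural "epoch"; one
epoch is defined as ``ceil(n_training_trials / batch_size)`` minibatches,
so the epoch count scales with pool size.

Seeding: every stochastic component draws from an RNG keyed on
``(master_seed, fold_id, iteration, purpose)``, making each result
addressable and reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .epochs import EpochDataset
from .pairing import PairExample, PairSamplingPlan, sample_pair_minibatch
from .nn.network import ComparatorNetwork


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class TrainConfig:
    """Optimization protocol: Adam, batch 144, patience-30 early stopping."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 144
    patience_epochs: int = 30
    max_epochs: int = 500
    steps_per_epoch: int | None = None  # default: ceil(n_train_trials / batch)
    n_val_pairs: int = 720
    n_iterations: int = 10
    seed: int = 0
    record_pair_sources: bool = False  # keep full per-pair provenance (audits)

    def __post_init__(self) -> None:
        if self.patience_epochs < 1 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("patience_epochs, batch_size and max_epochs must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class FoldPlan:
    """One cross-validation fold: a held-out subject and the 80/20 split."""

    test_subject: object
    train_subjects: list
    val_subjects: list
    fold_id: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        train, val = set(self.train_subjects), set(self.val_subjects)
        if train & val or self.test_subject in train | val:
            raise ValueError("fold pools must be disjoint")


@dataclass
class TrainResult:
    """Per-epoch history plus the restored-best bookkeeping."""

    train_loss: list[float]
    train_acc: list[float]
    val_loss: list[float]
    val_acc: list[float]
    best_epoch: int  # 1-based
    fold_id: int
    iteration: int
    seed: int
    subjects_seen: set = field(default_factory=set)
    pair_sources: list | None = None
    metrics: dict = field(default_factory=dict)

    @property
    def best_val_loss(self) -> float:
        return self.val_loss[self.best_epoch - 1]

    @property
    def best_val_acc(self) -> float:
        return self.val_acc[self.best_epoch - 1]


class EarlyStopper:
    """Stop when the monitored loss fails to improve for ``patience`` epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best_loss = math.inf
        self.best_epoch = 0

    def update(self, loss: float, epoch: int) -> bool:
        """Record epoch ``epoch`` (1-based); True means stop now."""
        if loss < self.best_loss:
            self.best_loss = loss
            self.best_epoch = epoch
            return False
        return epoch - self.best_epoch >= self.patience


def _subfold_rng(cfg_seed: int, fold_id: int, iteration: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, fold_id, iteration, purpose])


def make_loso_folds(
    ds: EpochDataset, seed: int = 0, val_fraction: float = 0.2
) -> list[FoldPlan]:
    """One fold per subject; remaining subjects split 80/20 train/val.

    The split is by subject (rounded to nearest, at least one validation
    subject).  Requires at least 3 subjects.
    """
    subjects = ds.subjects
    if len(subjects) < 3:
        raise ValueError(f"need >= 3 subjects for leave-one-subject-out, got {len(subjects)}")
    folds = []
    for fold_id, test_subject in enumerate(subjects):
        rng = np.random.default_rng([seed, fold_id])
        rest = [s for s in subjects if s != test_subject]
        order = list(rng.permutation(len(rest)))
        n_val = min(len(rest) - 1, max(1, round(val_fraction * len(rest))))
        val = [rest[i] for i in order[:n_val]]
        train = [rest[i] for i in order[n_val:]]
        folds.append(FoldPlan(test_subject, train, val, fold_id=fold_id, seed=seed))
    return folds


def resplit_fold(ds: EpochDataset, fold: FoldPlan, seed_key: list[int],
                 val_fraction: float = 0.2) -> FoldPlan:
    """Re-randomize a fold's 80/20 train/val split (same held-out subject)."""
    rng = np.random.default_rng(seed_key)
    rest = fold.train_subjects + fold.val_subjects
    order = list(rng.permutation(len(rest)))
    n_val = min(len(rest) - 1, max(1, round(val_fraction * len(rest))))
    val = [rest[i] for i in order[:n_val]]
    train = [rest[i] for i in order[n_val:]]
    return FoldPlan(fold.test_subject, train, val, fold_id=fold.fold_id, seed=fold.seed)


def pairs_to_arrays(pairs: list[PairExample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack pair examples into (N, 2, channels, bins) inputs and 0/1 labels.

    Label convention matches the output units: 0 = same, 1 = different.
    """
    x = np.stack([np.stack([p.signal_a, p.signal_b]) for p in pairs]).astype(np.float32)
    y = np.array([0 if p.same else 1 for p in pairs], dtype=np.int64)
    return x, y


def train_model(
    model: ComparatorNetwork,
    ds: EpochDataset,
    fold: FoldPlan,
    plan: PairSamplingPlan,
    cfg: TrainConfig,
    iteration: int = 0,
) -> TrainResult:
    """Train the pair comparator on one fold; restores best weights.

    The model is modified in place; the returned record holds the
    histories, the best epoch, and provenance for leakage audits.
    """
    train_pool = ds.select_subjects(fold.train_subjects)
    val_pool = ds.select_subjects(fold.val_subjects)

    rng_train = _subfold_rng(cfg.seed, fold.fold_id, iteration, 1)
    rng_val = _subfold_rng(cfg.seed, fold.fold_id, iteration, 2)

    # frozen validation pair set
    val_plan = replace(plan, batch_size=cfg.n_val_pairs)
    val_pairs = sample_pair_minibatch(val_pool, val_plan, rng_val)
    x_val, y_val = pairs_to_arrays(val_pairs)

    steps = cfg.steps_per_epoch or max(1, math.ceil(train_pool.n_trials / cfg.batch_size))
    opt = model.make_optimizer(cfg.learning_rate, cfg.beta1, cfg.beta2)
    stopper = EarlyStopper(cfg.patience_epochs)

    result = TrainResult([], [], [], [], 0, fold.fold_id, iteration, cfg.seed,
                         pair_sources=[] if cfg.record_pair_sources else None)
    best_weights = None
    for epoch in range(1, cfg.max_epochs + 1):
        ep_loss, ep_acc = [], []
        for _ in range(steps):
            batch = sample_pair_minibatch(train_pool, plan, rng_train)
            for p in batch:
                result.subjects_seen.update(s for s, _t in p.sources_a | p.sources_b)
            if result.pair_sources is not None:
                result.pair_sources.extend((p.sources_a, p.sources_b) for p in batch)
            x, y = pairs_to_arrays(batch)
            try:
                loss, acc = model.train_step(x, y, opt)
            except FloatingPointError as err:
                raise DivergenceError(f"epoch {epoch}: {err}") from err
            ep_loss.append(loss)
            ep_acc.append(acc)
        result.train_loss.append(float(np.mean(ep_loss)))
        result.train_acc.append(float(np.mean(ep_acc)))
        v_loss, v_acc = model.evaluate(x_val, y_val, batch_size=128)
        result.val_loss.append(v_loss)
        result.val_acc.append(v_acc)
        improved = v_loss < stopper.best_loss
        stop = stopper.update(v_loss, epoch)
        if improved:
            best_weights = model.get_weights()
        if stop:
            break
    result.best_epoch = stopper.best_epoch
    if best_weights is not None:
        model.set_weights(best_weights)
    return result


def run_iterations(
    build_fn,
    ds: EpochDataset,
    fold: FoldPlan,
    plan: PairSamplingPlan,
    cfg: TrainConfig,
    resplit_per_iteration: bool = True,
    eval_fn=None,
) -> list[TrainResult]:
    """Repeat training ``cfg.n_iterations`` times with fresh initialization.

    Each iteration re-randomizes the 80/20 train/validation split (unless
    ``resplit_per_iteration`` is False), rebuilds the model via
    ``build_fn(seed)`` with a distinct derived seed, and optionally runs
    ``eval_fn(model, fold, iteration) -> dict`` whose output is stored in
    the result's ``metrics``.  Downstream aggregation averages metrics
    across iterations within a subject, then across subjects.
    """
    results = []
    for it in range(cfg.n_iterations):
        fold_i = (
            resplit_fold(ds, fold, [cfg.seed, fold.fold_id, it, 3])
            if resplit_per_iteration
            else fold
        )
        model_seed = int(_subfold_rng(cfg.seed, fold.fold_id, it, 4).integers(2**31))
        model = build_fn(seed=model_seed)
        try:
            res = train_model(model, ds, fold_i, plan, cfg, iteration=it)
        except DivergenceError as err:
            raise DivergenceError(f"iteration {it}: {err}") from err
        if eval_fn is not None:
            res.metrics = eval_fn(model, fold_i, it)
        results.append(res)
    return results
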