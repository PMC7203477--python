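"""End-to-end experiment orchestration and baseline classifiers.

Runs any subset of the pair-comparison variations (single_single,
single_average, average_average) and of the baselines (direct CNN
classifier, linear SVM, sparse multinomial logistic regression) over
leave-one-subject-out folds, aggregates per-subject accuracies (mean
over iterations within subject, then over subjects), and writes CSV
records plus a JSON manifest.

Baselines operate on the same binned, scaled, flattened features
(31 × 37 = 1147 per trial by default).  The SVM is a linear-kernel
max-margin classifier with its C hyperparameter grid-searched over
[0.0001 … 100]; the sparse regression is L1-penalized multinomial
logistic regression with λ from [0.001 … 1000] mapped to the inverse
penalty C = 1/λ.  Hyperparameters are selected by inner 5-fold
cross-validation on the training subjects (the protocol uses no
validation subjects for these models).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .epochs import EpochDataset, PreprocessConfig, preprocess
from .synth import SyntheticConfig, generate_dataset
from .pairing import PairSamplingPlan, build_test_pairs, make_trial_average, _PoolIndex
from .nn.network import ArchitectureSpec, build_baseline_network, build_ptc_network
from .training import TrainConfig, FoldPlan, make_loso_folds, run_iterations
from .dictionary import build_dictionary, evaluate_scheme

SVM_C_GRID = (0.0001, 0.001, 0.01, 0.1, 1, 10, 100)
SMLR_LAMBDA_GRID = (0.001, 0.01, 0.1, 1, 10, 100, 1000)


class DegenerateTestError(ValueError):
    """Raised when a paired t-test has zero-variance differences."""


def paired_ttest(acc_a, acc_b) -> tuple[float, float]:
    """Two-sided paired t-test over subject-aligned accuracy vectors."""
    a, b = np.asarray(acc_a, dtype=float), np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors with >= 2 subjects")
    d = a - b
    scale = max(1.0, float(np.abs(d).max()))
    if np.std(d) <= 1e-12 * scale:
        raise DegenerateTestError("zero-variance differences: t statistic undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


@dataclass
class ExperimentConfig:
    """Everything one experiment run needs; YAML-serializable."""

    synthetic: SyntheticConfig | None = None
    dataset_path: str | None = None
    variations: tuple[str, ...] = ("single_single", "single_average", "average_average")
    baselines: tuple[str, ...] = ()
    baseline_trial_modes: tuple[str, ...] = ("single",)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    arch: ArchitectureSpec = field(default_factory=ArchitectureSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    average_k: int = 20
    dictionary_n_per_class: int = 100
    n_test_averages_per_class: int = 80
    max_folds: int | None = None  # cap folds for reduced-scale runs
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.variations and not self.baselines:
            raise ValueError("select at least one variation or baseline")


@dataclass
class ResultsTable:
    """Per (analysis, subject, iteration) records plus aggregation rules."""

    records: pd.DataFrame  # columns: analysis, subject, iteration, metric, value
    confusions: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        """Mean over iterations within subject, then mean over subjects."""
        per_subject = (
            self.records.groupby(["analysis", "metric", "subject"])["value"]
            .mean()
            .reset_index()
        )
        return (
            per_subject.groupby(["analysis", "metric"])["value"].mean().reset_index()
        )

    def per_subject(self, analysis: str, metric: str) -> pd.Series:
        rows = self.records[
            (self.records["analysis"] == analysis) & (self.records["metric"] == metric)
        ]
        return rows.groupby("subject")["value"].mean()

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.csv", index=False)
        self.aggregate().to_csv(out / "summary.csv", index=False)
        for name, mat in self.confusions.items():
            np.savetxt(out / f"confusion_{name}.csv", np.asarray(mat), delimiter=",")


def _load_input(cfg: ExperimentConfig) -> EpochDataset:
    from .epochs import load_epochs

    if cfg.synthetic is not None:
        raw = generate_dataset(cfg.synthetic)
    elif cfg.dataset_path:
        raw = load_epochs(cfg.dataset_path)
    else:
        raise ValueError("config needs a synthetic block or a dataset_path")
    return preprocess(raw, cfg.preprocess)


def _flatten(ds: EpochDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = ds.data.reshape(ds.n_trials, -1)
    y = ds.metadata["class_label"].to_numpy()
    groups = ds.metadata["subject_id"].to_numpy()
    return x, y, groups


def _averaged_pool(ds: EpochDataset, k: int, n_per_class: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Within-class k-trial averages (features flattened) for baselines."""
    index = _PoolIndex(ds)
    xs, ys = [], []
    for lab in ds.label_set:
        for _ in range(n_per_class):
            s, _src = make_trial_average(ds, lab, k, frozenset(), rng, index)
            xs.append(s.ravel())
            ys.append(lab)
    return np.stack(xs), np.asarray(ys)


def baseline_linear(
    ds: EpochDataset,
    kind: str,
    folds: list[FoldPlan],
    trial_mode: str = "single",
    average_k: int = 20,
    n_averages_per_class: int = 80,
    seed: int = 0,
) -> pd.DataFrame:
    """Linear SVM or sparse multinomial logistic regression per fold.

    Trained on all non-test subjects; hyperparameters picked by inner
    5-fold CV over the printed grids.  Returns one record per fold.
    """
    from sklearn.model_selection import GridSearchCV
    from sklearn.svm import LinearSVC
    from sklearn.linear_model import LogisticRegression

    if kind == "svm":
        base = LinearSVC(dual="auto", max_iter=5000)
        grid = {"C": list(SVM_C_GRID)}
    elif kind == "smlr":
        base = LogisticRegression(
            penalty="l1", solver="saga", max_iter=3000, tol=1e-3
        )
        grid = {"C": [1.0 / lam for lam in SMLR_LAMBDA_GRID]}
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")

    rows = []
    for fold in folds:
        known = ds.select_subjects(fold.train_subjects + fold.val_subjects)
        test = ds.select_subjects([fold.test_subject])
        rng = np.random.default_rng([seed, fold.fold_id, 11])
        if trial_mode == "averaged":
            x_tr, y_tr = _averaged_pool(known, average_k, n_averages_per_class, rng)
            x_te, y_te = _averaged_pool(test, average_k, n_averages_per_class, rng)
        else:
            x_tr, y_tr, _ = _flatten(known)
            x_te, y_te, _ = _flatten(test)
        if len(set(y_tr)) < 2:
            raise ValueError(f"fold {fold.fold_id}: degenerate single-class training pool")
        search = GridSearchCV(base, grid, cv=5, n_jobs=1)
        search.fit(x_tr, y_tr)
        acc = float((search.predict(x_te) == y_te).mean()) * 100
        rows.append(
            {
                "analysis": f"{kind}_{trial_mode}",
                "subject": fold.test_subject,
                "iteration": 0,
                "metric": "multiclass_accuracy",
                "value": acc,
                "hyperparameter": float(search.best_params_["C"]),
            }
        )
    return pd.DataFrame(rows)


def baseline_dnn(
    ds: EpochDataset,
    folds: list[FoldPlan],
    cfg: TrainConfig,
    arch: ArchitectureSpec | None = None,
    trial_mode: str = "single",
    average_k: int = 20,
    n_averages_per_class: int = 80,
) -> pd.DataFrame:
    """Direct 3-class CNN baseline trained per fold × iteration.

    Uses the same hidden topology and optimization protocol as the pair
    network, with single-trial (1-channel) input and one output per
    class; trains on labelled trials (or k-trial averages) rather than
    pairs.
    """
    arch = arch or ArchitectureSpec()
    labels = list(ds.label_set)
    rows = []
    for fold in folds:
        for it in range(cfg.n_iterations):
            rng = np.random.default_rng([cfg.seed, fold.fold_id, it, 21])
            model_seed = int(rng.integers(2**31))
            model = build_baseline_network(arch, n_classes=len(labels), seed=model_seed)
            known = ds.select_subjects(fold.train_subjects)
            val = ds.select_subjects(fold.val_subjects)
            test = ds.select_subjects([fold.test_subject])

            def xy(pool):
                if trial_mode == "averaged":
                    x, y = _averaged_pool(pool, average_k, n_averages_per_class, rng)
                    x = x.reshape(len(x), 1, *pool.data.shape[1:])
                else:
                    x = pool.data[:, None].astype(np.float32)
                    y = pool.metadata["class_label"].to_numpy()
                return x.astype(np.float32), np.array([labels.index(c) for c in y])

            x_tr, y_tr = xy(known)
            x_val, y_val = xy(val)
            x_te, y_te = xy(test)

            opt = model.make_optimizer(cfg.learning_rate, cfg.beta1, cfg.beta2)
            from .training import EarlyStopper

            stopper = EarlyStopper(cfg.patience_epochs)
            best_weights = None
            order_rng = np.random.default_rng([cfg.seed, fold.fold_id, it, 22])
            n = len(x_tr)
            for epoch in range(1, cfg.max_epochs + 1):
                perm = order_rng.permutation(n)
                for start in range(0, n, cfg.batch_size):
                    sel = perm[start : start + cfg.batch_size]
                    model.train_step(x_tr[sel], y_tr[sel], opt)
                v_loss, _v_acc = model.evaluate(x_val, y_val)
                improved = v_loss < stopper.best_loss
                stop = stopper.update(v_loss, epoch)
                if improved:
                    best_weights = model.get_weights()
                if stop:
                    break
            if best_weights is not None:
                model.set_weights(best_weights)
            probs = model.predict_proba(x_te)
            acc = float((probs.argmax(axis=1) == y_te).mean()) * 100
            rows.append(
                {
                    "analysis": f"dnn_{trial_mode}",
                    "subject": fold.test_subject,
                    "iteration": it,
                    "metric": "multiclass_accuracy",
                    "value": acc,
                }
            )
    return pd.DataFrame(rows)


def run_experiment(cfg: ExperimentConfig) -> ResultsTable:
    """Execute every selected analysis over LOSO folds; returns all records.

    Pair-comparison variations train one comparator per fold × iteration,
    then evaluate both protocols against a dictionary built from the
    training+validation subjects (never the test subject).  Deterministic
    for a fixed ``cfg.seed``.
    """
    ds = _load_input(cfg)
    folds = make_loso_folds(ds, seed=cfg.seed)
    if cfg.max_folds is not None:
        folds = folds[: cfg.max_folds]

    records: list[pd.DataFrame] = []
    confusions: dict = {}

    for scheme in cfg.variations:
        plan = PairSamplingPlan(
            scheme=scheme,
            batch_size=cfg.train.batch_size,
            average_k=cfg.average_k,
            seed=cfg.seed,
        )
        rows = []
        for fold in folds:

            def eval_fn(model, fold_i, iteration, _scheme=scheme):
                rng = np.random.default_rng([cfg.seed, fold_i.fold_id, iteration, 31])
                known = ds.select_subjects(fold_i.train_subjects + fold_i.val_subjects)
                test = ds.select_subjects([fold_i.test_subject])
                pairs = build_test_pairs(
                    test,
                    known,
                    _scheme,
                    n_known_per_class=cfg.dictionary_n_per_class,
                    n_test_averages_per_class=cfg.n_test_averages_per_class,
                    average_k=cfg.average_k,
                    rng=rng,
                )
                sd, mc = evaluate_scheme(model, pairs, ds.label_set)
                return {
                    "same_different_accuracy": sd.accuracy,
                    "multiclass_accuracy": mc.accuracy,
                    "sd_confusion": sd.confusion,
                    "mc_confusion": mc.confusion,
                }

            results = run_iterations(
                lambda seed: build_ptc_network(cfg.arch, seed=seed),
                ds,
                fold,
                plan,
                cfg.train,
                eval_fn=eval_fn,
            )
            for res in results:
                for metric in ("same_different_accuracy", "multiclass_accuracy"):
                    rows.append(
                        {
                            "analysis": scheme,
                            "subject": fold.test_subject,
                            "iteration": res.iteration,
                            "metric": metric,
                            "value": res.metrics[metric],
                        }
                    )
                key = f"{scheme}_sd"
                confusions[key] = confusions.get(key, 0) + res.metrics["sd_confusion"] / (
                    len(folds) * cfg.train.n_iterations
                )
                key = f"{scheme}_mc"
                confusions[key] = confusions.get(key, 0) + res.metrics["mc_confusion"] / (
                    len(folds) * cfg.train.n_iterations
                )
        records.append(pd.DataFrame(rows))

    for kind in cfg.baselines:
        for mode in cfg.baseline_trial_modes:
            if kind == "dnn":
                records.append(
                    baseline_dnn(ds, folds, cfg.train, cfg.arch, trial_mode=mode,
                                 average_k=cfg.average_k)
                )
            else:
                records.append(
                    baseline_linear(ds, kind, folds, trial_mode=mode,
                                    average_k=cfg.average_k, seed=cfg.seed)
                )

    table = ResultsTable(pd.concat(records, ignore_index=True), confusions)
    if cfg.output_dir:
        table.save(cfg.output_dir)
        manifest = {
            "seed": cfg.seed,
            "variations": list(cfg.variations),
            "baselines": list(cfg.baselines),
            "n_folds": len(folds),
            "n_iterations": cfg.train.n_iterations,
            "arch": cfg.arch.to_dict(),
        }
        Path(cfg.output_dir, "manifest.json").write_text(json.dumps(manifest, indent=2))
    return table
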