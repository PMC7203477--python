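"""Train a pair comparator on one leave-one-subject-out fold and evaluate.

A reduced-scale run (4 subjects, 2-block network, few epochs) that still
exercises the full pipeline: dynamic balanced pair minibatches, frozen
validation pairs with early stopping, best-weight restoration, and both
evaluation protocols (same/different and dictionary multiclass) on the
held-out subject.  Takes a few minutes on one CPU.
"""

import numpy as np

from ptcdecode import (
    ArchitectureSpec,
    PairSamplingPlan,
    SyntheticConfig,
    TrainConfig,
    build_ptc_network,
    build_test_pairs,
    evaluate_scheme,
    generate_dataset,
    make_loso_folds,
    preprocess,
    train_model,
)

ds = preprocess(generate_dataset(
    SyntheticConfig(n_subjects=4, trials_per_class_range=(60, 60), seed=7)
))
fold = make_loso_folds(ds, seed=0)[0]
print(f"fold 0: test {fold.test_subject}, train {fold.train_subjects}, "
      f"val {fold.val_subjects}")

arch = ArchitectureSpec(n_blocks=2, filters_per_block=(12, 48))
model = build_ptc_network(arch, seed=1)
plan = PairSamplingPlan(scheme="single_average", average_k=20, seed=1)
cfg = TrainConfig(max_epochs=8, patience_epochs=4, n_val_pairs=432,
                  n_iterations=1, seed=1)
res = train_model(model, ds, fold, plan, cfg)
print(f"trained {len(res.val_loss)} epochs; best epoch {res.best_epoch} "
      f"with validation accuracy {res.best_val_acc:.2f}")

known = ds.select_subjects(fold.train_subjects + fold.val_subjects)
test = ds.select_subjects([fold.test_subject])
pairs = build_test_pairs(test, known, "single_average", n_known_per_class=30,
                         average_k=20, rng=np.random.default_rng(2))
sd, mc = evaluate_scheme(model, pairs, ds.label_set)
print(f"held-out subject: same/different accuracy {sd.accuracy:.1f}% (chance 50), "
      f"dictionary accuracy {mc.accuracy:.1f}% (chance 33.3)")
print("same/different confusion (% per actual row):")
print(np.round(sd.confusion, 1))
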