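"""Dictionary decoding: multiclass decisions from pairwise judgements.

Uses stub comparators to demonstrate the decision rule in isolation:
an oracle comparator decodes perfectly, and a class-uninformative random
comparator recovers the 1/3 chance level — the dictionary rule adds no
information of its own.
"""

import numpy as np

from ptcdecode import (
    FunctionComparator,
    RandomComparator,
    SyntheticConfig,
    build_dictionary,
    classify_with_dictionary,
    evaluate_multiclass,
    generate_dataset,
    preprocess,
)

ds = preprocess(generate_dataset(
    SyntheticConfig(n_subjects=5, trials_per_class_range=(40, 40), seed=4)
))
known = ds.select_subjects(ds.subjects[:4])
test = ds.select_subjects(ds.subjects[4:])

dictionary = build_dictionary(known, n_per_class=50, entry_kind="single",
                              rng=np.random.default_rng(0))
print(f"dictionary: {len(dictionary.signals)} entries "
      f"({dictionary.n_per_class}) drawn from 4 'known' subjects")

decision = classify_with_dictionary(RandomComparator(1), test.data[0], dictionary)
print(f"one query, random comparator -> scores "
      f"{ {k: round(v, 3) for k, v in decision.scores.items()} } "
      f"-> predicts {decision.predicted_class!r}")

res = evaluate_multiclass(RandomComparator(2), test, dictionary)
print(f"random comparator over {res.n_queries} queries: {res.accuracy:.1f}% "
      f"(chance = 33.33%)")

# an oracle that leaks the true template correlation decodes far above chance
from ptcdecode.synth import class_template

cfg = SyntheticConfig(n_subjects=5, trials_per_class_range=(40, 40), seed=4)
templates = np.stack([class_template(cfg, k, 4).ravel() for k in range(3)])


def template_match(batch):
    a = batch[:, 0].reshape(len(batch), -1)
    b = batch[:, 1].reshape(len(batch), -1)
    ka = np.corrcoef(np.vstack([a, templates]))[: len(a), len(a):].argmax(axis=1)
    kb = np.corrcoef(np.vstack([b, templates]))[: len(b), len(b):].argmax(axis=1)
    return np.where(ka == kb, 0.9, 0.1)


res = evaluate_multiclass(FunctionComparator(template_match), test, dictionary)
print(f"template-matching comparator: {res.accuracy:.1f}% — pooling many weak "
      f"pairwise judgements recovers the class")
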