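"""Balanced same/different pair sampling and the three pairing schemes.

Shows the ordered pair-type combinatorics (3 same + 6 different types for
3 classes), the 2:1 weighting that balances same vs different draws, and
the disjointness guarantees of the averaging schemes.
"""

import numpy as np

from ptcdecode import (
    PairSamplingPlan,
    SyntheticConfig,
    enumerate_pair_types,
    generate_dataset,
    preprocess,
    sample_pair_minibatch,
)

types = enumerate_pair_types(3)
print(f"3 classes -> {len(types)} ordered pair types: "
      f"{sum(t.same for t in types)} same, {sum(not t.same for t in types)} different")

ds = preprocess(generate_dataset(SyntheticConfig(n_subjects=4, trials_per_class_range=(30, 30), seed=1)))

plan = PairSamplingPlan(scheme="single_single", batch_size=5000, seed=2)
batch = sample_pair_minibatch(ds, plan)
p_same = np.mean([p.same for p in batch])
print(f"single_single, 5000 draws: P(same) = {p_same:.3f} (weights 2:1 make it 1/2)")

plan = PairSamplingPlan(scheme="average_average", batch_size=200, average_k=20, seed=3)
batch = sample_pair_minibatch(ds, plan)
overlaps = sum(bool(p.sources_a & p.sources_b) for p in batch)
print(f"average_average, 200 draws of 20-trial averages: {overlaps} source overlaps "
      f"(averages never share trials)")
print(f"example pair: {len(batch[0].sources_a)} + {len(batch[0].sources_b)} distinct "
      f"source trials, label = {batch[0].label}")
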