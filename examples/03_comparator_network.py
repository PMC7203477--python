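"""Build the pair-comparator network and inspect its structure.

The canonical architecture stacks two 31 x 37 signals as a 2-channel
image, batch-normalizes, and runs four densely-concatenated blocks of
3 x 3 convolutions (12 -> 24 -> 36 -> 48 filters), a 3-filter reduction
convolution, and dense layers of 64 and 32 units down to a 2-unit
same/different softmax.
"""

import numpy as np

from ptcdecode import (
    ArchitectureSpec,
    build_baseline_network,
    build_ptc_network,
    count_trainable_params,
    forward_pair,
)

spec = ArchitectureSpec()
model = build_ptc_network(spec, seed=0)
print(f"input: {spec.input_channels} x {spec.spatial_shape[0]} x {spec.spatial_shape[1]}")
print(f"channel progression after each block's concat+batchnorm: {spec.concat_channels()}")
print(f"(block 1: 12 conv filters + 2 input maps = {model.block_output_channels(1)} maps)")
print(f"trainable parameters (pair network): {count_trainable_params(model):,}")

baseline = build_baseline_network(spec, n_classes=3, seed=0)
print(f"trainable parameters (3-class baseline, same hidden layers): "
      f"{count_trainable_params(baseline):,}")

pair = np.random.default_rng(0).normal(size=(4, 2, 31, 37)).astype(np.float32)
probs = forward_pair(model, pair)
print(f"untrained forward pass on 4 random pairs -> [P(same), P(different)] rows:")
print(np.round(probs, 3))
print("rows sum to 1; unit 0 is 'same' by persisted convention")
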