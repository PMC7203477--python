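"""Stub comparators implementing the pair-probability protocol.

A *comparator* is anything with
``predict_pair_proba(batch: (B, 2, channels, bins)) -> (B, 2)`` returning
[P(same), P(different)] rows.  Trained networks satisfy it; the stubs
here provide degenerate reference behaviour for protocol tests and
chance-level calibration.
"""

from __future__ import annotations

import numpy as np


class RandomComparator:
    """Class-uninformative comparator: P(same) ~ Uniform(0, 1), input-ignored.

    Feeding this through the same/different and dictionary protocols
    recovers their chance levels (50% and 1/K).
    """

    def __init__(self, seed: int = 0):
        self.rng = np.random.default_rng(seed)

    def predict_pair_proba(self, batch: np.ndarray) -> np.ndarray:
        p = self.rng.random(len(batch))
        return np.column_stack([p, 1.0 - p])


class FunctionComparator:
    """Wraps ``fn(batch) -> P(same) vector`` into the comparator protocol.

    Useful for oracle stubs in tests, e.g. deciding "same" from a class
    marker embedded in the signals.
    """

    def __init__(self, fn):
        self.fn = fn

    def predict_pair_proba(self, batch: np.ndarray) -> np.ndarray:
        p = np.asarray(self.fn(np.asarray(batch)), dtype=float)
        return np.column_stack([p, 1.0 - p])


class ConstantComparator:
    """Always returns the same P(same); e.g. 1.0 for an always-same stub."""

    def __init__(self, p_same: float):
        self.p_same = float(p_same)

    def predict_pair_proba(self, batch: np.ndarray) -> np.ndarray:
        return np.tile([self.p_same, 1.0 - self.p_same], (len(batch), 1))
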