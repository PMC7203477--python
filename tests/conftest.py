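import numpy as np
import pandas as pd
import pytest

from ptcdecode.epochs import EpochDataset
from ptcdecode.synth import SyntheticConfig, generate_dataset
from ptcdecode.epochs import preprocess


def make_dataset(n_subjects=3, trials_per_class=4, n_channels=4, n_timepoints=20,
                 labels=("face", "scene", "word"), sampling_rate=250.0, seed=0):
    """Small handmade dataset with reproducible random content."""
    rng = np.random.default_rng(seed)
    rows, parts = [], []
    for s in range(n_subjects):
        tid = 0
        for lab in labels:
            for _ in range(trials_per_class):
                rows.append({"subject_id": f"S{s}", "trial_id": tid, "class_label": lab})
                tid += 1
    n = len(rows)
    data = rng.normal(0, 10, (n, n_channels, n_timepoints))
    return EpochDataset(
        data=data,
        metadata=pd.DataFrame(rows),
        sampling_rate=sampling_rate,
        label_set=tuple(labels),
    )


@pytest.fixture
def tiny_dataset():
    return make_dataset()


@pytest.fixture(scope="session")
def small_synthetic():
    """4-subject synthetic dataset at the canonical 31 x 370 shape."""
    cfg = SyntheticConfig(n_subjects=4, trials_per_class_range=(25, 28), seed=3)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_binned(small_synthetic):
    return preprocess(small_synthetic)
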