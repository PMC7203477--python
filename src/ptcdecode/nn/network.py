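"""The densely-concatenated convolutional comparator and its builders.

The canonical architecture takes a pair of 31 × 37 signals stacked as a
``2 × 31 × 37`` input (or a single trial, ``1 × 31 × 37``, for the
baseline classifier).  The input is batch-normalized, then passed through
four blocks of (3 × 3 zero-padded convolution → leaky ReLU → concatenate
with everything seen so far → batch norm), DenseNet-style, with filter
counts rising 12 → 24 → 36 → 48.  A final 3-filter convolution reduces
the stack, which is flattened into dense layers of 64 and 32 units
(dropout 10% each) and a softmax output: 2 units (same/different) for the
pair network, one per class for the baseline.

Output-unit convention, persisted with the weights: unit 0 is "same".
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .layers import (
    DTYPE,
    Adam,
    BatchNorm2d,
    Conv2d,
    Dense,
    Dropout,
    LeakyReLU,
    Param,
    softmax,
    softmax_cross_entropy,
)


class ConfigurationError(ValueError):
    """Raised when an architecture description violates its invariants."""


@dataclass
class ArchitectureSpec:
    """Declarative description of the comparator / baseline network."""

    input_channels: int = 2
    spatial_shape: tuple[int, int] = (31, 37)
    n_blocks: int = 4
    kernel: tuple[int, int] = (3, 3)
    filters_per_block: tuple[int, ...] = (12, 24, 36, 48)
    reduction_filters: int = 3
    dense_widths: tuple[int, ...] = (64, 32)
    output_units: int = 2
    leaky_slope: float = 0.3
    dropout_dense: float = 0.10

    def __post_init__(self) -> None:
        f = tuple(self.filters_per_block)
        if len(f) != self.n_blocks:
            raise ConfigurationError(
                f"filters_per_block has {len(f)} entries for {self.n_blocks} blocks"
            )
        if any(b >= a for a, b in zip(f[1:], f)):
            raise ConfigurationError("filters_per_block must be strictly increasing")
        if f[0] != 12 or f[-1] != 48:
            raise ConfigurationError("filter schedule must run from 12 to 48")
        if self.output_units < 2:
            raise ConfigurationError("output_units must be >= 2")
        if self.input_channels not in (1, 2):
            raise ConfigurationError("input_channels must be 1 (baseline) or 2 (pair)")

    def concat_channels(self) -> list[int]:
        """Channel count after each block's concatenation (and batch norm).

        ``c_i = c_{i-1} + f_i`` with ``c_0 = input_channels``; for the
        canonical pair network this is [14, 38, 74, 122].
        """
        c = [self.input_channels]
        for f in self.filters_per_block:
            c.append(c[-1] + f)
        return c[1:]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        d = dict(d)
        for key in ("spatial_shape", "kernel", "filters_per_block", "dense_widths"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


class ComparatorNetwork:
    """A built (trainable) network; the model handle used everywhere.

    ``predict_proba`` runs in evaluation mode (running batch-norm
    statistics, no dropout); ``train_step`` does one forward/backward and
    Adam update on a labelled batch.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        c0 = spec.input_channels
        self.bn_in = BatchNorm2d(c0, name="bn_in")
        self.blocks = []
        c = c0
        for i, f in enumerate(spec.filters_per_block):
            conv = Conv2d(c, f, spec.kernel, rng, name=f"block{i + 1}.conv")
            act = LeakyReLU(spec.leaky_slope)
            bn = BatchNorm2d(c + f, name=f"block{i + 1}.bn")
            self.blocks.append((conv, act, bn))
            c = c + f
        self.reduce_conv = Conv2d(c, spec.reduction_filters, spec.kernel, rng, name="reduce.conv")
        self.reduce_act = LeakyReLU(spec.leaky_slope)
        h, w = spec.spatial_shape
        n_flat = spec.reduction_filters * h * w
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        self.dense = []
        n_in = n_flat
        for j, width in enumerate(spec.dense_widths):
            self.dense.append(
                (
                    Dense(n_in, width, rng, name=f"dense{j + 1}"),
                    LeakyReLU(spec.leaky_slope),
                    Dropout(spec.dropout_dense, self._dropout_rng),
                )
            )
            n_in = width
        self.out = Dense(n_in, spec.output_units, rng, name="out")

    # -- introspection ----------------------------------------------------
    @property
    def params(self) -> list[Param]:
        ps = list(self.bn_in.params)
        for conv, _act, bn in self.blocks:
            ps += conv.params + bn.params
        ps += self.reduce_conv.params
        for d, _a, _dr in self.dense:
            ps += d.params
        ps += self.out.params
        return ps

    def block_output_channels(self, block: int) -> int:
        """Feature maps after block ``block`` (1-based) concat + batch norm."""
        return self.spec.concat_channels()[block - 1]

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch shaped (N, input_channels, H, W)."""
        x = np.asarray(x, dtype=DTYPE)
        expect = (self.spec.input_channels, *self.spec.spatial_shape)
        if x.ndim != 4 or x.shape[1:] != expect:
            raise ValueError(f"expected input (N, {expect[0]}, {expect[1]}, {expect[2]}), got {x.shape}")
        # internal layout is channels-last for convolution speed
        t = self.bn_in.forward(np.ascontiguousarray(x.transpose(0, 2, 3, 1)), train)
        self._split_channels = []
        for conv, act, bn in self.blocks:
            u = act.forward(conv.forward(t, train), train)
            self._split_channels.append(u.shape[-1])
            t = bn.forward(np.concatenate([u, t], axis=-1), train)
        r = self.reduce_act.forward(self.reduce_conv.forward(t, train), train)
        n = r.shape[0]
        self._r_shape = r.shape
        z = r.reshape(n, -1)
        for d, a, dr in self.dense:
            z = dr.forward(a.forward(d.forward(z, train), train), train)
        return self.out.forward(z, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.out.backward(dlogits)
        for d, a, dr in reversed(self.dense):
            dz = d.backward(a.backward(dr.backward(dz)))
        dr_img = dz.reshape(self._r_shape)
        dt = self.reduce_conv.backward(self.reduce_act.backward(dr_img))
        for (conv, act, bn), f in zip(reversed(self.blocks), reversed(self._split_channels)):
            dcat = bn.backward(dt)
            du, dt_prev = dcat[..., :f], dcat[..., f:]
            dt = dt_prev + conv.backward(act.backward(du))
        self.bn_in.backward(dt)

    # -- user-facing inference/training -----------------------------------
    def predict_proba(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Softmax output probabilities, evaluated in batches."""
        x = np.asarray(x)
        out = []
        for start in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[start : start + batch_size], train=False)))
        return np.concatenate(out, axis=0) if out else np.empty((0, self.spec.output_units))

    def predict_pair_proba(self, pair_batch: np.ndarray) -> np.ndarray:
        """Comparator protocol: columns [P(same), P(different)] (unit 0 = same)."""
        return self.predict_proba(pair_batch)

    def make_optimizer(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999) -> Adam:
        return Adam(self.params, lr=lr, beta1=beta1, beta2=beta2)

    def train_step(self, x: np.ndarray, y: np.ndarray, opt: Adam) -> tuple[float, float]:
        """One gradient step; returns (loss, batch accuracy)."""
        opt.zero_grad()
        logits = self.forward(x, train=True)
        loss, dlogits = softmax_cross_entropy(logits, y)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss {loss}")
        self.backward(dlogits)
        opt.step()
        acc = float((logits.argmax(axis=1) == y).mean())
        return loss, acc

    def evaluate(self, x: np.ndarray, y: np.ndarray, batch_size: int = 512) -> tuple[float, float]:
        """(mean cross-entropy, accuracy) in evaluation mode."""
        losses, correct, n = [], 0, x.shape[0]
        for start in range(0, n, batch_size):
            xb, yb = x[start : start + batch_size], y[start : start + batch_size]
            logits = self.forward(xb, train=False)
            loss, _ = softmax_cross_entropy(logits, yb)
            losses.append(loss * len(yb))
            correct += int((logits.argmax(axis=1) == yb).sum())
        return float(np.sum(losses) / n), correct / n

    # -- persistence -------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        ws = [p.value.copy() for p in self.params]
        for bn in self._all_bns():
            ws += [bn.running_mean.copy(), bn.running_var.copy()]
        return ws

    def set_weights(self, ws: list[np.ndarray]) -> None:
        ps = self.params
        for p, w in zip(ps, ws[: len(ps)]):
            p.value[...] = w
        rest = ws[len(ps) :]
        for bn, (m, v) in zip(self._all_bns(), zip(rest[0::2], rest[1::2])):
            bn.running_mean[...] = m
            bn.running_var[...] = v

    def _all_bns(self) -> list[BatchNorm2d]:
        return [self.bn_in] + [bn for _c, _a, bn in self.blocks]

    def save(self, path) -> None:
        """Weights as .npz plus a JSON manifest (spec, conventions, seed)."""
        path = Path(path)
        ws = self.get_weights()
        np.savez(path.with_suffix(".npz"), *ws)
        manifest = {
            "spec": self.spec.to_dict(),
            "unit0": "same" if self.spec.output_units == 2 else "class0",
            "seed": self.seed,
            "n_weight_arrays": len(ws),
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_model(path) -> ComparatorNetwork:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    spec = ArchitectureSpec.from_dict(manifest["spec"])
    model = ComparatorNetwork(spec, seed=manifest.get("seed", 0))
    with np.load(path.with_suffix(".npz")) as z:
        model.set_weights([z[k] for k in z.files])
    return model


def build_ptc_network(spec: ArchitectureSpec | None = None, seed: int = 0) -> ComparatorNetwork:
    """The pair comparator: 2-channel input, 2 output units (same/different)."""
    spec = spec or ArchitectureSpec()
    if spec.input_channels != 2 or spec.output_units != 2:
        raise ConfigurationError(
            "pair network requires input_channels=2 and output_units=2"
        )
    return ComparatorNetwork(spec, seed=seed)


def build_baseline_network(
    spec: ArchitectureSpec | None = None, n_classes: int = 3, seed: int = 0
) -> ComparatorNetwork:
    """The matched direct classifier: 1-channel input, one unit per class.

    Hidden topology is identical to the pair network built from the same
    spec; only the input and output layers differ.
    """
    spec = spec or ArchitectureSpec()
    d = spec.to_dict()
    d["input_channels"] = 1
    d["output_units"] = n_classes
    return ComparatorNetwork(ArchitectureSpec.from_dict(d), seed=seed)


def count_trainable_params(model: ComparatorNetwork) -> int:
    """Total element count over all trainable tensors."""
    return sum(p.size for p in model.params)


def forward_pair(model: ComparatorNetwork, pair_batch: np.ndarray) -> np.ndarray:
    """Per-pair probability 2-vectors, [P(same), P(different)], order kept."""
    pair_batch = np.asarray(pair_batch)
    if pair_batch.ndim == 3:
        pair_batch = pair_batch[None]
    return model.predict_pair_proba(pair_batch)
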