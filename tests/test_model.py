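"""Architecture contracts: channel bookkeeping, parameter counts, outputs."""

import numpy as np
import pytest

from ptcdecode.nn import (
    ArchitectureSpec,
    build_baseline_network,
    build_ptc_network,
    count_trainable_params,
    forward_pair,
    load_model,
)
from ptcdecode.nn.network import ConfigurationError


def closed_form_param_count(spec: ArchitectureSpec) -> int:
    """Independent layer-by-layer parameter count from the architecture description alone.

    conv: (kh*kw*c_in + 1) * f;  batch norm: 2 * channels;
    dense: (n_in + 1) * n_out.  Channel bookkeeping follows the concat
    rule c_i = c_{i-1} + f_i starting at the input channel count.
    """
    kh, kw = spec.kernel
    total = 2 * spec.input_channels  # input batch norm
    c = spec.input_channels
    for f in spec.filters_per_block:
        total += (kh * kw * c + 1) * f  # conv + bias
        c += f
        total += 2 * c  # post-concat batch norm
    total += (kh * kw * c + 1) * spec.reduction_filters
    n_in = spec.reduction_filters * spec.spatial_shape[0] * spec.spatial_shape[1]
    for w in spec.dense_widths:
        total += (n_in + 1) * w
        n_in = w
    total += (n_in + 1) * spec.output_units
    return total


def random_valid_spec(rng: np.random.Generator) -> ArchitectureSpec:
    """A random spec satisfying the 12 → 48 strictly-increasing invariant."""
    n_blocks = int(rng.integers(2, 6))
    inner = sorted(rng.choice(np.arange(13, 48), size=n_blocks - 2, replace=False))
    filters = (12, *map(int, inner), 48)
    paired = bool(rng.integers(0, 2))
    return ArchitectureSpec(
        input_channels=2 if paired else 1,
        spatial_shape=(int(rng.integers(4, 32)), int(rng.integers(4, 38))),
        n_blocks=n_blocks,
        filters_per_block=filters,
        reduction_filters=int(rng.integers(1, 6)),
        dense_widths=(int(rng.integers(8, 65)), int(rng.integers(4, 33))),
        output_units=2 if paired else int(rng.integers(2, 6)),
    )


class TestArchitectureSpec:
    def test_canonical_concat_progression(self):
        assert ArchitectureSpec().concat_channels() == [14, 38, 74, 122]

    def test_baseline_concat_progression(self):
        spec = ArchitectureSpec(input_channels=1, output_units=3)
        assert spec.concat_channels() == [13, 37, 73, 121]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"filters_per_block": (12, 24, 36)},  # length mismatch
            {"filters_per_block": (12, 36, 24, 48)},  # not increasing
            {"filters_per_block": (10, 24, 36, 48)},  # wrong start
            {"output_units": 1},
            {"input_channels": 3},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            ArchitectureSpec(**kwargs)

    def test_round_trips_through_dict(self):
        spec = ArchitectureSpec()
        assert ArchitectureSpec.from_dict(spec.to_dict()) == spec


class TestBuilders:
    def test_block_one_outputs_fourteen_maps(self):
        model = build_ptc_network()
        assert model.block_output_channels(1) == 12 + 2 == 14

    def test_output_unit_counts(self):
        assert build_ptc_network().spec.output_units == 2
        assert build_baseline_network(n_classes=3).spec.output_units == 3

    def test_ptc_builder_rejects_single_input_spec(self):
        spec = ArchitectureSpec(input_channels=1, output_units=3)
        with pytest.raises(ConfigurationError):
            build_ptc_network(spec)

    def test_hidden_shapes_identical_between_ptc_and_baseline(self):
        ptc = build_ptc_network()
        base = build_baseline_network(n_classes=3)
        for (ca, _aa, _ba), (cb, _ab, _bb) in zip(ptc.blocks, base.blocks):
            assert ca.out_channels == cb.out_channels
        assert [d.w.value.shape[1] for d, _a, _dr in ptc.dense] == [
            d.w.value.shape[1] for d, _a, _dr in base.dense
        ]

    def test_spatial_dims_preserved_through_blocks(self):
        spec = ArchitectureSpec(n_blocks=2, filters_per_block=(12, 48))
        model = build_ptc_network(spec, seed=0)
        x = np.random.default_rng(0).normal(size=(3, 2, 31, 37)).astype(np.float32)
        t = model.bn_in.forward(np.ascontiguousarray(x.transpose(0, 2, 3, 1)))
        for conv, act, bn in model.blocks:
            u = act.forward(conv.forward(t))
            assert u.shape[1:3] == (31, 37)
            t = bn.forward(np.concatenate([u, t], axis=-1))
            assert t.shape[1:3] == (31, 37)


class TestParameterCount:
    def test_toy_dense_layer(self):
        # 2 -> 3 dense with bias has 2*3 + 3 = 9 parameters
        from ptcdecode.nn.layers import Dense

        d = Dense(2, 3, np.random.default_rng(0))
        assert sum(p.size for p in d.params) == 9

    def test_canonical_count_matches_closed_form(self):
        spec = ArchitectureSpec()
        assert count_trainable_params(build_ptc_network(spec)) == closed_form_param_count(spec)

    def test_baseline_has_fewer_params_than_ptc(self):
        spec = ArchitectureSpec()
        ptc = count_trainable_params(build_ptc_network(spec))
        base = count_trainable_params(build_baseline_network(spec, n_classes=3))
        assert base < ptc

    def test_twenty_randomized_specs_match_closed_form(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            spec = random_valid_spec(rng)
            model = (
                build_ptc_network(spec)
                if spec.input_channels == 2
                else build_baseline_network(spec, n_classes=spec.output_units)
            )
            assert count_trainable_params(model) == closed_form_param_count(spec)


class TestForward:
    @pytest.fixture(scope="class")
    def small_model(self):
        spec = ArchitectureSpec(
            n_blocks=2, filters_per_block=(12, 48), spatial_shape=(8, 9),
            dense_widths=(16, 8),
        )
        return build_ptc_network(spec, seed=1)

    def test_probabilities_normalized_and_order_preserved(self, small_model):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 2, 8, 9)).astype(np.float32)
        p = forward_pair(small_model, x)
        assert p.shape == (40, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        # order-preserving: evaluating a subset row-by-row gives same rows
        p_sub = forward_pair(small_model, x[5:10])
        np.testing.assert_allclose(p_sub, p[5:10], atol=1e-6)

    def test_single_pair_accepted(self, small_model):
        x = np.zeros((2, 8, 9), dtype=np.float32)
        assert forward_pair(small_model, x).shape == (1, 2)

    def test_shape_mismatch_rejected(self, small_model):
        with pytest.raises(ValueError, match="expected input"):
            small_model.forward(np.zeros((4, 2, 7, 9), dtype=np.float32))

    def test_untrained_mean_p_same_not_degenerate(self, small_model):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1000, 2, 8, 9)).astype(np.float32)
        p_same = forward_pair(small_model, x)[:, 0]
        assert 0.3 < p_same.mean() < 0.7

    def test_save_load_round_trip(self, small_model, tmp_path):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 2, 8, 9)).astype(np.float32)
        before = small_model.predict_proba(x)
        small_model.save(tmp_path / "model")
        back = load_model(tmp_path / "model")
        np.testing.assert_allclose(back.predict_proba(x), before, atol=1e-6)


class TestTrainStep:
    def test_gradient_descent_reduces_loss(self):
        spec = ArchitectureSpec(
            n_blocks=2, filters_per_block=(12, 48), spatial_shape=(6, 7),
            dense_widths=(8, 4), dropout_dense=0.0,
        )
        model = build_ptc_network(spec, seed=0)
        rng = np.random.default_rng(3)
        x = rng.normal(size=(32, 2, 6, 7)).astype(np.float32)
        y = rng.integers(0, 2, 32)
        opt = model.make_optimizer()
        losses = [model.train_step(x, y, opt)[0] for _ in range(30)]
        assert losses[-1] < losses[0]

    def test_overfits_noiseless_pair_set(self):
        """Capacity check: >= 99% training accuracy on 64 clean pairs."""
        spec = ArchitectureSpec(n_blocks=2, filters_per_block=(12, 48))
        model = build_ptc_network(spec, seed=5)
        rng = np.random.default_rng(4)
        patterns = rng.normal(size=(3, 31, 37)).astype(np.float32)
        x = np.empty((64, 2, 31, 37), dtype=np.float32)
        y = np.empty(64, dtype=np.int64)
        for i in range(64):
            a = rng.integers(0, 3)
            same = rng.integers(0, 2) == 0
            b = a if same else (a + 1 + rng.integers(0, 2)) % 3
            x[i, 0], x[i, 1] = patterns[a], patterns[b]
            y[i] = 0 if same else 1
        opt = model.make_optimizer()
        acc = 0.0
        for _step in range(500):
            _loss, acc = model.train_step(x, y, opt)
            if acc >= 0.99:
                break
        assert acc >= 0.99


class TestConvPaths:
    def test_fused_and_im2col_convolutions_agree(self):
        """The shift-accumulate path used for many-channel/few-filter
        layers matches the im2col path bit-for-bit to float32 tolerance."""
        from ptcdecode.nn.layers import Conv2d

        rng = np.random.default_rng(0)
        fused = Conv2d(62, 3, (3, 3), np.random.default_rng(5))
        assert fused._fused
        plain = Conv2d(62, 3, (3, 3), np.random.default_rng(5))
        plain.__class__ = type("NoFuse", (Conv2d,), {"_fused": property(lambda s: False)})
        x = rng.normal(size=(3, 11, 13, 62)).astype(np.float32)
        y1 = fused.forward(x, train=True)
        y2 = plain.forward(x, train=True)
        np.testing.assert_allclose(y1, y2, atol=1e-4)
        dy = rng.normal(size=y1.shape).astype(np.float32)
        dx1, dx2 = fused.backward(dy), plain.backward(dy)
        np.testing.assert_allclose(dx1, dx2, atol=1e-4)
        np.testing.assert_allclose(fused.w.grad, plain.w.grad, atol=1e-3)
        np.testing.assert_allclose(fused.b.grad, plain.b.grad, atol=1e-4)
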