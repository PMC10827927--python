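import numpy as np
import pytest

import ertnet.nn as nn
from ertnet import (EEGNetBaseline, ERTNet, ERTNetConfig,
                    min_detectable_frequency, multi_head_attention,
                    parameter_count, positional_encoding)
from ertnet.model import ConfigError

from .conftest import tiny_model_config
from .oracles import ertnet_forward_loops, mha_loops


def model_params_as_lists(model):
    pd = model.param_dict
    bn = model._bn_layers()
    c = model.config
    blocks = []
    for b in range(c.n_blocks):
        blocks.append({
            "wq": pd[f"block{b}.mha.Wq"].value.tolist(),
            "wk": pd[f"block{b}.mha.Wk"].value.tolist(),
            "wv": pd[f"block{b}.mha.Wv"].value.tolist(),
            "wo": pd[f"block{b}.mha.Wo"].value.tolist(),
            "ln1_gamma": pd[f"block{b}.ln1.gamma"].value.tolist(),
            "ln1_beta": pd[f"block{b}.ln1.beta"].value.tolist(),
            "ln2_gamma": pd[f"block{b}.ln2.gamma"].value.tolist(),
            "ln2_beta": pd[f"block{b}.ln2.beta"].value.tolist(),
            "ff_w": pd[f"block{b}.ff.W"].value.tolist(),
            "ff_b": pd[f"block{b}.ff.b"].value.tolist(),
        })
    out = {
        "temporal": pd["temporal.W"].value.tolist(),
        "spatial": pd["spatial.W"].value.tolist(),
        "sep_depthwise": pd["sep.depthwise.W"].value.tolist(),
        "sep_pointwise": pd["sep.pointwise.W"].value.tolist(),
        "blocks": blocks,
        "head_w": pd["head.W"].value.tolist(),
        "head_b": pd["head.b"].value.tolist(),
    }
    for i in (1, 2, 3):
        layer = bn[f"bn{i}"]
        out[f"bn{i}_mean"] = layer.running_mean.tolist()
        out[f"bn{i}_var"] = layer.running_var.tolist()
        out[f"bn{i}_gamma"] = layer.gamma.value.tolist()
        out[f"bn{i}_beta"] = layer.beta.value.tolist()
    return out


class TestConfig:
    def test_f2_is_always_f1_times_d(self):
        cfg = ERTNetConfig(n_channels=32, n_samples=512, n_classes=4,
                           f1=8, kernel_length=64, depth=4)
        assert cfg.f2 == 32
        with pytest.raises(ConfigError):
            ERTNetConfig(n_channels=32, n_samples=512, n_classes=4,
                         f1=8, kernel_length=64, depth=4, f2=31)

    def test_kernel_longer_than_epoch_rejected(self):
        with pytest.raises(ConfigError):
            ERTNetConfig(n_channels=4, n_samples=32, n_classes=2,
                         f1=2, kernel_length=64, depth=2)

    def test_token_sequence_shape(self):
        cfg = ERTNetConfig(n_channels=32, n_samples=512, n_classes=4,
                           f1=8, kernel_length=64, depth=4,
                           pool1=4, pool2=8)
        assert cfg.sequence_length == 16
        assert cfg.f2 == 32


class TestForward:
    def test_softmax_rows_sum_to_one(self):
        model = ERTNet(tiny_model_config(), seed=0)
        x = np.random.default_rng(0).normal(size=(5, 8, 64))
        probs = model.predict_proba(x)
        assert probs.shape == (5, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_matches_straight_loop_reimplementation(self):
        """Full eval-mode forward equals a dependency-free loop oracle."""
        cfg = ERTNetConfig(n_channels=4, n_samples=32, n_classes=2, f1=2,
                           kernel_length=8, depth=2, pool1=2, pool2=4,
                           n_heads=2, sep_kernel_length=4, dropout=0.0)
        model = ERTNet(cfg, seed=5)
        rng = np.random.default_rng(5)
        # randomize batch-norm running statistics so the check is not
        # trivially exercising mean 0 / var 1
        for bn in model._bn_layers().values():
            bn.running_mean = rng.normal(0, 0.3, bn.running_mean.shape)
            bn.running_var = rng.uniform(0.5, 1.5, bn.running_var.shape)
        x = rng.normal(size=(4, 32))
        got = model.forward(x)[0]
        expected = ertnet_forward_loops(
            x.tolist(), model_params_as_lists(model),
            {"f1": 2, "depth": 2, "f2": 4, "pool1": 2, "pool2": 4,
             "n_heads": 2, "n_blocks": 1, "alpha": 1.0})
        np.testing.assert_allclose(got, expected, atol=1e-4)

    def test_permutation_sensitivity_is_due_to_positional_encoding(self):
        """With PE, token order matters; without it the GAP head makes the
        logits permutation-invariant."""
        cfg = tiny_model_config(dropout=0.0)
        model = ERTNet(cfg, seed=1)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 8, 64))
        # capture tokens entering the transformer and permute them
        import ertnet.nn as _nn
        idx_pe = next(i for i, l in enumerate(model.net.layers)
                      if isinstance(l, _nn.AddPositionalEncoding))

        def logits_with_permutation(perm, use_pe):
            h = x
            for i, layer in enumerate(model.net.layers):
                if i == idx_pe:
                    h = h[:, perm, :]
                    if use_pe:
                        h = layer.forward(h, False)
                    continue
                h = layer.forward(h, False)
            return h

        perm = rng.permutation(cfg.sequence_length)
        base_pe = logits_with_permutation(np.arange(cfg.sequence_length), True)
        shuf_pe = logits_with_permutation(perm, True)
        assert np.abs(base_pe - shuf_pe).max() > 1e-6
        base = logits_with_permutation(np.arange(cfg.sequence_length), False)
        shuf = logits_with_permutation(perm, False)
        np.testing.assert_allclose(base, shuf, atol=1e-5)

    def test_separable_conv_composes_depthwise_then_pointwise(self):
        rng = np.random.default_rng(2)
        dw = nn.DepthwiseTemporalConv(3, 5, rng)
        pw = nn.PointwiseConv(3, 3, rng)
        x = rng.normal(size=(2, 3, 16))
        composed = pw.forward(dw.forward(x, False), False)
        # explicit composition: correlate each map, then mix maps
        manual = np.zeros_like(composed)
        left = (5 - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (left, 5 - 1 - left)))
        for b in range(2):
            for g in range(3):
                for s in range(16):
                    acc = 0.0
                    for m in range(3):
                        conv = sum(dw.W.value[m, t] * xp[b, m, s + t]
                                   for t in range(5))
                        acc += pw.W.value[g, m] * conv
                    manual[b, g, s] = acc
        np.testing.assert_allclose(composed, manual, atol=1e-6)

    def test_gradients_match_finite_differences(self):
        cfg = ERTNetConfig(n_channels=3, n_samples=32, n_classes=3, f1=2,
                           kernel_length=5, depth=2, pool1=2, pool2=2,
                           n_heads=2, dropout=0.0, sep_kernel_length=4)
        model = ERTNet(cfg, seed=1)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 3, 32))
        y = np.array([0, 1, 2, 1])

        def loss():
            l, _, _ = nn.softmax_cross_entropy(
                model.forward(x, training=True), y)
            return l

        for p in model.params:
            p.grad[...] = 0.0
        l, _, dl = nn.softmax_cross_entropy(model.forward(x, training=True), y)
        model.net.backward(dl)
        eps = 1e-6
        for p in model.params:
            flat = p.value.ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size),
                                replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                assert abs((lp - lm) / (2 * eps) - p.grad.ravel()[i]) < 1e-6, \
                    p.name


class TestMultiHeadAttention:
    def test_matches_loop_oracle_over_many_trials(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            x = rng.normal(size=(3, 4))
            wq = rng.normal(size=(2, 4, 4))
            wk = rng.normal(size=(2, 4, 4))
            wv = rng.normal(size=(2, 4, 4))
            wo = rng.normal(size=(8, 4))
            got = multi_head_attention(x, wq, wk, wv, wo)
            expected = mha_loops(x.tolist(), wq.tolist(), wk.tolist(),
                                 wv.tolist(), wo.tolist())
            np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_single_token_reduces_to_value_projection(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 4))
        wq, wk = rng.normal(size=(2, 2, 4, 4))
        wv = rng.normal(size=(2, 4, 4))
        wo = rng.normal(size=(8, 4))
        got = multi_head_attention(x, wq, wk, wv, wo)
        concat = np.concatenate([x @ wv[h] for h in range(2)], axis=1)
        np.testing.assert_allclose(got, concat @ wo, atol=1e-10)

    def test_zero_query_key_gives_uniform_attention(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(5, 4))
        wv = rng.normal(size=(2, 4, 4))
        wo = rng.normal(size=(8, 4))
        zeros = np.zeros((2, 4, 4))
        got = multi_head_attention(x, zeros, zeros, wv, wo)
        mean_token = x.mean(axis=0, keepdims=True)
        expected_row = np.concatenate(
            [mean_token @ wv[h] for h in range(2)], axis=1) @ wo
        np.testing.assert_allclose(got, np.repeat(expected_row, 5, axis=0),
                                   atol=1e-10)

    def test_attention_rows_conserve_probability(self):
        rng = np.random.default_rng(5)
        layer = nn.MultiHeadAttention(3, 4, rng)
        for _ in range(50):
            x = rng.normal(size=(2, 6, 4)) * rng.uniform(0.1, 10)
            layer.forward(x, False)
            np.testing.assert_allclose(layer._attn.sum(axis=-1), 1.0,
                                       atol=1e-6)


class TestTransformerBlock:
    def _block(self, seed=0, width=4, heads=2):
        rng = np.random.default_rng(seed)
        mha = nn.MultiHeadAttention(heads, width, rng)
        ln1 = nn.LayerNorm(width)
        ff = nn.Sequential([nn.Dense(width, width, rng), nn.ELU()])
        ln2 = nn.LayerNorm(width)
        return nn.Sequential([nn.Residual(mha, ln1), nn.Residual(ff, ln2)])

    def test_shape_preserved_for_any_length(self):
        block = self._block()
        rng = np.random.default_rng(1)
        for d in (1, 3, 9):
            x = rng.normal(size=(2, d, 4))
            assert block.forward(x, False).shape == x.shape

    def test_layer_norm_standardizes_rows(self):
        ln = nn.LayerNorm(8)
        x = np.random.default_rng(2).normal(2.0, 3.0, size=(4, 5, 8))
        y = ln.forward(x, False)
        np.testing.assert_allclose(y.mean(axis=-1), 0.0, atol=1e-6)
        np.testing.assert_allclose(y.var(axis=-1), 1.0, atol=1e-3)

    def test_zeroed_weights_make_block_identity_like(self):
        block = self._block(seed=3)
        for layer in block.layers:
            for p in layer.params:
                if not p.name.endswith("gamma"):
                    p.value[...] = 0.0
        # with gamma untouched=1, residual of a zero branch is layer-norm(x)
        x = np.random.default_rng(3).normal(size=(1, 4, 4))
        y = block.forward(x, False)
        ln = nn.LayerNorm(4)
        expected = ln.forward(ln.forward(x, False), False)
        np.testing.assert_allclose(y, expected, atol=1e-10)


class TestPositionalEncoding:
    def test_first_row_and_range(self):
        pe = positional_encoding(7, 6)
        np.testing.assert_allclose(pe[0, 0::2], 0.0)
        np.testing.assert_allclose(pe[0, 1::2], 1.0)
        assert np.all(np.abs(pe) <= 1.0)

    def test_rows_are_distinct(self):
        pe = positional_encoding(64, 8)
        dists = np.linalg.norm(pe[:, None] - pe[None, :], axis=-1)
        assert dists[~np.eye(64, dtype=bool)].min() > 1e-6


class TestBookkeeping:
    def test_min_detectable_frequency(self):
        assert min_detectable_frequency(128, 64) == pytest.approx(2.0)
        assert min_detectable_frequency(200, 14) == pytest.approx(14.2857,
                                                                  abs=1e-3)
        assert min_detectable_frequency(123.0, 1) == 123.0
        with pytest.raises(ValueError):
            min_detectable_frequency(128, 0)

    def test_parameter_count_itemization(self):
        cfg = tiny_model_config()
        model = ERTNet(cfg, seed=0)
        total, items = parameter_count(model)
        assert items["temporal.W"] == cfg.f1 * cfg.kernel_length
        assert items["spatial.W"] == cfg.f1 * cfg.depth * cfg.n_channels
        assert items["block0.mha.Wq"] == cfg.n_heads * cfg.f2 ** 2
        assert items["block0.mha.Wo"] == cfg.n_heads * cfg.f2 * cfg.f2
        assert total == sum(items.values())

    def test_elu_definition(self):
        assert nn.elu(np.array(0.0)) == 0.0
        assert nn.elu(np.array(1.0)) == 1.0
        assert nn.elu(np.array(-1.0)) == pytest.approx(np.expm1(-1.0))
        assert nn.elu(np.array(-50.0), alpha=2.0) == pytest.approx(-2.0,
                                                                   abs=1e-6)

    def test_checkpoint_round_trip(self, tmp_path):
        model = ERTNet(tiny_model_config(), seed=9, dtype=np.float32)
        x = np.random.default_rng(0).normal(size=(3, 8, 64))
        before = model.forward(x)
        path = model.save(tmp_path / "ck.npz")
        from ertnet.model import _SoftmaxClassifier
        clone = _SoftmaxClassifier.load(path)
        assert isinstance(clone, ERTNet)
        np.testing.assert_array_equal(before, clone.forward(x))

    def test_eegnet_baseline_shares_extraction_names(self):
        cfg = tiny_model_config()
        a = ERTNet(cfg, seed=0)
        b = EEGNetBaseline(cfg, seed=0)
        ert_names = {p.name for p in a.params}
        eeg_names = {p.name for p in b.params}
        shared = {n for n in ert_names & eeg_names
                  if n.split(".")[0] in ("temporal", "bn1", "spatial",
                                         "bn2", "sep", "bn3")}
        assert "temporal.W" in shared and "sep.pointwise.W" in shared
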