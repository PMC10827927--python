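"""The ERTNet architecture: EEGNet-style feature extraction followed by a
transformer encoder block and a global-average-pooled softmax head.

Layer order (fixed):

1. temporal convolution, F1 kernels of length T, same padding, *no*
   activation (keeps the kernels interpretable as linear filters), batch
   norm;
2. depthwise spatial convolution across all C electrodes with depth
   multiplier D (collapses the channel axis), batch norm, ELU;
3. average pool (length 4 by default), dropout;
4. separable convolution to F2 = F1 x D maps (depthwise temporal +
   pointwise mixing), batch norm, ELU, average pool (length 8), dropout;
5. squeeze/transpose to a token sequence [d x F2], add fixed sinusoidal
   positional encoding;
6. n_blocks transformer encoder blocks: full-width multi-head
   self-attention (each head's projections are F2 x F2; the concatenated
   heads are projected by W^O of shape [n*F2, F2]) with residual + layer
   norm, then a single ELU feed-forward layer with residual + layer norm;
7. global average pooling over tokens, dense softmax over K classes.

Convolution biases are disabled (each conv feeds a batch norm).
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import (AddPositionalEncoding, Adam, AvgPool, BatchNorm, Dense,
                 DepthwiseSpatialConv, DepthwiseTemporalConv, Dropout, ELU,
                 GlobalAveragePool, LayerNorm, MultiHeadAttention, Param,
                 PointwiseConv, Residual, Sequential, TemporalConv, ToTokens,
                 multi_head_attention, positional_encoding)

__all__ = [
    "ERTNetConfig", "ERTNet", "EEGNetBaseline", "min_detectable_frequency",
    "parameter_count", "multi_head_attention", "positional_encoding",
    "EXTRACTION_PREFIXES",
]


class ConfigError(ValueError):
    pass


#: parameter-name prefixes forming the transferable feature extractor
EXTRACTION_PREFIXES = ("temporal", "bn1", "spatial", "bn2", "sep", "bn3")


@dataclass(frozen=True)
class ERTNetConfig:
    """Every architectural symbol in one place.

    F2 is tied to F1 * D; passing an inconsistent value raises.  Dropout
    defaults to the subject-dependent setting 0.5 (use 0.25 for
    subject-independent protocols).
    """

    n_channels: int
    n_samples: int
    n_classes: int
    f1: int = 8
    kernel_length: int = 64       # T, in samples
    depth: int = 4                # D, spatial kernels per temporal kernel
    f2: int | None = None         # pointwise kernels; always F1 * D
    pool1: int = 4
    pool2: int = 8
    n_heads: int = 8
    n_blocks: int = 1
    dropout: float = 0.5
    transformer_dropout: float = 0.0
    elu_alpha: float = 1.0
    sep_kernel_length: int = 16
    ff_dim: int | None = None     # single-layer feed-forward width (= F2)

    def __post_init__(self) -> None:
        if self.f2 is None:
            object.__setattr__(self, "f2", self.f1 * self.depth)
        elif self.f2 != self.f1 * self.depth:
            raise ConfigError(
                f"F2 must equal F1 x D = {self.f1 * self.depth}, got {self.f2}")
        if self.ff_dim is None:
            object.__setattr__(self, "ff_dim", self.f2)
        elif self.ff_dim != self.f2:
            raise ConfigError("single-layer feed-forward requires ff_dim == F2")
        if self.kernel_length > self.n_samples:
            raise ConfigError("kernel length T exceeds epoch length S")
        if self.kernel_length < 1 or self.f1 < 1 or self.depth < 1:
            raise ConfigError("F1, T, D must be positive")
        if self.n_heads < 1 or self.n_blocks < 0:
            raise ConfigError("need n_heads >= 1 and n_blocks >= 0")
        if self.sequence_length < 1:
            raise ConfigError(
                "pooling leaves no tokens: S // pool1 // pool2 == 0")
        if not 0 <= self.dropout < 1:
            raise ConfigError("dropout must be in [0, 1)")

    @property
    def sequence_length(self) -> int:
        """Token count d after both pooling stages (remainders truncated)."""
        return self.n_samples // self.pool1 // self.pool2


def min_detectable_frequency(sampling_rate: float, kernel_length: int) -> float:
    """Lowest frequency a length-T temporal kernel can resolve: Sr / T.

    A kernel shorter than one period of an oscillation cannot represent it,
    so band-limited class information below Sr/T is invisible to the
    temporal filter bank.
    """
    if kernel_length < 1:
        raise ValueError("kernel_length must be >= 1")
    return sampling_rate / kernel_length


class _SoftmaxClassifier:
    """Shared machinery: forward, loss/grad, prediction, checkpointing."""

    config: ERTNetConfig
    net: Sequential

    def __init__(self, config: ERTNetConfig, seed: int = 0,
                 dtype=np.float64):
        self.config = config
        self.seed = seed
        self.dtype = np.dtype(dtype)
        self._init_rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 7919]))
        self.net = Sequential(self._build(self._init_rng))
        for p in self.net.params:
            p.value = p.value.astype(self.dtype)
            p.grad = np.zeros_like(p.value)
        for bn in self._bn_layers().values():
            bn.running_mean = bn.running_mean.astype(self.dtype)
            bn.running_var = bn.running_var.astype(self.dtype)

    # subclasses implement _build
    def _build(self, rng) -> list[nn.Layer]:  # pragma: no cover
        raise NotImplementedError

    def _extraction_layers(self, rng) -> list[nn.Layer]:
        c = self.config
        return [
            TemporalConv(c.f1, c.kernel_length, rng, name="temporal"),
            BatchNorm(c.f1, name="bn1"),
            DepthwiseSpatialConv(c.f1, c.depth, c.n_channels, rng,
                                 name="spatial"),
            BatchNorm(c.f2, name="bn2"),
            ELU(c.elu_alpha),
            AvgPool(c.pool1),
            Dropout(c.dropout, self._dropout_rng),
            DepthwiseTemporalConv(c.f2, min(c.sep_kernel_length,
                                            c.n_samples // c.pool1),
                                  rng, name="sep.depthwise"),
            PointwiseConv(c.f2, c.f2, rng, name="sep.pointwise"),
            BatchNorm(c.f2, name="bn3"),
            ELU(c.elu_alpha),
            AvgPool(c.pool2),
            Dropout(c.dropout, self._dropout_rng),
        ]

    # ------------------------------------------------------------------
    @property
    def params(self) -> list[Param]:
        return self.net.params

    @property
    def param_dict(self) -> dict[str, Param]:
        return {p.name: p for p in self.net.params}

    def _bn_layers(self) -> dict[str, BatchNorm]:
        out = {}
        def walk(layer):
            if isinstance(layer, BatchNorm):
                out[layer.gamma.name.rsplit(".", 1)[0]] = layer
            for child in getattr(layer, "layers", []):
                walk(child)
            if isinstance(layer, Residual):
                walk(layer.inner)
                walk(layer.norm)
        walk(self.net)
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        return self.net.forward(x, training)

    def loss_and_grad(self, x: np.ndarray, labels: np.ndarray
                      ) -> tuple[float, np.ndarray]:
        logits = self.forward(x, training=True)
        loss, probs, dlogits = nn.softmax_cross_entropy(logits, labels)
        self.net.backward(dlogits)
        return loss, probs

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        chunks = [nn._softmax_last(self.forward(x[i:i + batch_size]))
                  for i in range(0, len(x), batch_size)]
        return np.concatenate(chunks)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    # ------------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params}
        for name, bn in self._bn_layers().items():
            state[f"{name}.running_mean"] = bn.running_mean.copy()
            state[f"{name}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        pd = self.param_dict
        for name, value in state.items():
            if name.endswith((".running_mean", ".running_var")):
                bn_name, attr = name.rsplit(".", 1)
                setattr(self._bn_layers()[bn_name], attr,
                        value.astype(self.dtype))
            else:
                if pd[name].value.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name}")
                pd[name].value[...] = value

    def save(self, path) -> Path:
        """Portable checkpoint: config JSON + named weight arrays (npz)."""
        path = Path(path)
        payload = {"__config__": np.frombuffer(
            json.dumps({"config": asdict(self.config), "seed": self.seed,
                        "dtype": self.dtype.name,
                        "class": type(self).__name__}).encode(), dtype=np.uint8)}
        payload.update(self.state_dict())
        buf = _stdio.BytesIO()
        np.savez(buf, **payload)
        path.write_bytes(buf.getvalue())
        return path

    @classmethod
    def load(cls, path) -> "_SoftmaxClassifier":
        with np.load(Path(path), allow_pickle=False) as z:
            meta = json.loads(bytes(z["__config__"].tobytes()).decode())
            state = {k: z[k] for k in z.files if k != "__config__"}
        klass = {"ERTNet": ERTNet, "EEGNetBaseline": EEGNetBaseline}[
            meta["class"]]
        model = klass(ERTNetConfig(**meta["config"]), seed=meta["seed"],
                      dtype=np.dtype(meta.get("dtype", "float64")))
        model.load_state_dict(state)
        return model


class ERTNet(_SoftmaxClassifier):
    """Convolution + transformer emotion classifier (see module docstring)."""

    def _build(self, rng):
        c = self.config
        layers = self._extraction_layers(rng)
        layers += [ToTokens(), AddPositionalEncoding()]
        for b in range(c.n_blocks):
            mha = MultiHeadAttention(c.n_heads, c.f2, rng,
                                     name=f"block{b}.mha")
            layers.append(Residual(mha, LayerNorm(c.f2, name=f"block{b}.ln1")))
            ff = Sequential([
                Dense(c.f2, c.f2, rng, name=f"block{b}.ff"),
                ELU(c.elu_alpha),
            ])
            if c.transformer_dropout > 0:
                ff.layers.append(Dropout(c.transformer_dropout,
                                         self._dropout_rng))
            layers.append(Residual(ff, LayerNorm(c.f2, name=f"block{b}.ln2")))
        layers += [GlobalAveragePool(),
                   Dense(c.f2, c.n_classes, rng, name="head")]
        return layers


class _Flatten(nn.Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class EEGNetBaseline(_SoftmaxClassifier):
    """EEGNet-style head: the identical extraction stack followed by
    flatten + dense.  Shipped as the transfer-learning source: its
    extraction weights drop bit-exactly into an ERTNet with matching
    (C, F1, T, D)."""

    def _build(self, rng):
        c = self.config
        flat = c.f2 * c.sequence_length
        return self._extraction_layers(rng) + [
            _Flatten(), Dense(flat, c.n_classes, rng, name="head")]


def parameter_count(model: _SoftmaxClassifier) -> tuple[int, dict[str, int]]:
    """Exact trainable-parameter total, itemized by parameter name."""
    itemized = {p.name: p.size for p in model.params}
    return sum(itemized.values()), itemized


def make_optimizer(model: _SoftmaxClassifier, lr: float = 1e-3) -> Adam:
    return Adam(model.params, lr=lr)
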