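"""Minimal neural-network layer engine on numpy.

Reverse-mode gradients are derived per layer (each layer caches what its
backward pass needs), which keeps the engine small and auditable: the
architecture uses a fixed repertoire — temporal / depthwise-spatial /
separable convolutions, batch normalization, ELU, average pooling,
dropout, full-width multi-head self-attention, layer normalization, dense
layers and global average pooling.  All convolutions are cross-correlations
with "same" zero padding (left pad = (T-1)//2), stride 1, bias-free when a
batch norm follows.

Shapes: the extraction stack runs on [B, C, S] / [B, F, C, S] / [B, F, S];
the transformer part on token sequences [B, d, F].
"""

from __future__ import annotations

import math

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft


class Param:
    """A named trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


def glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def elu(x: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """x for x > 0, alpha * (exp(x) - 1) otherwise; continuous at 0."""
    return np.where(x > 0, x, alpha * np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(x > 0, 1.0, y + alpha)


def positional_encoding(d: int, width: int) -> np.ndarray:
    """Fixed sinusoidal table: PE[p, 2i] = sin(p / 10000^(2i/width)),
    PE[p, 2i+1] = cos(p / 10000^(2i/width))."""
    if d < 1 or width < 1:
        raise ValueError("d and width must be >= 1")
    pe = np.empty((d, width))
    pos = np.arange(d)[:, None]
    idx = np.arange(width)
    denom = np.power(10000.0, (idx - idx % 2) / width)  # exponent 2i for the pair
    arg = pos / denom[None, :]
    pe[:, 0::2] = np.sin(arg[:, 0::2])
    pe[:, 1::2] = np.cos(arg[:, 1::2])
    return pe


class Layer:
    params: list[Param]

    def __init__(self):
        self.params = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _same_pad(T: int) -> tuple[int, int]:
    left = (T - 1) // 2
    return left, T - 1 - left


class TemporalConv(Layer):
    """[B, C, S] -> [B, F1, C, S]; one bank of F1 length-T kernels applied
    along time (cross-correlation, same padding), shared across channels.

    Computed by FFT (exact up to rounding): the same-padded input has
    length S + T - 1, so a transform of length >= S + T - 1 makes circular
    correlation equal linear correlation.
    """

    def __init__(self, f1: int, t: int, rng: np.random.Generator,
                 name: str = "temporal"):
        super().__init__()
        self.t = t
        self.W = Param(f"{name}.W", glorot_uniform(rng, (f1, t), t, t))
        self.params = [self.W]

    def forward(self, x, training):
        T = self.t
        left, right = _same_pad(T)
        S = x.shape[-1]
        self._S = S
        self._N = next_fast_len(S + T - 1)
        xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
        self._xpf = rfft(xp, self._N)                    # B,C,Nf
        wf = rfft(self.W.value, self._N)                 # F,Nf
        prod = self._xpf[:, None, :, :] * wf.conj()[None, :, None, :]
        return irfft(prod, self._N)[..., :S]

    def backward(self, grad):
        T, S, N = self.t, self._S, self._N
        left, _ = _same_pad(T)
        self._gf = rfft(grad, N)                         # B,F,C,Nf
        # dW[f, t] = sum_{b,c,s} grad[b,f,c,s] * xp[b,c,s+t]
        acc = np.einsum("bfcn,bcn->fn", self._gf.conj(), self._xpf,
                        optimize=True)
        self.W.grad += irfft(acc, N)[:, :T]
        # dxp[u] = sum_{f,t} grad[f, u - t] * w[f, t]  (linear convolution)
        wf = rfft(self.W.value, N)                       # F,Nf
        dxpf = np.einsum("bfcn,fn->bcn", self._gf, wf, optimize=True)
        dxp = irfft(dxpf, N)[..., : S + T - 1]
        return dxp[:, :, left:left + S]


class DepthwiseSpatialConv(Layer):
    """[B, F1, C, S] -> [B, F1*D, S]; D spatial weight vectors over all C
    electrodes per temporal map, collapsing the channel axis."""

    def __init__(self, f1: int, d: int, c: int, rng: np.random.Generator,
                 name: str = "spatial"):
        super().__init__()
        self.f1, self.d = f1, d
        self.W = Param(f"{name}.W", glorot_uniform(rng, (f1, d, c), c, d))
        self.params = [self.W]

    def forward(self, x, training):
        self._x = x
        y = np.einsum("bfcs,fjc->bfjs", x, self.W.value, optimize=True)
        b, f, j, s = y.shape
        return y.reshape(b, f * j, s)

    def backward(self, grad):
        b, fj, s = grad.shape
        g4 = grad.reshape(b, self.f1, self.d, s)
        self.W.grad += np.einsum("bfjs,bfcs->fjc", g4, self._x, optimize=True)
        return np.einsum("bfjs,fjc->bfcs", g4, self.W.value, optimize=True)


class DepthwiseTemporalConv(Layer):
    """[B, F, S] -> [B, F, S]; per-map temporal kernel (separable conv,
    depthwise half), FFT-computed like :class:`TemporalConv`."""

    def __init__(self, f: int, t: int, rng: np.random.Generator,
                 name: str = "sep.depthwise"):
        super().__init__()
        self.t = t
        self.W = Param(f"{name}.W", glorot_uniform(rng, (f, t), t, t))
        self.params = [self.W]

    def forward(self, x, training):
        T = self.t
        left, right = _same_pad(T)
        S = x.shape[-1]
        self._S = S
        self._N = next_fast_len(S + T - 1)
        xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
        self._xpf = rfft(xp, self._N)                    # B,F,Nf
        wf = rfft(self.W.value, self._N)                 # F,Nf
        return irfft(self._xpf * wf.conj(), self._N)[..., :S]

    def backward(self, grad):
        T, S, N = self.t, self._S, self._N
        left, _ = _same_pad(T)
        gf = rfft(grad, N)                               # B,F,Nf
        acc = np.einsum("bfn,bfn->fn", gf.conj(), self._xpf, optimize=True)
        self.W.grad += irfft(acc, N)[:, :T]
        wf = rfft(self.W.value, N)
        dxp = irfft(gf * wf, N)[..., : S + T - 1]
        return dxp[:, :, left:left + S]


class PointwiseConv(Layer):
    """[B, F_in, S] -> [B, F_out, S]; 1x1 feature mixing (separable conv,
    pointwise half)."""

    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator,
                 name: str = "sep.pointwise"):
        super().__init__()
        self.W = Param(f"{name}.W",
                       glorot_uniform(rng, (f_out, f_in), f_in, f_out))
        self.params = [self.W]

    def forward(self, x, training):
        self._x = x
        return np.einsum("bfs,gf->bgs", x, self.W.value, optimize=True)

    def backward(self, grad):
        self.W.grad += np.einsum("bgs,bfs->gf", grad, self._x, optimize=True)
        return np.einsum("bgs,gf->bfs", grad, self.W.value, optimize=True)


class BatchNorm(Layer):
    """Normalize over all axes but the feature axis; affine scale/shift.

    Running statistics (exponential average, momentum 0.1) are used at
    evaluation time.
    """

    def __init__(self, n_features: int, feature_axis: int = 1,
                 name: str = "bn", eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.axis = feature_axis
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(f"{name}.gamma", np.ones(n_features))
        self.beta = Param(f"{name}.beta", np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.params = [self.gamma, self.beta]

    def _shape(self, ndim):
        shape = [1] * ndim
        shape[self.axis] = -1
        return shape

    def forward(self, x, training):
        axes = tuple(i for i in range(x.ndim) if i != self.axis)
        shape = self._shape(x.ndim)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(shape)) * self._invstd.reshape(shape)
        self._axes = axes
        self._n = x.size // x.shape[self.axis]
        self._training = training
        return self.gamma.value.reshape(shape) * self._xhat \
            + self.beta.value.reshape(shape)

    def backward(self, grad):
        shape = self._shape(grad.ndim)
        axes = self._axes
        self.gamma.grad += (grad * self._xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        dxhat = grad * self.gamma.value.reshape(shape)
        if not self._training:
            return dxhat * self._invstd.reshape(shape)
        n = self._n
        sum_dxhat = dxhat.sum(axis=axes).reshape(shape)
        sum_dxhat_xhat = (dxhat * self._xhat).sum(axis=axes).reshape(shape)
        return (self._invstd.reshape(shape) / n) * (
            n * dxhat - sum_dxhat - self._xhat * sum_dxhat_xhat)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training):
        self._x = x
        self._y = elu(x, self.alpha)
        return self._y

    def backward(self, grad):
        return grad * _elu_grad(self._x, self._y, self.alpha)


class AvgPool(Layer):
    """Average pooling along the last axis; trailing remainder truncated."""

    def __init__(self, length: int):
        super().__init__()
        self.length = length

    def forward(self, x, training):
        p = self.length
        n_out = x.shape[-1] // p
        self._in_len = x.shape[-1]
        y = x[..., : n_out * p].reshape(*x.shape[:-1], n_out, p).mean(axis=-1)
        return y

    def backward(self, grad):
        p = self.length
        dx = np.zeros(grad.shape[:-1] + (self._in_len,), dtype=grad.dtype)
        dx[..., : grad.shape[-1] * p] = np.repeat(grad / p, p, axis=-1)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class ToTokens(Layer):
    """[B, F, S'] -> [B, S', F]: squeeze + transpose to a token sequence."""

    def forward(self, x, training):
        return np.transpose(x, (0, 2, 1))

    def backward(self, grad):
        return np.transpose(grad, (0, 2, 1))


class AddPositionalEncoding(Layer):
    def forward(self, x, training):
        self._pe = positional_encoding(x.shape[1], x.shape[2]).astype(x.dtype)
        return x + self._pe[None]

    def backward(self, grad):
        return grad


def _softmax_last(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def multi_head_attention(x: np.ndarray, wq: np.ndarray, wk: np.ndarray,
                         wv: np.ndarray, wo: np.ndarray) -> np.ndarray:
    """Full-width multi-head self-attention.

    Each of the n heads projects the [d, F] token matrix with its own
    F x F query/key/value matrices (heads are full feature width, not the
    split-head convention), scores are scaled by sqrt(F), the n head
    outputs are concatenated to [d, n*F] and projected back to F by wo.

    x may be [d, F] or batched [B, d, F]; wq/wk/wv are [n, F, F] and wo is
    [n*F, F].
    """
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    n, F, _ = wq.shape
    scale = 1.0 / math.sqrt(F)
    q = np.einsum("bdf,nfg->bndg", x, wq, optimize=True)
    k = np.einsum("bdf,nfg->bndg", x, wk, optimize=True)
    v = np.einsum("bdf,nfg->bndg", x, wv, optimize=True)
    scores = np.einsum("bndg,bneg->bnde", q, k, optimize=True) * scale
    attn = _softmax_last(scores)
    heads = np.einsum("bnde,bneg->bndg", attn, v, optimize=True)
    b, _, d, _ = heads.shape
    concat = np.transpose(heads, (0, 2, 1, 3)).reshape(b, d, n * F)
    out = concat @ wo
    return out[0] if squeeze else out


class MultiHeadAttention(Layer):
    """Layer wrapper around :func:`multi_head_attention` with gradients."""

    def __init__(self, n_heads: int, width: int, rng: np.random.Generator,
                 name: str = "mha"):
        super().__init__()
        self.n, self.F = n_heads, width
        def mk(nm, shape, fi, fo):
            return Param(f"{name}.{nm}", glorot_uniform(rng, shape, fi, fo))
        self.Wq = mk("Wq", (n_heads, width, width), width, width)
        self.Wk = mk("Wk", (n_heads, width, width), width, width)
        self.Wv = mk("Wv", (n_heads, width, width), width, width)
        self.Wo = mk("Wo", (n_heads * width, width), n_heads * width, width)
        self.params = [self.Wq, self.Wk, self.Wv, self.Wo]

    def forward(self, x, training):
        n, F = self.n, self.F
        self._x = x
        scale = 1.0 / math.sqrt(F)
        self._q = np.einsum("bdf,nfg->bndg", x, self.Wq.value, optimize=True)
        self._k = np.einsum("bdf,nfg->bndg", x, self.Wk.value, optimize=True)
        self._v = np.einsum("bdf,nfg->bndg", x, self.Wv.value, optimize=True)
        scores = np.einsum("bndg,bneg->bnde", self._q, self._k,
                           optimize=True) * scale
        self._attn = _softmax_last(scores)
        heads = np.einsum("bnde,bneg->bndg", self._attn, self._v,
                          optimize=True)
        b, _, d, _ = heads.shape
        self._concat = np.transpose(heads, (0, 2, 1, 3)).reshape(b, d, n * F)
        return self._concat @ self.Wo.value

    def backward(self, grad):
        n, F = self.n, self.F
        b, d, _ = grad.shape
        scale = 1.0 / math.sqrt(F)
        self.Wo.grad += np.einsum("bdm,bdf->mf", self._concat, grad,
                                  optimize=True)
        dconcat = grad @ self.Wo.value.T
        dheads = np.transpose(dconcat.reshape(b, d, n, F), (0, 2, 1, 3))
        dattn = np.einsum("bndg,bneg->bnde", dheads, self._v, optimize=True)
        dv = np.einsum("bnde,bndg->bneg", self._attn, dheads, optimize=True)
        # softmax backward (rows of attn)
        tmp = (dattn * self._attn).sum(axis=-1, keepdims=True)
        dscores = self._attn * (dattn - tmp)
        dq = np.einsum("bnde,bneg->bndg", dscores, self._k,
                       optimize=True) * scale
        dk = np.einsum("bnde,bndg->bneg", dscores, self._q,
                       optimize=True) * scale
        x = self._x
        self.Wq.grad += np.einsum("bdf,bndg->nfg", x, dq, optimize=True)
        self.Wk.grad += np.einsum("bdf,bndg->nfg", x, dk, optimize=True)
        self.Wv.grad += np.einsum("bdf,bndg->nfg", x, dv, optimize=True)
        dx = np.einsum("bndg,nfg->bdf", dq, self.Wq.value, optimize=True)
        dx += np.einsum("bndg,nfg->bdf", dk, self.Wk.value, optimize=True)
        dx += np.einsum("bndg,nfg->bdf", dv, self.Wv.value, optimize=True)
        return dx


class LayerNorm(Layer):
    """Normalize each token (last axis) to zero mean, unit variance, then
    apply the learned affine."""

    def __init__(self, width: int, name: str = "ln", eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Param(f"{name}.gamma", np.ones(width))
        self.beta = Param(f"{name}.beta", np.zeros(width))
        self.params = [self.gamma, self.beta]

    def forward(self, x, training):
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._invstd
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad):
        F = grad.shape[-1]
        self.gamma.grad += (grad * self._xhat).sum(axis=tuple(range(grad.ndim - 1)))
        self.beta.grad += grad.sum(axis=tuple(range(grad.ndim - 1)))
        dxhat = grad * self.gamma.value
        s1 = dxhat.sum(axis=-1, keepdims=True)
        s2 = (dxhat * self._xhat).sum(axis=-1, keepdims=True)
        return (self._invstd / F) * (F * dxhat - s1 - self._xhat * s2)


class Dense(Layer):
    """Affine map on the last axis."""

    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator,
                 name: str = "dense", bias: bool = True):
        super().__init__()
        self.W = Param(f"{name}.W", glorot_uniform(rng, (f_in, f_out),
                                                   f_in, f_out))
        self.b = Param(f"{name}.b", np.zeros(f_out)) if bias else None
        self.params = [self.W] + ([self.b] if bias else [])

    def forward(self, x, training):
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, grad):
        flat_x = self._x.reshape(-1, self._x.shape[-1])
        flat_g = grad.reshape(-1, grad.shape[-1])
        self.W.grad += flat_x.T @ flat_g
        if self.b is not None:
            self.b.grad += flat_g.sum(axis=0)
        return grad @ self.W.value.T


class GlobalAveragePool(Layer):
    """[B, d, F] -> [B, F]: mean over the token axis."""

    def forward(self, x, training):
        self._d = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return np.repeat(grad[:, None, :], self._d, axis=1) / self._d


class Residual(Layer):
    """y = LayerNorm(x + inner(x)) — the transformer sub-block pattern."""

    def __init__(self, inner: Layer, norm: LayerNorm):
        super().__init__()
        self.inner = inner
        self.norm = norm
        self.params = inner.params + norm.params

    def forward(self, x, training):
        return self.norm.forward(x + self.inner.forward(x, training), training)

    def backward(self, grad):
        g = self.norm.backward(grad)
        return g + self.inner.backward(g)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers
        self.params = [p for l in layers for p in l.params]

    def forward(self, x, training):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy over the batch; returns (loss, probs, dlogits)."""
    probs = _softmax_last(logits)
    b = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(b), labels] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(b), labels] -= 1.0
    return float(loss), probs, dlogits / b


class Adam:
    """Adam optimizer (beta1 0.9, beta2 0.999) with optional decoupled
    weight decay (applied directly to the weights, not through the
    moments).  Decay prunes redundant filters: a kernel duplicating
    another's function receives vanishing loss gradient and shrinks."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.l1_params: list[Param] = []
        self.l1_strength = 0.0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            if self.weight_decay > 0:
                p.value -= self.lr * self.weight_decay * p.value
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
        for p in self.l1_params:
            # proximal soft-threshold (sparsity on batch-norm scales:
            # branches whose scale is not defended by the loss collapse to 0)
            thr = self.lr * self.l1_strength
            p.value[...] = np.sign(p.value) * np.maximum(
                np.abs(p.value) - thr, 0.0)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
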