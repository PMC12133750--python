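"""Neural-network layers and optimiser built on the autodiff engine.

Layers hold their parameters as ``Tensor`` objects with
``requires_grad=True`` and expose them through ``parameters()``.
Initialisation is Glorot-uniform from a caller-supplied seeded
generator, so a model built twice from the same seed is bit-identical.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv1d, depthwise_conv1d, softmax

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "GRU",
    "MultiHeadSelfAttention",
    "TransformerEncoderLayer",
    "GATLayer",
    "Conv1dLayer",
    "Adam",
    "cross_entropy",
]


class Module:
    """Base class: recursive parameter collection."""

    def parameters(self) -> list[Tensor]:
        def collect(obj) -> list[Tensor]:
            if isinstance(obj, Tensor):
                return [obj] if obj.requires_grad else []
            if isinstance(obj, Module):
                return obj.parameters()
            if isinstance(obj, (list, tuple)):
                out: list[Tensor] = []
                for item in obj:
                    out.extend(collect(item))
                return out
            return []

        params: list[Tensor] = []
        for v in self.__dict__.values():
            params.extend(collect(v))
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _glorot(rng: np.random.Generator, *shape) -> np.ndarray:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.w = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.w
        if self.b is not None:
            out = out + self.b
        return out


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps) ** 0.5 * self.gamma + self.beta


class GRU(Module):
    """Unidirectional GRU over a (batch, time, features) sequence.

    Gates: z = sig(xW_z + hU_z + b_z), r = sig(xW_r + hU_r + b_r),
    n = tanh(xW_n + r*(hU_n) + b_n), h' = (1-z)*n + z*h.  Biases start
    at zero, so an all-zero input keeps the state at zero.
    """

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_hidden = d_hidden
        self.w = Tensor(_glorot(rng, d_in, 3 * d_hidden), requires_grad=True)
        self.u = Tensor(_glorot(rng, d_hidden, 3 * d_hidden), requires_grad=True)
        self.b = Tensor(np.zeros(3 * d_hidden), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        H = self.d_hidden
        xw = x @ self.w + self.b  # one big matmul for all steps
        h = Tensor(np.zeros((B, H)))
        outs = []
        for t in range(T):
            gates_x = xw[:, t, :]
            hu = h @ self.u
            z = (gates_x[:, :H] + hu[:, :H]).sigmoid()
            r = (gates_x[:, H : 2 * H] + hu[:, H : 2 * H]).sigmoid()
            n = (gates_x[:, 2 * H :] + r * hu[:, 2 * H :]).tanh()
            h = (1.0 - z) * n + z * h
            outs.append(h)
        from .autodiff import stack

        return stack(outs, axis=1)  # B x T x H


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, heads: int, rng: np.random.Generator):
        if d_model % heads:
            raise ValueError(f"d_model={d_model} not divisible by heads={heads}")
        self.heads = heads
        self.d_head = d_model // heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self.last_attention: np.ndarray | None = None  # B x heads x T x T

    def __call__(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        h, dh = self.heads, self.d_head

        def split(t: Tensor) -> Tensor:  # B,T,D -> B,h,T,dh
            return t.reshape(B, T, h, dh).transpose((0, 2, 1, 3))

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(dh))
        att = softmax(scores, axis=-1)
        self.last_attention = att.data
        out = (att @ v).transpose((0, 2, 1, 3)).reshape(B, T, D)
        return self.wo(out)


class TransformerEncoderLayer(Module):
    """Pre-norm encoder block: x + MHSA(LN(x)); x + FFN(LN(x))."""

    def __init__(self, d_model: int, heads: int, d_ff: int, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(d_model, heads, rng)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.ff2(self.ff1(self.ln2(x)).relu())


class GATLayer(Module):
    """Graph attention over channels, batched over trials.

    Per head: project node features with W, score each directed pair
    with LeakyReLU(a_src . Wh_i + a_dst . Wh_j), mask to the adjacency
    (positive edge weights enter the softmax as a log-weight prior),
    softmax over each node's neighbourhood, aggregate.  Heads are
    concatenated on hidden layers and averaged on the final layer.
    """

    def __init__(
        self,
        d_in: int,
        d_out: int,
        heads: int,
        rng: np.random.Generator,
        concat_heads: bool = True,
        activation: bool = True,
        leaky_alpha: float = 0.2,
    ):
        self.heads = heads
        self.concat_heads = concat_heads
        self.activation = activation
        self.leaky_alpha = leaky_alpha
        self.w = [Tensor(_glorot(rng, d_in, d_out), requires_grad=True) for _ in range(heads)]
        self.a_src = [Tensor(_glorot(rng, d_out, 1), requires_grad=True) for _ in range(heads)]
        self.a_dst = [Tensor(_glorot(rng, d_out, 1), requires_grad=True) for _ in range(heads)]
        self.last_attention: np.ndarray | None = None  # heads x B x C x C

    def __call__(self, x: Tensor, adjacency: np.ndarray) -> Tensor:
        adj = np.asarray(adjacency, dtype=float)
        C = adj.shape[0]
        if x.shape[-2] != C:
            raise ValueError(f"adjacency size {C} does not match node count {x.shape[-2]}")
        if np.any(adj.sum(axis=1) == 0) or np.any(np.diag(adj) == 0):
            raise ValueError("every node needs a self-loop (softmax over an empty neighbourhood)")
        with np.errstate(divide="ignore"):
            log_prior = np.where(adj > 0, np.log(np.maximum(adj, 1e-30)), -1e9)

        head_outs = []
        atts = []
        for Wh_w, a_s, a_d in zip(self.w, self.a_src, self.a_dst):
            wh = x @ Wh_w  # B x C x d_out
            src = wh @ a_s  # B x C x 1
            dst = wh @ a_d  # B x C x 1
            e = (src + dst.swapaxes(-1, -2)).leaky_relu(self.leaky_alpha)  # B x C x C
            att = softmax(e + log_prior, axis=-1)
            atts.append(att.data)
            head_outs.append(att @ wh)
        self.last_attention = np.stack(atts)
        if self.concat_heads:
            out = concat(head_outs, axis=-1)
        else:
            out = head_outs[0]
            for h in head_outs[1:]:
                out = out + h
            out = out * (1.0 / len(head_outs))
        return out.leaky_relu(self.leaky_alpha) if self.activation else out


class Conv1dLayer(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator, padding: int | None = None):
        if not 3 <= kernel <= 5:
            raise ValueError(f"kernel size {kernel} outside the supported 3-5 range")
        limit = np.sqrt(6.0 / (c_in * kernel + c_out))
        self.w = Tensor(rng.uniform(-limit, limit, size=(c_out, c_in, kernel)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.padding = kernel // 2 if padding is None else padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, padding=self.padding)


class DepthwiseConv1dLayer(Module):
    """Per-channel temporal convolution; keeps channels separate."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator, padding: int | None = None):
        if not 3 <= kernel <= 5:
            raise ValueError(f"kernel size {kernel} outside the supported 3-5 range")
        limit = np.sqrt(6.0 / (kernel + 1))
        self.w = Tensor(rng.uniform(-limit, limit, size=(channels, kernel)), requires_grad=True)
        self.b = Tensor(np.zeros(channels), requires_grad=True)
        self.padding = kernel // 2 if padding is None else padding

    def __call__(self, x: Tensor) -> Tensor:
        return depthwise_conv1d(x, self.w, self.b, padding=self.padding)


class Adam:
    """Adam optimiser with bias correction and decoupled weight decay
    (AdamW-style: decay is applied to the parameters directly, not mixed
    into the gradient moments)."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas=(0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                p.data = p.data - self.lr * self.weight_decay * p.data


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy from logits; gradient is softmax - onehot."""
    n, k = logits.shape
    shift = logits - logits.data.max(axis=1, keepdims=True)  # constant shift
    log_z = shift.exp().sum(axis=1, keepdims=True).log()
    log_probs = shift - log_z
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    return -(log_probs * onehot).sum() * (1.0 / n)
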