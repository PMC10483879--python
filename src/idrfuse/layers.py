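"""Neural building blocks composed from :mod:`idrfuse.autograd` primitives.

All layers operate on small dense arrays: sequence layers take an
(L, D) matrix (one protein at a time), image-style layers take
(B, C, H, W) batches of windowed residue tensors.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, maximum, pad2d, softmax

__all__ = [
    "Module", "Dense", "Conv1dSeq", "LSTMSeq", "BiLSTMSeq",
    "Adam", "bce_loss", "softmax", "sliding_stack",
]


class Module:
    """Minimal parameter container with ordered, named parameters."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}

    def param(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True)
        self._params[name] = t
        return t

    def add_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + name, t) for name, t in self._params.items()]
        for cname, child in self._children.items():
            out.extend(child.named_parameters(prefix + cname + "."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, t in self.named_parameters():
            t.data = np.asarray(state[name], dtype=np.float64).reshape(t.shape)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=shape)


class Dense(Module):
    def __init__(self, rng, d_in: int, d_out: int, name: str = "dense"):
        super().__init__()
        self.W = self.param("W", glorot(rng, d_in, d_out, (d_in, d_out)))
        self.b = self.param("b", np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


def sliding_stack(x: Tensor, k: int) -> list[Tensor]:
    """k zero-padded shifted views of an (L, D) sequence, each (L, D).

    View ``j`` holds, at row ``i``, the features of residue ``i + j - k//2``
    (zeros outside the protein) — the standard trick that turns windowed
    operations into elementwise ones.
    """
    L, D = x.shape
    half = k // 2
    zeros = Tensor(np.zeros((half, D)))
    padded = concat([zeros, x, zeros], axis=0)
    return [padded[j : j + L, :] for j in range(k)]


class Conv1dSeq(Module):
    """Same-padding 1-D convolution along the sequence axis."""

    def __init__(self, rng, d_in: int, d_out: int, k: int = 5):
        super().__init__()
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.k = k
        self.W = self.param("W", glorot(rng, d_in * k, d_out, (k, d_in, d_out)))
        self.b = self.param("b", np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        views = sliding_stack(x, self.k)
        out = self.b + views[0] @ self.W[0]
        for j in range(1, self.k):
            out = out + views[j] @ self.W[j]
        return out


class LSTMSeq(Module):
    """Unidirectional LSTM over an (L, D) sequence, returning (L, H)."""

    def __init__(self, rng, d_in: int, hidden: int):
        super().__init__()
        self.hidden = hidden
        self.Wx = self.param("Wx", glorot(rng, d_in, 4 * hidden, (d_in, 4 * hidden)))
        self.Wh = self.param("Wh", glorot(rng, hidden, 4 * hidden, (hidden, 4 * hidden)))
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = self.param("b", b)

    def __call__(self, x: Tensor, reverse: bool = False) -> Tensor:
        L, _ = x.shape
        H = self.hidden
        h = Tensor(np.zeros((1, H)))
        c = Tensor(np.zeros((1, H)))
        order = range(L - 1, -1, -1) if reverse else range(L)
        outputs: list[Tensor | None] = [None] * L
        for t in order:
            gates = x[t : t + 1, :] @ self.Wx + h @ self.Wh + self.b
            i = gates[:, 0:H].sigmoid()
            f = gates[:, H : 2 * H].sigmoid()
            g = gates[:, 2 * H : 3 * H].tanh()
            o = gates[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs[t] = h
        return concat(outputs, axis=0)


class BiLSTMSeq(Module):
    """Bidirectional LSTM; concatenates the two directions to (L, 2H)."""

    def __init__(self, rng, d_in: int, hidden: int):
        super().__init__()
        self.fwd = self.add_child("fwd", LSTMSeq(rng, d_in, hidden))
        self.bwd = self.add_child("bwd", LSTMSeq(rng, d_in, hidden))

    def __call__(self, x: Tensor) -> Tensor:
        return concat([self.fwd(x), self.bwd(x, reverse=True)], axis=1)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-2,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for idx, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[idx] = self.b1 * self.m[idx] + (1 - self.b1) * g
            self.v[idx] = self.b2 * self.v[idx] + (1 - self.b2) * g * g
            mhat = self.m[idx] / (1 - self.b1 ** self.t)
            vhat = self.v[idx] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_loss(probs: Tensor, labels: np.ndarray, pos_weight: float = 1.0,
             eps: float = 1e-7) -> Tensor:
    """Mean per-residue binary cross-entropy; ``pos_weight`` upweights the
    (minority) disordered class."""
    y = np.asarray(labels, dtype=float).reshape(probs.shape)
    p = probs * (1 - 2 * eps) + eps
    terms = Tensor(y * pos_weight) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
    return -terms.mean()


def maxpool_stack(views: list[Tensor]) -> Tensor:
    out = views[0]
    for v in views[1:]:
        out = maximum(out, v)
    return out
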