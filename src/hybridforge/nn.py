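"""Minimal feed-forward neural-network layers with reverse-mode gradients.

Provides exactly what the specificity model needs: affine layers, ELU and
ReLU activations, layer normalization, flattening, a decoupled-weight-decay
Adam optimizer, and the two losses (per-sample cosine distance, softmax
cross-entropy).  Everything is plain numpy and deterministic given the
initializing random generator.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: ``params``/``grads`` are parallel lists of arrays."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Linear(Layer):
    """Affine map on the last axis; PyTorch-style uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        bound = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.b = rng.uniform(-bound, bound, size=n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x = self._x
        gw = x.reshape(-1, x.shape[-1]).T @ gout.reshape(-1, gout.shape[-1])
        self.grads[0] += gw
        self.grads[1] += gout.reshape(-1, gout.shape[-1]).sum(axis=0)
        return gout @ self.W.T


class ELU(Layer):
    def __init__(self, alpha: float = 1.0) -> None:
        super().__init__()
        self.alpha = alpha
        self._out: np.ndarray | None = None
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        out = np.where(self._mask, x, self.alpha * np.expm1(x))
        self._out = out
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * np.where(self._mask, 1.0, self._out + self.alpha)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class LayerNorm(Layer):
    """Normalization over the last axis with learnable scale and shift."""

    def __init__(self, dim: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.eps = eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self._xhat: np.ndarray | None = None
        self._inv_std: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_std
        return self._xhat * self.gamma + self.beta

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        flat = gout.reshape(-1, gout.shape[-1])
        self.grads[0] += (gout * xhat).reshape(-1, flat.shape[-1]).sum(axis=0)
        self.grads[1] += flat.sum(axis=0)
        gx_hat = gout * self.gamma
        term = (
            gx_hat
            - gx_hat.mean(axis=-1, keepdims=True)
            - xhat * (gx_hat * xhat).mean(axis=-1, keepdims=True)
        )
        return term * inv_std


class Flatten(Layer):
    """Collapse all axes after the first (batch) axis."""

    def __init__(self) -> None:
        super().__init__()
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    @property
    def params(self) -> list[np.ndarray]:  # type: ignore[override]
        return [p for layer in self.layers for p in layer.params]

    @params.setter
    def params(self, value) -> None:  # set by Layer.__init__; ignored
        pass

    @property
    def grads(self) -> list[np.ndarray]:  # type: ignore[override]
        return [g for layer in self.layers for g in layer.grads]

    @grads.setter
    def grads(self, value) -> None:
        pass

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def zero_grads(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class AdamW:
    """Adam with decoupled weight decay (applied to every parameter)."""

    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ) -> None:
        self.params = params
        self.grads = grads
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p) for p in params]
        self._v = [np.zeros_like(p) for p in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        for p, g, m, v in zip(self.params, self.grads, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            p -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p)


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cos(u, v) for two nonzero vectors; range [0, 2]."""
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine distance undefined for a zero vector")
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch {u.shape} vs {v.shape}")
    return float(1.0 - np.dot(u, v) / (nu * nv))


def cosine_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Batch-mean cosine distance and its gradient w.r.t. ``pred``.

    ``pred`` and ``target`` are (B, D); the loss is the per-sample cosine
    distance averaged over the batch.
    """
    eps = 1e-12
    np_ = np.linalg.norm(pred, axis=1, keepdims=True) + eps
    nt = np.linalg.norm(target, axis=1, keepdims=True) + eps
    dots = (pred * target).sum(axis=1, keepdims=True)
    cos = dots / (np_ * nt)
    loss = float(np.mean(1.0 - cos))
    grad = -(target / (np_ * nt) - pred * dots / (np_**3 * nt)) / pred.shape[0]
    return loss, grad


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Softmax cross-entropy (batch mean) and gradient w.r.t. logits."""
    shifted = logits - logits.max(axis=1, keepdims=True)
    expv = np.exp(shifted)
    probs = expv / expv.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + 1e-12)))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n
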