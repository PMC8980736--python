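"""Minimal NumPy feed-forward machinery for the docking surrogate.

Implements exactly what the surrogate architecture needs: spectrally
normalized dense layers (power-iteration estimate of the largest singular
value, one update per training step), LeakyReLU, inverted dropout,
parameter-free identity skip connections on shape-matched layers, and the
Adam optimizer. Weight matrices are stored as (n_in, n_out); the
power-iteration vectors are auxiliary state, not trainable parameters.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SpectralDense", "Adam", "leaky_relu", "leaky_relu_grad"]

_EPS = 1e-12


def leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def leaky_relu_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, np.float32(1.0), np.float32(slope))


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / (np.linalg.norm(v) + _EPS)


class SpectralDense:
    """Dense layer y = x @ (W / sigma) + b with spectral normalization.

    sigma is the power-iteration estimate of the largest singular value of
    W; u/v are the singular-vector estimates and are excluded from the
    trainable-parameter count. Initialization is Glorot-uniform from the
    supplied generator, so a seeded generator makes construction
    bit-reproducible.
    """

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int,
                 dtype=np.float32) -> None:
        if n_in < 1 or n_out < 1:
            raise ValueError(f"invalid layer dims ({n_in}, {n_out})")
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.u = _normalize(rng.standard_normal(n_out)).astype(dtype)
        self.v = np.zeros(n_in, dtype=dtype)
        self.sigma = dtype(1.0)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.power_iteration()

    @property
    def n_in(self) -> int:
        return self.W.shape[0]

    @property
    def n_out(self) -> int:
        return self.W.shape[1]

    def power_iteration(self, n_iter: int = 1) -> None:
        """Refresh the largest-singular-value estimate (u, v, sigma)."""
        for _ in range(n_iter):
            self.v = _normalize(self.W @ self.u).astype(self.W.dtype)
            self.u = _normalize(self.W.T @ self.v).astype(self.W.dtype)
        self.sigma = self.W.dtype.type(
            max(float(self.v @ self.W @ self.u), _EPS))

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x @ (self.W / self.sigma) + self.b

    def backward(self, x: np.ndarray, dy: np.ndarray) -> np.ndarray:
        """Accumulate dW/db for inputs x and upstream gradient dy; return dx.

        Differentiates through the normalization with u, v held fixed
        (sigma = v^T W u), the standard spectral-norm gradient.
        """
        w_bar = self.W / self.sigma
        d_wbar = x.T @ dy
        self.db += dy.sum(axis=0)
        self.dW += (d_wbar - float(np.vdot(d_wbar, w_bar))
                    * np.outer(self.v, self.u)) / self.sigma
        return dy @ w_bar.T

    def zero_grad(self) -> None:
        self.dW[...] = 0
        self.db[...] = 0

    def trainable(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(self.W, self.dW), (self.b, self.db)]

    def n_parameters(self) -> int:
        return self.W.size + self.b.size

    def state(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b, "u": self.u, "v": self.v,
                "sigma": np.asarray(self.sigma)}

    def load_state(self, state) -> None:
        self.W = np.asarray(state["W"], dtype=self.W.dtype)
        self.b = np.asarray(state["b"], dtype=self.b.dtype)
        self.u = np.asarray(state["u"], dtype=self.W.dtype)
        self.v = np.asarray(state["v"], dtype=self.W.dtype)
        self.sigma = self.W.dtype.type(float(state["sigma"]))
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)


class Adam:
    """Adaptive-moment gradient optimizer (Kingma & Ba defaults)."""

    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]],
                 lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
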