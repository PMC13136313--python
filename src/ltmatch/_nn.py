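"""Minimal feed-forward network stack (numpy, CPU).

Just enough machinery for the Q-networks used here: fully connected
layers with ReLU activations, explicit backpropagation, Adam updates,
and a two-encoder late-fusion architecture that embeds the candidate and
donor feature blocks separately before a shared Q trunk.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["MLP", "QNetwork", "Adam"]


class MLP:
    """Fully connected net: ReLU after every layer except the last (linear)."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator, zero_init: bool = False):
        self.sizes = tuple(int(s) for s in sizes)
        self.W: List[np.ndarray] = []
        self.b: List[np.ndarray] = []
        for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
            if zero_init:
                w = np.zeros((fan_in, fan_out))
            else:  # He initialization, suited to ReLU
                w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            self.W.append(w)
            self.b.append(np.zeros(fan_out))

    @property
    def params(self) -> List[np.ndarray]:
        out: List[np.ndarray] = []
        for w, b in zip(self.W, self.b):
            out.extend((w, b))
        return out

    def forward(self, x: np.ndarray) -> Tuple[np.ndarray, list]:
        cache = []
        h = x
        last = len(self.W) - 1
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            z = h @ w + b
            if i < last:
                a = np.maximum(z, 0.0)
            else:
                a = z
            cache.append((h, z))
            h = a
        return h, cache

    def backward(self, cache: list, dout: np.ndarray) -> Tuple[List[np.ndarray], np.ndarray]:
        """Gradients for every (W, b) plus the gradient w.r.t. the input."""
        grads: List[np.ndarray] = [None] * (2 * len(self.W))
        last = len(self.W) - 1
        d = dout
        for i in range(last, -1, -1):
            h, z = cache[i]
            if i < last:
                d = d * (z > 0.0)
            grads[2 * i] = h.T @ d
            grads[2 * i + 1] = d.sum(axis=0)
            d = d @ self.W[i].T
        return grads, d

    def copy(self) -> "MLP":
        clone = MLP(self.sizes, np.random.default_rng(0))
        clone.W = [w.copy() for w in self.W]
        clone.b = [b.copy() for b in self.b]
        return clone


class QNetwork:
    """Late-fusion Q-network over (candidate, donor) feature blocks.

    Two upstream encoders embed the blocks into denser representations;
    the concatenated embeddings feed a shared trunk that outputs one
    action value per action.
    """

    def __init__(
        self,
        d_cand: int,
        d_donor: int,
        candidate_embed_dim: int = 64,
        donor_embed_dim: int = 64,
        encoder_hidden: Sequence[int] = (128,),
        trunk_hidden: Sequence[int] = (256, 256),
        n_actions: int = 3,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ):
        rng = rng or np.random.default_rng(0)
        self.cand_encoder = MLP((d_cand, *encoder_hidden, candidate_embed_dim), rng, zero_init)
        self.donor_encoder = MLP((d_donor, *encoder_hidden, donor_embed_dim), rng, zero_init)
        self.trunk = MLP(
            (candidate_embed_dim + donor_embed_dim, *trunk_hidden, n_actions), rng, zero_init
        )
        self.n_actions = n_actions

    @property
    def params(self) -> List[np.ndarray]:
        return self.cand_encoder.params + self.donor_encoder.params + self.trunk.params

    def encode(self, xc: np.ndarray, xd: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Candidate and donor embeddings (no fusion)."""
        ec, _ = self.cand_encoder.forward(xc)
        ed, _ = self.donor_encoder.forward(xd)
        return ec, ed

    def forward(self, xc: np.ndarray, xd: np.ndarray):
        if xc.shape[1] != self.cand_encoder.sizes[0]:
            raise ValueError(
                f"candidate block has {xc.shape[1]} features, expected {self.cand_encoder.sizes[0]}"
            )
        if xd.shape[1] != self.donor_encoder.sizes[0]:
            raise ValueError(
                f"donor block has {xd.shape[1]} features, expected {self.donor_encoder.sizes[0]}"
            )
        ec, cc = self.cand_encoder.forward(xc)
        ed, cd = self.donor_encoder.forward(xd)
        fused = np.concatenate([ec, ed], axis=1)
        q, ct = self.trunk.forward(fused)
        return q, (cc, cd, ct, ec.shape[1])

    def backward(self, cache, dq: np.ndarray) -> List[np.ndarray]:
        cc, cd, ct, split = cache
        gt, dfused = self.trunk.backward(ct, dq)
        gc, _ = self.cand_encoder.backward(cc, dfused[:, :split])
        gd, _ = self.donor_encoder.backward(cd, dfused[:, split:])
        return gc + gd + gt

    def q_values(self, xc: np.ndarray, xd: np.ndarray) -> np.ndarray:
        q, _ = self.forward(xc, xd)
        return q

    def copy(self) -> "QNetwork":
        clone = object.__new__(QNetwork)
        clone.cand_encoder = self.cand_encoder.copy()
        clone.donor_encoder = self.donor_encoder.copy()
        clone.trunk = self.trunk.copy()
        clone.n_actions = self.n_actions
        return clone

    def load_params(self, params: List[np.ndarray]) -> None:
        own = self.params
        if len(own) != len(params):
            raise ValueError("parameter list length mismatch")
        for dst, src in zip(own, params):
            dst[...] = src


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params: List[np.ndarray], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
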