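"""Conservative Q-learning (CQL) on waitlist episode datasets.

The action-value function is a late-fusion network: separate encoders
embed the candidate block (statics + MELD) and the donor block (features
+ flags), and a shared trunk maps the fused embedding to one value per
action (WAIT, DELIST, TRANSPLANT).  Training minimizes

    L(theta) = alpha * E_s[ logsumexp_a Q(s,a) - Q(s, a_data) ] + L_DDQN

where the first term penalizes large values on actions absent from the
data (the conservatism regularizer, weighted by ``alpha``) and the second
is the double-deep-Q temporal-difference loss: the online network picks
the bootstrap action at the next state, the target network evaluates it,
and terminal transitions bootstrap to zero.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._nn import Adam, QNetwork
from .episodes import ACTIONS, EpisodeDataset

__all__ = ["CQLAgent", "cql_loss", "greedy_action", "q_values"]


def cql_loss(
    network: QNetwork,
    target_network: QNetwork,
    batch: Dict[str, np.ndarray],
    alpha: float,
    gamma: float,
    with_grads: bool = True,
):
    """Loss on one batch: ``(total, td, conservative[, grads])``.

    ``batch`` holds ``xc, xd, action, reward, terminal`` and the
    next-state blocks ``xc_next, xd_next`` (ignored on terminal rows).
    """
    xc, xd = batch["xc"], batch["xd"]
    a = batch["action"]
    r = batch["reward"]
    terminal = batch["terminal"]
    n = len(a)
    if n == 0:
        raise ValueError("empty batch")

    q, cache = network.forward(xc, xd)
    if not np.all(np.isfinite(q)):
        raise FloatingPointError("non-finite Q values in training batch")
    idx = np.arange(n)
    q_data = q[idx, a]

    # DDQN target: online selects, target evaluates; terminal -> reward only
    q_next_online = network.q_values(batch["xc_next"], batch["xd_next"])
    a_star = np.argmax(q_next_online, axis=1)
    q_next_target = target_network.q_values(batch["xc_next"], batch["xd_next"])
    y = r + gamma * q_next_target[idx, a_star] * (~terminal)

    td_err = q_data - y
    td = float(np.mean(td_err**2))

    qmax = q.max(axis=1, keepdims=True)
    lse = (qmax[:, 0] + np.log(np.exp(q - qmax).sum(axis=1)))
    conservative = float(np.mean(lse - q_data))
    total = alpha * conservative + td

    if not with_grads:
        return total, td, conservative

    softmax = np.exp(q - qmax)
    softmax /= softmax.sum(axis=1, keepdims=True)
    dq = alpha * softmax / n
    dq[idx, a] -= alpha / n
    dq[idx, a] += 2.0 * td_err / n
    grads = network.backward(cache, dq)
    return total, td, conservative, grads


class CQLAgent(BaseEstimator):
    """Offline Q-learning agent with CQL regularization.

    Parameters mirror the training setup: ``alpha`` is the conservatism
    weight, ``gamma`` the discount, ``hidden_sizes`` the Q-trunk widths,
    ``encoder_hidden``/``*_embed_dim`` the upstream encoder shapes.
    ``iterations`` defaults to a desk-scale budget; the full-scale run
    uses 1,250,000 iterations at batch size 256.

    Fitted attributes: ``network_``, ``target_network_``, ``history_``
    (per-log-interval TD loss, conservative loss and mean value
    estimate), and the feature standardization stats ``center_`` /
    ``scale_``.
    """

    def __init__(
        self,
        alpha: float = 0.1,
        gamma: float = 0.99,
        hidden_sizes: Tuple[int, ...] = (256, 256),
        encoder_hidden: Tuple[int, ...] = (128,),
        candidate_embed_dim: int = 64,
        donor_embed_dim: int = 64,
        iterations: int = 50_000,
        batch_size: int = 256,
        learning_rate: float = 1e-4,
        target_update_interval: int = 2000,
        log_interval: int = 1000,
        probe_size: int = 512,
        seed: int = 0,
    ):
        self.alpha = alpha
        self.gamma = gamma
        self.hidden_sizes = hidden_sizes
        self.encoder_hidden = encoder_hidden
        self.candidate_embed_dim = candidate_embed_dim
        self.donor_embed_dim = donor_embed_dim
        self.iterations = iterations
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.target_update_interval = target_update_interval
        self.log_interval = log_interval
        self.probe_size = probe_size
        self.seed = seed

    # ------------------------------------------------------------------
    def _standardize(self, xc: np.ndarray, xd: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        dc = xc.shape[1]
        x = np.concatenate([xc, xd], axis=1)
        x = (x - self.center_) / self.scale_
        return x[:, :dc], x[:, dc:]

    def _arrays(self, dataset: EpisodeDataset) -> Dict[str, np.ndarray]:
        tr = dataset.transitions
        sidx = tr["state_idx"].to_numpy()
        nidx = tr["next_state_idx"].to_numpy()
        terminal = tr["terminal"].to_numpy().astype(bool)
        safe_next = np.where(nidx >= 0, nidx, 0)
        xc, xd = self._standardize(dataset.X_cand, dataset.X_donor)
        return {
            "xc": xc[sidx],
            "xd": xd[sidx],
            "action": tr["action"].to_numpy().astype(np.int64),
            "reward": tr["reward"].to_numpy().astype(float),
            "terminal": terminal,
            "xc_next": np.where(terminal[:, None], 0.0, xc[safe_next]),
            "xd_next": np.where(terminal[:, None], 0.0, xd[safe_next]),
        }

    def fit(self, dataset: EpisodeDataset, y=None) -> "CQLAgent":
        if dataset.n_transitions == 0:
            raise ValueError("cannot fit on an empty dataset")
        rng = np.random.default_rng(self.seed)

        x_all = np.concatenate([dataset.X_cand, dataset.X_donor], axis=1)
        self.center_ = x_all.mean(axis=0)
        scale = x_all.std(axis=0)
        self.scale_ = np.where(scale < 1e-8, 1.0, scale)
        self.n_features_cand_ = dataset.X_cand.shape[1]
        self.n_features_donor_ = dataset.X_donor.shape[1]

        data = self._arrays(dataset)
        n = len(data["action"])

        self.network_ = QNetwork(
            d_cand=self.n_features_cand_,
            d_donor=self.n_features_donor_,
            candidate_embed_dim=self.candidate_embed_dim,
            donor_embed_dim=self.donor_embed_dim,
            encoder_hidden=self.encoder_hidden,
            trunk_hidden=self.hidden_sizes,
            n_actions=len(ACTIONS),
            rng=rng,
        )
        self.target_network_ = self.network_.copy()
        opt = Adam(self.network_.params, lr=self.learning_rate)

        probe = rng.choice(n, size=min(self.probe_size, n), replace=False)
        probe_xc, probe_xd = data["xc"][probe], data["xd"][probe]

        history = []
        for it in range(1, self.iterations + 1):
            sel = rng.integers(0, n, size=min(self.batch_size, n))
            batch = {k: v[sel] for k, v in data.items()}
            try:
                total, td, cons, grads = cql_loss(
                    self.network_, self.target_network_, batch, self.alpha, self.gamma
                )
            except FloatingPointError:
                self.history_ = pd.DataFrame(history)
                raise RuntimeError(
                    f"training diverged at iteration {it}; history has "
                    f"{len(history)} logged intervals"
                )
            opt.step(grads)
            if it % self.target_update_interval == 0:
                self.target_network_ = self.network_.copy()
            if it % self.log_interval == 0 or it == self.iterations:
                value = float(self.network_.q_values(probe_xc, probe_xd).max(axis=1).mean())
                history.append(
                    {
                        "iteration": it,
                        "td_loss": td,
                        "conservative_loss": cons,
                        "total_loss": total,
                        "mean_value": value,
                    }
                )
        self.history_ = pd.DataFrame(
            history, columns=["iteration", "td_loss", "conservative_loss", "total_loss", "mean_value"]
        )
        return self

    # ------------------------------------------------------------------
    def q_values(self, X_cand: np.ndarray, X_donor: np.ndarray) -> np.ndarray:
        """Action values for raw (unstandardized) feature blocks."""
        xc, xd = self._standardize(np.atleast_2d(X_cand), np.atleast_2d(X_donor))
        out = np.empty((len(xc), len(ACTIONS)))
        for lo in range(0, len(xc), 8192):
            hi = lo + 8192
            out[lo:hi] = self.network_.q_values(xc[lo:hi], xd[lo:hi])
        return out

    def encode_state(self, X_cand: np.ndarray, X_donor: np.ndarray):
        """Candidate and donor embeddings for raw feature blocks."""
        xc, xd = self._standardize(np.atleast_2d(X_cand), np.atleast_2d(X_donor))
        return self.network_.encode(xc, xd)

    def predict(self, dataset_or_xc, X_donor: np.ndarray | None = None) -> np.ndarray:
        """Greedy actions; ties break by fixed order WAIT < DELIST < TRANSPLANT."""
        if isinstance(dataset_or_xc, EpisodeDataset):
            q = self.q_values(dataset_or_xc.X_cand, dataset_or_xc.X_donor)
        else:
            q = self.q_values(dataset_or_xc, X_donor)
        return np.argmax(q, axis=1)

    def decide(self, dataset: EpisodeDataset) -> np.ndarray:
        return self.predict(dataset)

    def action_probabilities(self, dataset: EpisodeDataset, temperature: float = 1.0) -> np.ndarray:
        """Softmax policy over Q values at the given temperature."""
        q = self.q_values(dataset.X_cand, dataset.X_donor) / max(temperature, 1e-12)
        q -= q.max(axis=1, keepdims=True)
        p = np.exp(q)
        return p / p.sum(axis=1, keepdims=True)

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint (parameters + config + history) as one .npz archive."""
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.network_.params)}
        arrays.update({f"t{i}": p for i, p in enumerate(self.target_network_.params)})
        arrays["center"] = self.center_
        arrays["scale"] = self.scale_
        arrays["history"] = self.history_.to_numpy()
        arrays["history_columns"] = np.array(list(self.history_.columns))
        arrays["config"] = np.array(json.dumps(self.get_params(), default=list))
        arrays["dims"] = np.array([self.n_features_cand_, self.n_features_donor_])
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "CQLAgent":
        with np.load(path, allow_pickle=False) as z:
            params = json.loads(str(z["config"]))
            for key in ("hidden_sizes", "encoder_hidden"):
                params[key] = tuple(params[key])
            agent = cls(**params)
            agent.n_features_cand_, agent.n_features_donor_ = (int(v) for v in z["dims"])
            agent.center_ = z["center"]
            agent.scale_ = z["scale"]
            rng = np.random.default_rng(0)
            agent.network_ = QNetwork(
                agent.n_features_cand_,
                agent.n_features_donor_,
                agent.candidate_embed_dim,
                agent.donor_embed_dim,
                agent.encoder_hidden,
                agent.hidden_sizes,
                len(ACTIONS),
                rng,
            )
            agent.target_network_ = agent.network_.copy()
            agent.network_.load_params([z[f"p{i}"] for i in range(len(agent.network_.params))])
            agent.target_network_.load_params(
                [z[f"t{i}"] for i in range(len(agent.target_network_.params))]
            )
            agent.history_ = pd.DataFrame(z["history"], columns=list(z["history_columns"]))
        return agent


def greedy_action(agent: CQLAgent, X_cand: np.ndarray, X_donor: np.ndarray) -> np.ndarray:
    """Argmax action(s); deterministic tie-break WAIT < DELIST < TRANSPLANT."""
    return np.argmax(q_values(agent, X_cand, X_donor), axis=1)


def q_values(agent: CQLAgent, X_cand: np.ndarray, X_donor: np.ndarray) -> np.ndarray:
    return agent.q_values(X_cand, X_donor)
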