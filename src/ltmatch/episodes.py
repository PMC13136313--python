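"""Waitlist MDP episodes from registry tables.

Each candidate contributes one episode with one step per MELD
observation.  Only terminal actions are observed in registry data, so
every non-final step is an inferred WAIT; the final step carries the
terminal action implied by the outcome (TRANSPLANT for transplant
outcomes, with the true donor attached; DELIST for waitlist death or
recovery).  Censored candidates contribute only their WAIT transitions.

At every non-transplant step a potential donor is sampled uniformly from
the blood-type-matched organs (used anywhere or discarded) recovered
within a symmetric day window of the observation; the state is the
candidate's static features, the current MELD, and that donor's features
plus two flags recording whether the organ eventually caused a graft
failure or was eventually discarded.  When the matched pool is empty a
"no-offer" placeholder (all-zero donor vector, flags false) is attached.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .registry import (
    BLOOD_TYPES,
    CANDIDATE_STATE_FEATURES,
    DONOR_STATE_FEATURES,
    OutcomeLabel,
    RegistryTables,
    TRANSPLANT_OUTCOMES,
)
from .rewards import RewardParams

__all__ = [
    "ACTIONS",
    "WAIT",
    "DELIST",
    "TRANSPLANT",
    "EpisodeDataset",
    "match_donor_pool",
    "build_episodes",
]

ACTIONS = ("WAIT", "DELIST", "TRANSPLANT")
WAIT, DELIST, TRANSPLANT = 0, 1, 2

#: Candidate feature block, fixed order: statics, blood-type one-hot, MELD.
CANDIDATE_BLOCK = tuple(CANDIDATE_STATE_FEATURES) + tuple(
    f"blood_type_{bt}" for bt in BLOOD_TYPES
) + ("meld",)
#: Donor feature block, fixed order: donor features then the two flags.
DONOR_BLOCK = tuple(DONOR_STATE_FEATURES) + ("is_graft_failure_donor", "is_discarded_donor")


def match_donor_pool(candidate, obs_date: int, donors: pd.DataFrame, window_days: int = 3) -> pd.DataFrame:
    """All donors with the candidate's blood type recovered within the window.

    ``candidate`` may be a row of the candidates table or a blood-type
    string.  Both used (anywhere) and discarded organs are eligible.
    Rows are ordered deterministically by (|recovery_date - obs_date|,
    donor_id); an empty frame is a valid result.
    """
    bt = candidate if isinstance(candidate, str) else candidate["blood_type"]
    sel = donors[
        (donors["blood_type"] == bt)
        & ((donors["recovery_date"] - obs_date).abs() <= window_days)
    ].copy()
    sel["_dist"] = (sel["recovery_date"] - obs_date).abs()
    sel = sel.sort_values(["_dist", "donor_id"], kind="stable").drop(columns="_dist")
    return sel.reset_index(drop=True)


@dataclass
class EpisodeDataset:
    """Materialized transitions of a waitlist MDP.

    ``states`` has one row per (episode, step), including the final
    observation of censored episodes; ``transitions`` has one row per
    action.  ``X_cand``/``X_donor`` are the aligned per-state feature
    blocks in the fixed orders :data:`CANDIDATE_BLOCK` / :data:`DONOR_BLOCK`.
    """

    states: pd.DataFrame
    transitions: pd.DataFrame
    X_cand: np.ndarray
    X_donor: np.ndarray
    provenance: Dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def episode_ids(self) -> np.ndarray:
        return self.states["episode_id"].unique()

    def subset(self, episode_ids) -> "EpisodeDataset":
        """Restrict to the given episodes, reindexing state pointers."""
        keep = self.states["episode_id"].isin(episode_ids).to_numpy()
        new_index = -np.ones(len(self.states), dtype=np.int64)
        new_index[keep] = np.arange(keep.sum())
        states = self.states.loc[keep].reset_index(drop=True)
        tr_keep = self.transitions["episode_id"].isin(episode_ids).to_numpy()
        tr = self.transitions.loc[tr_keep].reset_index(drop=True)
        tr["state_idx"] = new_index[tr["state_idx"].to_numpy()]
        nxt = tr["next_state_idx"].to_numpy()
        tr["next_state_idx"] = np.where(nxt >= 0, new_index[nxt], -1)
        return EpisodeDataset(
            states, tr, self.X_cand[keep], self.X_donor[keep], dict(self.provenance)
        )

    # -- serialization ----------------------------------------------------

    def write(self, path, fmt: str = "parquet") -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        if fmt == "parquet":
            self.states.to_parquet(path / "states.parquet", index=False)
            self.transitions.to_parquet(path / "transitions.parquet", index=False)
        elif fmt == "csv":
            self.states.to_csv(path / "states.csv", index=False)
            self.transitions.to_csv(path / "transitions.csv", index=False)
        else:
            raise ValueError(f"unknown format {fmt!r}")
        meta = {
            "format": fmt,
            "candidate_columns": list(CANDIDATE_BLOCK),
            "donor_columns": [f"donor_{f}" for f in DONOR_STATE_FEATURES]
            + ["is_graft_failure_donor", "is_discarded_donor"],
            "provenance": self.provenance,
        }
        (path / "episodes.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def read(cls, path) -> "EpisodeDataset":
        path = Path(path)
        meta = json.loads((path / "episodes.json").read_text())
        fmt = meta["format"]
        reader = pd.read_parquet if fmt == "parquet" else pd.read_csv
        states = reader(path / f"states.{ 'parquet' if fmt == 'parquet' else 'csv'}")
        transitions = reader(path / f"transitions.{ 'parquet' if fmt == 'parquet' else 'csv'}")
        X_cand = states[list(meta["candidate_columns"])].to_numpy(dtype=float)
        X_donor = states[list(meta["donor_columns"])].to_numpy(dtype=float)
        return cls(states, transitions, X_cand, X_donor, meta.get("provenance", {}))


def _registry_hash(registry: RegistryTables) -> str:
    h = 0
    for df in registry:
        h ^= int(pd.util.hash_pandas_object(df, index=False).sum())
    return f"{h & 0xFFFFFFFFFFFFFFFF:016x}"


def build_episodes(
    registry: RegistryTables,
    reward_params: RewardParams = RewardParams(),
    sampling_seed: int = 0,
    window_days: int = 3,
) -> EpisodeDataset:
    """Convert registry tables into an :class:`EpisodeDataset`.

    Donor sampling at WAIT/DELIST states is uniform over the matched pool
    and deterministic given ``sampling_seed``.  Candidates with a
    transplant outcome but no recorded donor are excluded (their count is
    recorded in ``provenance['n_excluded_no_donor']``).
    """
    from . import rewards as rw

    rng = np.random.default_rng(sampling_seed)
    cands, meld_obs, donors = registry

    cand = cands.set_index("candidate_id", drop=False)
    tx_outcomes = {o.value for o in TRANSPLANT_OUTCOMES}
    bad = cand.index[
        cand["outcome"].isin(tx_outcomes) & cand["donor_id"].isna()
    ]
    n_excluded = len(bad)
    if n_excluded:
        cand = cand.drop(index=bad)

    obs = meld_obs[meld_obs["candidate_id"].isin(cand.index)].sort_values(
        ["candidate_id", "obs_date"], kind="stable"
    )
    cand_ids = obs["candidate_id"].to_numpy()
    obs_dates = obs["obs_date"].to_numpy()
    melds = obs["meld"].to_numpy()
    n_states = len(obs)

    # step index within each episode (1-based) and per-episode length
    counts = obs.groupby("candidate_id", sort=False).size()
    lengths = counts.reindex(pd.unique(cand_ids)).to_numpy()
    step = np.concatenate([np.arange(1, c + 1) for c in lengths]) if n_states else np.array([], dtype=int)
    is_last = np.concatenate([np.arange(1, c + 1) == c for c in lengths]) if n_states else np.array([], dtype=bool)

    outcome_per_state = cand["outcome"].reindex(cand_ids).to_numpy()
    bt_per_state = cand["blood_type"].reindex(cand_ids).to_numpy()
    true_donor_per_state = cand["donor_id"].reindex(cand_ids).to_numpy()

    # ---- donor sampling, vectorized per blood type ----------------------
    donor_dates_all = donors["recovery_date"].to_numpy()
    attached = np.full(n_states, -1, dtype=np.int64)  # positional index into donors
    pool_size = np.zeros(n_states, dtype=np.int64)
    for bt in BLOOD_TYPES:
        didx = np.flatnonzero((donors["blood_type"] == bt).to_numpy())
        didx = didx[np.argsort(donor_dates_all[didx], kind="stable")]
        ddates = donor_dates_all[didx]
        sel = np.flatnonzero(bt_per_state == bt)
        if len(sel) == 0:
            continue
        lo = np.searchsorted(ddates, obs_dates[sel] - window_days, side="left")
        hi = np.searchsorted(ddates, obs_dates[sel] + window_days, side="right")
        size = hi - lo
        pool_size[sel] = size
        nonempty = size > 0
        pick = lo[nonempty] + rng.integers(0, size[nonempty])
        attached[sel[nonempty]] = didx[pick]

    # transplant terminal states carry the true donor, not a sampled one
    is_tx_terminal = is_last & np.isin(outcome_per_state, list(tx_outcomes))
    # map donor_id -> positional index (row order is not guaranteed to equal id)
    id_to_pos = pd.Series(np.arange(len(donors)), index=donors["donor_id"].to_numpy())
    donor_pos = id_to_pos.reindex(true_donor_per_state[is_tx_terminal].astype(np.int64)).to_numpy()
    if np.isnan(donor_pos).any():
        missing = np.isnan(donor_pos).sum()
        raise ValueError(f"{missing} transplanted candidates reference unknown donor ids")
    attached[is_tx_terminal] = donor_pos.astype(np.int64)

    # ---- state feature blocks -------------------------------------------
    X_cand = np.empty((n_states, len(CANDIDATE_BLOCK)))
    for j, name in enumerate(CANDIDATE_STATE_FEATURES):
        X_cand[:, j] = cand[name].reindex(cand_ids).to_numpy(dtype=float)
    for j, bt in enumerate(BLOOD_TYPES):
        X_cand[:, len(CANDIDATE_STATE_FEATURES) + j] = (bt_per_state == bt).astype(float)
    X_cand[:, -1] = melds

    has_donor = attached >= 0
    X_donor = np.zeros((n_states, len(DONOR_BLOCK)))
    dsub = donors.iloc[attached[has_donor]]
    for j, name in enumerate(DONOR_STATE_FEATURES):
        X_donor[has_donor, j] = dsub[name].to_numpy(dtype=float)
    is_gf_donor = np.zeros(n_states, dtype=bool)
    is_discarded = np.zeros(n_states, dtype=bool)
    is_gf_donor[has_donor] = dsub["caused_graft_failure"].to_numpy()
    is_discarded[has_donor] = (dsub["disposition"] == "DISCARDED").to_numpy()
    X_donor[:, len(DONOR_STATE_FEATURES)] = is_gf_donor
    X_donor[:, len(DONOR_STATE_FEATURES) + 1] = is_discarded

    donor_id_attached = np.full(n_states, -1, dtype=np.int64)
    donor_id_attached[has_donor] = donors["donor_id"].to_numpy()[attached[has_donor]]

    states = pd.DataFrame(
        {
            "episode_id": cand_ids,
            "step": step,
            "obs_date": obs_dates,
            "meld": melds,
            "donor_id": donor_id_attached,
            "is_graft_failure_donor": is_gf_donor,
            "is_discarded_donor": is_discarded,
            "pool_size": pool_size,
            "outcome": outcome_per_state,
            "is_terminal_state": is_last,
        }
    )
    for j, name in enumerate(CANDIDATE_BLOCK):
        states[name] = X_cand[:, j]
    # donor features are prefixed to avoid colliding with candidate names
    # (age, weight, height exist on both); the two flags are already columns
    for j, name in enumerate(DONOR_STATE_FEATURES):
        states[f"donor_{name}"] = X_donor[:, j]

    # ---- transitions -----------------------------------------------------
    censored = outcome_per_state == OutcomeLabel.CENSORED.value
    is_transition = ~(is_last & censored)  # censored episodes drop the final state's action
    tr_idx = np.flatnonzero(is_transition)

    action = np.full(n_states, WAIT, dtype=np.int64)
    action[is_last & np.isin(outcome_per_state, list(tx_outcomes))] = TRANSPLANT
    action[
        is_last
        & np.isin(
            outcome_per_state,
            [OutcomeLabel.WAITLIST_DEATH.value, OutcomeLabel.DELIST_RECOVERED.value],
        )
    ] = DELIST

    terminal = is_last & ~censored
    next_idx = np.arange(n_states) + 1
    next_idx[terminal] = -1
    # single-state censored episodes contribute nothing; guard bounds
    next_idx = np.where(next_idx >= n_states, -1, next_idx)

    # rewards
    reward = np.zeros(n_states)
    nonlast = ~is_last
    nxt = np.arange(n_states)[nonlast] + 1
    reward[nonlast] = rw.wait_reward(
        melds[nonlast], melds[nxt], is_gf_donor[nonlast], is_discarded[nonlast], reward_params
    )
    for oc, r in (
        (OutcomeLabel.WAITLIST_DEATH.value, reward_params.beta3),
        (OutcomeLabel.DELIST_RECOVERED.value, reward_params.beta4),
        (OutcomeLabel.GRAFT_FAILURE.value, reward_params.beta5),
        (OutcomeLabel.TRANSPLANT_SUCCESS.value, reward_params.beta6),
    ):
        reward[is_last & (outcome_per_state == oc)] = r

    transitions = pd.DataFrame(
        {
            "episode_id": cand_ids[tr_idx],
            "step": step[tr_idx],
            "state_idx": tr_idx,
            "next_state_idx": next_idx[tr_idx],
            "action": action[tr_idx],
            "reward": reward[tr_idx],
            "terminal": terminal[tr_idx],
            "outcome": np.where(terminal[tr_idx], outcome_per_state[tr_idx], ""),
        }
    )

    provenance = {
        "registry_hash": _registry_hash(registry),
        "sampling_seed": int(sampling_seed),
        "window_days": int(window_days),
        "n_excluded_no_donor": int(n_excluded),
        "reward_params": {
            "beta1": reward_params.beta1,
            "beta2": reward_params.beta2,
            "beta3": reward_params.beta3,
            "beta4": reward_params.beta4,
            "beta5": reward_params.beta5,
            "beta6": reward_params.beta6,
            "meld_anchor": reward_params.meld_anchor,
        },
    }
    return EpisodeDataset(states, transitions, X_cand, X_donor, provenance)
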