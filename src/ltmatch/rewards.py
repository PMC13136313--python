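"""Reward function for the liver-transplant waitlist decision process.

The reward has three components, one per action:

* ``wait`` — short-term reward driven by the change in MELD between
  consecutive observations, scaled by how close the next MELD is to an
  anchor score (the cohort median, 24), plus indicator bonuses for waiting
  on a potential donor that eventually caused a graft failure (``beta1``)
  or was eventually discarded (``beta2``).  Waiting on such organs is
  rewarded because, on average, they are lower-quality than organs that
  were actually used.
* ``delist`` — terminal reward depending on why the candidate left the
  list: ``beta3`` (penalty) for waitlist death / deterioration, ``beta4``
  for recovery.
* ``transplant`` — terminal reward for the operation outcome: ``beta5``
  (penalty) for 1-year graft failure, ``beta6`` for a successful graft.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, List

import numpy as np

from .registry import OutcomeLabel

__all__ = [
    "RewardParams",
    "wait_reward",
    "delist_reward",
    "transplant_reward",
    "reward_grid",
]

MELD_MIN = 6
MELD_MAX = 40


@dataclass(frozen=True)
class RewardParams:
    """Reward parameterization.

    Defaults are the parameterization selected by grid search:
    beta1=1.0, beta2=0.25, beta3=-1.0, beta4=1.0, beta5=-4.0, beta6=1.0,
    with the MELD anchor at 24 (the cohort median MELD).
    """

    beta1: float = 1.0
    beta2: float = 0.25
    beta3: float = -1.0
    beta4: float = 1.0
    beta5: float = -4.0
    beta6: float = 1.0
    meld_anchor: int = 24

    def __post_init__(self) -> None:
        if not self.beta2 < self.beta1:
            raise ValueError(
                f"beta2 must be < beta1 (got beta2={self.beta2}, beta1={self.beta1})"
            )
        if self.beta3 >= 0:
            raise ValueError(f"beta3 must be negative, got {self.beta3}")
        if self.beta5 >= 0:
            raise ValueError(f"beta5 must be negative, got {self.beta5}")
        if self.beta4 <= 0:
            raise ValueError(f"beta4 must be positive, got {self.beta4}")
        if self.beta6 <= 0:
            raise ValueError(f"beta6 must be positive, got {self.beta6}")
        if self.meld_anchor <= 0:
            raise ValueError(f"meld_anchor must be positive, got {self.meld_anchor}")


def _check_meld(value, name: str) -> None:
    arr = np.asarray(value)
    if np.any(arr < MELD_MIN) or np.any(arr > MELD_MAX):
        raise ValueError(f"{name} out of range [{MELD_MIN}, {MELD_MAX}]")


def wait_reward(
    meld_i,
    meld_next,
    is_gf_donor,
    is_discarded_donor,
    params: RewardParams = RewardParams(),
):
    """Reward for deciding to wait, given consecutive MELD scores.

    ``(meld_i - meld_next) * min(meld_next, anchor) / anchor``
    ``+ beta1 * 1[gf donor] + beta2 * 1[discarded donor]``

    Accepts scalars or arrays (broadcast elementwise).
    """
    _check_meld(meld_i, "meld_i")
    _check_meld(meld_next, "meld_next")
    meld_i = np.asarray(meld_i, dtype=float)
    meld_next = np.asarray(meld_next, dtype=float)
    anchor = float(params.meld_anchor)
    base = (meld_i - meld_next) * np.minimum(meld_next, anchor) / anchor
    bonus = params.beta1 * np.asarray(is_gf_donor, dtype=float)
    bonus = bonus + params.beta2 * np.asarray(is_discarded_donor, dtype=float)
    out = base + bonus
    return float(out) if out.ndim == 0 else out


def delist_reward(outcome: OutcomeLabel, params: RewardParams = RewardParams()) -> float:
    """Terminal reward for delisting: beta3 if died, beta4 if recovered."""
    if outcome == OutcomeLabel.WAITLIST_DEATH:
        return params.beta3
    if outcome == OutcomeLabel.DELIST_RECOVERED:
        return params.beta4
    raise ValueError(f"delist_reward is undefined for outcome {outcome!r}")


def transplant_reward(outcome: OutcomeLabel, params: RewardParams = RewardParams()) -> float:
    """Terminal reward for transplanting: beta5 if graft failure, beta6 if success."""
    if outcome == OutcomeLabel.GRAFT_FAILURE:
        return params.beta5
    if outcome == OutcomeLabel.TRANSPLANT_SUCCESS:
        return params.beta6
    raise ValueError(f"transplant_reward is undefined for outcome {outcome!r}")


#: Grid-search ranges for the reward sensitivity analysis.
BETA1_GRID = (1.0, 0.5)
BETA2_GRID = (0.0, 0.1, 0.25, 0.5)
BETA3_GRID = (-1.0,)
BETA4_GRID = (1.0,)
BETA5_GRID = (-2.0, -4.0, -8.0)
BETA6_GRID = (1.0, 2.0)


def reward_grid() -> List[RewardParams]:
    """Enumerate the reward parameter grid, keeping only beta2 < beta1.

    The unfiltered Cartesian product has 2*4*1*1*3*2 = 48 elements; the
    beta2 < beta1 constraint (discarded organs should be avoided, but less
    strongly than organs that definitively caused graft failure) removes
    the (beta1=0.5, beta2=0.5) combinations.
    """
    grid = []
    for b1, b2, b3, b4, b5, b6 in itertools.product(
        BETA1_GRID, BETA2_GRID, BETA3_GRID, BETA4_GRID, BETA5_GRID, BETA6_GRID
    ):
        if not b2 < b1:
            continue
        grid.append(RewardParams(b1, b2, b3, b4, b5, b6))
    return grid
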