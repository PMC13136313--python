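"""Comparison policies: MELD-threshold rules and static predictive models.

Every policy implements ``decide(dataset) -> actions`` over the states of
an :class:`~ltmatch.episodes.EpisodeDataset`, the same contract as the
learned agent, so the evaluation suite is policy-agnostic.

The predictive baselines are conventional single-timepoint classifiers:

* action models — 3-class classifiers of the recorded action given the
  state (behavior cloning);
* outcome models — 4-class classifiers of the terminal outcome, trained
  only on terminal states, whose predictions map to actions (predicted
  success -> TRANSPLANT, predicted recovery -> DELIST, predicted graft
  failure or waitlist death -> WAIT);
* graft-failure models — binary graft-failure risk fitted only on the
  donor-recipient pairs that actually occurred; TRANSPLANT when the
  predicted risk is below a threshold ``tau``, never DELIST.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.class_weight import compute_sample_weight
from xgboost import XGBClassifier

from .episodes import ACTIONS, DELIST, TRANSPLANT, WAIT, EpisodeDataset
from .registry import OutcomeLabel

__all__ = [
    "ThresholdPolicy",
    "ActionPolicyModel",
    "OutcomePolicyModel",
    "GraftFailurePolicyModel",
    "BehaviorReplayPolicy",
    "ConstantPolicy",
    "threshold_decide",
    "fit_action_model",
    "fit_outcome_model",
    "fit_graft_failure_model",
]

THRESHOLDS = (15, 20, 24, 30)

#: Mapping from predicted terminal outcome to an action: preserve the
#: good outcomes, avoid the bad ones by waiting.
OUTCOME_TO_ACTION = {
    OutcomeLabel.TRANSPLANT_SUCCESS.value: TRANSPLANT,
    OutcomeLabel.DELIST_RECOVERED.value: DELIST,
    OutcomeLabel.GRAFT_FAILURE.value: WAIT,
    OutcomeLabel.WAITLIST_DEATH.value: WAIT,
}


def _one_hot_probs(actions: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    p = np.full((len(actions), len(ACTIONS)), eps)
    p[np.arange(len(actions)), actions] = 1.0
    return p / p.sum(axis=1, keepdims=True)


class ThresholdPolicy(BaseEstimator):
    """MELD-k rule: TRANSPLANT whenever MELD >= k, otherwise WAIT.

    The boundary is inclusive by default (MELD 15 is the usual floor for
    waitlist placement, so a score of exactly 15 transplants); never
    delists.  ``strict=True`` switches to a strict inequality.
    """

    def __init__(self, k: int = 15, strict: bool = False):
        self.k = k
        self.strict = strict

    def fit(self, dataset: EpisodeDataset | None = None, y=None) -> "ThresholdPolicy":
        return self

    def decide(self, dataset: EpisodeDataset) -> np.ndarray:
        meld = dataset.states["meld"].to_numpy()
        if self.strict:
            tx = meld > self.k
        else:
            tx = meld >= self.k
        return np.where(tx, TRANSPLANT, WAIT)

    def action_probabilities(self, dataset: EpisodeDataset, temperature: float = 1.0) -> np.ndarray:
        return _one_hot_probs(self.decide(dataset))


def threshold_decide(policy: ThresholdPolicy, dataset: EpisodeDataset) -> np.ndarray:
    return policy.decide(dataset)


class BehaviorReplayPolicy(BaseEstimator):
    """Replays the recorded actions (identity policy; match rate 100%).

    States that carry no recorded action (the final observation of a
    censored episode) map to WAIT.
    """

    def fit(self, dataset=None, y=None):
        return self

    def decide(self, dataset: EpisodeDataset) -> np.ndarray:
        acts = np.full(dataset.n_states, WAIT, dtype=np.int64)
        tr = dataset.transitions
        acts[tr["state_idx"].to_numpy()] = tr["action"].to_numpy()
        return acts

    def action_probabilities(self, dataset: EpisodeDataset, temperature: float = 1.0) -> np.ndarray:
        return _one_hot_probs(self.decide(dataset))


class ConstantPolicy(BaseEstimator):
    """Always emits one action (e.g. a never-transplant control)."""

    def __init__(self, action: int = WAIT):
        self.action = action

    def fit(self, dataset=None, y=None):
        return self

    def decide(self, dataset: EpisodeDataset) -> np.ndarray:
        return np.full(dataset.n_states, self.action, dtype=np.int64)

    def action_probabilities(self, dataset: EpisodeDataset, temperature: float = 1.0) -> np.ndarray:
        return _one_hot_probs(self.decide(dataset))


# ---------------------------------------------------------------------------
# predictive models


def _make_learner(learner: str, seed: int, n_classes: int):
    if learner == "logistic":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, class_weight="balanced", random_state=seed),
        )
    if learner == "xgboost":
        return XGBClassifier(
            n_estimators=100,
            max_depth=4,
            learning_rate=0.1,
            n_jobs=1,
            random_state=seed,
            verbosity=0,
            objective="multi:softprob" if n_classes > 2 else "binary:logistic",
        )
    raise ValueError(f"unknown learner {learner!r}; use 'logistic' or 'xgboost'")


def _features(dataset: EpisodeDataset, rows: np.ndarray | slice = slice(None)) -> np.ndarray:
    return np.concatenate([dataset.X_cand[rows], dataset.X_donor[rows]], axis=1)


class _PredictiveBase(BaseEstimator):
    learner: str
    seed: int

    def _fit_learner(self, X: np.ndarray, y: np.ndarray):
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError(
                f"degenerate training data: only one class present ({classes.tolist()})"
            )
        self.classes_ = classes
        model = _make_learner(self.learner, self.seed, len(classes))
        if self.learner == "xgboost":
            # xgboost needs consecutive labels and explicit balancing weights
            y_enc = np.searchsorted(classes, y)
            model.fit(X, y_enc, sample_weight=compute_sample_weight("balanced", y_enc))
        else:
            model.fit(X, y)
        self.model_ = model
        return self

    def _proba(self, X: np.ndarray) -> np.ndarray:
        return self.model_.predict_proba(X)


class ActionPolicyModel(_PredictiveBase):
    """3-class action classifier on states (behavior cloning)."""

    def __init__(self, learner: str = "logistic", seed: int = 0):
        self.learner = learner
        self.seed = seed

    def fit(self, dataset: EpisodeDataset, y=None) -> "ActionPolicyModel":
        tr = dataset.transitions
        X = _features(dataset, tr["state_idx"].to_numpy())
        return self._fit_learner(X, tr["action"].to_numpy())

    def predict_action_proba(self, dataset: EpisodeDataset) -> np.ndarray:
        """(n_states, 3) action probabilities in fixed action order."""
        proba = self._proba(_features(dataset))
        out = np.full((dataset.n_states, len(ACTIONS)), 1e-9)
        for j, cls in enumerate(self.classes_):
            out[:, int(cls)] = proba[:, j]
        return out / out.sum(axis=1, keepdims=True)

    def decide(self, dataset: EpisodeDataset) -> np.ndarray:
        return np.argmax(self.predict_action_proba(dataset), axis=1)

    def action_probabilities(self, dataset: EpisodeDataset, temperature: float = 1.0) -> np.ndarray:
        return self.predict_action_proba(dataset)


class OutcomePolicyModel(_PredictiveBase):
    """4-class terminal-outcome classifier mapped to actions."""

    def __init__(self, learner: str = "logistic", seed: int = 0):
        self.learner = learner
        self.seed = seed

    def fit(self, dataset: EpisodeDataset, y=None) -> "OutcomePolicyModel":
        tr = dataset.transitions
        term = tr[tr["terminal"]]
        X = _features(dataset, term["state_idx"].to_numpy())
        return self._fit_learner(X, term["outcome"].to_numpy())

    def decide(self, dataset: EpisodeDataset) -> np.ndarray:
        proba = self._proba(_features(dataset))
        pred = self.classes_[np.argmax(proba, axis=1)]
        return np.array([OUTCOME_TO_ACTION[p] for p in pred], dtype=np.int64)

    def action_probabilities(self, dataset: EpisodeDataset, temperature: float = 1.0) -> np.ndarray:
        return _one_hot_probs(self.decide(dataset))


class GraftFailurePolicyModel(_PredictiveBase):
    """Binary 1-year graft-failure risk on true transplant pairs.

    TRANSPLANT when predicted risk < ``tau``, else WAIT; never DELIST.
    The learners are fitted with balanced class weights (graft failure is
    ~7% of transplants), so ``tau`` operates on the reweighted scale.
    """

    def __init__(self, learner: str = "logistic", tau: float = 0.5, seed: int = 0):
        self.learner = learner
        self.tau = tau
        self.seed = seed

    def fit(self, dataset: EpisodeDataset, y=None) -> "GraftFailurePolicyModel":
        tr = dataset.transitions
        term = tr[tr["terminal"] & (tr["action"] == TRANSPLANT)]
        X = _features(dataset, term["state_idx"].to_numpy())
        y_gf = (term["outcome"] == OutcomeLabel.GRAFT_FAILURE.value).to_numpy().astype(int)
        return self._fit_learner(X, y_gf)

    def graft_failure_risk(self, dataset: EpisodeDataset) -> np.ndarray:
        proba = self._proba(_features(dataset))
        col = int(np.flatnonzero(self.classes_ == 1)[0])
        return proba[:, col]

    def decide(self, dataset: EpisodeDataset) -> np.ndarray:
        risk = self.graft_failure_risk(dataset)
        return np.where(risk < self.tau, TRANSPLANT, WAIT)

    def action_probabilities(self, dataset: EpisodeDataset, temperature: float = 1.0) -> np.ndarray:
        return _one_hot_probs(self.decide(dataset))


def fit_action_model(dataset: EpisodeDataset, learner: str = "logistic", seed: int = 0) -> ActionPolicyModel:
    return ActionPolicyModel(learner=learner, seed=seed).fit(dataset)


def fit_outcome_model(dataset: EpisodeDataset, learner: str = "logistic", seed: int = 0) -> OutcomePolicyModel:
    return OutcomePolicyModel(learner=learner, seed=seed).fit(dataset)


def fit_graft_failure_model(
    dataset: EpisodeDataset, learner: str = "logistic", tau: float = 0.5, seed: int = 0
) -> GraftFailurePolicyModel:
    return GraftFailurePolicyModel(learner=learner, tau=tau, seed=seed).fit(dataset)
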