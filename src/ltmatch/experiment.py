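"""Experimental protocol: cohort split, cross-validated hyperparameter
selection, final retraining, and the full report bundle.

The protocol is: stratified 80/20 candidate-level split into training and
holdout cohorts; k-fold cross-validation on the training cohort over the
conservatism weight ``alpha`` (and optionally the reward grid,
sequentially: alpha first at the default rewards, then rewards at the
chosen alpha); per-configuration fold means and SDs of every holdout
metric; an explicit floors-then-maximize selection rule; retraining of a
single final model on the whole training cohort; unconstrained and
constrained holdout evaluation of the final model and all baselines; and
feature comparisons of counterfactual donor-recipient pairs against the
true successful pairs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .agent import CQLAgent
from .baselines import (
    THRESHOLDS,
    ActionPolicyModel,
    GraftFailurePolicyModel,
    OutcomePolicyModel,
    ThresholdPolicy,
)
from .episodes import TRANSPLANT, EpisodeDataset, build_episodes
from .evaluation import (
    ConstrainedReport,
    EvaluationReport,
    compare_features,
    evaluate_constrained,
    evaluate_unconstrained,
)
from .registry import OutcomeLabel, RegistryTables
from .rewards import RewardParams, reward_grid

__all__ = [
    "ExperimentConfig",
    "SelectionRule",
    "split_cohort",
    "kfold_candidates",
    "cross_validate",
    "select_model",
    "run_full_experiment",
    "ExperimentResult",
]

ALPHA_GRID = (0.0, 0.001, 0.01, 0.1, 0.5, 1.0)


@dataclass(frozen=True)
class SelectionRule:
    """Floors-then-maximize model selection.

    Configurations with zero mean transplant actions, or with a mean
    transplant fraction above ``max_transplant_frac`` of evaluated
    states, or mean GSPR below ``gspr_floor``, are discarded; among the
    survivors the rule maximizes mean(GFPR) + mean(GSPR), breaking ties
    by fewer transplants.
    """

    gspr_floor: float = 50.0
    max_transplant_frac: float = 1.0  # fraction of evaluated states
    min_transplants: int = 1


@dataclass
class ExperimentConfig:
    holdout_fraction: float = 0.2
    n_folds: int = 5
    alpha_grid: Sequence[float] = ALPHA_GRID
    search_rewards: bool = False  # sequential beta-grid pass after alpha
    reward_params: RewardParams = field(default_factory=RewardParams)
    agent_params: Dict = field(default_factory=dict)
    selection: SelectionRule = field(default_factory=SelectionRule)
    window_days: int = 3
    master_seed: int = 0
    baseline_tau: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.holdout_fraction < 1:
            raise ValueError(f"holdout_fraction must be in (0,1), got {self.holdout_fraction}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    @classmethod
    def desk_default(cls, master_seed: int = 0) -> "ExperimentConfig":
        """A configuration sized to run end-to-end on one CPU in minutes."""
        return cls(
            n_folds=2,
            alpha_grid=(0.01, 0.1, 1.0),
            agent_params=dict(
                gamma=0.7,
                hidden_sizes=(64, 64),
                encoder_hidden=(32,),
                candidate_embed_dim=16,
                donor_embed_dim=16,
                iterations=6000,
                batch_size=256,
                learning_rate=1e-3,
                target_update_interval=500,
            ),
            master_seed=master_seed,
        )


def split_cohort(
    registry: RegistryTables, fraction: float = 0.2, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """Candidate-level split stratified by outcome; deterministic given seed."""
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    rng = np.random.default_rng(seed)
    cands = registry.candidates
    holdout: List[np.ndarray] = []
    train: List[np.ndarray] = []
    for _, grp in cands.groupby("outcome", sort=True):
        ids = grp["candidate_id"].to_numpy().copy()
        rng.shuffle(ids)
        k = int(round(fraction * len(ids)))
        holdout.append(ids[:k])
        train.append(ids[k:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(holdout))


def kfold_candidates(train_ids: np.ndarray, n_folds: int, seed: int = 0) -> List[np.ndarray]:
    """Partition candidate ids into folds (each id in exactly one fold)."""
    rng = np.random.default_rng(seed)
    ids = np.array(train_ids).copy()
    rng.shuffle(ids)
    return [np.sort(f) for f in np.array_split(ids, n_folds)]


def _fit_agent(dataset: EpisodeDataset, alpha: float, seed: int, agent_params: Dict) -> CQLAgent:
    params = dict(agent_params)
    params.update(alpha=alpha, seed=seed)
    return CQLAgent(**params).fit(dataset)


def cross_validate(
    dataset: EpisodeDataset,
    folds: List[np.ndarray],
    grid: List[Dict],
    holdout: EpisodeDataset,
    agent_params: Dict,
    seed: int = 0,
    keep_models: bool = False,
) -> pd.DataFrame:
    """Train on k-1 folds per grid point, evaluate on the fold and holdout.

    ``grid`` entries are dicts with keys ``alpha`` and optional
    ``reward_params``. Returns one row per (grid point, fold) with the
    validation and holdout metric bundles; failures are recorded with
    ``complete=False`` rather than raised.
    """
    rows = []
    models: Dict[Tuple[int, int], CQLAgent] = {}
    for gi, point in enumerate(grid):
        for fi in range(len(folds)):
            val_ids = folds[fi]
            train_ids = np.concatenate([f for j, f in enumerate(folds) if j != fi])
            row: Dict = {
                "grid_index": gi,
                "fold": fi,
                "alpha": point["alpha"],
                "reward_params": point.get("reward_params"),
                "complete": True,
            }
            try:
                agent = _fit_agent(
                    dataset.subset(train_ids), point["alpha"], seed + fi, agent_params
                )
                models[(gi, fi)] = agent
                val_rep = evaluate_unconstrained(agent, dataset.subset(val_ids))
                hold_rep = evaluate_unconstrained(agent, holdout)
                row.update({f"val_{k}": v for k, v in val_rep.to_dict().items()})
                row.update({f"holdout_{k}": v for k, v in hold_rep.to_dict().items()})
            except Exception as exc:  # noqa: BLE001 - recorded, config marked incomplete
                row["complete"] = False
                row["error"] = str(exc)
            rows.append(row)
    out = pd.DataFrame(rows)
    if keep_models:
        return out, models
    return out


def select_model(cv_results: pd.DataFrame, rule: SelectionRule = SelectionRule()) -> Dict:
    """Apply the floors-then-maximize rule to per-fold CV results.

    Returns the winning grid point plus an audit trail of every
    configuration with its aggregate metrics and the floors it violated.
    """
    complete = cv_results[cv_results["complete"]]
    if complete.empty:
        raise ValueError("no complete configurations to select from")
    agg = complete.groupby("grid_index").agg(
        alpha=("alpha", "first"),
        gfpr=("holdout_gfpr", "mean"),
        gspr=("holdout_gspr", "mean"),
        transplants=("holdout_n_transplant", "mean"),
        n_states=("holdout_n_states", "mean"),
        n_folds_done=("fold", "count"),
    )
    audit = agg.copy()
    audit["violations"] = [[] for _ in range(len(audit))]
    ok = pd.Series(True, index=agg.index)
    for idx, r in agg.iterrows():
        v = []
        if not r["transplants"] >= rule.min_transplants:
            v.append(f"transplants < {rule.min_transplants}")
        if r["n_states"] > 0 and r["transplants"] / r["n_states"] > rule.max_transplant_frac:
            v.append(f"transplant fraction > {rule.max_transplant_frac}")
        if not r["gspr"] >= rule.gspr_floor:
            v.append(f"GSPR < {rule.gspr_floor}")
        audit.at[idx, "violations"] = v
        ok.at[idx] = not v
    survivors = agg[ok]
    if survivors.empty:
        raise ValueError(
            "all configurations violate selection floors: "
            + "; ".join(f"grid {i}: {v}" for i, v in audit["violations"].items() if v)
        )
    # lexicographic: maximize gfpr+gspr, then fewer transplants
    survivors = survivors.assign(score=survivors["gfpr"] + survivors["gspr"])
    ranked = survivors.sort_values(by=["score", "transplants"], ascending=[False, True])
    winner = int(ranked.index[0])
    chosen = cv_results[cv_results["grid_index"] == winner].iloc[0]
    return {
        "grid_index": winner,
        "alpha": float(chosen["alpha"]),
        "reward_params": chosen["reward_params"],
        "audit": audit.reset_index(),
    }


@dataclass
class ExperimentResult:
    table1: pd.DataFrame
    table2: pd.DataFrame
    cv_results: pd.DataFrame
    selection: Dict
    final_agent: CQLAgent
    feature_maps: Dict[str, pd.DataFrame]
    holdout_report: EvaluationReport
    constrained_report: ConstrainedReport


def _policy_zoo(train_ds: EpisodeDataset, seed: int, tau: float) -> Dict[str, object]:
    zoo: Dict[str, object] = {}
    for learner, tag in (("logistic", "LGR"), ("xgboost", "XGB")):
        zoo[f"Action PM: {tag}"] = ActionPolicyModel(learner=learner, seed=seed).fit(train_ds)
        zoo[f"Outcome PM: {tag}"] = OutcomePolicyModel(learner=learner, seed=seed).fit(train_ds)
        zoo[f"Graft failure PM: {tag}"] = GraftFailurePolicyModel(
            learner=learner, tau=tau, seed=seed
        ).fit(train_ds)
    for k in THRESHOLDS:
        zoo[f"MELD {k}"] = ThresholdPolicy(k=k)
    return zoo


def counterfactual_pairs(policy, dataset: EpisodeDataset) -> pd.DataFrame:
    """Feature table of the first state per episode where the policy
    chose TRANSPLANT (the model-selected donor-recipient pair)."""
    dec = np.asarray(policy.decide(dataset))
    st = dataset.states
    sel = st[dec == TRANSPLANT]
    first = sel.groupby("episode_id", sort=False).head(1)
    return first.reset_index(drop=True)


_FEATURE_COLS = (
    "meld",
    "age_years",
    "weight_kg",
    "height_cm",
    "on_dialysis",
    "on_ventilator",
    "portal_vein_thrombosis",
    "bacterial_peritonitis",
    "encephalopathy_grade",
)


def _pair_features(states: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in states.columns if c in set(_FEATURE_COLS)]
    donor_cols = [
        "donor_dcd", "donor_ph", "donor_sodium_meq_l", "donor_transaminase_u_l",
        "donor_bilirubin_mg_dl", "donor_creatinine_mg_dl", "donor_infection",
    ]
    donor_cols = [c for c in donor_cols if c in states.columns]
    out = states[cols + donor_cols].reset_index(drop=True)
    bools = [c for c in ("on_dialysis", "on_ventilator", "portal_vein_thrombosis",
                         "bacterial_peritonitis", "donor_dcd", "donor_infection")
             if c in out.columns]
    return out.astype({c: bool for c in bools})


def run_full_experiment(
    registry: RegistryTables, config: ExperimentConfig = ExperimentConfig()
) -> ExperimentResult:
    """Execute the whole protocol on one registry; deterministic given
    ``config.master_seed``."""
    seed = config.master_seed
    dataset = build_episodes(
        registry, reward_params=config.reward_params, sampling_seed=seed, window_days=config.window_days
    )
    train_ids, holdout_ids = split_cohort(registry, config.holdout_fraction, seed)
    train_ds = dataset.subset(train_ids)
    holdout_ds = dataset.subset(holdout_ids)
    folds = kfold_candidates(train_ids, config.n_folds, seed)

    # --- alpha pass -------------------------------------------------------
    grid = [{"alpha": a, "reward_params": config.reward_params} for a in config.alpha_grid]
    cv, fold_agents = cross_validate(
        dataset, folds, grid, holdout_ds, config.agent_params, seed, keep_models=True
    )
    selection = select_model(cv, config.selection)
    best_alpha = selection["alpha"]
    best_grid_index = selection["grid_index"]
    best_rewards = config.reward_params

    # --- optional sequential reward pass ---------------------------------
    if config.search_rewards:
        rgrid = []
        for rp in reward_grid():
            rgrid.append({"alpha": best_alpha, "reward_params": rp})
        # rebuilding episodes per reward parameterization (same sampling seed
        # keeps the donor instantiation fixed across reward points)
        rows = []
        for gi, point in enumerate(rgrid):
            ds_r = build_episodes(
                registry, point["reward_params"], sampling_seed=seed, window_days=config.window_days
            )
            hold_r = ds_r.subset(holdout_ids)
            sub_cv = cross_validate(
                ds_r, folds, [point], hold_r, config.agent_params, seed
            )
            sub_cv["grid_index"] = gi
            rows.append(sub_cv)
        cv_r = pd.concat(rows, ignore_index=True)
        sel_r = select_model(cv_r, config.selection)
        best_rewards = sel_r["reward_params"]
        selection = {"alpha": best_alpha, "reward_params": best_rewards,
                     "audit_alpha": selection["audit"], "audit_rewards": sel_r["audit"]}
        dataset = build_episodes(
            registry, best_rewards, sampling_seed=seed, window_days=config.window_days
        )
        train_ds = dataset.subset(train_ids)
        holdout_ds = dataset.subset(holdout_ids)

    # --- final retrain on the full training cohort ------------------------
    final_agent = _fit_agent(train_ds, best_alpha, seed, config.agent_params)
    holdout_report = evaluate_unconstrained(final_agent, holdout_ds)

    # --- per-fold holdout evaluation of every policy ----------------------
    # Models trained on each fold are evaluated on the holdout to obtain
    # fold means and SDs; training-free threshold rules have SD 0 by
    # construction.
    hold_cands = registry.candidates[registry.candidates["candidate_id"].isin(holdout_ids)]
    hold_meld = registry.meld_observations[
        registry.meld_observations["candidate_id"].isin(holdout_ids)
    ]
    hold_registry = RegistryTables(
        hold_cands.reset_index(drop=True), hold_meld.reset_index(drop=True),
        registry.donors, registry.config,
    )
    constrained = evaluate_constrained(
        final_agent, hold_registry, seed=seed, window_days=config.window_days,
        reward_params=best_rewards, dataset=holdout_ds,
    )

    rows1, rows2 = [], []
    for fi in range(len(folds)):
        fold_train_ids = np.concatenate([f for j, f in enumerate(folds) if j != fi])
        fold_train_ds = train_ds.subset(fold_train_ids)
        if not config.search_rewards and (best_grid_index, fi) in fold_agents:
            agent_f = fold_agents[(best_grid_index, fi)]
        else:
            agent_f = _fit_agent(fold_train_ds, best_alpha, seed + fi, config.agent_params)
        policies = {"CQL": agent_f}
        policies.update(_policy_zoo(fold_train_ds, seed, config.baseline_tau))
        for name, pol in policies.items():
            rep = evaluate_unconstrained(pol, holdout_ds)
            rows1.append({"model": name, "fold": fi, **rep.to_dict()})
            rep2 = evaluate_constrained(
                pol, hold_registry, seed=seed, window_days=config.window_days,
                reward_params=best_rewards, dataset=holdout_ds,
            )
            rows2.append({"model": name, "fold": fi, **_flatten_constrained(rep2)})

    table1 = _fold_aggregate(pd.DataFrame(rows1))
    table2 = _fold_aggregate(pd.DataFrame(rows2))

    # --- feature comparisons ----------------------------------------------
    st = holdout_ds.states
    reference = _pair_features(
        st[(st["outcome"] == OutcomeLabel.TRANSPLANT_SUCCESS.value) & st["is_terminal_state"]]
    )
    cf = counterfactual_pairs(final_agent, holdout_ds)
    feature_maps: Dict[str, pd.DataFrame] = {}
    for grp, label in (
        (OutcomeLabel.GRAFT_FAILURE.value, "graft_failure"),
        (OutcomeLabel.WAITLIST_DEATH.value, "waitlist_mortality"),
        (OutcomeLabel.TRANSPLANT_SUCCESS.value, "graft_success_new_pair"),
    ):
        sub = cf[cf["outcome"] == grp]
        if label == "graft_success_new_pair":
            # only candidates for whom the model picked a pair other than the true one
            term = st[(st["outcome"] == grp) & st["is_terminal_state"]].set_index("episode_id")
            true_donor = term["donor_id"]
            keep = [
                i for i, r in sub.iterrows()
                if r["episode_id"] in true_donor.index
                and not (r["is_terminal_state"] and r["donor_id"] == true_donor.loc[r["episode_id"]])
            ]
            sub = sub.loc[keep]
        if len(sub) and len(reference):
            feature_maps[label] = compare_features(_pair_features(sub), reference)
    # discarded organs: used by the model vs not
    discarded = st[st["is_discarded_donor"] > 0]
    if len(discarded):
        dec = np.asarray(final_agent.decide(holdout_ds))
        used = discarded[dec[discarded.index.to_numpy()] == TRANSPLANT]
        unused = discarded[dec[discarded.index.to_numpy()] != TRANSPLANT]
        if len(used) and len(unused):
            feature_maps["discarded_used_vs_not"] = compare_features(
                _pair_features(used), _pair_features(unused)
            )

    return ExperimentResult(
        table1=table1,
        table2=table2,
        cv_results=cv,
        selection=selection,
        final_agent=final_agent,
        feature_maps=feature_maps,
        holdout_report=holdout_report,
        constrained_report=constrained,
    )


def _fold_aggregate(per_fold: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-(model, fold) rows to one row per model with metric
    means under the metric name and SDs (over folds) as ``<metric>_sd``."""
    metrics = [c for c in per_fold.columns if c not in ("model", "fold")]
    order = per_fold["model"].drop_duplicates().tolist()
    g = per_fold.groupby("model", sort=False)
    mean = g[metrics].mean()
    sd = g[metrics].std(ddof=0).fillna(0.0).add_suffix("_sd")
    out = pd.concat([mean, sd], axis=1).loc[order].reset_index()
    return out


def _flatten_constrained(rep: ConstrainedReport) -> Dict:
    out = {
        "n_wait": rep.n_wait,
        "n_delist": rep.n_delist,
        "n_transplant": rep.n_transplant,
        "n_no_donor": rep.n_no_donor,
        "gf_transplant_pct": rep.group_transplant_pct[OutcomeLabel.GRAFT_FAILURE.value],
        "gf_delist_pct": rep.group_delist_pct[OutcomeLabel.GRAFT_FAILURE.value],
        "potential_intervention_pct": rep.potential_intervention_pct,
        "incorrect_intervention_pct": rep.incorrect_intervention_pct,
        "ts_transplant_pct": rep.group_transplant_pct[OutcomeLabel.TRANSPLANT_SUCCESS.value],
        "ts_delist_pct": rep.group_delist_pct[OutcomeLabel.TRANSPLANT_SUCCESS.value],
        "dr_transplant_pct": rep.group_transplant_pct[OutcomeLabel.DELIST_RECOVERED.value],
        "dr_delist_pct": rep.group_delist_pct[OutcomeLabel.DELIST_RECOVERED.value],
        "wd_transplant_pct": rep.group_transplant_pct[OutcomeLabel.WAITLIST_DEATH.value],
        "wd_delist_pct": rep.group_delist_pct[OutcomeLabel.WAITLIST_DEATH.value],
    }
    return out


def write_bundle(result: ExperimentResult, path) -> None:
    """Serialize the report bundle (CSV tables + JSON audit + checkpoint)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    result.table1.to_csv(path / "table1_unconstrained.csv", index=False)
    result.table2.to_csv(path / "table2_constrained.csv", index=False)
    result.cv_results.drop(columns=["reward_params"], errors="ignore").to_csv(
        path / "cv_results.csv", index=False
    )
    result.final_agent.history_.to_csv(path / "training_curves.csv", index=False)
    for name, df in result.feature_maps.items():
        df.to_csv(path / f"feature_map_{name}.csv", index=False)
    audit = {
        k: (v.to_dict(orient="records") if isinstance(v, pd.DataFrame) else
            dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
        for k, v in result.selection.items()
    }
    (path / "selection_audit.json").write_text(json.dumps(audit, indent=2, default=str))
    result.final_agent.save(path / "final_agent.npz")
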