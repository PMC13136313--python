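"""Policy evaluation: clinically grounded metrics, a constrained
allocation simulator, weighted importance sampling, and feature
comparisons.

Unconstrained metrics (the policy is queried independently at every
state; a candidate may be "transplanted" at several states):

* action match rate — percent of decisions equal to the recorded ones;
* GFPR — of graft-failure candidates, percent whose true terminal pair
  the policy declined to transplant;
* GFIR — of graft-failure candidates, percent offered a transplant at an
  earlier (non-terminal) state, i.e. matched to an alternative donor;
* GSPR — of successful-transplant candidates, percent transplanted at the
  true terminal state or any earlier state;
* CRR — of recovered (delisted) candidates, percent the policy delisted
  at any state (a terminal-state-only variant is available);
* CIR — of waitlist-mortality candidates, percent the policy would have
  transplanted at some state.

The constrained simulator replays the holdout chronologically with a
live donor pool: a donor leaves the pool when transplanted, a candidate
leaves the waitlist after any terminal action, and a donor claimed by
several candidates goes to the closest candidate in time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .episodes import ACTIONS, DELIST, TRANSPLANT, WAIT, EpisodeDataset, build_episodes
from .registry import OutcomeLabel, RegistryTables
from .rewards import RewardParams

__all__ = [
    "EvaluationReport",
    "ConstrainedReport",
    "evaluate_unconstrained",
    "evaluate_constrained",
    "wis_value",
    "compare_features",
]


@dataclass
class EvaluationReport:
    """Unconstrained metric bundle (percent metrics in [0, 100])."""

    action_match_rate: float
    n_wait: int
    n_delist: int
    n_transplant: int
    gfpr: float
    gfir: float
    gspr: float
    crr: float
    cir: float
    n_states: int = 0

    def to_dict(self) -> Dict[str, float]:
        return dict(self.__dict__)


def _pct(numer: int, denom: int, name: str) -> float:
    if denom == 0:
        warnings.warn(f"metric {name} is undefined: empty outcome subgroup")
        return float("nan")
    return 100.0 * numer / denom


def evaluate_unconstrained(
    policy, holdout: EpisodeDataset, crr_any_state: bool = True
) -> EvaluationReport:
    """Query ``policy`` at every recorded state of the holdout and tally."""
    decisions_all = np.asarray(policy.decide(holdout))
    tr = holdout.transitions
    sidx = tr["state_idx"].to_numpy()
    dec = decisions_all[sidx]
    recorded = tr["action"].to_numpy()

    match = 100.0 * float(np.mean(dec == recorded)) if len(dec) else float("nan")
    n_wait = int(np.sum(dec == WAIT))
    n_delist = int(np.sum(dec == DELIST))
    n_transplant = int(np.sum(dec == TRANSPLANT))

    df = pd.DataFrame(
        {
            "episode_id": tr["episode_id"].to_numpy(),
            "terminal": tr["terminal"].to_numpy(),
            "outcome": tr["outcome"].to_numpy(),
            "decision": dec,
        }
    )
    g = df.groupby("episode_id", sort=False)
    per_ep = pd.DataFrame(
        {
            "tx_any": g["decision"].apply(lambda d: bool((d == TRANSPLANT).any())),
            "delist_any": g["decision"].apply(lambda d: bool((d == DELIST).any())),
        }
    )
    term = df[df["terminal"]].set_index("episode_id")
    per_ep["outcome"] = term["outcome"].reindex(per_ep.index)
    per_ep["tx_terminal"] = (
        (term["decision"] == TRANSPLANT).reindex(per_ep.index, fill_value=False).astype(bool)
    )
    per_ep["delist_terminal"] = (
        (term["decision"] == DELIST).reindex(per_ep.index, fill_value=False).astype(bool)
    )
    nonterm = df[~df["terminal"]].groupby("episode_id", sort=False)["decision"]
    tx_early = nonterm.apply(lambda d: bool((d == TRANSPLANT).any()))
    per_ep["tx_early"] = tx_early.reindex(per_ep.index, fill_value=False).astype(bool)

    gf = per_ep[per_ep["outcome"] == OutcomeLabel.GRAFT_FAILURE.value]
    ts = per_ep[per_ep["outcome"] == OutcomeLabel.TRANSPLANT_SUCCESS.value]
    dr = per_ep[per_ep["outcome"] == OutcomeLabel.DELIST_RECOVERED.value]
    wd = per_ep[per_ep["outcome"] == OutcomeLabel.WAITLIST_DEATH.value]

    gfpr = _pct(int((~gf["tx_terminal"]).sum()), len(gf), "GFPR")
    gfir = _pct(int(gf["tx_early"].sum()), len(gf), "GFIR")
    gspr = _pct(int((ts["tx_terminal"] | ts["tx_early"]).sum()), len(ts), "GSPR")
    if crr_any_state:
        crr = _pct(int(dr["delist_any"].sum()), len(dr), "CRR")
    else:
        crr = _pct(int(dr["delist_terminal"].sum()), len(dr), "CRR")
    cir = _pct(int(wd["tx_any"].sum()), len(wd), "CIR")

    return EvaluationReport(
        action_match_rate=match,
        n_wait=n_wait,
        n_delist=n_delist,
        n_transplant=n_transplant,
        gfpr=gfpr,
        gfir=gfir,
        gspr=gspr,
        crr=crr,
        cir=cir,
        n_states=len(dec),
    )


# ---------------------------------------------------------------------------
# constrained simulator


@dataclass
class ConstrainedReport:
    """Tally of the chronological, resource-constrained replay.

    Percentages are over the candidates of each true-outcome group; in
    the graft-failure group ``transplant_pct`` splits exactly into
    ``potential_intervention_pct`` (new donor) plus
    ``incorrect_intervention_pct`` (the same donor that failed).
    """

    n_wait: int
    n_delist: int
    n_transplant: int
    n_no_donor: int
    group_transplant_pct: Dict[str, float]
    group_delist_pct: Dict[str, float]
    potential_intervention_pct: float
    incorrect_intervention_pct: float
    group_sizes: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> Dict:
        return dict(self.__dict__)


_GROUPS = (
    OutcomeLabel.GRAFT_FAILURE.value,
    OutcomeLabel.TRANSPLANT_SUCCESS.value,
    OutcomeLabel.DELIST_RECOVERED.value,
    OutcomeLabel.WAITLIST_DEATH.value,
)


def evaluate_constrained(
    policy,
    holdout_registry: RegistryTables,
    seed: int = 0,
    window_days: int = 3,
    reward_params: RewardParams = RewardParams(),
    dataset: Optional[EpisodeDataset] = None,
) -> ConstrainedReport:
    """Chronological sweep with single-use donors and removable candidates.

    The policy's decision at each visited state is resolved in date
    order: TRANSPLANT claims the state's attached donor (claims on the
    same donor go to the candidate closest in time, ties broken by
    earlier listing date then candidate id; an already-used donor
    downgrades the decision to WAIT and counts as "no donor"); DELIST
    removes the candidate; after any terminal event the candidate's later
    states are skipped.
    """
    if dataset is None:
        dataset = build_episodes(
            holdout_registry, reward_params=reward_params, sampling_seed=seed, window_days=window_days
        )
    decisions = np.asarray(policy.decide(dataset))
    st = dataset.states
    cands = holdout_registry.candidates.set_index("candidate_id")
    listing = cands["listing_date"]
    true_donor = cands["donor_id"]

    order = np.lexsort(
        (st["step"].to_numpy(), st["episode_id"].to_numpy(), st["obs_date"].to_numpy())
    )
    ep = st["episode_id"].to_numpy()[order]
    dates = st["obs_date"].to_numpy()[order]
    donor_ids = st["donor_id"].to_numpy()[order]
    dec = decisions[order]

    donors = holdout_registry.donors
    donor_used = dict.fromkeys(donors["donor_id"].to_numpy().tolist(), False)
    recovery = donors.set_index("donor_id")["recovery_date"]

    removed: set = set()
    terminal_event: Dict[int, tuple] = {}  # cand -> (kind, donor_id or None)
    n_wait = n_delist = n_transplant = n_no_donor = 0

    i = 0
    n = len(ep)
    while i < n:
        day = dates[i]
        j = i
        claims: Dict[int, list] = {}
        pass_rows = []
        while j < n and dates[j] == day:
            c = ep[j]
            if c not in removed:
                pass_rows.append(j)
                if dec[j] == TRANSPLANT:
                    d = int(donor_ids[j])
                    claims.setdefault(d, []).append((c, j))
            j += 1

        # resolve transplant claims for this day
        awarded: Dict[int, int] = {}  # candidate -> donor
        for d, claimants in claims.items():
            if d < 0 or donor_used.get(d, True):
                continue
            if len(claimants) == 1:
                winner = claimants[0][0]
            else:
                key = lambda cj: (
                    abs(int(recovery.loc[d]) - int(day)),
                    int(listing.loc[cj[0]]),
                    int(cj[0]),
                )
                winner = min(claimants, key=key)[0]
            donor_used[d] = True
            awarded[winner] = d

        for r in pass_rows:
            c = ep[r]
            if c in removed:
                continue
            a = dec[r]
            if a == TRANSPLANT:
                if c in awarded:
                    n_transplant += 1
                    removed.add(c)
                    terminal_event[c] = ("TRANSPLANT", awarded[c])
                else:
                    n_no_donor += 1
                    n_wait += 1  # downgraded to WAIT
            elif a == DELIST:
                n_delist += 1
                removed.add(c)
                terminal_event[c] = ("DELIST", None)
            else:
                n_wait += 1
        i = j

    outcome = cands["outcome"]
    group_tx: Dict[str, float] = {}
    group_delist: Dict[str, float] = {}
    sizes: Dict[str, int] = {}
    eval_ids = set(st["episode_id"].unique().tolist())
    pot = inc = 0
    gf_total = 0
    for grp in _GROUPS:
        ids = [c for c in outcome.index[outcome == grp] if c in eval_ids]
        sizes[grp] = len(ids)
        tx = sum(1 for c in ids if terminal_event.get(c, ("",))[0] == "TRANSPLANT")
        dl = sum(1 for c in ids if terminal_event.get(c, ("",))[0] == "DELIST")
        group_tx[grp] = _pct(tx, len(ids), f"constrained transplant% [{grp}]")
        group_delist[grp] = _pct(dl, len(ids), f"constrained delist% [{grp}]")
        if grp == OutcomeLabel.GRAFT_FAILURE.value:
            gf_total = len(ids)
            for c in ids:
                ev = terminal_event.get(c)
                if ev and ev[0] == "TRANSPLANT":
                    if not np.isnan(true_donor.loc[c]) and int(true_donor.loc[c]) == ev[1]:
                        inc += 1
                    else:
                        pot += 1

    return ConstrainedReport(
        n_wait=n_wait,
        n_delist=n_delist,
        n_transplant=n_transplant,
        n_no_donor=n_no_donor,
        group_transplant_pct=group_tx,
        group_delist_pct=group_delist,
        potential_intervention_pct=_pct(pot, gf_total, "potential intervention"),
        incorrect_intervention_pct=_pct(inc, gf_total, "incorrect intervention"),
        group_sizes=sizes,
    )


# ---------------------------------------------------------------------------
# weighted importance sampling


def wis_value(
    policy,
    holdout: EpisodeDataset,
    behavior_model,
    temperature: float = 1.0,
    clip: float = 100.0,
    gamma: float = 0.99,
) -> float:
    """Self-normalized off-policy value estimate.

    Per-episode weight is the product over steps of
    ``pi_e(a_t|s_t) / pi_b(a_t|s_t)``, each ratio clipped to
    ``[1/clip, clip]``; the estimate is ``sum(w_i G_i) / sum(w_i)`` with
    ``G_i`` the discounted return of episode i under the dataset rewards.
    """
    pi_e = np.asarray(policy.action_probabilities(holdout, temperature))
    pi_b = np.asarray(behavior_model.predict_action_proba(holdout))
    tr = holdout.transitions
    sidx = tr["state_idx"].to_numpy()
    a = tr["action"].to_numpy()
    ratio = pi_e[sidx, a] / np.maximum(pi_b[sidx, a], 1e-12)
    ratio = np.clip(ratio, 1.0 / clip, clip)

    df = pd.DataFrame(
        {
            "episode_id": tr["episode_id"].to_numpy(),
            "step": tr["step"].to_numpy(),
            "reward": tr["reward"].to_numpy(),
            "ratio": ratio,
        }
    )
    df["disc"] = gamma ** (df["step"] - 1)
    g = df.groupby("episode_id", sort=False)
    returns = g.apply(lambda x: float((x["reward"] * x["disc"]).sum()), include_groups=False)
    weights = g["ratio"].prod()
    total = float(weights.sum())
    if total <= 0:
        warnings.warn("WIS undefined: total importance weight is zero")
        return float("nan")
    return float((weights * returns).sum() / total)


# ---------------------------------------------------------------------------
# feature comparisons


def _hedges_g(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    pooled = ((na - 1) * va + (nb - 1) * vb) / max(na + nb - 2, 1)
    if pooled == 0:
        return 0.0
    d = (a.mean() - b.mean()) / np.sqrt(pooled)
    correction = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)  # small-sample correction
    return float(d * correction)


def _cohens_h(p1: float, p2: float) -> float:
    return float(2.0 * np.arcsin(np.sqrt(p1)) - 2.0 * np.arcsin(np.sqrt(p2)))


def _cramers_v(table: np.ndarray) -> float:
    chi2 = stats.chi2_contingency(table, correction=False)[0]
    n = table.sum()
    k = min(table.shape) - 1
    if n == 0 or k == 0:
        return 0.0
    return float(np.sqrt(chi2 / (n * k)))


def _feature_kind(col: pd.Series) -> str:
    vals = col.dropna().unique()
    if col.dtype == bool or set(np.unique(vals)).issubset({0, 1, True, False}):
        return "binary"
    if col.dtype == object or str(col.dtype).startswith("category"):
        return "categorical"
    if np.issubdtype(col.dtype, np.integer) and len(vals) <= 6:
        return "categorical"
    return "continuous"


def compare_features(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-feature tests and effect sizes of group A versus reference B.

    Continuous features: Shapiro-Wilk normality screen selects Student's
    t-test vs Mann-Whitney U; effect size Hedge's g (signed, A minus B).
    Binary: Fisher exact, Cohen's h. Multi-category: chi-squared,
    Cramer's V (non-directional). Features constant in both groups are
    flagged untestable rather than significant.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    shared = [c for c in group_a.columns if c in group_b.columns]
    rows = []
    n_tests = max(len(shared), 1)
    threshold = alpha / n_tests if bonferroni else alpha
    for col in shared:
        a = group_a[col].dropna()
        b = group_b[col].dropna()
        kind = _feature_kind(pd.concat([a, b]))
        row = {
            "feature": col,
            "kind": kind,
            "test": None,
            "p_value": np.nan,
            "effect_size": np.nan,
            "effect_name": None,
            "direction": 0,
            "significant": False,
            "testable": True,
        }
        if a.nunique() <= 1 and b.nunique() <= 1 and (
            a.nunique() == 0 or b.nunique() == 0 or a.iloc[0] == b.iloc[0]
        ):
            row["testable"] = False
            rows.append(row)
            continue
        if kind == "continuous":
            av, bv = a.to_numpy(float), b.to_numpy(float)
            normal = True
            for v in (av, bv):
                if len(v) >= 3 and np.ptp(v) > 0:
                    sub = v if len(v) <= 5000 else v[:: max(1, len(v) // 5000)][:5000]
                    normal &= stats.shapiro(sub).pvalue > 0.05
            if normal:
                row["test"] = "t"
                row["p_value"] = float(stats.ttest_ind(av, bv).pvalue)
            else:
                row["test"] = "mannwhitney"
                row["p_value"] = float(stats.mannwhitneyu(av, bv, alternative="two-sided").pvalue)
            row["effect_size"] = _hedges_g(av, bv)
            row["effect_name"] = "hedges_g"
            row["direction"] = int(np.sign(row["effect_size"]))
        elif kind == "binary":
            av, bv = a.astype(float), b.astype(float)
            t = np.array(
                [
                    [float((av == 1).sum()), float((av == 0).sum())],
                    [float((bv == 1).sum()), float((bv == 0).sum())],
                ]
            )
            row["test"] = "fisher"
            row["p_value"] = float(stats.fisher_exact(t)[1])
            row["effect_size"] = _cohens_h(av.mean(), bv.mean())
            row["effect_name"] = "cohens_h"
            row["direction"] = int(np.sign(row["effect_size"]))
        else:
            cats = sorted(set(a.unique()) | set(b.unique()))
            t = np.array(
                [
                    [float((a == c).sum()) for c in cats],
                    [float((b == c).sum()) for c in cats],
                ]
            )
            t = t[:, t.sum(axis=0) > 0]
            row["test"] = "chi2"
            row["p_value"] = float(stats.chi2_contingency(t, correction=False)[1])
            row["effect_size"] = _cramers_v(t)
            row["effect_name"] = "cramers_v"
            row["direction"] = 0  # non-directional
        row["significant"] = bool(row["p_value"] < threshold)
        rows.append(row)
    return pd.DataFrame(rows)
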