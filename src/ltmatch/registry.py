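"""Synthetic liver-transplant registry generator.

Produces three flat tables — candidates, MELD observations, donors — with
the statistical structure the downstream waitlist decision analysis
assumes: per-candidate MELD trajectories that drift over time with a
hidden severity variable, a concurrent donor stream in which low-quality
organs are discarded non-randomly, and four terminal outcomes assigned by
a synthetic behavior policy (waitlist death, transplant with or without
1-year graft failure, delisting after recovery, censoring at study end).

Default parameters are calibrated so that, at the default cohort size,
roughly 63% of candidates are transplanted, 17% die on the waitlist, ~7%
of transplants end in 1-year graft failure, episodes carry ~4.9 MELD
observations on average, and the blood-type-matched potential-donor pool
at each MELD timepoint averages ~8.1 organs.

Calendar time is an abstract non-negative integer day index; no real
dates are used. The study horizon scales with cohort size so that the
per-day balance between candidate demand and donor supply — and hence the
donor-pool statistics — is invariant to ``n_candidates``.
"""

from __future__ import annotations

import enum
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeLabel",
    "GeneratorConfig",
    "RegistryTables",
    "generate_cohort",
    "write_registry",
    "read_registry",
]


class OutcomeLabel(str, enum.Enum):
    """Terminal outcome of a waitlist episode.

    GRAFT_FAILURE means graft loss or all-cause death within 1 year
    post-transplant; CENSORED means the candidate was still waiting at
    study end with no defined outcome.
    """

    WAITLIST_DEATH = "WAITLIST_DEATH"
    DELIST_RECOVERED = "DELIST_RECOVERED"
    TRANSPLANT_SUCCESS = "TRANSPLANT_SUCCESS"
    GRAFT_FAILURE = "GRAFT_FAILURE"
    CENSORED = "CENSORED"


TRANSPLANT_OUTCOMES = (OutcomeLabel.TRANSPLANT_SUCCESS, OutcomeLabel.GRAFT_FAILURE)

BLOOD_TYPES = ("O", "A", "B", "AB")
#: Approximate US blood-type frequencies.
BLOOD_TYPE_PROBS = (0.45, 0.40, 0.11, 0.04)

MELD_MIN, MELD_MAX = 6, 40


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic registry.

    The committed defaults are the study conditions for the analysis;
    hazard intercepts were calibrated once against the target cohort
    composition and then frozen.
    """

    n_candidates: int = 40_000
    seed: int = 0

    # --- calendar -------------------------------------------------------
    #: Study horizon in days per candidate; the horizon is
    #: ``round(days_per_candidate * n_candidates)`` (floor 365) so donor
    #: supply/demand per day does not depend on cohort size.
    days_per_candidate: float = 0.66

    # --- donor stream ---------------------------------------------------
    donor_arrival_rate: float = 3.22  # donors per day
    donor_window_days: int = 3  # symmetric matching window
    discard_intercept: float = -0.60
    discard_quality_coef: float = 1.30  # discard logit decreases in quality

    # --- MELD trajectories ---------------------------------------------
    meld0_mean: float = 17.0
    meld0_severity_coef: float = 4.0
    meld0_sd: float = 3.0
    meld_drift: float = 0.55  # per-step drift scale, multiplies severity
    meld_drift_shift: float = 0.35  # population-level worsening trend
    meld_noise_sd: float = 2.2
    obs_gap_mean_days: float = 30.0
    max_steps: int = 60

    # --- behavior-policy hazards (per observation) ----------------------
    death_intercept: float = -2.58
    death_meld_coef: float = 1.40
    recovery_intercept: float = -5.12
    recovery_meld_coef: float = 1.80  # recovery logit decreases in MELD
    tx_intercept: float = -1.62
    tx_meld_coef: float = 0.90
    tx_quality_coef: float = 0.60

    # --- graft-failure model -------------------------------------------
    gf_intercept: float = -2.08
    gf_quality_coef: float = 0.90  # GF logit decreases in donor quality
    gf_severity_coef: float = 0.35  # ... and increases in candidate acuity

    def __post_init__(self) -> None:
        if self.n_candidates < 0:
            raise ValueError(f"n_candidates must be >= 0, got {self.n_candidates}")
        for name in ("donor_arrival_rate", "obs_gap_mean_days", "days_per_candidate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("meld_noise_sd", "meld0_sd", "meld_drift"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if self.donor_window_days < 0:
            raise ValueError("donor_window_days must be >= 0")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")

    @property
    def study_days(self) -> int:
        return max(365, int(round(self.days_per_candidate * self.n_candidates)))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# table schemas

CANDIDATE_COLUMNS: Dict[str, str] = {
    "candidate_id": "int64",
    "blood_type": "object",
    "listing_date": "int64",
    "age_years": "float64",
    "sex": "int64",
    "weight_kg": "float64",
    "height_cm": "float64",
    "on_dialysis": "bool",
    "on_ventilator": "bool",
    "portal_vein_thrombosis": "bool",
    "bacterial_peritonitis": "bool",
    "encephalopathy_grade": "int64",
    "latent_severity": "float64",
    "outcome": "object",
    "outcome_date": "int64",
    "donor_id": "float64",  # NaN unless transplanted
}

MELD_COLUMNS: Dict[str, str] = {
    "candidate_id": "int64",
    "obs_date": "int64",
    "meld": "int64",
}

DONOR_COLUMNS: Dict[str, str] = {
    "donor_id": "int64",
    "blood_type": "object",
    "recovery_date": "int64",
    "age_years": "float64",
    "weight_kg": "float64",
    "height_cm": "float64",
    "dcd": "bool",
    "ph": "float64",
    "sodium_meq_l": "float64",
    "transaminase_u_l": "float64",
    "bilirubin_mg_dl": "float64",
    "creatinine_mg_dl": "float64",
    "infection": "bool",
    "latent_quality": "float64",
    "disposition": "object",
    "caused_graft_failure": "bool",
}

SCHEMAS = {
    "candidates": CANDIDATE_COLUMNS,
    "meld_observations": MELD_COLUMNS,
    "donors": DONOR_COLUMNS,
}

#: Candidate features exposed to policies, in fixed order. The hidden
#: generator variable latent_severity is deliberately excluded.
CANDIDATE_STATE_FEATURES = (
    "age_years",
    "sex",
    "weight_kg",
    "height_cm",
    "on_dialysis",
    "on_ventilator",
    "portal_vein_thrombosis",
    "bacterial_peritonitis",
    "encephalopathy_grade",
)

#: Donor features exposed to policies, in fixed order (latent_quality and
#: disposition/graft-failure labels are not part of the feature block;
#: the two donor flags are carried separately in the state).
DONOR_STATE_FEATURES = (
    "age_years",
    "weight_kg",
    "height_cm",
    "dcd",
    "ph",
    "sodium_meq_l",
    "transaminase_u_l",
    "bilirubin_mg_dl",
    "creatinine_mg_dl",
    "infection",
)


@dataclass
class RegistryTables:
    candidates: pd.DataFrame
    meld_observations: pd.DataFrame
    donors: pd.DataFrame
    config: GeneratorConfig | None = None

    def __iter__(self):
        return iter((self.candidates, self.meld_observations, self.donors))


# ---------------------------------------------------------------------------
# generation


def _empty_tables(config: GeneratorConfig) -> RegistryTables:
    frames = {}
    for name, schema in SCHEMAS.items():
        frames[name] = pd.DataFrame({c: pd.Series(dtype=t) for c, t in schema.items()})
    return RegistryTables(frames["candidates"], frames["meld_observations"], frames["donors"], config)


def _make_donors(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    horizon = config.study_days
    n = rng.poisson(config.donor_arrival_rate * (horizon + 1))
    q = rng.normal(size=n)
    bt = rng.choice(BLOOD_TYPES, size=n, p=BLOOD_TYPE_PROBS)
    recovery = rng.integers(0, horizon + 1, size=n)
    discard_p = _sigmoid(config.discard_intercept - config.discard_quality_coef * q)
    discarded = rng.random(n) < discard_p
    donors = pd.DataFrame(
        {
            "donor_id": np.arange(n, dtype=np.int64),
            "blood_type": bt,
            "recovery_date": recovery.astype(np.int64),
            "age_years": np.clip(rng.normal(45.0 - 8.0 * q, 12.0), 12.0, 85.0),
            "weight_kg": np.clip(rng.normal(80.0, 15.0, size=n), 35.0, 160.0),
            "height_cm": np.clip(rng.normal(172.0, 10.0, size=n), 140.0, 205.0),
            "dcd": rng.random(n) < _sigmoid(-1.5 - 0.8 * q),
            "ph": np.clip(rng.normal(7.35 + 0.06 * q, 0.08), 6.8, 7.8),
            "sodium_meq_l": np.clip(rng.normal(140.0 + 2.5 * q, 4.5), 115.0, 170.0),
            "transaminase_u_l": np.exp(rng.normal(3.6 - 0.5 * q, 0.6)),
            "bilirubin_mg_dl": np.exp(rng.normal(-0.3 - 0.2 * q, 0.5)),
            "creatinine_mg_dl": np.exp(rng.normal(0.0 - 0.15 * q, 0.4)),
            "infection": rng.random(n) < _sigmoid(-2.0 - 0.5 * q),
            "latent_quality": q,
            "disposition": np.where(discarded, "DISCARDED", "USED"),
            "caused_graft_failure": np.zeros(n, dtype=bool),  # filled by the sweep
        }
    )
    return donors


def _make_candidates(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_candidates
    horizon = config.study_days
    sev = rng.normal(size=n)
    enc_latent = sev + rng.normal(0, 1.0, size=n)
    enc = np.digitize(enc_latent, [0.5, 1.3, 2.0, 2.7]).astype(np.int64)
    cands = pd.DataFrame(
        {
            "candidate_id": np.arange(n, dtype=np.int64),
            "blood_type": rng.choice(BLOOD_TYPES, size=n, p=BLOOD_TYPE_PROBS),
            "listing_date": rng.integers(0, horizon + 1, size=n).astype(np.int64),
            "age_years": np.clip(rng.normal(55.0, 10.0, size=n), 18.0, 80.0),
            "sex": rng.integers(0, 2, size=n).astype(np.int64),
            "weight_kg": np.clip(rng.normal(82.0, 18.0, size=n), 35.0, 180.0),
            "height_cm": np.clip(rng.normal(170.0, 10.0, size=n), 140.0, 205.0),
            "on_dialysis": rng.random(n) < _sigmoid(-2.2 + 0.8 * sev),
            "on_ventilator": rng.random(n) < _sigmoid(-3.5 + 0.9 * sev),
            "portal_vein_thrombosis": rng.random(n) < _sigmoid(-2.5 + 0.3 * sev),
            "bacterial_peritonitis": rng.random(n) < _sigmoid(-2.8 + 0.5 * sev),
            "encephalopathy_grade": enc,
            "latent_severity": sev,
            "outcome": OutcomeLabel.CENSORED.value,
            "outcome_date": np.zeros(n, dtype=np.int64),
            "donor_id": np.full(n, np.nan),
        }
    )
    return cands


def _make_trajectories(
    config: GeneratorConfig, rng: np.random.Generator, listing: np.ndarray, sev: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Precompute (dates, melds) arrays of shape (n, max_steps).

    The MELD path is an integer random walk clipped to [6, 40] whose
    per-candidate drift is ``meld_drift * (severity + drift_shift)``;
    inter-observation gaps are geometric with the configured mean.
    """
    n = len(listing)
    k = config.max_steps
    gaps = rng.geometric(1.0 / config.obs_gap_mean_days, size=(n, k))
    gaps[:, 0] = 0  # first observation at listing
    dates = listing[:, None] + np.cumsum(gaps, axis=1)

    meld0 = np.clip(
        np.round(
            config.meld0_mean
            + config.meld0_severity_coef * sev
            + rng.normal(0, config.meld0_sd, size=n)
        ),
        MELD_MIN,
        MELD_MAX,
    )
    drift = config.meld_drift * (sev + config.meld_drift_shift)
    steps = np.round(drift[:, None] + rng.normal(0, config.meld_noise_sd, size=(n, k - 1)))
    melds = np.empty((n, k))
    melds[:, 0] = meld0
    for j in range(1, k):  # sequential clip: the walk reflects at the bounds
        melds[:, j] = np.clip(melds[:, j - 1] + steps[:, j - 1], MELD_MIN, MELD_MAX)
    return dates.astype(np.int64), melds.astype(np.int64)


def generate_cohort(config: GeneratorConfig = GeneratorConfig()) -> RegistryTables:
    """Generate a synthetic registry. Deterministic given ``config.seed``.

    Outcomes are assigned by a chronological sweep over all candidate
    MELD observations: at each observation a competing-hazards draw picks
    waitlist death, recovery-delisting, a transplant offer acceptance
    (propensity increasing in MELD and in the best available donor's
    quality), or continued waiting. Accepted transplants consume a
    blood-type-matched, not-yet-used, non-discarded donor within the
    matching window, so each used donor is linked to at most one candidate.
    """
    rng = np.random.default_rng(config.seed)
    if config.n_candidates == 0:
        return _empty_tables(config)

    donors = _make_donors(config, rng)
    cands = _make_candidates(config, rng)
    sev = cands["latent_severity"].to_numpy()
    dates, melds = _make_trajectories(
        config, rng, cands["listing_date"].to_numpy(), sev
    )

    horizon = config.study_days
    n, k = dates.shape

    # per-blood-type donor arrays sorted by recovery date
    by_bt = {}
    for bt in BLOOD_TYPES:
        idx = np.flatnonzero((donors["blood_type"] == bt).to_numpy())
        order = np.argsort(donors["recovery_date"].to_numpy()[idx], kind="stable")
        idx = idx[order]
        by_bt[bt] = {
            "ids": idx,
            "dates": donors["recovery_date"].to_numpy()[idx],
            "quality": donors["latent_quality"].to_numpy()[idx],
            "usable": (donors["disposition"].to_numpy()[idx] == "USED"),
            "used": np.zeros(len(idx), dtype=bool),
        }

    # event order: all in-horizon observations, chronological
    in_horizon = dates <= horizon
    cand_ev, step_ev = np.nonzero(in_horizon)
    date_ev = dates[cand_ev, step_ev]
    order = np.lexsort((step_ev, cand_ev, date_ev))
    cand_ev, step_ev, date_ev = cand_ev[order], step_ev[order], date_ev[order]

    u_main = rng.random(len(cand_ev))
    u_gf = rng.random(len(cand_ev))

    cfg = config
    w = cfg.donor_window_days
    active = np.ones(n, dtype=bool)
    n_obs = in_horizon.sum(axis=1)  # provisional: censored keep all in-horizon obs
    outcome = np.full(n, OutcomeLabel.CENSORED.value, dtype=object)
    true_donor = np.full(n, -1, dtype=np.int64)
    cand_bt = cands["blood_type"].to_numpy()

    for e in range(len(cand_ev)):
        i = cand_ev[e]
        if not active[i]:
            continue
        s = step_ev[e]
        day = date_ev[e]
        m = (melds[i, s] - 24.0) / 10.0
        p_death = _sigmoid(cfg.death_intercept + cfg.death_meld_coef * m)
        p_rec = _sigmoid(cfg.recovery_intercept - cfg.recovery_meld_coef * m)
        u = u_main[e]
        if u < p_death:
            active[i] = False
            n_obs[i] = s + 1
            outcome[i] = OutcomeLabel.WAITLIST_DEATH.value
            continue
        if u < p_death + p_rec:
            active[i] = False
            n_obs[i] = s + 1
            outcome[i] = OutcomeLabel.DELIST_RECOVERED.value
            continue
        pool = by_bt[cand_bt[i]]
        lo = np.searchsorted(pool["dates"], day - w, side="left")
        hi = np.searchsorted(pool["dates"], day + w, side="right")
        if hi <= lo:
            continue
        avail = pool["usable"][lo:hi] & ~pool["used"][lo:hi]
        if not avail.any():
            continue
        qs = np.where(avail, pool["quality"][lo:hi], -np.inf)
        j = int(np.argmax(qs))
        p_tx = _sigmoid(cfg.tx_intercept + cfg.tx_meld_coef * m + cfg.tx_quality_coef * qs[j])
        if u < p_death + p_rec + p_tx:
            active[i] = False
            n_obs[i] = s + 1
            pool["used"][lo + j] = True
            true_donor[i] = pool["ids"][lo + j]
            p_gf = _sigmoid(
                cfg.gf_intercept - cfg.gf_quality_coef * qs[j] + cfg.gf_severity_coef * sev[i]
            )
            if u_gf[e] < p_gf:
                outcome[i] = OutcomeLabel.GRAFT_FAILURE.value
            else:
                outcome[i] = OutcomeLabel.TRANSPLANT_SUCCESS.value

    # a candidate whose first observation already falls outside the horizon
    # keeps that single observation and is censored immediately
    n_obs = np.maximum(n_obs, 1)

    cands["outcome"] = outcome
    last = n_obs - 1
    cands["outcome_date"] = dates[np.arange(n), last]
    cands["donor_id"] = np.where(true_donor >= 0, true_donor.astype(float), np.nan)

    # graft-failure flags: linked used donors inherit the recipient outcome;
    # used donors never linked to this cohort (organs placed outside it) get
    # a population-level draw from the same quality-dependent model.
    gf_flag = np.zeros(len(donors), dtype=bool)
    linked = true_donor[true_donor >= 0]
    gf_flag[linked] = (outcome[true_donor >= 0] == OutcomeLabel.GRAFT_FAILURE.value)
    unlinked = (donors["disposition"].to_numpy() == "USED") & ~np.isin(
        np.arange(len(donors)), linked
    )
    q_un = donors["latent_quality"].to_numpy()[unlinked]
    p_un = _sigmoid(
        config.gf_intercept
        - config.gf_quality_coef * q_un
        + config.gf_severity_coef * rng.normal(size=unlinked.sum())
    )
    gf_flag[unlinked] = rng.random(unlinked.sum()) < p_un
    donors["caused_graft_failure"] = gf_flag

    # MELD observations table
    rows = np.repeat(np.arange(n), n_obs)
    cols = np.concatenate([np.arange(c) for c in n_obs])
    meld_obs = pd.DataFrame(
        {
            "candidate_id": rows.astype(np.int64),
            "obs_date": dates[rows, cols],
            "meld": melds[rows, cols],
        }
    )

    for col, dtype in CANDIDATE_COLUMNS.items():
        cands[col] = cands[col].astype(dtype)
    for col, dtype in DONOR_COLUMNS.items():
        donors[col] = donors[col].astype(dtype)
    return RegistryTables(cands, meld_obs, donors, config)


# ---------------------------------------------------------------------------
# serialization


def _validate_schema(df: pd.DataFrame, name: str) -> pd.DataFrame:
    schema = SCHEMAS[name]
    for col in schema:
        if col not in df.columns:
            raise ValueError(f"table '{name}' is missing required column '{col}'")
    out = df[list(schema)].copy()
    for col, dtype in schema.items():
        out[col] = out[col].astype(dtype)
    return out


def write_registry(tables: RegistryTables, path, fmt: str = "parquet") -> None:
    """Write the three tables plus a JSON schema/config sidecar.

    ``fmt`` is ``parquet`` (exact binary round-trip) or ``csv`` (plain
    text; floats are written in shortest round-trip representation).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames = {
        "candidates": tables.candidates,
        "meld_observations": tables.meld_observations,
        "donors": tables.donors,
    }
    for name, df in frames.items():
        df = _validate_schema(df, name)
        if fmt == "parquet":
            df.to_parquet(path / f"{name}.parquet", index=False)
        elif fmt == "csv":
            df.to_csv(path / f"{name}.csv", index=False)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    sidecar = {
        "schema_version": 1,
        "format": fmt,
        "schemas": SCHEMAS,
        "config": asdict(tables.config) if tables.config is not None else None,
    }
    (path / "registry.json").write_text(json.dumps(sidecar, indent=2))


def read_registry(path) -> RegistryTables:
    """Read tables written by :func:`write_registry`, validating schemas."""
    path = Path(path)
    sidecar = json.loads((path / "registry.json").read_text())
    fmt = sidecar["format"]
    frames = {}
    for name in SCHEMAS:
        fp = path / (f"{name}.parquet" if fmt == "parquet" else f"{name}.csv")
        if fmt == "parquet":
            df = pd.read_parquet(fp)
        else:
            df = pd.read_csv(fp)
            if df.empty:
                df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in SCHEMAS[name].items()})
        frames[name] = _validate_schema(df, name)
    config = (
        GeneratorConfig(**sidecar["config"]) if sidecar.get("config") is not None else None
    )
    return RegistryTables(
        frames["candidates"], frames["meld_observations"], frames["donors"], config
    )
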