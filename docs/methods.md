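# Methods

This note documents the models, numerical choices and scope of
`ltmatch`: what each component assumes, which knobs matter, and what the
synthetic experiments do and do not demonstrate.

## Waitlist MDP

Each candidate episode has one step per recorded MELD score. The state
at a step is (candidate statics + blood-type one-hot + current MELD;
donor features + two flags). Actions are WAIT / DELIST / TRANSPLANT,
with DELIST and TRANSPLANT terminal. Registries record only the terminal
action at the final MELD, so every earlier step is an inferred WAIT: the
fact that another MELD was measured is read as the decision to keep the
candidate listed. Censored candidates (no defined outcome at study end)
contribute only their WAIT transitions.

At every non-transplant step one potential donor is sampled uniformly
from the matched pool: organs (used anywhere in the system or discarded)
with the candidate's identical blood type recovered within a symmetric
window of the observation date. Choices made here, and why:

- **Window, not nearest.** "Closest recovery date" is operationalized as
  a ±3-day window; a unique-nearest rule would force pool size 1 and
  could not produce a multi-donor pool at each timepoint. The donor
  arrival rate of the generator is calibrated jointly with this window.
- **Identical blood type only.** Matching is same-type, not
  ABO-compatible (a stricter and simpler reading); ABO-compatibility
  could be added as a config switch without touching the pipeline.
- **Empty pool.** If no organ matches, a "no-offer" placeholder (all-zero
  donor vector, both flags false) is attached so every state has the
  same shape. This case is rare under the default generator (<1% of
  states for the common blood types; more frequent for AB candidates).
- **One instantiation.** One donor per state is one random instantiation
  of a much larger state space; re-running `build_episodes` with another
  `sampling_seed` yields an alternative instantiation for sensitivity
  checks.
- Candidates with a transplant outcome but no recorded donor are
  excluded, with the count logged in the dataset provenance.

## Reward function

Three components, case-split by the action taken (rewards attach only to
the transition on which the action is taken):

- WAIT: `(MELD_i − MELD_{i+1}) · min(MELD_{i+1}, 24)/24` — improvement is
  rewarded, deterioration penalized, scaled by how close the next score
  is to the anchor 24 (the cohort median MELD) — plus `β₁` when the
  attached potential donor eventually caused a graft failure and `β₂`
  when it was eventually discarded. These bonuses encode the assumption
  that such organs are, on average, lower quality than used organs, so
  declining them should be reinforced; `β₂ < β₁` because organs are
  discarded for many reasons, graft failure is definitive.
- DELIST: `β₃ < 0` if the candidate died or deteriorated, `β₄ > 0` if
  they recovered.
- TRANSPLANT: `β₅ < 0` on 1-year graft failure (the worst outcome — two
  lives are affected), `β₆ > 0` on success.

Defaults: (1.0, 0.25, −1.0, 1.0, −4.0, 1.0). The sensitivity grid is
β₁∈{1.0, 0.5}, β₂∈{0, 0.1, 0.25, 0.5}, β₃=−1, β₄=1, β₅∈{−2, −4, −8},
β₆∈{1, 2}, filtered to β₂ < β₁ (42 of 48 combinations). The filter is
applied as a hard constraint; a donor flagged both graft-failure and
discarded is impossible by construction (discarded organs were never
transplanted), but the reward function would sum both bonuses if
presented with one.

## Synthetic registry generator

The generator replaces restricted national registry data. It emulates
exactly the structure the pipeline consumes, with these mechanisms:

- **Severity.** A hidden per-candidate `latent_severity ~ N(0,1)` drives
  the initial MELD, the MELD drift, and the comorbidity indicators
  (dialysis, ventilation, encephalopathy, ...). It is never exposed in
  any state feature block.
- **MELD trajectories.** Integer random walk clipped to [6, 40]:
  increments are `round(drift + N(0, σ))` with per-candidate drift
  `meld_drift · (severity + drift_shift)` (default 0.55 and 0.35, i.e.
  the population worsens slightly on average), σ = 2.2. Observation gaps
  are geometric with mean 30 days; the cadence is a free choice (no
  published inter-observation timing exists) calibrated so episodes
  average ≈4.9 observations.
- **Donor stream and quality.** Donors arrive as a Poisson stream (3.22
  per day) with a hidden `latent_quality ~ N(0,1)` that generates the
  observable features (age, DCD, pH, sodium, transaminases, ...) and two
  structural properties: the discard probability is a logistic function
  *decreasing* in quality (non-random discards), and the graft-failure
  probability among used organs is logistic, decreasing in donor quality
  and increasing in recipient severity.
- **Outcome assignment.** A chronological sweep over all observations
  applies competing hazards at each step: waitlist death (logit
  increasing in MELD), recovery-delisting (decreasing in MELD), and a
  behavior-policy transplant propensity (increasing in MELD and in the
  quality of the best available matched organ). Accepted transplants
  consume a not-yet-used, non-discarded matched donor, so each used
  donor links to at most one candidate; used donors never linked to a
  cohort candidate represent organs placed outside the cohort and
  receive a population-level graft-failure draw.
- **Calendar.** Integer day indices; the horizon scales with cohort size
  (0.66 days per candidate) so the per-day supply/demand balance — and
  therefore pool sizes and transplant availability — is invariant to
  `n_candidates`. Candidates whose trajectory passes the study end are
  censored (~1% under defaults; the recovered fraction absorbs the rest
  of the non-transplant, non-death remainder, ~19%).

Hazard intercepts were calibrated once against the target cohort
composition (63% transplanted / 17% waitlist death / 7% graft failure
among transplants; ≈4.93 observations per episode; ≈8.09 matched donors
per timepoint) and committed as the defaults.

What the generator does **not** emulate: geographic allocation regions
and acuity circles, exception points (HCC), re-listings, measurement
error in MELD, seasonality in the donor stream, and any correlation
structure between candidate features beyond the single severity factor.
Passing tests on this cohort therefore show that the pipeline's
machinery behaves as specified under a plausible data-generating
process, not that the learned policies would transfer to real registry
data.

## Conservative Q-learning agent

Loss: `α·E_s[logsumexp_a Q(s,a) − Q(s,a_data)] + L_DDQN`, with the
double-deep-Q TD term `(Q(s,a_data) − r − γ·Q_target(s', argmax_a
Q_online(s',a)))²` and a reward-only target at terminal transitions.
α is tuned over {0, 0.001, 0.01, 0.1, 0.5, 1.0} by cross-validation.

Architecture: two upstream encoders (one hidden layer of 128 units by
default) embed the candidate and donor blocks into 64-dimensional
representations; their concatenation feeds a 256×256 ReLU trunk with 3
outputs. Inputs are standardized to zero mean/unit variance using
statistics of the training states (constant columns get scale 1).

Numerics and defaults:

- Adam (β₁=0.9, β₂=0.999), learning rate 1e-4, batch 256, hard target
  copy every 2,000 steps; He initialization; all in numpy, CPU-only,
  fully deterministic given the seed.
- **Discount.** Default γ = 0.99. Episodes here are short (≈5 steps) and
  WAIT carries positive donor-flag bonuses, so at γ → 1 waiting is
  nearly free and the optimal policy degenerates toward never acting;
  the desk-scale experiment configuration therefore uses γ = 0.7, which
  values the terminal outcome about one to two steps ahead and produces
  the intended conservative-but-active policies. γ is exposed in the
  config and worth a sensitivity pass in any new setting.
- Greedy action ties break by the fixed order WAIT < DELIST <
  TRANSPLANT.
- Training diagnostics logged per interval: TD loss, conservative loss,
  and the mean value estimate (mean over a fixed probe set of
  max_a Q) — converging loss with diverging value estimates indicates
  overestimation (α too small); flat values with high loss indicate
  underfitting (α too large).
- Non-finite Q values abort training with the history retained.

**Problem sizes.** The full-scale setting (1.25M iterations, batch 256,
256×256 trunk) is supported via configuration (`--full-scale` on the
CLI). The committed experiment defaults are desk-scale: cohorts of
2,000–40,000 candidates, a (64,64) trunk with (32,)→16 encoders, 6,000–
20,000 iterations, 2-fold cross-validation — sizes chosen so the whole
protocol runs in minutes on one CPU while preserving every qualitative
property the tests assert.

## Baselines

- MELD-k thresholds, k ∈ {15, 20, 24, 30}: transplant whenever MELD ≥ k
  (inclusive, matching the reading of MELD 15 as the listing floor; a
  `strict` flag switches to >). Never delist.
- Action / outcome / graft-failure prediction models × logistic
  regression / gradient-boosted trees, all class-weight balanced. The
  outcome model maps predicted outcomes to actions (success→TRANSPLANT,
  recovery→DELIST, graft failure or death→WAIT — avoid the bad outcome);
  the graft-failure model transplants when predicted risk < τ (default
  0.5 on the balanced scale) and never delists. The outcome→action map
  and τ rule are this package's choices; they reproduce the qualitative
  signatures expected of these model families (outcome models
  over-transplant; graft-failure models never delist).

## Evaluation

Unconstrained metrics query the policy independently at every recorded
state. GFPR uses the terminal-state decision on the true pair; GFIR/GSPR
/CIR count TRANSPLANT at earlier states of the same episode ("earlier
donor" means the donor instantiated at an earlier state — no wider
search is performed); CRR counts DELIST at any state by default, with a
terminal-only variant behind a flag. Empty outcome subgroups report NaN
with a warning, never 0.

The constrained replay sweeps states chronologically: a transplant
decision claims the state's attached donor; a donor claimed by several
candidates goes to the closest in time (ties: earlier listing date, then
candidate id); an already-consumed donor downgrades the decision to WAIT
(logged as a "no-donor" event — the fallback is this package's choice);
candidates leave after any terminal action.

WIS uses a behavior policy cloned by the action-prediction model,
converts the evaluated policy to probabilities (softmax over Q at
temperature 1 for the agent; smoothed one-hot for deterministic
policies), clips per-step ratios at 100, and self-normalizes. It is
reported as a secondary diagnostic; the clinically grounded rates above
are primary.

Feature comparisons use a Shapiro–Wilk screen (α = 0.05) to choose
Student's t vs Mann–Whitney for continuous features (effect size:
Hedge's g with small-sample correction), Fisher exact for binary
(Cohen's h), chi-squared for multi-category (Cramér's V,
non-directional). No multiple-testing correction by default; a
Bonferroni switch is provided. Constant features are reported untestable.

## Experimental protocol and model selection

Stratified (by outcome) candidate-level 80/20 split; k-fold
cross-validation on the training cohort over the α grid (and optionally,
sequentially, the β grid at the selected α — the sequential order
reflects that α is the algorithmic knob and β the problem definition);
per-configuration fold means and SDs of every holdout metric. Model
selection formalizes "high GFPR, high GSPR, low but non-zero transplant
count" as an explicit rule: discard configurations with zero transplants
or GSPR below a floor (default 50%), maximize GFPR + GSPR, break ties
toward fewer transplants; the full audit trail is returned. The final
model is retrained on the whole training cohort with the selected
configuration. The report tables carry, for every policy (agent,
predictive models, thresholds), the fold mean of each holdout metric
under the metric's name and the fold SD as `<metric>_sd`; policies that
ignore training (the threshold rules) have SD exactly 0.

## Known limitations

- The generator's single-factor severity/quality structure makes the
  learning problem easier than real registry data; the donor-flag
  features are strongly informative of graft failure by construction.
- The inferred-WAIT assumption (every earlier MELD implies a decision to
  keep waiting) is untestable within registry-style data.
- The constrained replay still offers each candidate only the sampled
  donor at each state, a far thinner offer stream than real allocation.
- WIS estimates degrade when the evaluated policy deviates strongly from
  the cloned behavior policy; treat them as relative diagnostics.
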