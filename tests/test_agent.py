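import numpy as np
import pandas as pd
import pytest

from ltmatch._nn import QNetwork
from ltmatch.agent import CQLAgent, cql_loss
from ltmatch.episodes import DELIST, TRANSPLANT, WAIT, EpisodeDataset


def random_batch(rng, n=4, dc=5, dd=4, terminal=None):
    if terminal is None:
        terminal = rng.random(n) < 0.5
    return {
        "xc": rng.normal(size=(n, dc)),
        "xd": rng.normal(size=(n, dd)),
        "action": rng.integers(0, 3, size=n),
        "reward": rng.normal(size=n),
        "terminal": np.asarray(terminal, dtype=bool),
        "xc_next": rng.normal(size=(n, dc)),
        "xd_next": rng.normal(size=(n, dd)),
    }


def small_net(rng, dc=5, dd=4, zero_init=False):
    return QNetwork(dc, dd, 8, 8, (8,), (16,), 3, rng, zero_init=zero_init)


def make_tabular_dataset(transitions, n_states, repeats=30):
    """EpisodeDataset for an explicit tabular MDP.

    ``transitions``: list of (s, a, r, s_next or None). States are one-hot
    in the candidate block; the donor block is a single zero feature.
    """
    rows = []
    for rep in range(repeats):
        for s, a, r, nxt in transitions:
            rows.append((s, a, r, nxt))
    xc_states = np.eye(n_states)
    k = len(rows)
    state_pos = np.array([r[0] for r in rows])
    next_state = np.array([r[3] if r[3] is not None else -1 for r in rows])
    # states array: one entry per occurrence plus appended rows for next states
    X_cand = xc_states[state_pos]
    X_cand_next_bank = xc_states
    # build a flat state bank: originals then one canonical row per state
    X_cand_full = np.vstack([X_cand, X_cand_next_bank])
    X_donor_full = np.zeros((len(X_cand_full), 1))
    next_idx = np.where(next_state >= 0, k + next_state, -1)
    tr = pd.DataFrame(
        {
            "episode_id": np.arange(k),
            "step": np.ones(k, dtype=int),
            "state_idx": np.arange(k),
            "next_state_idx": next_idx,
            "action": [r[1] for r in rows],
            "reward": [float(r[2]) for r in rows],
            "terminal": next_state < 0,
            "outcome": "",
        }
    )
    states = pd.DataFrame(
        {"episode_id": np.arange(len(X_cand_full)), "step": 1}
    )
    return EpisodeDataset(states, tr, X_cand_full, X_donor_full, {})


# 3-state chain: optimal policy is WAIT, WAIT, TRANSPLANT under gamma=0.9
CHAIN = [
    (0, WAIT, 0.0, 1),
    (0, DELIST, -1.0, None),
    (0, TRANSPLANT, 0.2, None),
    (1, WAIT, 0.0, 2),
    (1, DELIST, -1.0, None),
    (1, TRANSPLANT, 2.0, None),
    (2, WAIT, 0.0, None),
    (2, DELIST, -1.0, None),
    (2, TRANSPLANT, 3.0, None),
]


def value_iteration_chain(gamma=0.9, iters=200):
    """Independent tabular oracle for the CHAIN MDP."""
    q = np.zeros((3, 3))
    model = {(s, a): (r, nxt) for s, a, r, nxt in CHAIN}
    for _ in range(iters):
        v = q.max(axis=1)
        for (s, a), (r, nxt) in model.items():
            q[s, a] = r + (gamma * v[nxt] if nxt is not None else 0.0)
    return q


class TestCQLLoss:
    def test_alpha_zero_reduces_to_td(self):
        rng = np.random.default_rng(0)
        net = small_net(rng)
        batch = random_batch(rng)
        total, td, cons = cql_loss(net, net.copy(), batch, 0.0, 0.9, with_grads=False)
        assert total == td
        assert cons != 0.0  # the term is still reported, just unweighted

    def test_uniform_q_conservative_term_is_log3(self):
        rng = np.random.default_rng(1)
        net = small_net(rng, zero_init=True)  # Q identically zero
        batch = random_batch(rng)
        _, _, cons = cql_loss(net, net.copy(), batch, 1.0, 0.9, with_grads=False)
        assert cons == pytest.approx(np.log(3.0), abs=1e-12)

    def test_terminal_target_is_reward_only(self):
        """A terminal transition with Q(s, a) == r has zero TD error, and
        perturbing its next-state features never changes the loss."""
        rng = np.random.default_rng(2)
        net = small_net(rng, zero_init=True)
        batch = random_batch(rng, n=3, terminal=[True, True, True])
        batch["reward"] = np.zeros(3)  # Q == 0 == r
        _, td, _ = cql_loss(net, net.copy(), batch, 0.5, 0.9, with_grads=False)
        assert td == pytest.approx(0.0, abs=1e-12)

    def test_terminal_loss_invariant_to_next_state(self):
        rng = np.random.default_rng(3)
        net = small_net(rng)
        batch = random_batch(rng, n=6, terminal=[True, False, True, False, True, True])
        ref = cql_loss(net, net.copy(), batch, 0.3, 0.95, with_grads=False)
        batch2 = dict(batch)
        batch2["xc_next"] = batch["xc_next"].copy()
        batch2["xd_next"] = batch["xd_next"].copy()
        batch2["xc_next"][batch["terminal"]] += rng.normal(size=(4, 5)) * 10
        batch2["xd_next"][batch["terminal"]] += rng.normal(size=(4, 4)) * 10
        out = cql_loss(net, net.copy(), batch2, 0.3, 0.95, with_grads=False)
        assert out == pytest.approx(ref, abs=1e-12)

    def test_gradients_match_finite_differences(self):
        """Analytic gradients of the full CQL objective agree with central
        finite differences to 1e-4 on a 2-sample batch."""
        rng = np.random.default_rng(4)
        net = small_net(rng)
        tgt = small_net(np.random.default_rng(5))
        batch = random_batch(rng, n=2, terminal=[False, True])
        _, _, _, grads = cql_loss(net, tgt, batch, 0.3, 0.9)
        eps = 1e-6
        for p, g in zip(net.params, grads):
            flat_ix = rng.choice(p.size, size=min(p.size, 6), replace=False)
            for fi in flat_ix:
                ix = np.unravel_index(fi, p.shape)
                orig = p[ix]
                p[ix] = orig + eps
                lp = cql_loss(net, tgt, batch, 0.3, 0.9, with_grads=False)[0]
                p[ix] = orig - eps
                lm = cql_loss(net, tgt, batch, 0.3, 0.9, with_grads=False)[0]
                p[ix] = orig
                assert (lp - lm) / (2 * eps) == pytest.approx(g[ix], abs=1e-4)

    def test_empty_batch_rejected(self):
        rng = np.random.default_rng(6)
        net = small_net(rng)
        with pytest.raises(ValueError, match="empty"):
            cql_loss(net, net.copy(), random_batch(rng, n=0), 0.1, 0.9)


class TestEncoders:
    def test_candidate_embedding_independent_of_donor_block(self):
        rng = np.random.default_rng(7)
        net = small_net(rng)
        xc = rng.normal(size=(1, 5))
        ec1, ed1 = net.encode(xc, rng.normal(size=(1, 4)))
        ec2, ed2 = net.encode(xc, rng.normal(size=(1, 4)))
        assert np.array_equal(ec1, ec2)
        assert not np.array_equal(ed1, ed2)

    def test_zero_initialized_encoder_gives_zero_embedding(self):
        rng = np.random.default_rng(8)
        net = small_net(rng, zero_init=True)
        ec, ed = net.encode(rng.normal(size=(3, 5)), rng.normal(size=(3, 4)))
        assert np.all(ec == 0.0) and np.all(ed == 0.0)

    def test_dimension_mismatch_names_block(self):
        rng = np.random.default_rng(9)
        net = small_net(rng)
        with pytest.raises(ValueError, match="candidate block"):
            net.forward(rng.normal(size=(1, 7)), rng.normal(size=(1, 4)))
        with pytest.raises(ValueError, match="donor block"):
            net.forward(rng.normal(size=(1, 5)), rng.normal(size=(1, 2)))


AGENT_KW = dict(
    hidden_sizes=(16,),
    encoder_hidden=(8,),
    candidate_embed_dim=8,
    donor_embed_dim=8,
    batch_size=64,
    learning_rate=1e-3,
    target_update_interval=200,
    log_interval=500,
)


class TestTraining:
    def test_zero_iterations_returns_initialization(self):
        ds = make_tabular_dataset(CHAIN, 3, repeats=5)
        a = CQLAgent(alpha=0.1, iterations=0, seed=0, **AGENT_KW).fit(ds)
        b = CQLAgent(alpha=0.1, iterations=0, seed=0, **AGENT_KW).fit(ds)
        for pa, pb in zip(a.network_.params, b.network_.params):
            assert np.array_equal(pa, pb)
        assert len(a.history_) == 0

    def test_fit_deterministic_given_seed(self):
        ds = make_tabular_dataset(CHAIN, 3, repeats=10)
        a = CQLAgent(alpha=0.1, gamma=0.9, iterations=300, seed=3, **AGENT_KW).fit(ds)
        b = CQLAgent(alpha=0.1, gamma=0.9, iterations=300, seed=3, **AGENT_KW).fit(ds)
        for pa, pb in zip(a.network_.params, b.network_.params):
            assert np.array_equal(pa, pb)
        pd.testing.assert_frame_equal(a.history_, b.history_)

    def test_greedy_policy_matches_value_iteration_oracle(self):
        """On a fully covered 3-state MDP, small-alpha CQL recovers the
        value-iteration optimal policy (WAIT, WAIT, TRANSPLANT)."""
        q_star = value_iteration_chain(gamma=0.9)
        oracle = q_star.argmax(axis=1)
        assert list(oracle) == [WAIT, WAIT, TRANSPLANT]
        ds = make_tabular_dataset(CHAIN, 3, repeats=40)
        agent = CQLAgent(alpha=0.01, gamma=0.9, iterations=4000, seed=0, **AGENT_KW).fit(ds)
        greedy = agent.predict(np.eye(3), np.zeros((3, 1)))
        assert list(greedy) == list(oracle)
        # learned action values approximate the oracle on the data actions
        q = agent.q_values(np.eye(3), np.zeros((3, 1)))
        assert np.allclose(q, q_star, atol=0.35)

    def test_mean_value_estimate_nonincreasing_in_alpha(self, dataset_small):
        """More conservatism yields lower end-of-training value estimates
        on a fixed dataset and seed."""
        ids = dataset_small.episode_ids()[:400]
        ds = dataset_small.subset(ids)
        values = []
        for alpha in (0.0, 0.1, 1.0):
            ag = CQLAgent(alpha=alpha, gamma=0.9, iterations=1500, seed=1, **AGENT_KW).fit(ds)
            values.append(ag.history_["mean_value"].iloc[-1])
        assert values[0] >= values[1] >= values[2]

    def test_tie_break_order_wait_delist_transplant(self):
        ds = make_tabular_dataset(CHAIN, 3, repeats=2)
        agent = CQLAgent(alpha=0.0, iterations=0, seed=0, **AGENT_KW).fit(ds)
        # zero the trunk output layer -> all-equal Q values
        agent.network_.trunk.W[-1][...] = 0.0
        agent.network_.trunk.b[-1][...] = 0.0
        acts = agent.predict(np.eye(3), np.zeros((3, 1)))
        assert list(acts) == [WAIT, WAIT, WAIT]

    def test_checkpoint_round_trip(self, tmp_path):
        ds = make_tabular_dataset(CHAIN, 3, repeats=10)
        agent = CQLAgent(alpha=0.1, gamma=0.9, iterations=300, seed=2, **AGENT_KW).fit(ds)
        agent.save(tmp_path / "agent.npz")
        back = CQLAgent.load(tmp_path / "agent.npz")
        x = (np.eye(3), np.zeros((3, 1)))
        assert np.allclose(back.q_values(*x), agent.q_values(*x))
        assert back.alpha == agent.alpha
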