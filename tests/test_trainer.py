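"""GAE, the PPO objective, expert learning and the training loop."""

import numpy as np
import pytest

from rjtrl.codec import decompose
from rjtrl.env import MolEnv, RewardConfig
from rjtrl.nn.autodiff import Adam
from rjtrl.nn.policy_value import ActionRecord, PolicyValueNet
from rjtrl.trainer import (
    PPOConfig,
    TrajStep,
    Trajectory,
    compute_gae,
    expert_examples,
    expert_nll,
    ppo_loss,
    pretrain,
    train,
)


def make_traj(rewards, values):
    steps = [
        TrajStep(tree=None, action=None, reward=r, value=v, logp=0.0)
        for r, v in zip(rewards, values)
    ]
    return Trajectory(steps=steps)


def brute_force_gae(rewards, values, gamma, lam):
    """Direct double-sum evaluation of the defining advantage series."""
    n = len(rewards)
    nv = list(values[1:]) + [0.0]
    deltas = [rewards[t] + gamma * nv[t] - values[t] for t in range(n)]
    adv = [
        sum((gamma * lam) ** k * deltas[t + k] for k in range(n - t))
        for t in range(n)
    ]
    return np.array(adv)


class TestGAE:
    def test_lambda_zero_is_one_step_td(self, rng):
        r, v = rng.normal(size=6), rng.normal(size=6)
        adv, _ = compute_gae(make_traj(r, v), gamma=0.9, lam=0.0)
        nv = np.append(v[1:], 0.0)
        assert np.allclose(adv, r + 0.9 * nv - v, atol=1e-12)

    def test_lambda_one_gamma_one_is_monte_carlo(self, rng):
        r, v = rng.normal(size=5), rng.normal(size=5)
        adv, _ = compute_gae(make_traj(r, v), gamma=1.0, lam=1.0)
        returns = np.cumsum(r[::-1])[::-1]
        assert np.allclose(adv, returns - v, atol=1e-12)

    def test_matches_brute_force_on_random_trajectories(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 11))
            r = rng.uniform(-1, 1, size=n)
            v = rng.uniform(-1, 1, size=n)
            gamma = rng.uniform(0.5, 1.0)
            lam = rng.uniform(0.0, 1.0)
            adv, targets = compute_gae(make_traj(r, v), gamma, lam)
            ref = brute_force_gae(r, v, gamma, lam)
            assert np.abs(adv - ref).max() < 1e-10
            assert np.allclose(targets, adv + v, atol=1e-12)


class TestPPOLoss:
    @pytest.fixture()
    def net(self, vocab):
        return PolicyValueNet(vocab, d=8, seed=5)

    def _batch(self, net, vocab, advs, targets):
        tree = decompose("CC", vocab)
        out = net.policy_forward(tree)
        rng = np.random.default_rng(0)
        items = []
        for adv, tgt in zip(advs, targets):
            a = net.sample_action(out, rng)
            items.append(
                {"tree": tree, "action": a, "logp_old": a.logp, "adv": adv, "target": tgt}
            )
        return items

    def test_ratio_one_clip_term_is_mean_advantage(self, net, vocab):
        cfg = PPOConfig()
        batch = self._batch(net, vocab, [0.7, -0.3], [0.1, 0.2])
        _, comps = ppo_loss(net, batch, cfg)
        assert np.isclose(comps["clip"], np.mean([0.7, -0.3]), atol=1e-9)

    def test_hand_computed_two_transition_batch(self, net, vocab):
        """Loss equals the formula evaluated by hand on stated numbers."""
        cfg = PPOConfig(clip_eps=0.2, c_vf=0.5, c_ent=0.01)
        tree = decompose("CC", vocab)
        out = net.policy_forward(tree)
        rng = np.random.default_rng(1)
        a1, a2 = net.sample_action(out, rng), net.sample_action(out, rng)
        # behaviour log-probs shifted so the ratios are exp(+-0.5)
        batch = [
            {"tree": tree, "action": a1, "logp_old": a1.logp - 0.5, "adv": 1.0, "target": 0.3},
            {"tree": tree, "action": a2, "logp_old": a2.logp + 0.5, "adv": -2.0, "target": -0.1},
        ]
        loss, comps = ppo_loss(net, batch, cfg)
        r1, r2 = np.exp(0.5), np.exp(-0.5)
        v = net.value_forward(tree)
        surr1 = min(r1 * 1.0, np.clip(r1, 0.8, 1.2) * 1.0)
        surr2 = min(r2 * -2.0, np.clip(r2, 0.8, 1.2) * -2.0)
        l_clip = (surr1 + surr2) / 2
        l_vf = ((v - 0.3) ** 2 + (v + 0.1) ** 2) / 2

        def head_entropy(logp):
            p = np.exp(logp)
            return float(-(p * np.where(p > 0, logp, 0.0)).sum())

        ents = []
        for a in (a1, a2):
            e = head_entropy(out.logp_stop)
            if not a.stop:
                e += head_entropy(out.logp_node)
                e += head_entropy(out.word_logp(a.node))
                e += head_entropy(out.site_logp(a.node, a.word))
            ents.append(e)
        expected = -l_clip + 0.5 * l_vf - 0.01 * np.mean(ents)
        assert np.isclose(float(loss.data), expected, atol=1e-9)

    def test_clipped_equals_unclipped_within_range(self, net, vocab):
        """With all ratios inside [1 - eps, 1 + eps] the clipped surrogate
        coincides with the plain importance-weighted surrogate."""
        cfg = PPOConfig(clip_eps=0.2)
        tree = decompose("CC", vocab)
        out = net.policy_forward(tree)
        rng = np.random.default_rng(2)
        batch = []
        expected = []
        for adv in (0.5, -0.5, 1.5):
            a = net.sample_action(out, rng)
            shift = 0.1  # ratio exp(0.1) ~ 1.105 < 1.2
            batch.append(
                {"tree": tree, "action": a, "logp_old": a.logp - shift, "adv": adv, "target": 0.0}
            )
            expected.append(np.exp(shift) * adv)
        _, comps = ppo_loss(net, batch, cfg)
        assert np.isclose(comps["clip"], np.mean(expected), atol=1e-9)


class TestExpertExamples:
    def test_ethane_single_stop_example(self, vocab, rng):
        exs = expert_examples("CC", vocab, rng)
        assert len(exs) == 1
        assert exs[0].action.stop
        assert exs[0].state.n_nodes == 1

    def test_propane_one_attach_plus_stop(self, vocab, rng):
        exs = expert_examples("CCC", vocab, rng)
        assert len(exs) == 2
        assert not exs[0].action.stop and exs[1].action.stop
        assert exs[0].state.n_nodes == 1
        assert exs[1].state.n_nodes == 2

    @pytest.mark.parametrize("order", ["breadth", "depth"])
    def test_replaying_attachments_rebuilds_molecule(self, vocab, rng, fixture_smiles, order):
        from rjtrl.env import EnvState, apply_action
        from rjtrl.codec import assemble, canonical_smiles

        for smiles in fixture_smiles[:10]:
            exs = expert_examples(smiles, vocab, rng, order=order)
            state = EnvState(tree=exs[0].state, molecule=assemble(exs[0].state))
            for ex in exs:
                if ex.action.stop:
                    break
                state = apply_action(state, ex.action, vocab)
                assert state is not None
            assert canonical_smiles(state.molecule) == canonical_smiles(smiles)

    def test_states_grow_by_one_node(self, vocab, rng):
        exs = expert_examples("CC(C)Cc1ccc(O)cc1", vocab, rng)
        sizes = [ex.state.n_nodes for ex in exs]
        # attach examples grow 1..n-1 nodes; the stop example has all n
        assert sizes == list(range(1, len(exs))) + [len(exs)]


class TestExpertNLL:
    def test_uniform_policy_value_on_continue_example(self, vocab):
        """A policy with uniform heads scores a continue action at the
        product of the head sizes."""
        net = PolicyValueNet(vocab, d=8, seed=0)
        for p in net.parameters():
            p.data[:] = 0.0  # all logits zero => uniform heads
        tree = decompose("CC", vocab)
        n_allowed = 4  # CC-CC attachments: 2 x 2 site choices
        a = ActionRecord(stop=False, node=0, word=vocab.word_id("CC"), site=0)
        from rjtrl.vocab import site_mask, decode_site
        import numpy as np2

        mask = site_mask(tree.nodes[0], vocab.word(a.word))
        site = int(np2.flatnonzero(mask)[0])
        a = ActionRecord(stop=False, node=0, word=a.word, site=site)
        from rjtrl.trainer import ExpertExample

        nll = expert_nll([ExpertExample(tree, a)], net)
        expected = -np.log(0.5 * 1.0 * (1 / vocab.n_voc) * (1 / mask.sum()))
        assert np.isclose(float(nll.data), expected, atol=1e-9)

    def test_nll_decreases_under_optimization(self, vocab, fixture_smiles):
        net = PolicyValueNet(vocab, d=16, seed=4)
        history = pretrain(net, fixture_smiles[:10], n_steps=50, batch_size=8, seed=0)
        assert history[-1] < history[0]

    def test_pretraining_halves_nll_on_fixture_set(self, vocab, fixture_smiles):
        """Expert pretraining reduces the NLL by at least 50% from
        initialization within 200 steps."""
        net = PolicyValueNet(vocab, d=32, seed=0)
        history = pretrain(net, fixture_smiles[:50], n_steps=200, batch_size=16, seed=0)
        assert history[-1] <= 0.5 * history[0]


class TestTrainLoop:
    def test_fixed_seed_reproducible(self, vocab):
        def run():
            net = PolicyValueNet(vocab, d=8, seed=1)
            cfg = RewardConfig(
                score_fn=lambda m: m.GetNumHeavyAtoms() / 10, mode="step", t_max=4
            )
            env = MolEnv(vocab, cfg)
            ppo = PPOConfig(rollout_episodes=5, minibatch_size=8, epochs=1, seed=9)
            log = train(env, net, ppo, total_episodes=10)
            return [(r["score"], r["smiles"]) for r in log]

        assert run() == run()

    def test_zero_reward_keeps_entropy_high(self, vocab):
        """With no reward signal the policy stays near its (high-entropy)
        initialization: episode outcomes remain diverse."""
        net = PolicyValueNet(vocab, d=8, seed=2)
        cfg = RewardConfig(
            score_fn=lambda m: 0.0, mode="step", t_max=4, duplication_penalty=False
        )
        env = MolEnv(vocab, cfg)
        ppo = PPOConfig(rollout_episodes=20, minibatch_size=32, epochs=1, seed=0)
        log = train(env, net, ppo, total_episodes=100)
        outcomes = {r["smiles"] for r in log[-50:]}
        assert len(outcomes) > 10

    def test_score_improves_on_easy_objective(self, vocab):
        """Heavy-atom-count maximization: the moving average at the end
        beats the first rollout's mean."""
        net = PolicyValueNet(vocab, d=16, seed=3)
        cfg = RewardConfig(
            score_fn=lambda m: m.GetNumHeavyAtoms() / 10, mode="step", t_max=6
        )
        env = MolEnv(vocab, cfg)
        ppo = PPOConfig(
            rollout_episodes=8, minibatch_size=16, epochs=4, seed=0, lr=2e-3, c_ent=0.05
        )
        log = train(env, net, ppo, total_episodes=300)
        early = np.mean([r["score"] for r in log[:20]])
        assert log[-1]["moving_avg"] > early
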