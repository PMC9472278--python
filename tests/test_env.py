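"""Environment transitions, telescoping rewards and the duplication rule."""

import numpy as np
import pytest

from rjtrl.codec import SiteInfo, decompose
from rjtrl.env import DuplicationLedger, MolEnv, RewardConfig, apply_action, duplication_penalty
from rjtrl.nn.policy_value import ActionRecord, PolicyValueNet
from rjtrl.vocab import encode_site, site_mask


def heavy_atom_score(mol):
    return mol.GetNumHeavyAtoms() / 10.0


@pytest.fixture()
def env(vocab):
    cfg = RewardConfig(score_fn=heavy_atom_score, mode="step", t_max=8)
    return MolEnv(vocab, cfg)


def attach_cc(vocab, node=0):
    return ActionRecord(
        stop=False,
        node=node,
        word=vocab.word_id("CC"),
        site=encode_site(SiteInfo(1, 0, 0)),
    )


class TestReset:
    def test_ethane_initial_state(self, env):
        state = env.reset()
        assert state.tree.n_nodes == 1
        assert state.smiles == "CC"
        assert state.t == 0

    def test_ring_initial_state(self, vocab):
        cfg = RewardConfig(score_fn=heavy_atom_score, t_max=8)
        env = MolEnv(vocab, cfg, init_smiles="c1cncnc1")
        state = env.reset()
        assert state.tree.n_nodes == 1
        assert state.tree.nodes[0].kind == "ring"

    def test_reset_twice_identical(self, env):
        a = env.reset()
        b = env.reset()
        assert a.smiles == b.smiles and a.t == b.t


class TestApplyAction:
    def test_attach_bond_gives_propane(self, env, vocab):
        state = env.reset()
        nxt = apply_action(state, attach_cc(vocab), vocab)
        assert nxt.smiles == "CCC"
        assert nxt.t == 1

    def test_fifth_substituent_invalid(self, env, vocab):
        state = env.reset()
        for _ in range(10):
            nxt = apply_action(state, attach_cc(vocab, node=0), vocab)
            if nxt is None:
                break
            state = nxt
        assert nxt is None  # carbon valence eventually exceeded

    def test_stop_flags_done_without_change(self, env, vocab):
        state = env.reset()
        nxt = apply_action(state, ActionRecord(stop=True), vocab)
        assert nxt.done and nxt.smiles == state.smiles

    def test_every_intermediate_state_is_valid(self, vocab, rng):
        """Random valid rollouts decode to valid molecules at every step."""
        net = PolicyValueNet(vocab, d=8, seed=0)
        cfg = RewardConfig(score_fn=heavy_atom_score, t_max=6)
        env = MolEnv(vocab, cfg)
        for _ in range(10):
            state = env.reset()
            done = False
            while not done:
                out = net.policy_forward(state.tree)
                action = net.sample_action(out, rng)
                state, _, done, _ = env.step(action)
                assert state.molecule is not None
                assert state.smiles  # canonical form always available


class TestStepReward:
    def test_step_mode_telescopes(self, vocab):
        scores = iter([0.2, 0.5, 0.4])
        cfg = RewardConfig(score_fn=lambda m: None, mode="step", t_max=8,
                           duplication_penalty=False)
        # drive the reward sequence through a shim score function
        seq = [0.2, 0.5, 0.4]
        calls = {"i": -1}

        def score(mol):
            calls["i"] = min(calls["i"] + 1, len(seq) - 1)
            return seq[calls["i"]]

        cfg.score_fn = score
        env = MolEnv(vocab, cfg)
        env.reset()
        rewards = []
        for _ in range(3):
            _, r, done, _ = env.step(attach_cc(vocab))
            rewards.append(r)
        assert np.allclose(rewards, [0.2, 0.3, -0.1])

    def test_final_mode_zero_until_termination(self, vocab):
        cfg = RewardConfig(score_fn=heavy_atom_score, mode="final", t_max=8,
                           duplication_penalty=False)
        env = MolEnv(vocab, cfg)
        env.reset()
        _, r1, _, _ = env.step(attach_cc(vocab))
        _, r2, _, _ = env.step(attach_cc(vocab))
        state, r3, done, info = env.step(ActionRecord(stop=True))
        assert r1 == r2 == 0.0
        assert done
        assert np.isclose(r3, heavy_atom_score(state.molecule))

    def test_invalid_action_penalized_and_state_kept(self, vocab):
        cfg = RewardConfig(score_fn=heavy_atom_score, mode="step", t_max=20,
                           c_invalid=-0.5)
        env = MolEnv(vocab, cfg)
        env.reset()
        bad = ActionRecord(stop=False, node=0, word=vocab.word_id("CC"), site=383)
        state, r, done, info = env.step(bad)
        assert info["invalid_action"]
        assert r == -0.5
        assert state.smiles == "CC"
        assert not done

    def test_episode_ends_at_t_max(self, vocab):
        cfg = RewardConfig(score_fn=heavy_atom_score, mode="step", t_max=3)
        env = MolEnv(vocab, cfg)
        env.reset()
        done = False
        steps = 0
        while not done:
            _, _, done, _ = env.step(attach_cc(vocab))
            steps += 1
        assert steps == 3


class TestDuplicationPenalty:
    def test_fresh_molecule_keeps_score_final_mode(self, vocab):
        cfg = RewardConfig(score_fn=heavy_atom_score, mode="final", t_max=8)
        assert duplication_penalty(0.8, 0, [], cfg) == 0.8

    def test_overused_molecule_zeroed_final_mode(self, vocab):
        cfg = RewardConfig(score_fn=heavy_atom_score, mode="final", t_max=8)
        assert duplication_penalty(0.8, 3, [0.0, 0.0], cfg) == 0.0

    def test_step_mode_correction_zeroes_return(self, vocab):
        cfg = RewardConfig(score_fn=heavy_atom_score, mode="step", t_max=8)
        assert duplication_penalty(0.6, 3, [0.4, 0.2], cfg) == pytest.approx(-0.6)

    def test_return_driven_to_exact_zero_in_env(self, vocab):
        """After N_lim generations of the same molecule the whole-episode
        return is exactly zero."""
        cfg = RewardConfig(score_fn=heavy_atom_score, mode="step", t_max=4,
                           duplication_penalty=True, N_lim=2)
        env = MolEnv(vocab, cfg)
        returns = []
        for _ in range(5):
            env.reset()
            total = 0.0
            done = False
            while not done:
                _, r, done, info = env.step(
                    attach_cc(vocab) if env.state.t < 1 else ActionRecord(stop=True)
                )
                total += r
            returns.append(total)
        # first three pass through (n_dup = 0, 1, 2 <= N_lim), then zeroed
        assert returns[0] > 0
        assert np.allclose(returns[:3], returns[0])
        assert returns[3] == 0.0 and returns[4] == 0.0

    def test_ledger_counts_monotone(self):
        ledger = DuplicationLedger()
        ledger.increment("CC")
        ledger.increment("CC")
        assert ledger.count("CC") == 2
        assert ledger.count("CCC") == 0


class TestTelescopingProperty:
    def test_random_valid_episodes_return_equals_final_score(self, vocab, rng):
        """Step-mode undiscounted return equals the final molecule's score
        on random episodes without invalid actions."""
        cfg = RewardConfig(score_fn=heavy_atom_score, mode="step", t_max=6,
                           duplication_penalty=False)
        env = MolEnv(vocab, cfg)
        checked = 0
        for _ in range(200):
            env.reset()
            total, done, invalid = 0.0, False, False
            while not done:
                node = int(rng.integers(env.state.tree.n_nodes))
                word = int(rng.integers(vocab.n_voc))
                mask = site_mask(env.state.tree.nodes[node], vocab.word(word))
                site = int(rng.choice(np.flatnonzero(mask)))
                stop = rng.random() < 0.25
                action = ActionRecord(stop=stop, node=node, word=word, site=site)
                _, r, done, info = env.step(action)
                invalid = invalid or info["invalid_action"]
                total += r
            if not invalid:
                assert np.isclose(total, info["final_score"], atol=1e-12)
                checked += 1
        assert checked > 50
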