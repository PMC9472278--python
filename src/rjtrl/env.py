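"""The molecular-design RL environment.

States are reversible junction trees; every intermediate state decodes to a
valid molecule.  An attach action adds a new fragment node to an existing
node with a decoded site record; the modified tree is reassembled and
valence-validated.  Invalid attachments leave the state unchanged and emit a
small negative reward.  Rewards follow either the "step" scheme — the score
difference R_step(t) - R_step(t-1) with R_step(-1) defined as 0, so a clean
episode's undiscounted return telescopes to the final molecule's score — or
the "final" scheme (zero until termination).  A duplication penalty can
reset an episode's return to exactly zero once the generated molecule has
been produced more than N_lim times in the training run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

from rdkit import Chem

from .codec import RJTree, assemble, decompose
from .errors import RangeError
from .nn.policy_value import ActionRecord
from .vocab import Vocabulary, decode_site


@dataclass
class RewardConfig:
    """Reward scheme parameters.

    ``mode``: 'step' (telescoped per-step scores) or 'final' (score only at
    termination).  ``score_fn`` maps an RDKit Mol to a scalar, higher is
    better.  ``c_invalid`` is the penalty for valence-violating actions;
    ``N_lim`` the duplication threshold; ``gamma`` the discount rate used by
    the trainer.
    """

    score_fn: Callable
    mode: str = "step"
    duplication_penalty: bool = True
    N_lim: int = 2
    c_invalid: float = -0.5
    t_max: int = 30
    gamma: float = 0.99

    def __post_init__(self) -> None:
        if self.mode not in ("step", "final"):
            raise ValueError("mode must be 'step' or 'final'")
        if self.N_lim < 1:
            raise ValueError("N_lim must be >= 1")
        if self.c_invalid >= 0:
            raise ValueError("c_invalid must be negative")
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must be in (0, 1]")


class DuplicationLedger:
    """Run-scoped count of previously generated canonical forms."""

    def __init__(self) -> None:
        self.counts: dict = {}

    def count(self, smiles: str) -> int:
        return self.counts.get(smiles, 0)

    def increment(self, smiles: str) -> None:
        self.counts[smiles] = self.counts.get(smiles, 0) + 1


@dataclass
class EnvState:
    """An RL state: the tree, its cached assembly, and episode bookkeeping."""

    tree: RJTree
    t: int = 0
    molecule: Optional[Chem.Mol] = None
    done: bool = False
    episode_rewards: list = field(default_factory=list)
    cum_score: float = 0.0  # sum of telescoped increments emitted so far

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.molecule)


def apply_action(state: EnvState, action: ActionRecord, vocab: Vocabulary):
    """Pure transition: returns the new EnvState, or None for an invalid
    (valence-violating or structurally impossible) attachment."""
    if action.stop:
        return replace(state, done=True, episode_rewards=list(state.episode_rewards))
    tree = state.tree
    if not (0 <= action.node < tree.n_nodes):
        raise RangeError(f"action.node {action.node} does not index an existing node")
    try:
        word = vocab.word(action.word)
        site = decode_site(action.site)
    except RangeError:
        return None
    candidate = tree.copy()
    candidate.nodes.append(word)
    candidate.edges.append((action.node, tree.n_nodes, site))
    try:
        mol = assemble(candidate)
    except Exception:  # InvalidAssembly or an RDKit sanitization failure
        return None
    return EnvState(
        tree=candidate,
        t=state.t + 1,
        molecule=mol,
        done=False,
        episode_rewards=list(state.episode_rewards),
        cum_score=state.cum_score,
    )


def step_reward(state_prev: EnvState, state_new: EnvState, cfg: RewardConfig) -> float:
    """Reward for a valid non-terminal transition."""
    if cfg.mode == "final":
        return 0.0
    score = cfg.score_fn(state_new.molecule)
    return score - state_prev.cum_score


def duplication_penalty(final_score: float, n_dup: int, episode_rewards, cfg: RewardConfig) -> float:
    """Terminal reward under the duplication rule.

    When the molecule has been generated more than ``N_lim`` times before,
    the terminal reward is chosen so the episode's undiscounted return is
    exactly zero; otherwise the normal terminal reward is returned
    (the final score in 'final' mode, the residual telescoped increment in
    'step' mode).
    """
    emitted = float(sum(episode_rewards))
    if cfg.duplication_penalty and n_dup > cfg.N_lim:
        if cfg.mode == "final":
            return 0.0
        return -emitted
    if cfg.mode == "final":
        return final_score
    return final_score - emitted


class MolEnv:
    """Gym-style wrapper tying the codec, vocabulary and reward together."""

    def __init__(
        self,
        vocab: Vocabulary,
        cfg: RewardConfig,
        init_smiles: str = "CC",
        ledger: Optional[DuplicationLedger] = None,
    ):
        self.vocab = vocab
        self.cfg = cfg
        self.init_smiles = init_smiles
        self.ledger = ledger if ledger is not None else DuplicationLedger()
        self._init_tree = decompose(init_smiles, vocab)
        self.state: Optional[EnvState] = None

    def reset(self) -> EnvState:
        tree = self._init_tree.copy()
        self.state = EnvState(tree=tree, t=0, molecule=assemble(tree))
        return self.state

    def step(self, action: ActionRecord):
        """Returns (state, reward, done, info)."""
        if self.state is None or self.state.done:
            raise RuntimeError("environment must be reset before stepping")
        cfg = self.cfg
        prev = self.state
        info = {"valid": True, "invalid_action": False, "n_dup": None}

        if action.stop or prev.t + 1 >= cfg.t_max:
            nxt = None if action.stop else apply_action(prev, action, self.vocab)
            if nxt is None:
                # stop action, or invalid final attach: keep previous molecule
                info["invalid_action"] = not action.stop
                nxt = replace(prev, episode_rewards=list(prev.episode_rewards))
            nxt.done = True
            reward = self._terminal_reward(nxt, info)
            nxt.t = prev.t + 1
            nxt.episode_rewards.append(reward)
            self.state = nxt
            return nxt, reward, True, info

        nxt = apply_action(prev, action, self.vocab)
        if nxt is None:
            info["invalid_action"] = True
            reward = cfg.c_invalid
            nxt = replace(prev, t=prev.t + 1, episode_rewards=list(prev.episode_rewards))
        else:
            reward = step_reward(prev, nxt, cfg)
            nxt.cum_score = prev.cum_score + (reward if cfg.mode == "step" else 0.0)
        nxt.episode_rewards.append(reward)
        self.state = nxt
        return nxt, reward, False, info

    def _terminal_reward(self, state: EnvState, info: dict) -> float:
        cfg = self.cfg
        smiles = state.smiles
        score = cfg.score_fn(state.molecule)
        n_dup = self.ledger.count(smiles)
        info["n_dup"] = n_dup
        info["final_smiles"] = smiles
        info["final_score"] = score
        if cfg.duplication_penalty:
            reward = duplication_penalty(score, n_dup, state.episode_rewards, cfg)
        elif cfg.mode == "final":
            reward = score
        else:
            reward = score - float(sum(state.episode_rewards))
        self.ledger.increment(smiles)
        return reward
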