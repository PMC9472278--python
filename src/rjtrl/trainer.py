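"""PPO optimization with truncated GAE and optional expert learning.

The policy is optimized with the clipped surrogate objective plus a value
squared-error loss and an entropy bonus; advantages use truncated
generalized advantage estimation.  Expert learning extracts (state, action)
pairs from dataset molecules' trees — each prefix of a breadth-first
traversal from a randomly chosen root, paired with the attachment that
extends it, plus a final stop example — and minimizes the policy's negative
log-likelihood on them, either standalone (pretraining) or jointly with the
PPO loss weighted by ``c_exp``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .codec import RJTree, decompose
from .env import MolEnv
from .nn.autodiff import Adam, Tensor, minimum, stack
from .nn.policy_value import ActionRecord, PolicyValueNet
from .vocab import Vocabulary, encode_site

__all__ = [
    "PPOConfig",
    "Trajectory",
    "ExpertExample",
    "compute_gae",
    "ppo_loss",
    "expert_examples",
    "expert_nll",
    "pretrain",
    "train",
]


@dataclass
class PPOConfig:
    """Hyperparameters; defaults follow standard PPO practice."""

    clip_eps: float = 0.2
    lam: float = 0.95
    gamma: float = 0.99
    c_vf: float = 0.5
    c_ent: float = 0.01
    c_exp: float = 0.0
    lr: float = 3e-4
    epochs: int = 4
    minibatch_size: int = 64
    rollout_episodes: int = 64
    normalize_advantages: bool = True
    explore_eps: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.clip_eps < 1):
            raise ValueError("clip_eps must be in (0, 1)")
        if not (0 <= self.lam <= 1):
            raise ValueError("lam must be in [0, 1]")
        if self.c_exp < 0:
            raise ValueError("c_exp must be >= 0")
        if not (0 <= self.explore_eps < 1):
            raise ValueError("explore_eps must be in [0, 1)")


@dataclass
class TrajStep:
    tree: RJTree
    action: ActionRecord
    reward: float
    value: float
    logp: float


@dataclass
class Trajectory:
    steps: List[TrajStep] = field(default_factory=list)
    terminal: bool = True


def compute_gae(traj: Trajectory, gamma: float, lam: float):
    """Truncated generalized advantage estimation.

    delta_t = r_t + gamma * V(s_{t+1}) - V(s_t) with a bootstrap value of 0
    at the terminal state; A_t = sum_k (gamma * lam)^k * delta_{t+k};
    value targets are A_t + V(s_t).
    """
    rewards = np.array([s.reward for s in traj.steps], dtype=float)
    values = np.array([s.value for s in traj.steps], dtype=float)
    n = len(rewards)
    next_values = np.append(values[1:], 0.0)
    deltas = rewards + gamma * next_values - values
    adv = np.zeros(n)
    acc = 0.0
    for t in range(n - 1, -1, -1):
        acc = deltas[t] + gamma * lam * acc
        adv[t] = acc
    return adv, adv + values


def ppo_loss(net: PolicyValueNet, batch: Sequence[dict], cfg: PPOConfig):
    """Total PPO loss over a minibatch: -L_CLIP + c_vf * L_VF - c_ent * S.

    Each batch item holds ``tree``, ``action``, ``logp_old``, ``adv`` and
    ``target``.  Returns (loss Tensor, components dict of floats).
    """
    surrs, vlosses, ents = [], [], []
    for item in batch:
        logp, ent, value = net.action_logp_entropy_t(item["tree"], item["action"])
        ratio = (logp - item["logp_old"]).exp()
        adv = item["adv"]
        clipped = ratio.clip(1.0 - cfg.clip_eps, 1.0 + cfg.clip_eps)
        surrs.append(minimum(ratio * adv, clipped * adv))
        diff = value - item["target"]
        vlosses.append(diff * diff)
        ents.append(ent)
    l_clip = stack(surrs).mean()
    l_vf = stack(vlosses).mean()
    s_ent = stack(ents).mean()
    loss = -l_clip + cfg.c_vf * l_vf - cfg.c_ent * s_ent
    components = {
        "clip": float(l_clip.data),
        "vf": float(l_vf.data),
        "entropy": float(s_ent.data),
        "total": float(loss.data),
    }
    return loss, components


# ---------------------------------------------------------------------------
# expert learning


@dataclass
class ExpertExample:
    """A traversal prefix of a molecule's tree and the action extending it."""

    state: RJTree
    action: ActionRecord


def _reroot(tree: RJTree, new_root: int) -> RJTree:
    """Reorient edges away from ``new_root``, swapping site records whose
    direction flips."""
    adj: dict = {i: [] for i in range(tree.n_nodes)}
    for p, c, s in tree.edges:
        adj[p].append((c, s, False))
        adj[c].append((p, s, True))
    edges = []
    seen = {new_root}
    stack_ = [new_root]
    while stack_:
        u = stack_.pop()
        for v, s, flipped in adj[u]:
            if v in seen:
                continue
            seen.add(v)
            edges.append((u, v, s.swapped() if flipped else s))
            stack_.append(v)
    return RJTree(list(tree.nodes), edges, new_root)


def expert_examples(
    mol, vocab: Vocabulary, rng: np.random.Generator, order: str = "breadth"
) -> List[ExpertExample]:
    """Extract (prefix state, attach action) pairs from one molecule.

    The tree is re-rooted at a random node and traversed breadth-first (or
    depth-first) with the children visited in random order; each traversal
    edge yields an attachment example, and the complete tree yields one stop
    example.
    """
    tree = decompose(mol, vocab)
    root = int(rng.integers(tree.n_nodes))
    tree = _reroot(tree, root)

    # traversal over the re-rooted tree
    sequence = []  # (parent_old_idx, child_old_idx, site)
    if order == "breadth":
        frontier = [root]
        while frontier:
            nxt = []
            for u in frontier:
                children = tree.children(u)
                rng.shuffle(children)
                for v, s in children:
                    sequence.append((u, v, s))
                    nxt.append(v)
            frontier = nxt
    elif order == "depth":
        stack_ = [root]
        while stack_:
            u = stack_.pop()
            children = tree.children(u)
            rng.shuffle(children)
            for v, s in children:
                sequence.append((u, v, s))
                stack_.append(v)
    else:
        raise ValueError("order must be 'breadth' or 'depth'")

    new_index = {root: 0}
    prefix = RJTree([tree.nodes[root]], [], 0)
    examples = []
    for u, v, site in sequence:
        action = ActionRecord(
            stop=False,
            node=new_index[u],
            word=vocab.word_id(tree.nodes[v].structure),
            site=encode_site(site),
        )
        examples.append(ExpertExample(state=prefix.copy(), action=action))
        new_index[v] = prefix.n_nodes
        prefix = RJTree(
            prefix.nodes + [tree.nodes[v]],
            prefix.edges + [(new_index[u], new_index[v], site)],
            0,
        )
    examples.append(ExpertExample(state=prefix, action=ActionRecord(stop=True)))
    return examples


def expert_nll(examples: Sequence[ExpertExample], net: PolicyValueNet) -> Tensor:
    """Mean negative log-likelihood of the expert actions under the policy."""
    terms = []
    for ex in examples:
        logp, _, _ = net.action_logp_entropy_t(ex.state, ex.action)
        terms.append(-logp)
    return stack(terms).mean()


def pretrain(
    net: PolicyValueNet,
    dataset: Sequence[str],
    n_steps: int = 200,
    batch_size: int = 16,
    lr: float = 3e-3,
    seed: int = 0,
    order: str = "breadth",
):
    """Standalone expert pretraining; returns the per-step NLL history."""
    rng = np.random.default_rng(seed)
    pool: List[ExpertExample] = []
    for smiles in dataset:
        pool.extend(expert_examples(smiles, net.vocab, rng, order=order))
    if not pool:
        raise ValueError("empty expert dataset")
    opt = Adam(net.parameters(), lr=lr)
    history = []
    for _ in range(n_steps):
        idx = rng.choice(len(pool), size=min(batch_size, len(pool)), replace=False)
        nll = expert_nll([pool[i] for i in idx], net)
        opt.zero_grad()
        nll.backward()
        opt.step()
        history.append(float(nll.data))
    return history


# ---------------------------------------------------------------------------
# the main PPO loop


def _collect_episode(
    env: MolEnv, net: PolicyValueNet, rng: np.random.Generator, explore_eps: float = 0.0
):
    state = env.reset()
    traj = Trajectory()
    info = {}
    while True:
        out = net.policy_forward(state.tree)
        action = net.sample_action(out, rng, explore_eps=explore_eps)
        value = float(net.value_t(out.pool).data)
        tree = state.tree
        state, reward, done, info = env.step(action)
        traj.steps.append(TrajStep(tree, action, reward, value, action.logp))
        if done:
            break
    return traj, info


def train(
    env: MolEnv,
    net: PolicyValueNet,
    cfg: PPOConfig,
    expert_dataset: Optional[Sequence[str]] = None,
    total_episodes: int = 2000,
    stop_at_score: Optional[float] = None,
    log_path=None,
    checkpoint_dir=None,
    checkpoint_every: int = 10,
):
    """Alternate rollout collection and PPO minibatch updates.

    When ``expert_dataset`` is given and ``cfg.c_exp > 0``, each minibatch
    update adds ``c_exp`` times the expert NLL on a freshly resampled expert
    batch.  Logs one row per episode: (episode, score, moving average over
    the last 100, running maximum) — the three series typically plotted for
    a run.  Returns the log as a list of dicts.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.parameters(), lr=cfg.lr)
    expert_pool: List[ExpertExample] = []
    if expert_dataset and cfg.c_exp > 0:
        for smiles in expert_dataset:
            expert_pool.extend(expert_examples(smiles, net.vocab, rng))

    log: List[dict] = []
    recent: List[float] = []
    best = -np.inf
    episode = 0
    update = 0
    stop = False

    while episode < total_episodes and not stop:
        batch_items = []
        n_roll = min(cfg.rollout_episodes, total_episodes - episode)
        for _ in range(n_roll):
            traj, info = _collect_episode(env, net, rng, cfg.explore_eps)
            adv, targets = compute_gae(traj, cfg.gamma, cfg.lam)
            for step, a, tgt in zip(traj.steps, adv, targets):
                batch_items.append(
                    {
                        "tree": step.tree,
                        "action": step.action,
                        "logp_old": step.logp,
                        "adv": float(a),
                        "target": float(tgt),
                    }
                )
            episode += 1
            score = info.get("final_score", np.nan)
            recent.append(score)
            if len(recent) > 100:
                recent.pop(0)
            best = max(best, score)
            log.append(
                {
                    "episode": episode,
                    "score": score,
                    "moving_avg": float(np.mean(recent)),
                    "max": float(best),
                    "smiles": info.get("final_smiles", ""),
                    "n_dup": info.get("n_dup", 0),
                }
            )
            if stop_at_score is not None and best >= stop_at_score:
                stop = True
                break

        if cfg.normalize_advantages and len(batch_items) > 1:
            advs = np.array([b["adv"] for b in batch_items])
            mu, sd = advs.mean(), advs.std()
            for b in batch_items:
                b["adv"] = (b["adv"] - mu) / (sd + 1e-8)

        order_idx = np.arange(len(batch_items))
        for _ in range(cfg.epochs):
            rng.shuffle(order_idx)
            for lo in range(0, len(order_idx), cfg.minibatch_size):
                mb = [batch_items[i] for i in order_idx[lo : lo + cfg.minibatch_size]]
                loss, comps = ppo_loss(net, mb, cfg)
                if cfg.c_exp > 0 and expert_pool:
                    idx = rng.choice(
                        len(expert_pool),
                        size=min(cfg.minibatch_size, len(expert_pool)),
                        replace=False,
                    )
                    loss = loss + cfg.c_exp * expert_nll([expert_pool[i] for i in idx], net)
                if not np.isfinite(float(loss.data)):
                    _dump_diagnostics(log, comps, checkpoint_dir)
                    raise RuntimeError("non-finite PPO loss; diagnostics dumped")
                opt.zero_grad()
                loss.backward()
                opt.step()
        update += 1
        if checkpoint_dir is not None and update % checkpoint_every == 0:
            Path(checkpoint_dir).mkdir(parents=True, exist_ok=True)
            net.save(Path(checkpoint_dir) / f"update_{update:05d}.npz")

    if checkpoint_dir is not None:
        Path(checkpoint_dir).mkdir(parents=True, exist_ok=True)
        net.save(Path(checkpoint_dir) / "final.npz")
    if log_path is not None:
        save_log(log, log_path)
    return log


def save_log(log: Sequence[dict], path) -> None:
    """Write the per-episode training curves.

    CSV by default; a ``.jsonl`` suffix writes one JSON object per episode
    (episode, score, moving average, max, final SMILES, duplication count).
    """
    if str(path).endswith(".jsonl"):
        with open(path, "w") as fh:
            for row in log:
                fh.write(json.dumps(row) + "\n")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["episode", "score", "moving_avg", "max", "smiles", "n_dup"]
        )
        writer.writeheader()
        for row in log:
            writer.writerow(row)


def _dump_diagnostics(log, comps, checkpoint_dir) -> None:
    target = Path(checkpoint_dir) if checkpoint_dir else Path(".")
    target.mkdir(parents=True, exist_ok=True)
    payload = {"loss_components": comps, "last_episodes": log[-20:]}
    (target / "diagnostics.json").write_text(json.dumps(payload, indent=1, default=str))
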