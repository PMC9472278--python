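"""Canned desk-scale study runs shared by the test suite, the acceptance
script and the examples.

These fix the scaled-down study conditions in one place: hidden width 64,
the built-in mini-vocabulary, expert pretraining on 50 generated fixture
molecules, and a PPO setting tuned for small-vocabulary problems
(frequent updates, a stronger entropy bonus than the full-scale default).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .env import MolEnv, RewardConfig
from .fixtures import FixtureSpec, generate_fixtures, mini_vocabulary
from .nn.policy_value import PolicyValueNet
from .rewards import penalized_logp, similarity_reward
from .trainer import PPOConfig, pretrain, train

__all__ = ["DEFAULT_QUERY", "similarity_rediscovery_run", "penalized_logp_run"]

#: the 4-node rediscovery query: 2-(pyridin-4-yl)ethanol
#: (ring word + two C-C bond words + one C-O bond word)
DEFAULT_QUERY = "OCCc1ccncc1"

_DESK_PPO = dict(
    rollout_episodes=8, minibatch_size=32, epochs=4, c_ent=0.05, lr=2e-3
)


def _pretrained_net(seed: int, d: int = 64) -> PolicyValueNet:
    vocab = mini_vocabulary()
    net = PolicyValueNet(vocab, d=d, seed=seed)
    expert = generate_fixtures(FixtureSpec(seed=11, n_molecules=50, max_nodes=5))
    pretrain(net, expert, n_steps=150, batch_size=16, lr=3e-3, seed=seed)
    return net


def similarity_rediscovery_run(
    seed: int = 0,
    query: str = DEFAULT_QUERY,
    total_episodes: int = 2000,
    stop_at_score: Optional[float] = 0.9,
):
    """Step-reward similarity RL toward a query molecule from ethane.

    Returns the per-episode log.  The policy is expert-pretrained first, as
    in the full-scale pipeline.
    """
    net = _pretrained_net(seed)
    cfg = RewardConfig(score_fn=similarity_reward(query), mode="step", t_max=6)
    env = MolEnv(mini_vocabulary(), cfg, init_smiles="CC")
    ppo = PPOConfig(seed=seed, **_DESK_PPO)
    return train(
        env, net, ppo, total_episodes=total_episodes, stop_at_score=stop_at_score
    )


def penalized_logp_run(seed: int = 0, total_episodes: int = 2000):
    """Step-reward penalized-LogP maximization from ethane."""
    net = _pretrained_net(seed)
    cfg = RewardConfig(score_fn=penalized_logp, mode="step", t_max=8)
    env = MolEnv(mini_vocabulary(), cfg, init_smiles="CC")
    ppo = PPOConfig(seed=seed, **_DESK_PPO)
    return train(env, net, ppo, total_episodes=total_episodes)
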