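"""Factored policy distribution and shared value head.

The action has four components: whether to stop, which existing node to
extend, which vocabulary word to attach, and which site code to attach it
with.  The policy factorizes autoregressively,

    pi = pi(stop | pool) * pi(node | {h}) * pi(word | h_node)
         * pi(site | h_node, word embedding),

with the stop head evaluated first, gating the rest.  The stop and value
heads read the summed hidden state (sum pooling lets tree size inform
termination); the node head scores each node with a shared two-layer MLP;
site codes that are structurally impossible for the chosen fragment pair are
masked to exact zero probability.  Chemically invalid actions are left to
the environment's penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from ..codec import RJTree
from ..errors import RangeError
from ..vocab import Vocabulary, site_mask
from .autodiff import Tensor, concat, log_softmax
from .encoder import MLP2, RJTEncoder

__all__ = ["ActionRecord", "PolicyOutput", "PolicyValueNet"]


@dataclass(frozen=True)
class ActionRecord:
    """A sampled (or expert) action with its log-probability bookkeeping.

    For stop actions the node/word/site components are unused and set to -1.
    """

    stop: bool
    node: int = -1
    word: int = -1
    site: int = -1
    logp: float = 0.0
    entropy: float = 0.0


def _entropy(logp: np.ndarray) -> float:
    p = np.exp(logp)
    return float(-(p * np.where(p > 0, logp, 0.0)).sum())


@dataclass
class PolicyOutput:
    """Materialized policy heads for one state.

    ``p_node``/``p_stop`` are unconditional; the word and site heads are
    conditional on the chosen node (and word) and are materialized lazily
    through :meth:`word_logp` / :meth:`site_logp`.
    """

    net: "PolicyValueNet"
    tree: RJTree
    hs: list
    pool: Tensor
    logp_stop: np.ndarray  # [log p(continue), log p(stop)]
    logp_node: np.ndarray
    _word_cache: dict = field(default_factory=dict)
    _site_cache: dict = field(default_factory=dict)

    @property
    def p_stop(self) -> float:
        return float(np.exp(self.logp_stop[1]))

    @property
    def p_node(self) -> np.ndarray:
        return np.exp(self.logp_node)

    def word_logp(self, node: int) -> np.ndarray:
        if node not in self._word_cache:
            t = self.net.word_logp_t(self.hs, node)
            self._word_cache[node] = t.data
        return self._word_cache[node]

    def site_logp(self, node: int, word: int) -> np.ndarray:
        key = (node, word)
        if key not in self._site_cache:
            t = self.net.site_logp_t(self.tree, self.hs, node, word)
            self._site_cache[key] = t.data
        return self._site_cache[key]

    def p_word(self, node: int) -> np.ndarray:
        return np.exp(self.word_logp(node))

    def p_site(self, node: int, word: int) -> np.ndarray:
        return np.exp(self.site_logp(node, word))


class PolicyValueNet:
    """Encoder-sharing policy and value networks over RJT states."""

    def __init__(self, vocab: Vocabulary, d: int = 128, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.vocab = vocab
        self.d = d
        self.encoder = RJTEncoder(vocab, d=d, seed=seed)
        self.mlp_stop = MLP2(rng, d, d, 1)
        self.mlp_node = MLP2(rng, d, d, 1)
        self.mlp_word = MLP2(rng, d, d, vocab.n_voc)
        self.mlp_site = MLP2(rng, 2 * d, d, vocab.n_site)
        self.mlp_value = MLP2(rng, d, d, 1)

    def parameters(self):
        return (
            self.encoder.parameters()
            + self.mlp_stop.parameters()
            + self.mlp_node.parameters()
            + self.mlp_word.parameters()
            + self.mlp_site.parameters()
            + self.mlp_value.parameters()
        )

    # -- differentiable head evaluations -----------------------------------
    def stop_logp_t(self, pool: Tensor) -> Tensor:
        """[log p(continue), log p(stop)] as a Tensor of shape (2,)."""
        logit = self.mlp_stop(pool)
        return log_softmax(concat([Tensor(np.zeros(1)), logit]))

    def node_logp_t(self, hs) -> Tensor:
        scores = concat([self.mlp_node(h) for h in hs])
        return log_softmax(scores)

    def word_logp_t(self, hs, node: int) -> Tensor:
        if not (0 <= node < len(hs)):
            raise RangeError(f"node {node} out of range")
        return log_softmax(self.mlp_word(hs[node]))

    def site_logp_t(self, tree: RJTree, hs, node: int, word: int) -> Tensor:
        if not (0 <= word < self.vocab.n_voc):
            raise RangeError(f"word {word} out of range")
        mask = site_mask(tree.nodes[node], self.vocab.word(word))
        x = concat([hs[node], self.encoder.E_node[word]])
        return log_softmax(self.mlp_site(x), mask=mask)

    def value_t(self, pool: Tensor) -> Tensor:
        return self.mlp_value(pool)[0]

    # -- spec-level operations ---------------------------------------------
    def policy_forward(self, tree: RJTree) -> PolicyOutput:
        hs, pool = self.encoder.encode(tree)
        return PolicyOutput(
            net=self,
            tree=tree,
            hs=hs,
            pool=pool,
            logp_stop=self.stop_logp_t(pool).data,
            logp_node=self.node_logp_t(hs).data,
        )

    def value_forward(self, tree: RJTree) -> float:
        _, pool = self.encoder.encode(tree)
        return float(self.value_t(pool).data)

    def sample_action(
        self,
        out: PolicyOutput,
        rng: np.random.Generator,
        explore_eps: float = 0.0,
    ) -> ActionRecord:
        """Draw an action head by head (stop first) and record its total
        log-probability and summed head entropies.

        ``explore_eps`` mixes each head with a uniform distribution over its
        allowed categories (behaviour-policy exploration); the recorded
        log-probability is that of the mixture, so importance ratios against
        it remain correct.
        """

        def mix(logp_vec):
            """(sampling probabilities, log-probability lookup)."""
            p = np.exp(logp_vec)
            if explore_eps <= 0:
                return p, lambda i: float(logp_vec[i])
            allowed = p > 0
            pm = (1 - explore_eps) * p + explore_eps * allowed / allowed.sum()
            return pm, lambda i: float(np.log(pm[i]))

        p_stop_vec, lp_stop = mix(out.logp_stop)
        stop = rng.random() < p_stop_vec[1]
        logp = lp_stop(1 if stop else 0)
        entropy = _entropy(out.logp_stop)
        if stop:
            return ActionRecord(stop=True, logp=logp, entropy=entropy)
        p_node, lp_node = mix(out.logp_node)
        node = int(rng.choice(len(p_node), p=p_node))
        logp += lp_node(node)
        entropy += _entropy(out.logp_node)
        wl = out.word_logp(node)
        p_word, lp_word = mix(wl)
        word = int(rng.choice(len(p_word), p=p_word))
        logp += lp_word(word)
        entropy += _entropy(wl)
        sl = out.site_logp(node, word)
        p_site, lp_site = mix(sl)
        site = int(rng.choice(len(p_site), p=p_site))
        logp += lp_site(site)
        entropy += _entropy(sl)
        return ActionRecord(stop=False, node=node, word=word, site=site, logp=logp, entropy=entropy)

    def action_log_prob(self, out: PolicyOutput, action: ActionRecord) -> float:
        """Log-probability of ``action`` under materialized heads."""
        if action.stop:
            return float(out.logp_stop[1])
        if not (0 <= action.node < len(out.logp_node)):
            raise RangeError("action node out of range")
        return float(
            out.logp_stop[0]
            + out.logp_node[action.node]
            + out.word_logp(action.node)[action.word]
            + out.site_logp(action.node, action.word)[action.site]
        )

    # -- differentiable path for PPO / expert NLL ---------------------------
    def action_logp_entropy_t(self, tree: RJTree, action: ActionRecord):
        """(log pi(a|s), summed head entropy) as Tensors, for gradients."""
        hs, pool = self.encoder.encode(tree)
        lstop = self.stop_logp_t(pool)
        ent = _entropy_t(lstop)
        if action.stop:
            return lstop[1], ent, self.value_t(pool)
        lnode = self.node_logp_t(hs)
        lword = self.word_logp_t(hs, action.node)
        lsite = self.site_logp_t(tree, hs, action.node, action.word)
        logp = lstop[0] + lnode[action.node] + lword[action.word] + lsite[action.site]
        ent = ent + _entropy_t(lnode) + _entropy_t(lword) + _entropy_t(lsite)
        return logp, ent, self.value_t(pool)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(
            path,
            __meta_d=np.array([self.d]),
            __meta_vocab_hash=np.frombuffer(
                self.vocab.content_hash().encode(), dtype=np.uint8
            ),
            **arrays,
        )

    def load(self, path) -> None:
        data = np.load(path)
        stored = bytes(data["__meta_vocab_hash"]).decode()
        if stored != self.vocab.content_hash():
            raise ValueError(
                "checkpoint was trained against a different vocabulary "
                f"(hash {stored}, current {self.vocab.content_hash()})"
            )
        for i, p in enumerate(self.parameters()):
            arr = data[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError("checkpoint shape mismatch")
            p.data = arr.astype(np.float64)


def _entropy_t(logp: Tensor) -> Tensor:
    p = logp.exp()
    return -(p * logp).sum()
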