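"""Tree-structured GRU encoder over reversible junction trees.

Each node's word ID and each edge's site code are embedded with learnable
matrices ``E_node`` and ``E_edge``.  Messages ``m[i, j]`` flow along every
directed tree edge in two phases — bottom-up (leaves to root), then top-down
(root to leaves) — through a GRU cell whose input concatenates the sending
node's feature with the edge feature, and whose hidden input sums the
incoming messages from the other neighbours.  A node's hidden vector is
``ReLU(W_out @ concat(x_i, sum of incoming messages))``.

The edge feature for the reversed direction uses the site code with parent
and child fields swapped, so messages stay directionally informative.
"""

from __future__ import annotations

import numpy as np

from ..codec import RJTree
from ..errors import RangeError
from ..vocab import Vocabulary, encode_site
from .autodiff import Parameter, Tensor, concat

__all__ = ["TreeGRUCell", "RJTEncoder", "edge_feature_codes"]


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    fan = sum(shape)
    limit = np.sqrt(6.0 / fan)
    return rng.uniform(-limit, limit, size=shape)


class Linear:
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = Parameter(_glorot(rng, (n_out, n_in)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return self.W @ x + self.b

    def parameters(self):
        return [self.W, self.b]


class MLP2:
    """Two-layer perceptron with an interior ReLU."""

    def __init__(self, rng, n_in: int, n_hidden: int, n_out: int):
        self.l1 = Linear(rng, n_in, n_hidden)
        self.l2 = Linear(rng, n_hidden, n_out)

    def __call__(self, x: Tensor) -> Tensor:
        return self.l2(self.l1(x).relu())

    def parameters(self):
        return self.l1.parameters() + self.l2.parameters()


class TreeGRUCell:
    """GRU cell with per-message reset gates, as used in junction-tree
    encoders, extended with an edge feature concatenated onto the input."""

    def __init__(self, rng, d_in: int, d: int):
        self.d = d
        self.Wz = Linear(rng, d_in, d)
        self.Uz = Parameter(_glorot(rng, (d, d)))
        self.Wr = Linear(rng, d_in, d)
        self.Ur = Parameter(_glorot(rng, (d, d)))
        self.Wh = Linear(rng, d_in, d)
        self.Uh = Parameter(_glorot(rng, (d, d)))

    def __call__(self, x: Tensor, incoming) -> Tensor:
        """One message update.

        ``x``: concat(node feature, edge feature); ``incoming``: list of
        message Tensors from the other neighbours (may be empty).
        """
        if incoming:
            s = incoming[0]
            for m in incoming[1:]:
                s = s + m
        else:
            s = Tensor(np.zeros(self.d))
        z = (self.Wz(x) + self.Uz @ s).sigmoid()
        if incoming:
            gated = None
            for m in incoming:
                r = (self.Wr(x) + self.Ur @ m).sigmoid()
                rm = r * m
                gated = rm if gated is None else gated + rm
        else:
            gated = Tensor(np.zeros(self.d))
        h_tilde = (self.Wh(x) + self.Uh @ gated).tanh()
        one = Tensor(np.ones(self.d))
        return (one - z) * s + z * h_tilde

    def parameters(self):
        return (
            self.Wz.parameters()
            + [self.Uz]
            + self.Wr.parameters()
            + [self.Ur]
            + self.Wh.parameters()
            + [self.Uh]
        )


def edge_feature_codes(tree: RJTree) -> dict:
    """Site code for every directed edge (i, j) of the tree."""
    codes = {}
    for p, c, site in tree.edges:
        codes[(p, c)] = encode_site(site)
        codes[(c, p)] = encode_site(site.swapped())
    return codes


class RJTEncoder:
    """Embeddings + two-phase tree GRU + aggregation."""

    def __init__(self, vocab: Vocabulary, d: int = 128, seed: int = 0):
        if d <= 0:
            raise ValueError("hidden width must be positive")
        rng = np.random.default_rng(seed)
        self.vocab = vocab
        self.d = d
        scale = 1.0 / np.sqrt(d)
        self.E_node = Parameter(rng.normal(scale=scale, size=(vocab.n_voc, d)))
        self.E_edge = Parameter(rng.normal(scale=scale, size=(vocab.n_site, d)))
        self.cell = TreeGRUCell(rng, 2 * d, d)
        self.W_out = Linear(rng, 2 * d, d)

    def parameters(self):
        return [self.E_node, self.E_edge] + self.cell.parameters() + self.W_out.parameters()

    # -- operations --------------------------------------------------------
    def word_ids(self, tree: RJTree):
        return [self.vocab.word_id(w.structure) for w in tree.nodes]

    def embed(self, tree: RJTree):
        """Node features x_i (rows of E_node) and directed edge features
        y[(i, j)] (rows of E_edge at the oriented site code)."""
        ids = self.word_ids(tree)
        for w in ids:
            if not (0 <= w < self.vocab.n_voc):
                raise RangeError(f"word id {w} out of vocabulary")
        x = [self.E_node[w] for w in ids]
        y = {pair: self.E_edge[code] for pair, code in edge_feature_codes(tree).items()}
        return x, y

    def propagate(self, tree: RJTree, x, y) -> dict:
        """Two-phase message passing; returns {(i, j): m_ij} with exactly one
        message per directed edge."""
        messages: dict = {}
        order = self._bottom_up_order(tree)
        # bottom-up: message from each non-root node to its parent
        for i, parent in order:
            incoming = [
                messages[(k, i)] for k, _ in tree.neighbors(i) if k != parent
            ]
            messages[(i, parent)] = self.cell(concat([x[i], y[(i, parent)]]), incoming)
        # top-down: message from each parent to each child
        for i, parent in reversed(order):
            incoming = [
                messages[(k, parent)]
                for k, _ in tree.neighbors(parent)
                if k != i
            ]
            messages[(parent, i)] = self.cell(
                concat([x[parent], y[(parent, i)]]), incoming
            )
        return messages

    def aggregate(self, tree: RJTree, x, messages):
        """Hidden vectors h_i = ReLU(W_out @ concat(x_i, sum incoming))."""
        hs = []
        for i in range(tree.n_nodes):
            nbrs = [k for k, _ in tree.neighbors(i)]  # ascending index
            if nbrs:
                s = messages[(nbrs[0], i)]
                for k in nbrs[1:]:
                    s = s + messages[(k, i)]
            else:
                s = Tensor(np.zeros(self.d))
            hs.append(self.W_out(concat([x[i], s])).relu())
        return hs

    def encode(self, tree: RJTree):
        """Full pass: returns (list of h_i Tensors, pooled sum Tensor)."""
        x, y = self.embed(tree)
        messages = self.propagate(tree, x, y)
        hs = self.aggregate(tree, x, messages)
        pool = hs[0]
        for h in hs[1:]:
            pool = pool + h
        return hs, pool

    @staticmethod
    def _bottom_up_order(tree: RJTree):
        """(node, parent) pairs such that every node appears after all of its
        children; deterministic."""
        parent = {tree.root: None}
        order_bfs = [tree.root]
        frontier = [tree.root]
        while frontier:
            nxt = []
            for p in frontier:
                for c, _ in sorted(tree.children(p)):
                    parent[c] = p
                    order_bfs.append(c)
                    nxt.append(c)
            frontier = nxt
        return [(i, parent[i]) for i in reversed(order_bfs) if parent[i] is not None]
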