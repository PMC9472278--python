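"""Synthetic drug-like fixture molecules.

Fixtures are grown as random reversible junction trees over a vocabulary —
sampling words and structurally admissible site codes, rejecting
valence-invalid attachments — and then assembled to SMILES.  Every output
decomposes under the same vocabulary and passes the dataset filter by
construction.  A built-in mini-vocabulary of ~20 common ring/bond/atom
fragments lets the whole suite run with zero downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional

import numpy as np

from .codec import assemble, canonical_smiles, decompose, RJTree
from .vocab import Vocabulary, build_vocabulary, decode_site, site_mask

__all__ = ["MINI_VOCAB_SMILES", "mini_vocabulary", "FixtureSpec", "generate_fixtures"]

#: seed molecules whose decompositions span the built-in mini-vocabulary
#: (aromatic and saturated rings, common bonds, singleton hubs, and one
#: fused pair so that the kekulized fused-ring word is included)
MINI_VOCAB_SMILES = (
    "c1ccccc1",        # benzene
    "c1ccncc1",        # pyridine
    "c1cncnc1",        # pyrimidine
    "c1ccoc1",         # furan
    "c1ccsc1",         # thiophene
    "c1cc[nH]c1",      # pyrrole
    "C1CCCCC1",        # cyclohexane
    "C1CCCC1",         # cyclopentane
    "C1CCOC1",         # tetrahydrofuran
    "c1ccc2ccccc2c1",  # naphthalene (fused-ring word)
    "CC",              # C-C
    "CN",              # C-N
    "CO",              # C-O
    "C=C",             # C=C
    "C=O",             # C=O
    "CF",              # C-F
    "CCl",             # C-Cl
    "CS",              # C-S
    "C#N",             # nitrile
    "CC(C)(C)C",       # neopentane (carbon singleton hub)
)


@lru_cache(maxsize=1)
def mini_vocabulary() -> Vocabulary:
    return build_vocabulary(MINI_VOCAB_SMILES)


@dataclass
class FixtureSpec:
    """Reproducible fixture-set specification."""

    seed: int = 0
    n_molecules: int = 100
    max_nodes: int = 6
    vocabulary: Optional[Vocabulary] = None

    def vocab(self) -> Vocabulary:
        return self.vocabulary if self.vocabulary is not None else mini_vocabulary()


def random_tree(
    vocab: Vocabulary,
    rng: np.random.Generator,
    max_nodes: int,
    max_attempts: int = 30,
) -> RJTree:
    """Grow one random valid tree (rejection sampling on attachments)."""
    target = int(rng.integers(1, max_nodes + 1))
    tree = RJTree([vocab.word(int(rng.integers(vocab.n_voc)))], [], 0)
    attempts = 0
    while tree.n_nodes < target and attempts < max_attempts:
        attempts += 1
        node = int(rng.integers(tree.n_nodes))
        wid = int(rng.integers(vocab.n_voc))
        mask = site_mask(tree.nodes[node], vocab.word(wid))
        codes = np.flatnonzero(mask)
        code = int(rng.choice(codes))
        candidate = tree.copy()
        candidate.nodes.append(vocab.word(wid))
        candidate.edges.append((node, tree.n_nodes, decode_site(code)))
        try:
            assemble(candidate)
        except Exception:
            continue
        tree = candidate
    return tree


def generate_fixtures(spec: FixtureSpec) -> List[str]:
    """Generate ``spec.n_molecules`` SMILES, reproducibly for a given seed.

    Molecules whose assembled form does not re-decompose under the
    vocabulary (e.g. an angular ring fusion creating a cyclic fragment
    graph) are rejected and regrown.
    """
    vocab = spec.vocab()
    rng = np.random.default_rng(spec.seed)
    out: List[str] = []
    while len(out) < spec.n_molecules:
        tree = random_tree(vocab, rng, spec.max_nodes)
        try:
            smi = canonical_smiles(assemble(tree))
            # coverage check on the canonical form, the frame every consumer
            # parses: ring fusions can re-kekulize into out-of-vocab words
            decompose(smi, vocab)
        except Exception:
            continue
        out.append(smi)
    return out
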