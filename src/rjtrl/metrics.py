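"""Generation-set quality metrics (MOSES-style).

validity: fraction of parseable outputs; uniqueness: unique canonical forms
among valid outputs; novelty: fraction of unique outputs absent from a
reference set; internal diversity: one minus the mean pairwise fingerprint
similarity of the valid outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from .rewards import similarity

__all__ = ["GenerationMetrics", "compute_metrics"]


@dataclass(frozen=True)
class GenerationMetrics:
    validity: float
    uniqueness: float
    novelty: float
    internal_diversity: float

    def as_dict(self) -> dict:
        return {
            "validity": self.validity,
            "uniqueness": self.uniqueness,
            "novelty": self.novelty,
            "internal_diversity": self.internal_diversity,
        }


def compute_metrics(
    generated: Sequence[str], reference: Iterable[str] = ()
) -> GenerationMetrics:
    """Compute the four metrics; all lie in [0, 1].

    Permutation-invariant in the generated set.  Novelty is measured against
    the canonicalized reference; an empty reference gives novelty 1 for any
    non-empty valid set.
    """
    if not generated:
        raise ValueError("empty generated set")
    valid_mols, valid_smiles = [], []
    for s in generated:
        mol = Chem.MolFromSmiles(s)
        if mol is not None:
            valid_mols.append(mol)
            valid_smiles.append(Chem.MolToSmiles(mol))
    validity = len(valid_smiles) / len(generated)
    if not valid_smiles:
        return GenerationMetrics(0.0, 0.0, 0.0, 0.0)
    unique = sorted(set(valid_smiles))
    uniqueness = len(unique) / len(valid_smiles)
    ref = {Chem.MolToSmiles(m) for m in map(Chem.MolFromSmiles, reference) if m is not None}
    novelty = float(np.mean([s not in ref for s in unique]))
    pairs = list(combinations(range(len(valid_mols)), 2))
    if pairs:
        mean_sim = float(np.mean([similarity(valid_mols[i], valid_mols[j]) for i, j in pairs]))
    else:
        mean_sim = 1.0
    return GenerationMetrics(validity, uniqueness, novelty, 1.0 - mean_sim)
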