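"""Fragment vocabulary and the site-category index space.

The vocabulary maps canonical fragment structures to word IDs.  Site
information is flattened into a fixed dense categorical space of size
``n_site = 8 * 8 * 6``: parent atom index (up to the 8-atom ring maximum),
child atom index, and one of six direction codes — ``NA`` (type-1 edge), the
four fused-ring sign combinations, and spiro ``(0, 0)``.  Structurally
impossible codes are masked at sampling time rather than removed, keeping the
policy head a fixed width.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from rdkit import Chem

from .codec import MAX_RING_ATOMS, FragmentWord, SiteInfo, decompose
from .errors import RangeError, UnsupportedMolecule

logger = logging.getLogger(__name__)

MAX_FRAGMENT_ATOMS = MAX_RING_ATOMS

#: direction codes: (parent_dir, child_dir)
DIR_CODES = ((None, None), (1, 1), (1, -1), (-1, 1), (-1, -1), (0, 0))
_DIR_INDEX = {c: i for i, c in enumerate(DIR_CODES)}

N_SITE = MAX_FRAGMENT_ATOMS * MAX_FRAGMENT_ATOMS * len(DIR_CODES)


def encode_site(site: SiteInfo) -> int:
    """Flatten a SiteInfo into an integer in ``[0, N_SITE)``."""
    key = (site.parent_dir, site.child_dir)
    if key not in _DIR_INDEX:
        raise RangeError(f"inadmissible direction pair {key}")
    p, c = site.parent_atom_idx, site.child_atom_idx
    if not (0 <= p < MAX_FRAGMENT_ATOMS and 0 <= c < MAX_FRAGMENT_ATOMS):
        raise RangeError("site atom index outside the dense space")
    return (p * MAX_FRAGMENT_ATOMS + c) * len(DIR_CODES) + _DIR_INDEX[key]


def decode_site(code: int) -> SiteInfo:
    """Inverse of :func:`encode_site`."""
    if not (0 <= code < N_SITE):
        raise RangeError(f"site code {code} outside [0, {N_SITE})")
    pc, d = divmod(code, len(DIR_CODES))
    p, c = divmod(pc, MAX_FRAGMENT_ATOMS)
    pd, cd = DIR_CODES[d]
    edge_type = 1 if pd is None else 2
    return SiteInfo(edge_type, p, c, pd, cd)


def site_mask(parent: FragmentWord, child: FragmentWord):
    """Boolean mask over the dense site space: True = structurally possible
    for attaching a ``child`` fragment to a ``parent`` fragment."""
    mask = np.zeros(N_SITE, dtype=bool)
    both_rings = parent.is_ring and child.is_ring
    for p in range(parent.size):
        for c in range(child.size):
            base = (p * MAX_FRAGMENT_ATOMS + c) * len(DIR_CODES)
            if both_rings:
                for d in range(1, len(DIR_CODES)):
                    mask[base + d] = True
            else:
                mask[base] = True
    return mask


@dataclass
class Vocabulary:
    """Bidirectional map between canonical fragment structures and word IDs."""

    words: list = field(default_factory=list)  # list[FragmentWord]
    n_site: int = N_SITE

    def __post_init__(self) -> None:
        self.index = {w.structure: i for i, w in enumerate(self.words)}

    @property
    def n_voc(self) -> int:
        return len(self.words)

    def __contains__(self, structure: str) -> bool:
        return structure in self.index

    def __len__(self) -> int:
        return len(self.words)

    def word_id(self, structure: str) -> int:
        try:
            return self.index[structure]
        except KeyError:
            raise RangeError(f"fragment {structure!r} not in vocabulary") from None

    def word(self, word_id: int) -> FragmentWord:
        if not (0 <= word_id < self.n_voc):
            raise RangeError(f"word id {word_id} outside [0, {self.n_voc})")
        return self.words[word_id]

    # -- persistence -------------------------------------------------------
    def to_json(self) -> dict:
        return {
            "words": [w.structure for w in self.words],
            "max_fragment_atoms": MAX_FRAGMENT_ATOMS,
            "n_site": self.n_site,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def from_json(cls, obj: dict) -> "Vocabulary":
        return cls(words=[FragmentWord.from_structure(s) for s in obj["words"]])

    @classmethod
    def load(cls, path) -> "Vocabulary":
        return cls.from_json(json.loads(Path(path).read_text()))

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256("\n".join(w.structure for w in self.words).encode())
        return h.hexdigest()[:16]


def build_vocabulary(dataset: Iterable[str]) -> Vocabulary:
    """Collect the unique fragment words over all decompositions.

    Words are sorted by canonical structure, so the result does not depend on
    dataset order.  An undecomposable record aborts with its line number.
    """
    seen: dict = {}
    for lineno, smiles in enumerate(dataset, start=1):
        try:
            tree = decompose(smiles)
        except UnsupportedMolecule as exc:
            raise UnsupportedMolecule(f"record {lineno} ({smiles!r}): {exc}") from exc
        for w in tree.nodes:
            seen[w.structure] = w
    words = [seen[s] for s in sorted(seen)]
    return Vocabulary(words=words)


# ---------------------------------------------------------------------------
# dataset filtering


def _is_bridged_pair(ring_a, ring_b) -> bool:
    inter = set(ring_a) & set(ring_b)
    if len(inter) > 2:
        return True
    if len(inter) == 2:
        a, b = inter
        edges = {
            frozenset((ring_a[i], ring_a[(i + 1) % len(ring_a)]))
            for i in range(len(ring_a))
        }
        return frozenset((a, b)) not in edges
    return False


def count_substitution_sites(mol: Chem.Mol) -> int:
    """Ring atoms bearing at least one non-ring neighbour."""
    n = 0
    for atom in mol.GetAtoms():
        if not atom.IsInRing():
            continue
        if any(not nb.IsInRing() for nb in atom.GetNeighbors()):
            n += 1
    return n


def filter_dataset(
    dataset: Iterable[str],
    max_ring_atoms: int = MAX_RING_ATOMS,
    max_substitution_sites: int = 8,
) -> tuple:
    """Apply the dataset preparation rules.

    Removes unparseable records, macrocyclic compounds (any ring of more than
    ``max_ring_atoms`` atoms), bridge compounds with more than
    ``max_substitution_sites`` substitution sites, and molecules whose
    fragment graph cannot form a tree.  Returns ``(kept, report)`` where
    ``report`` is a Counter of per-rule rejection counts.
    """
    kept = []
    report: Counter = Counter()
    for smiles in dataset:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            report["unparseable"] += 1
            continue
        rings = [tuple(r) for r in Chem.GetSSSR(mol)]
        if any(len(r) > max_ring_atoms for r in rings):
            report["macrocycle"] += 1
            continue
        bridged = any(
            _is_bridged_pair(rings[i], rings[j])
            for i in range(len(rings))
            for j in range(i + 1, len(rings))
        )
        if bridged:
            if count_substitution_sites(mol) > max_substitution_sites:
                report["bridged_too_many_sites"] += 1
                continue
            # bridged pairs within the site budget still cannot be encoded
            report["bridged_unrepresentable"] += 1
            continue
        try:
            decompose(mol)
        except UnsupportedMolecule:
            report["non_tree_fragment_graph"] += 1
            continue
        kept.append(smiles)
        report["kept"] += 1
    for rule, count in sorted(report.items()):
        logger.info("filter_dataset: %s = %d", rule, count)
    return kept, report
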