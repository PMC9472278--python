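"""Reversible junction-tree (RJT) codec.

A molecule is fragmented into ring, bond and singleton clusters (SSSR ring
perception), each cluster becomes a tree node, and every edge carries "site
information": which atom of each fragment is shared, plus a direction ID for
fused ring pairs.  Unlike the plain junction tree, this record makes the
decomposition invertible — ``assemble(decompose(m))`` returns a molecule whose
canonical SMILES equals ``m``'s — without any auxiliary model.

Conventions
-----------
* Fragments are canonicalized standalone; a fragment's ``atom_order`` is the
  RDKit canonical atom ranking of its canonical form, so the same word always
  exposes the same index frame.
* For ring fragments the "canonical walk" starts at the rank-0 atom and
  proceeds toward its lower-ranked ring neighbour.  Direction +1 means the
  second shared atom immediately follows the first along that walk, -1 that
  it precedes it; spiro pairs use direction 0 on both sides.
* Stereochemistry is dropped on decomposition; hydrogens are implicit.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
from rdkit import Chem, RDLogger

from .errors import InvalidAssembly, SiteError, UnsupportedMolecule

RDLogger.DisableLog("rdApp.*")

MAX_RING_ATOMS = 8

MolLike = Union[str, Chem.Mol]

_BOND_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: 1,
}


# ---------------------------------------------------------------------------
# molecule helpers


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, dropping stereochemistry."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise UnsupportedMolecule(f"unparseable SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    return mol


def as_mol(mol: MolLike) -> Chem.Mol:
    return mol_from_smiles(mol) if isinstance(mol, str) else mol


def canonical_smiles(mol: MolLike) -> str:
    return Chem.MolToSmiles(as_mol(mol))


def validate_valence(mol: MolLike) -> bool:
    """True iff every atom's bonding is chemically admissible.

    Delegates to RDKit sanitization, i.e. the standard, charge-adjusted
    valence table (a neutral carbon with five bonds fails; an N+ with four
    single bonds passes).
    """
    try:
        probe = Chem.Mol(as_mol(mol))
        Chem.SanitizeMol(probe)
    except Exception:
        return False
    return True


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SiteInfo:
    """Per-edge record enabling deterministic assembly.

    ``parent_atom_idx`` / ``child_atom_idx`` index the fragments' canonical
    atom order.  Directions are ``None`` (type-1 edge), +1/-1 (fused ring
    pair) or 0/0 (spiro).
    """

    edge_type: int
    parent_atom_idx: int
    child_atom_idx: int
    parent_dir: Optional[int] = None
    child_dir: Optional[int] = None

    def __post_init__(self) -> None:
        if self.edge_type not in (1, 2):
            raise SiteError(f"edge_type must be 1 or 2, got {self.edge_type}")
        if self.edge_type == 1 and not (self.parent_dir is None and self.child_dir is None):
            raise SiteError("type-1 edges carry no direction IDs")
        if self.edge_type == 2 and (self.parent_dir is None or self.child_dir is None):
            raise SiteError("type-2 edges require direction IDs")

    @property
    def is_spiro(self) -> bool:
        return self.edge_type == 2 and self.parent_dir == 0

    def swapped(self) -> "SiteInfo":
        """The same record seen from the other end of the edge."""
        return SiteInfo(
            self.edge_type,
            self.child_atom_idx,
            self.parent_atom_idx,
            self.child_dir,
            self.parent_dir,
        )

    def as_tuple(self) -> tuple:
        return (
            self.edge_type,
            self.parent_atom_idx,
            self.child_atom_idx,
            self.parent_dir,
            self.child_dir,
        )

    @classmethod
    def from_tuple(cls, t: Sequence) -> "SiteInfo":
        return cls(*t)


@dataclass(frozen=True)
class FragmentWord:
    """A vocabulary word: a canonical ring, bond or single-atom fragment."""

    structure: str
    kind: str  # 'ring' | 'bond' | 'singleton'
    size: int

    @classmethod
    def from_structure(cls, structure: str) -> "FragmentWord":
        ref = _ref_entry(structure)
        return cls(structure=structure, kind=ref.kind, size=ref.size)

    @property
    def is_ring(self) -> bool:
        return self.kind == "ring"


@dataclass
class RJTree:
    """Rooted tree of fragment words with site-annotated edges.

    ``edges`` hold ``(parent_index, child_index, SiteInfo)`` oriented away
    from ``root``.
    """

    nodes: list  # list[FragmentWord]
    edges: list  # list[tuple[int, int, SiteInfo]]
    root: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def children(self, i: int):
        return [(c, s) for p, c, s in self.edges if p == i]

    def neighbors(self, i: int):
        """(neighbor, SiteInfo oriented i->neighbor) pairs, ascending index."""
        out = []
        for p, c, s in self.edges:
            if p == i:
                out.append((c, s))
            elif c == i:
                out.append((p, s.swapped()))
        out.sort(key=lambda t: t[0])
        return out

    def validate(self) -> None:
        n = self.n_nodes
        if n == 0:
            raise ValueError("empty tree")
        if len(self.edges) != n - 1:
            raise ValueError("edge count must be node count - 1")
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((p, c) for p, c, _ in self.edges)
        if g.number_of_edges() != n - 1 or not nx.is_connected(g):
            raise ValueError("edges do not form a tree")

    def copy(self) -> "RJTree":
        return RJTree(list(self.nodes), list(self.edges), self.root)

    def to_json(self) -> dict:
        return {
            "nodes": [w.structure for w in self.nodes],
            "edges": [[p, c, list(s.as_tuple())] for p, c, s in self.edges],
            "root": self.root,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "RJTree":
        nodes = [FragmentWord.from_structure(s) for s in obj["nodes"]]
        edges = [(p, c, SiteInfo.from_tuple(t)) for p, c, t in obj["edges"]]
        return cls(nodes, edges, obj.get("root", 0))


# ---------------------------------------------------------------------------
# reference fragments (one canonical frame per word)


class _RefEntry:
    __slots__ = ("mol", "kind", "size", "order", "rank", "walk_pos", "walk_seq")

    def __init__(self, structure: str):
        mol = Chem.MolFromSmiles(structure)
        if mol is None:
            raise UnsupportedMolecule(f"bad fragment structure {structure!r}")
        self.mol = mol
        self.size = mol.GetNumAtoms()
        nring = Chem.GetSSSR(mol)
        if self.size == 1:
            self.kind = "singleton"
        elif len(nring) >= 1:
            self.kind = "ring"
        else:
            if self.size != 2:
                raise UnsupportedMolecule(
                    f"fragment {structure!r} is neither ring, bond nor singleton"
                )
            self.kind = "bond"
        self.rank = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
        self.order = [0] * self.size  # rank -> atom index
        for idx, r in enumerate(self.rank):
            self.order[r] = idx
        self.walk_pos = None
        self.walk_seq = None
        if self.kind == "ring":
            self.walk_seq = _canonical_ring_walk(mol, self.rank)
            self.walk_pos = {a: i for i, a in enumerate(self.walk_seq)}

    def walk_neighbor(self, atom_idx: int, direction: int) -> int:
        seq, pos = self.walk_seq, self.walk_pos
        return seq[(pos[atom_idx] + direction) % len(seq)]


def _canonical_ring_walk(mol: Chem.Mol, rank: Sequence[int]) -> list:
    """Cyclic atom sequence of a simple-ring fragment, in a canonical
    orientation: start at the rank-0 atom, step toward its lower-ranked ring
    neighbour."""
    start = rank.index(0)
    nbrs = [n.GetIdx() for n in mol.GetAtomWithIdx(start).GetNeighbors()]
    if len(nbrs) != 2:
        raise SiteError("ring fragment is not a simple cycle")
    second = min(nbrs, key=lambda a: rank[a])
    seq = [start, second]
    while True:
        cur = seq[-1]
        nxt = [n.GetIdx() for n in mol.GetAtomWithIdx(cur).GetNeighbors() if n.GetIdx() != seq[-2]]
        if len(nxt) != 1:
            raise SiteError("ring fragment is not a simple cycle")
        if nxt[0] == start:
            return seq
        seq.append(nxt[0])


@lru_cache(maxsize=100_000)
def _ref_entry(structure: str) -> _RefEntry:
    return _RefEntry(structure)


# ---------------------------------------------------------------------------
# site information


def compute_site_info(
    parent: FragmentWord,
    child: FragmentWord,
    shared_atoms: Sequence[tuple],
) -> SiteInfo:
    """Build the SiteInfo for an edge from (parent_rank, child_rank) pairs of
    the shared atoms.

    One pair gives a type-1 edge (or a spiro type-2 edge when both fragments
    are rings); two pairs require two fused rings whose shared atoms are
    adjacent along each ring walk.  Deterministic: the pair whose parent rank
    is lower is taken as the first atom.
    """
    pairs = list(shared_atoms)
    if len(pairs) == 0 or len(pairs) > 2:
        raise SiteError(f"{len(pairs)} shared atoms; expected 1 or 2")
    for p_rank, c_rank in pairs:
        if not (0 <= p_rank < parent.size) or not (0 <= c_rank < child.size):
            raise SiteError("shared-atom index outside fragment")
    if len(pairs) == 1:
        (p_rank, c_rank) = pairs[0]
        if parent.is_ring and child.is_ring:
            return SiteInfo(2, p_rank, c_rank, 0, 0)
        return SiteInfo(1, p_rank, c_rank)
    if not (parent.is_ring and child.is_ring):
        raise SiteError("two shared atoms require two ring fragments")
    pairs.sort(key=lambda t: t[0])
    (pu, cu), (pv, cv) = pairs
    p_ref = _ref_entry(parent.structure)
    c_ref = _ref_entry(child.structure)
    p_dir = _walk_direction(p_ref, pu, pv)
    c_dir = _walk_direction(c_ref, cu, cv)
    return SiteInfo(2, pu, cu, p_dir, c_dir)


def _walk_direction(ref: _RefEntry, rank_u: int, rank_v: int) -> int:
    u, v = ref.order[rank_u], ref.order[rank_v]
    n = ref.size
    pu, pv = ref.walk_pos[u], ref.walk_pos[v]
    if (pu + 1) % n == pv:
        return 1
    if (pu - 1) % n == pv:
        return -1
    raise SiteError("shared atoms are not adjacent in the ring")


# ---------------------------------------------------------------------------
# decomposition


def decompose(mol: MolLike, vocabulary=None) -> RJTree:
    """Convert a molecule into its reversible junction tree.

    Fragments are SSSR rings and non-ring bonds; a shared atom becomes a
    singleton node whenever three or more otherwise-unlinked fragments meet
    there.  Raises :class:`UnsupportedMolecule` for macrocycles (rings of
    more than eight atoms), bridged ring pairs, polycyclic systems whose
    fragment graph is not a tree, and — when ``vocabulary`` is given — for
    fragments outside it.
    """
    mol = as_mol(mol)
    mol = Chem.Mol(mol)
    Chem.RemoveStereochemistry(mol)
    Chem.SanitizeMol(mol)
    n_atoms = mol.GetNumAtoms()
    if n_atoms == 0:
        raise UnsupportedMolecule("empty molecule")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise UnsupportedMolecule("disconnected molecule")

    kek = Chem.Mol(mol)
    try:
        Chem.Kekulize(kek, clearAromaticFlags=True)
    except Exception as exc:  # pragma: no cover - exotic aromaticity
        raise UnsupportedMolecule(f"cannot kekulize: {exc}") from exc

    rings = [tuple(r) for r in Chem.GetSSSR(Chem.Mol(mol))]
    for r in rings:
        if len(r) > MAX_RING_ATOMS:
            raise UnsupportedMolecule(f"macrocycle: ring of {len(r)} atoms")

    ring_edges = set()
    for r in rings:
        for i in range(len(r)):
            ring_edges.add(frozenset((r[i], r[(i + 1) % len(r)])))

    clusters: list = [("ring", r) for r in rings]
    for bond in kek.GetBonds():
        pair = (bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
        if frozenset(pair) not in ring_edges:
            clusters.append(("bond", pair))

    if not clusters:  # single atom, no bonds
        word, _, _ = _extract_word(kek, (0,), ())
        return RJTree([word], [], 0)

    atom2clusters: dict = {}
    for ci, (_, atoms) in enumerate(clusters):
        for a in atoms:
            atom2clusters.setdefault(a, []).append(ci)

    shared: dict = {}
    edges_set = set()

    # mandatory ring-ring edges (fused / spiro)
    for i in range(len(clusters)):
        if clusters[i][0] != "ring":
            continue
        for j in range(i + 1, len(clusters)):
            if clusters[j][0] != "ring":
                continue
            inter = set(clusters[i][1]) & set(clusters[j][1])
            if not inter:
                continue
            if len(inter) > 2:
                raise UnsupportedMolecule("bridged ring pair shares more than two atoms")
            edges_set.add((i, j))
            shared[(i, j)] = sorted(inter)

    # per-atom connection: link every set of fragments meeting at an atom
    singleton_words: dict = {}
    for a in sorted(atom2clusters):
        K = atom2clusters[a]
        if len(K) < 2:
            continue
        sub = nx.Graph()
        sub.add_nodes_from(K)
        sub.add_edges_from(
            (i, j) for (i, j) in edges_set if i in K and j in K
        )
        comps = sorted(sorted(c) for c in nx.connected_components(sub))
        if len(comps) == 1:
            continue
        reps = [c[0] for c in comps]
        if len(comps) == 2:
            i, j = sorted(reps)
            edges_set.add((i, j))
            shared[(i, j)] = [a]
        else:
            si = len(clusters)
            clusters.append(("singleton", (a,)))
            singleton_words[si] = a
            for rep in reps:
                edges_set.add((rep, si))
                shared[(rep, si)] = [a]

    g = nx.Graph()
    g.add_nodes_from(range(len(clusters)))
    g.add_edges_from(edges_set)
    if g.number_of_edges() != len(clusters) - 1 or not nx.is_connected(g):
        raise UnsupportedMolecule("fragment adjacency graph is not a tree")

    # per-cluster fragment words and rank frames
    words, rank_of_atom = [], []
    for kind, atoms in clusters:
        if kind == "ring":
            bonds = [(atoms[i], atoms[(i + 1) % len(atoms)]) for i in range(len(atoms))]
        elif kind == "bond":
            bonds = [atoms]
        else:
            bonds = []
        word, amap, ranks = _extract_word(kek, atoms, bonds)
        words.append(word)
        rank_of_atom.append({a: ranks[amap[a]] for a in atoms})
        if vocabulary is not None and word.structure not in vocabulary:
            raise UnsupportedMolecule(f"fragment {word.structure!r} not in vocabulary")

    # root: fragment containing the canonical first atom (lowest index tie-break)
    can_rank = list(Chem.CanonicalRankAtoms(mol))
    first_atom = can_rank.index(0)
    root = min(atom2clusters.get(first_atom, [0]))

    # orient edges away from the root (BFS) and attach site information
    tree_edges = []
    visited = {root}
    frontier = [root]
    while frontier:
        nxt = []
        for p in frontier:
            for q in sorted(g.neighbors(p)):
                if q in visited:
                    continue
                visited.add(q)
                nxt.append(q)
                key = (p, q) if (p, q) in shared else (q, p)
                atoms = shared[key]
                pairs = [(rank_of_atom[p][a], rank_of_atom[q][a]) for a in atoms]
                site = compute_site_info(words[p], words[q], pairs)
                tree_edges.append((p, q, site))
        frontier = nxt

    tree = RJTree(words, tree_edges, root)
    tree.validate()
    return tree


def _extract_word(kek: Chem.Mol, atoms: Sequence[int], bonds: Iterable[tuple]):
    """Extract a fragment as a standalone canonical molecule.

    Returns (FragmentWord, atom map parent->fragment index, fragment canonical
    ranks)."""
    em = Chem.RWMol()
    amap = {}
    for a in atoms:
        src = kek.GetAtomWithIdx(a)
        na = Chem.Atom(src.GetAtomicNum())
        na.SetFormalCharge(src.GetFormalCharge())
        amap[a] = em.AddAtom(na)
    for x, y in bonds:
        em.AddBond(amap[x], amap[y], kek.GetBondBetweenAtoms(x, y).GetBondType())
    sub = em.GetMol()
    try:
        Chem.SanitizeMol(sub)
    except Exception as exc:
        raise UnsupportedMolecule(f"cannot sanitize fragment: {exc}") from exc
    structure = Chem.MolToSmiles(sub)
    ranks = list(Chem.CanonicalRankAtoms(sub, breakTies=True))
    # ranks are computed on this instance; FragmentWord's frame is the parsed
    # canonical form, which is isomorphic with identical rank assignment.
    word = FragmentWord.from_structure(structure)
    return word, amap, ranks


# ---------------------------------------------------------------------------
# assembly


def assemble(tree: RJTree, sanitize: bool = True) -> Chem.Mol:
    """Depth-first merge of fragments into a molecule (the codec inverse).

    Child fragments are attached to the growing graph by unifying the shared
    atoms named by each edge's site information.  Raises
    :class:`InvalidAssembly` when site information is incompatible with the
    node types or the result fails valence validation.
    """
    tree.validate()
    em = Chem.RWMol()
    placed: dict = {}

    def merge_child(parent: int, child: int, site: SiteInfo) -> None:
        pw, cw = tree.nodes[parent], tree.nodes[child]
        p_ref, c_ref = _ref_entry(pw.structure), _ref_entry(cw.structure)
        if not (0 <= site.parent_atom_idx < pw.size) or not (0 <= site.child_atom_idx < cw.size):
            raise InvalidAssembly("site index outside fragment")
        if site.edge_type == 2 and not (pw.is_ring and cw.is_ring):
            raise InvalidAssembly("type-2 edge requires two ring nodes")
        if site.edge_type == 1 and pw.is_ring and cw.is_ring:
            raise InvalidAssembly("ring-ring edges must be type 2")
        pu = p_ref.order[site.parent_atom_idx]
        cu = c_ref.order[site.child_atom_idx]
        mapping = {cu: placed[parent][pu]}
        if site.edge_type == 2 and not site.is_spiro:
            if site.parent_dir not in (1, -1) or site.child_dir not in (1, -1):
                raise InvalidAssembly("fused edge requires +1/-1 directions")
            pv = p_ref.walk_neighbor(pu, site.parent_dir)
            cv = c_ref.walk_neighbor(cu, site.child_dir)
            mapping[cv] = placed[parent][pv]
        shared_globals = set(mapping.values())
        _merge_fragment(em, c_ref, mapping, shared_globals)
        placed[child] = mapping

    root_map: dict = {}
    _merge_fragment(em, _ref_entry(tree.nodes[tree.root].structure), root_map, set())
    placed[tree.root] = root_map

    stack = [tree.root]
    seen = {tree.root}
    while stack:
        p = stack.pop()
        for c, site in sorted(tree.children(p)):
            if c in seen:
                continue
            seen.add(c)
            merge_child(p, c, site)
            stack.append(c)

    mol = em.GetMol()
    if sanitize:
        try:
            # normalize aromaticity from the merged flags first: kekulizing
            # the raw flag state can fail where a ring mixes atoms placed by
            # aromatic and non-aromatic fragments
            partial = Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
            err = Chem.SanitizeMol(mol, partial, catchErrors=True)
            if err != Chem.SanitizeFlags.SANITIZE_NONE:
                raise InvalidAssembly(f"assembled graph failed sanitization at {err}")
            Chem.SanitizeMol(mol)
        except InvalidAssembly:
            raise
        except Exception as exc:
            raise InvalidAssembly(f"assembled graph failed sanitization: {exc}") from exc
    return mol


def _merge_fragment(em: Chem.RWMol, ref: _RefEntry, mapping: dict, shared_globals: set) -> None:
    """Add a fragment's atoms and bonds into the growing molecule, unifying
    atoms already named in ``mapping``."""
    for atom in ref.mol.GetAtoms():
        idx = atom.GetIdx()
        if idx in mapping:
            ex = em.GetAtomWithIdx(mapping[idx])
            if ex.GetAtomicNum() != atom.GetAtomicNum() or ex.GetFormalCharge() != atom.GetFormalCharge():
                raise InvalidAssembly("shared atoms differ between fragments")
            if atom.GetIsAromatic() and not ex.GetIsAromatic():
                ex.SetIsAromatic(True)
        else:
            na = Chem.Atom(atom.GetAtomicNum())
            na.SetFormalCharge(atom.GetFormalCharge())
            na.SetIsAromatic(atom.GetIsAromatic())
            na.SetNumExplicitHs(atom.GetNumExplicitHs())
            na.SetNoImplicit(atom.GetNoImplicit())
            mapping[idx] = em.AddAtom(na)
    for bond in ref.mol.GetBonds():
        gx = mapping[bond.GetBeginAtomIdx()]
        gy = mapping[bond.GetEndAtomIdx()]
        existing = em.GetBondBetweenAtoms(gx, gy)
        if existing is not None:
            if bond.GetBondType() == Chem.BondType.AROMATIC and existing.GetBondType() != Chem.BondType.AROMATIC:
                existing.SetBondType(Chem.BondType.AROMATIC)
                em.GetAtomWithIdx(gx).SetIsAromatic(True)
                em.GetAtomWithIdx(gy).SetIsAromatic(True)
            continue
        em.AddBond(gx, gy, bond.GetBondType())
        order = _BOND_ORDER.get(bond.GetBondType(), 1)
        for g in (gx, gy):
            if g in shared_globals:
                ex = em.GetAtomWithIdx(g)
                h = ex.GetNumExplicitHs()
                if h > 0:
                    ex.SetNumExplicitHs(max(0, h - order))


def roundtrip(smiles: str, vocabulary=None) -> bool:
    """True iff ``smiles`` survives decompose -> assemble unchanged."""
    mol = mol_from_smiles(smiles)
    want = Chem.MolToSmiles(mol)
    got = Chem.MolToSmiles(assemble(decompose(mol, vocabulary)))
    return want == got
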