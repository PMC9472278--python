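"""Scoring functions for molecular design.

Implements the penalized LogP benchmark score, feature-fingerprint
similarity, the distance-based protein-interaction score, and the
multiobjective combination with docking, synthetic-accessibility and LogP
penalty terms.  External docking is exposed only as an adapter contract; a
deterministic mock engine ships for tests and end-to-end runs.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import AllChem, Crippen, Lipinski, rdFingerprintGenerator

from .codec import MolLike, as_mol
from .errors import AdapterError, ScoreError

__all__ = [
    "penalized_logp",
    "PenalizedLogPConfig",
    "sa_score",
    "similarity",
    "InteractionSpec",
    "Pose",
    "interaction_score",
    "MultiObjectiveWeights",
    "multiobjective_reward",
    "DockingAdapter",
    "MockDockingEngine",
]


# ---------------------------------------------------------------------------
# synthetic accessibility (RDKit contrib scorer)

_sascorer = None


def _get_sascorer():
    global _sascorer
    if _sascorer is None:
        from rdkit.Chem import RDConfig

        path = os.path.join(RDConfig.RDContribDir, "SA_Score")
        if path not in sys.path:
            sys.path.append(path)
        import sascorer  # noqa: F401

        _sascorer = sascorer
    return _sascorer


def sa_score(mol: MolLike) -> float:
    """Synthetic-accessibility score (1 easy ... 10 hard)."""
    try:
        return float(_get_sascorer().calculateScore(as_mol(mol)))
    except Exception as exc:
        raise ScoreError(f"SA score failed: {exc}") from exc


# ---------------------------------------------------------------------------
# penalized LogP


@dataclass(frozen=True)
class PenalizedLogPConfig:
    """Normalization constants of the benchmark lineage (ZINC250k
    statistics); each descriptor is standardized before combination."""

    logp_mean: float = 2.4570953396190123
    logp_std: float = 1.434324401111988
    sa_mean: float = -3.0525811293166134
    sa_std: float = 0.8335207024513095
    cycle_mean: float = -0.0485696876403053
    cycle_std: float = 0.2860212110245455


def _largest_ring_size(mol: Chem.Mol) -> int:
    rings = mol.GetRingInfo().AtomRings()
    return max((len(r) for r in rings), default=0)


def penalized_logp(mol: MolLike, config: PenalizedLogPConfig = PenalizedLogPConfig()) -> float:
    """Octanol-water LogP penalized by synthetic accessibility and by rings
    larger than six atoms, each term standardized by dataset statistics."""
    m = as_mol(mol)
    try:
        logp = Crippen.MolLogP(m)
        sa = -sa_score(m)
        largest = _largest_ring_size(m)
        cycle = -max(0, largest - 6)
    except ScoreError:
        raise
    except Exception as exc:
        raise ScoreError(f"penalized LogP failed: {exc}") from exc
    return (
        (logp - config.logp_mean) / config.logp_std
        + (sa - config.sa_mean) / config.sa_std
        + (cycle - config.cycle_mean) / config.cycle_std
    )


# ---------------------------------------------------------------------------
# fingerprint similarity

_fp_gen = None


def _fingerprint(mol: Chem.Mol):
    global _fp_gen
    if _fp_gen is None:
        _fp_gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=2,
            atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
        )
    return _fp_gen.GetSparseCountFingerprint(mol)


def similarity(mol_a: MolLike, mol_b: MolLike) -> float:
    """Jaccard (Tanimoto) index of feature-typed circular fingerprints of
    radius 2 (FCFP4)."""
    try:
        fa = _fingerprint(as_mol(mol_a))
        fb = _fingerprint(as_mol(mol_b))
        return float(DataStructs.TanimotoSimilarity(fa, fb))
    except ScoreError:
        raise
    except Exception as exc:
        raise ScoreError(f"similarity failed: {exc}") from exc


def similarity_reward(query: MolLike) -> Callable:
    """Score function handle: similarity of a molecule to a fixed query."""
    q = as_mol(query)

    def fn(mol: Chem.Mol) -> float:
        return similarity(mol, q)

    return fn


# ---------------------------------------------------------------------------
# interaction score


@dataclass
class Pose:
    """A docked (or mock) pose: coordinates plus acceptor annotations."""

    coords: np.ndarray  # (n_atoms, 3)
    acceptor_flags: np.ndarray  # (n_atoms,) bool


@dataclass
class InteractionSpec:
    """Target protein atoms and the distance window of the clamp."""

    protein_atoms: Sequence  # list of 3D coordinates
    d_min: float = 3.0
    d_max: float = 6.0

    def __post_init__(self) -> None:
        if not self.d_min < self.d_max:
            raise ValueError("d_min must be < d_max")


def interaction_score(pose: Pose, spec: InteractionSpec) -> float:
    """Distance-clamped hydrogen-bond proximity score in [0, 1].

    For each specified protein atom, the closest compound acceptor at
    distance d scores 1 for d <= d_min, 0 for d >= d_max, and linearly in
    between; the total is the mean over the protein atoms.  Poses without
    acceptors score 0.
    """
    flags = np.asarray(pose.acceptor_flags, dtype=bool)
    if not flags.any():
        return 0.0
    acceptors = np.asarray(pose.coords, dtype=float)[flags]
    scores = []
    for p in spec.protein_atoms:
        d = float(np.min(np.linalg.norm(acceptors - np.asarray(p, dtype=float), axis=1)))
        if d <= spec.d_min:
            scores.append(1.0)
        elif d >= spec.d_max:
            scores.append(0.0)
        else:
            scores.append((spec.d_max - d) / (spec.d_max - spec.d_min))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# multiobjective reward


@dataclass
class MultiObjectiveWeights:
    """Term weights; the docking score is clipped to +-``dock_clip`` and
    enters negated (more negative binding energy = better)."""

    c_intr: float = 10.0
    c_sa: float = 1.0
    c_logp: float = 5.0
    dock_clip: float = 500.0

    def __post_init__(self) -> None:
        if min(self.c_intr, self.c_sa, self.c_logp) < 0:
            raise ValueError("weights must be >= 0")


def sa_penalty(sa: float, threshold: float = 4.0) -> float:
    """Hinge penalty restricting the SA score below ``threshold``."""
    return max(0.0, sa - threshold)


def logp_penalty(logp: float, low: float = 0.0, high: float = 5.0) -> float:
    """Hinge penalty restricting LogP to the range [low, high]."""
    return max(0.0, low - logp) + max(0.0, logp - high)


def multiobjective_reward(
    dock_score: float,
    pose: Pose,
    mol: MolLike,
    spec: InteractionSpec,
    weights: MultiObjectiveWeights = MultiObjectiveWeights(),
) -> float:
    """c_intr * interaction - clip(dG) - c_sa * P_SA - c_logp * P_LogP."""
    m = as_mol(mol)
    intr = interaction_score(pose, spec)
    dg = float(np.clip(dock_score, -weights.dock_clip, weights.dock_clip))
    p_sa = sa_penalty(sa_score(m))
    p_logp = logp_penalty(Crippen.MolLogP(m))
    return weights.c_intr * intr - dg - weights.c_sa * p_sa - weights.c_logp * p_logp


# ---------------------------------------------------------------------------
# docking adapter contract

_acceptor_query = None


def acceptor_flags(mol: Chem.Mol) -> np.ndarray:
    """Hydrogen-bond-acceptor flags per atom (RDKit's Lipinski pattern)."""
    global _acceptor_query
    if _acceptor_query is None:
        _acceptor_query = Lipinski.HAcceptorSmarts
    flags = np.zeros(mol.GetNumAtoms(), dtype=bool)
    for (idx,) in mol.GetSubstructMatches(_acceptor_query):
        flags[idx] = True
    return flags


def get_score_fn(name: str, **params) -> Callable:
    """Look up a reward function by configuration name.

    ``penalized_logp`` (no parameters), ``similarity`` (``query`` SMILES),
    or ``multiobjective`` with the mock docking engine (``protein_atoms``,
    optional ``d_min``/``d_max`` and term weights).
    """
    if name == "penalized_logp":
        cfg = PenalizedLogPConfig(**params)
        return lambda mol: penalized_logp(mol, cfg)
    if name == "similarity":
        return similarity_reward(params["query"])
    if name == "multiobjective":
        engine_name = params.pop("engine", "mock")
        if engine_name != "mock":
            raise AdapterError(
                "only the mock docking engine ships with the core package"
            )
        spec = InteractionSpec(
            protein_atoms=params.pop("protein_atoms"),
            d_min=params.pop("d_min", 3.0),
            d_max=params.pop("d_max", 6.0),
        )
        weights = MultiObjectiveWeights(**params)
        engine = MockDockingEngine()

        def fn(mol: Chem.Mol) -> float:
            dg, pose = engine.dock(mol)
            return multiobjective_reward(dg, pose, mol, spec, weights)

        return fn
    raise ValueError(f"unknown reward function {name!r}")


class DockingAdapter:
    """Contract for external docking engines.

    Implementations return ``(dG, Pose)`` for a molecule; failures raise
    :class:`AdapterError`.  The core package never executes a real engine.
    """

    def dock(self, mol: Chem.Mol):  # pragma: no cover - interface
        raise NotImplementedError


class MockDockingEngine(DockingAdapter):
    """Deterministic stand-in engine for tests and end-to-end runs.

    dG = -(heavy atom count) / 5; the pose is a flat 2D-coordinate embedding
    with RDKit acceptor annotations, optionally shifted by ``offset``.
    """

    def __init__(self, offset=(0.0, 0.0, 0.0)):
        self.offset = np.asarray(offset, dtype=float)

    def dock(self, mol: Chem.Mol):
        try:
            m = Chem.Mol(mol)
            dg = -m.GetNumHeavyAtoms() / 5.0
            AllChem.Compute2DCoords(m)
            conf = m.GetConformer()
            coords = np.array(
                [list(conf.GetAtomPosition(i)) for i in range(m.GetNumAtoms())]
            )
            return dg, Pose(coords + self.offset, acceptor_flags(m))
        except Exception as exc:
            raise AdapterError(f"mock docking failed: {exc}") from exc
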