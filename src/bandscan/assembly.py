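"""Rigid-body superposition and subunit grafting.

Complex models are assembled by aligning a shared scaffold between two
structures and carrying "cargo" subunits across with the fitted transform —
e.g. moving a ubiquitin-like modifier from the complex where it was solved
onto the scaffold of the complex being modelled. The fit is the classic
least-squares (Kabsch/SVD) superposition.

``homolog_rmsd`` implements the duplicate-alignment trick for comparing two
homologous proteins: a copy of the first is superimposed onto the second over
sequence-aligned CA pairs and the residual CA RMSD is reported.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align

from .structure import AtomSet, Structure, select

__all__ = ["RigidTransform", "AtomPairing", "kabsch_fit", "graft_subunit",
           "homolog_rmsd"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation determinant is not +1 (improper rotation)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class AtomPairing:
    """1:1 atom correspondence between a mobile and a reference set.

    ``pairs[k] = (i_mobile, j_reference)`` index into the respective AtomSets.
    """

    pairs: list[tuple[int, int]]
    mode: str = "by-name"

    def __post_init__(self):
        if len(self.pairs) < 3:
            raise ValueError("need at least 3 atom pairs for a rigid fit")
        left = [p[0] for p in self.pairs]
        right = [p[1] for p in self.pairs]
        if len(set(left)) != len(left) or len(set(right)) != len(right):
            raise ValueError("atom pairs must be unique on both sides")

    @classmethod
    def by_order(cls, n: int) -> "AtomPairing":
        return cls([(i, i) for i in range(n)], mode="by-order")

    @classmethod
    def by_name(cls, mobile: AtomSet, reference: AtomSet) -> "AtomPairing":
        """Pair atoms sharing (res_seq, icode, atom name); chain IDs may differ."""
        sm, sr = mobile.structure, reference.structure
        ref_index = {}
        for k, j in enumerate(reference.indices):
            key = (int(sr.res_seq[j]), str(sr.icode[j]), str(sr.name[j]))
            ref_index.setdefault(key, k)
        pairs = []
        for k, i in enumerate(mobile.indices):
            key = (int(sm.res_seq[i]), str(sm.icode[i]), str(sm.name[i]))
            if key in ref_index:
                pairs.append((k, ref_index[key]))
        return cls(pairs, mode="by-name")


def kabsch_fit(mobile: AtomSet, reference: AtomSet,
               pairing: AtomPairing | None = None) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of paired atoms; returns (transform, rmsd).

    Without an explicit pairing the sets are paired in order and must have
    equal sizes. Collinear (rank-deficient) pairings are rejected.
    """
    if pairing is None:
        if len(mobile) != len(reference):
            raise ValueError("sets of unequal size need an explicit pairing")
        pairing = AtomPairing.by_order(len(mobile))
    mi = np.array([p[0] for p in pairing.pairs])
    ri = np.array([p[1] for p in pairing.pairs])
    x = mobile.coord[mi]
    y = reference.coord[ri]
    return _kabsch(x, y)


def _kabsch(x: np.ndarray, y: np.ndarray) -> tuple[RigidTransform, float]:
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    x0 = x - xc
    y0 = y - yc
    H = x0.T @ y0
    U, S, Vt = np.linalg.svd(H)
    # degenerate if the paired points span < 2 dimensions
    spread = np.linalg.svd(x0, compute_uv=False)
    if spread[1] < 1e-8 * max(spread[0], 1.0):
        raise ValueError("collinear or degenerate atom pairing; fit is ill-posed")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(x) - y) ** 2, axis=1))))
    return transform, rmsd


def graft_subunit(donor: Structure, donor_scaffold: AtomSet,
                  acceptor: Structure, acceptor_scaffold: AtomSet,
                  cargo: AtomSet) -> Structure:
    """Carry ``cargo`` from the donor into the acceptor's frame.

    The donor scaffold is superimposed onto the acceptor scaffold (pairing by
    residue number + atom name, falling back to in-order pairing when the
    selections match 1:1); cargo atoms are transformed by that fit and
    appended to the acceptor. Acceptor atoms are never modified and the
    cargo's internal geometry is preserved exactly (rigid motion). On a chain
    ID collision the cargo is assigned fresh chain IDs with a logged warning.
    """
    if cargo.structure is not donor:
        raise ValueError("cargo must be an AtomSet of the donor structure")
    pairing = AtomPairing.by_name(donor_scaffold, acceptor_scaffold)
    transform, rmsd = kabsch_fit(donor_scaffold, acceptor_scaffold, pairing)
    logger.info("graft: scaffold fit over %d pairs, rmsd %.3f A",
                len(pairing.pairs), rmsd)

    cargo_struct = cargo.to_structure()
    cargo_struct = cargo_struct.with_coord(transform.apply(cargo_struct.coord))

    taken = set(acceptor.chains)
    colliding = [c for c in cargo_struct.chains if c in taken]
    if colliding:
        fresh = iter(c for c in "ZYXWVUTSRQPONMLKJIHGFEDCBA0123456789"
                     if c not in taken and c not in cargo_struct.chains)
        mapping = {c: next(fresh) for c in colliding}
        warnings.warn(f"graft: cargo chain IDs {colliding} collide with the "
                      f"acceptor; reassigned {mapping}")
        new_chain = cargo_struct.chain_id.copy()
        for old, new in mapping.items():
            new_chain[cargo_struct.chain_id == old] = new
        cargo_struct.chain_id = new_chain

    fields = {f: np.concatenate([getattr(acceptor, f), getattr(cargo_struct, f)])
              for f in Structure._FIELDS}
    coord = np.concatenate([acceptor.coord, cargo_struct.coord])
    out = Structure(coord=coord, title=acceptor.title, **fields)
    out.serial = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# Homolog RMSD by duplicate alignment
# ---------------------------------------------------------------------------

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _ca_trace(s: Structure) -> tuple[str, np.ndarray]:
    mask = (s.name == "CA") & ~s.is_hetero
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError("structure has no CA atoms")
    seq = "".join(_THREE_TO_ONE.get(str(s.res_name[i]), "X") for i in idx)
    return seq, s.coord[idx]


def homolog_rmsd(a: Structure, b: Structure, min_matched: int = 20) -> float:
    """CA RMSD between two homologous chains via sequence-then-structure alignment.

    Two different proteins have no native atom correspondence; instead the
    sequences are globally aligned (match +1, mismatch -1, gap -2), a duplicate
    of ``a`` is superimposed onto ``b`` over the matched CA pairs, and the CA
    RMSD over those pairs after superposition is returned.
    """
    seq_a, ca_a = _ca_trace(a)
    seq_b, ca_b = _ca_trace(b)
    aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                    mismatch_score=-1, open_gap_score=-2,
                                    extend_gap_score=-2)
    alignment = aligner.align(seq_a, seq_b)[0]
    pairs_a, pairs_b = [], []
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        pairs_a.extend(range(a0, a1))
        pairs_b.extend(range(b0, b1))
    if len(pairs_a) < min_matched:
        raise ValueError(f"only {len(pairs_a)} matched positions; "
                         f"need at least {min_matched}")
    _, rmsd = _kabsch(ca_a[pairs_a], ca_b[pairs_b])
    return rmsd
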