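"""Anisotropic network model (ANM) over CA nodes, mode animation, and the
two-mode combination scan.

The complex is reduced to one node per residue (its CA atom); nodes within a
cutoff are joined by identical Hookean springs. The 3N x 3N Hessian has
super-elements H_ij = -(gamma / d_ij^2) r_ij r_ij^T for connected pairs, with
diagonal blocks closing each row-block sum to zero, so rigid translations are
exact zero modes. "Major" modes are the lowest-frequency non-rigid
eigenvectors; animating a mode displaces every atom of a residue by that
residue's CA displacement (per-residue rigid translation), the simplest
all-atom reconstruction of a CA-level mode.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .structure import Structure

__all__ = ["ElasticNetwork", "ModeSet", "ConformerEnsemble", "FrameInfo",
           "build_anm", "normal_modes", "animate_mode", "combined_mode_scan"]

ZERO_MODE_RELATIVE_THRESHOLD = 1e-8


@dataclass
class ElasticNetwork:
    """CA-node network of a structure."""

    node_coords: np.ndarray            # (N, 3)
    node_map: list[tuple[str, int, str]]   # node -> (chain_id, res_seq, icode)
    cutoff: float = 15.0
    gamma: float = 1.0
    node_atom_indices: np.ndarray | None = None  # CA atom index per node

    def __post_init__(self):
        self.node_coords = np.asarray(self.node_coords, dtype=float).reshape(-1, 3)
        if len(self.node_coords) < 2:
            raise ValueError("need at least 2 nodes")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if len(self.node_map) != len(self.node_coords):
            raise ValueError("node_map length must equal node count")

    @classmethod
    def from_structure(cls, s: Structure, cutoff: float = 15.0,
                       gamma: float = 1.0) -> "ElasticNetwork":
        mask = (s.name == "CA") & ~s.is_hetero
        idx = np.flatnonzero(mask)
        node_map = [(str(s.chain_id[i]), int(s.res_seq[i]), str(s.icode[i]))
                    for i in idx]
        return cls(s.coord[idx].copy(), node_map, cutoff=cutoff, gamma=gamma,
                   node_atom_indices=idx)


@dataclass
class ModeSet:
    """Non-rigid eigenmodes, lowest frequency first."""

    eigenvalues: np.ndarray    # (k,), ascending, all above the zero threshold
    eigenvectors: np.ndarray   # (k, 3N), unit norm
    n_zero_skipped: int

    def mode(self, rank: int) -> tuple[float, np.ndarray]:
        """1-based access: mode(1) is the lowest-frequency non-rigid mode."""
        if rank < 1 or rank > len(self.eigenvalues):
            raise IndexError(f"mode rank {rank} out of range 1..{len(self.eigenvalues)}")
        return float(self.eigenvalues[rank - 1]), self.eigenvectors[rank - 1]


@dataclass
class FrameInfo:
    """Provenance of one ensemble frame."""

    stage: str
    mode_rank: int | None = None
    frame_index: int | None = None
    amplitude: float | None = None
    parent_frame: dict | None = None
    draw_index: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


@dataclass
class ConformerEnsemble:
    """Indexed coordinate frames sharing the parent structure's topology."""

    parent: Structure
    frames: list[np.ndarray] = field(default_factory=list)
    provenance: list[FrameInfo] = field(default_factory=list)

    def __post_init__(self):
        if len(self.frames) != len(self.provenance):
            raise ValueError("one provenance record per frame required")
        for f in self.frames:
            if f.shape != self.parent.coord.shape:
                raise ValueError("frame topology differs from parent")

    def __len__(self) -> int:
        return len(self.frames)

    def append(self, coord: np.ndarray, info: FrameInfo) -> None:
        if coord.shape != self.parent.coord.shape:
            raise ValueError("frame topology differs from parent")
        self.frames.append(coord)
        self.provenance.append(info)

    def extend(self, other: "ConformerEnsemble") -> None:
        for coord, info in zip(other.frames, other.provenance):
            self.append(coord, info)


def build_anm(net: ElasticNetwork) -> np.ndarray:
    """Assemble the 3N x 3N ANM Hessian for a network.

    Symmetric by construction; every row-block sums to zero, so uniform
    translations lie exactly in the null space.
    """
    coords = net.node_coords
    n = len(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    dist2 = np.einsum("ijk,ijk->ij", diff, diff)
    if np.min(dist2 + np.eye(n)) < 1e-12:
        raise ValueError("coincident nodes in elastic network")
    connected = (dist2 <= net.cutoff ** 2) & ~np.eye(n, dtype=bool)
    hessian = np.zeros((3 * n, 3 * n))
    ii, jj = np.nonzero(connected)
    for i, j in zip(ii, jj):
        if i >= j:
            continue
        r = diff[i, j]
        block = -(net.gamma / dist2[i, j]) * np.outer(r, r)
        hessian[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
        hessian[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
        hessian[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        hessian[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return hessian


def normal_modes(hessian: np.ndarray, k: int) -> ModeSet:
    """The ``k`` lowest-frequency non-rigid modes of an ANM Hessian.

    Eigenpairs with eigenvalue below ``1e-8 x`` the largest eigenvalue are
    treated as rigid-body (zero) modes and skipped. Eigenvector signs follow
    the convention that the largest-magnitude component is positive, making
    repeated runs reproducible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    evals, evecs = scipy.linalg.eigh(hessian)
    threshold = ZERO_MODE_RELATIVE_THRESHOLD * max(evals[-1], 1e-300)
    nonzero = np.flatnonzero(evals > threshold)
    if len(nonzero) < k:
        raise ValueError(f"requested {k} modes but only {len(nonzero)} "
                         "non-rigid modes exist")
    n_zero = int(nonzero[0])
    sel = nonzero[:k]
    vectors = evecs[:, sel].T.copy()
    for v in vectors:
        if v[np.argmax(np.abs(v))] < 0:
            v *= -1.0
    vectors /= np.linalg.norm(vectors, axis=1, keepdims=True)
    return ModeSet(eigenvalues=evals[sel].copy(), eigenvectors=vectors,
                   n_zero_skipped=n_zero)


def _mode_displacement_field(s: Structure, net: ElasticNetwork,
                             vector: np.ndarray) -> np.ndarray:
    """Per-atom displacement for unit mode amplitude: each atom inherits its
    residue's CA node displacement."""
    node_disp = vector.reshape(-1, 3)
    residue_key = {key: i for i, key in enumerate(net.node_map)}
    disp = np.zeros_like(s.coord)
    for chain, seq, icode, idx in s.iter_residues():
        node = residue_key.get((chain, seq, icode))
        if node is None:
            # residues with no CA node (ligands, pseudo-atoms) ride with the
            # spatially nearest node of their own chain, so they stay attached
            # to their body; chains with no nodes at all do not move
            candidates = [i for i, (c, _, _) in enumerate(net.node_map)
                          if c == chain]
            if not candidates:
                continue
            centroid = s.coord[idx].mean(axis=0)
            node = candidates[int(np.argmin(np.linalg.norm(
                net.node_coords[candidates] - centroid, axis=1)))]
        disp[idx] = node_disp[node]
    return disp


def animate_mode(s: Structure, net: ElasticNetwork, mode_rank: int,
                 n_frames: int = 28, rmsd_max: float = 10.0,
                 modes: ModeSet | None = None,
                 amplitude_profile: str = "sine") -> ConformerEnsemble:
    """One animation cycle of a normal mode within a CA-RMSD budget.

    Frame t (t = 1..n_frames) displaces along the mode by
    ``a_t = A sin(2 pi t / n_frames)`` (or a symmetric linear ramp when
    ``amplitude_profile="linear"``), with A chosen so the largest frame-to-
    parent CA RMSD equals ``rmsd_max`` exactly. For a unit eigenvector the
    CA RMSD at amplitude a is ``|a| / sqrt(N)``, so ``A = rmsd_max sqrt(N)``
    up to the profile's maximum.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if modes is None:
        modes = normal_modes(build_anm(net), mode_rank)
    _, vector = modes.mode(mode_rank)
    if np.linalg.norm(vector) < 1e-12:
        raise ValueError("zero-norm mode vector")
    n_nodes = len(net.node_coords)
    t = np.arange(1, n_frames + 1)
    if amplitude_profile == "sine":
        profile = np.sin(2.0 * np.pi * t / n_frames)
    elif amplitude_profile == "linear":
        profile = 1.0 - np.abs(2.0 * t / n_frames - 1.0)  # 0 -> 1 -> 0 ramp
        profile[t > n_frames // 2] *= -1.0
    else:
        raise ValueError(f"unknown amplitude profile {amplitude_profile!r}")
    peak = np.max(np.abs(profile))
    amplitudes = profile * (rmsd_max * np.sqrt(n_nodes) / peak)
    disp_unit = _mode_displacement_field(s, net, vector)

    ensemble = ConformerEnsemble(parent=s)
    for frame_index, a in zip(t, amplitudes):
        ensemble.append(s.coord + a * disp_unit,
                        FrameInfo(stage="mode", mode_rank=mode_rank,
                                  frame_index=int(frame_index), amplitude=float(a)))
    return ensemble


def combined_mode_scan(s: Structure, secondary_frame_picks=(5, 10, 15, 20, 25),
                       n_frames: int = 28, rmsd_max: float = 10.0,
                       cutoff: float = 15.0, gamma: float = 1.0) -> ConformerEnsemble:
    """Two-mode combination: selected frames of mode 2 reseed a mode-1 scan.

    Mode 2 of the input structure is animated; at each picked frame the
    elastic network is rebuilt on the displaced coordinates, mode 1 is
    recomputed there, and a fresh ``n_frames`` animation is emitted. The
    ensemble holds ``len(picks) x n_frames`` frames with two-stage provenance.
    """
    picks = list(secondary_frame_picks)
    ensemble = ConformerEnsemble(parent=s)
    if not picks:
        return ensemble
    net = ElasticNetwork.from_structure(s, cutoff=cutoff, gamma=gamma)
    stage_a = animate_mode(s, net, mode_rank=2, n_frames=n_frames, rmsd_max=rmsd_max)
    for pick in picks:
        if pick < 1 or pick > len(stage_a):
            raise IndexError(f"frame pick {pick} outside 1..{len(stage_a)}")
        start = s.with_coord(stage_a.frames[pick - 1])
        start_info = stage_a.provenance[pick - 1]
        net_b = ElasticNetwork.from_structure(start, cutoff=cutoff, gamma=gamma)
        stage_b = animate_mode(start, net_b, mode_rank=1, n_frames=n_frames,
                               rmsd_max=rmsd_max)
        for coord, info in zip(stage_b.frames, stage_b.provenance):
            ensemble.append(coord, FrameInfo(
                stage="combined", mode_rank=info.mode_rank,
                frame_index=info.frame_index, amplitude=info.amplitude,
                parent_frame=start_info.to_dict()))
    return ensemble
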