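"""Triage of externally generated ternary poses.

Docking produces many candidate orientations of the target protein around
the E3 ligase; this module filters them by the anchor-distance criterion
(the PROTAC tether bounds how far the target lysine can sit from the E2
catalytic cysteine — about 50 A), groups them by density clustering on
mobile-subunit RMSD, and picks the best-scoring pose that satisfies the
filter. Interface energies are inputs, supplied alongside the poses.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from .assembly import kabsch_fit
from .structure import AtomSet, Structure, select

__all__ = ["PoseSet", "anchor_distance_filter", "cluster_poses",
           "select_candidate", "CandidateSelection"]


@dataclass
class PoseSet:
    """Candidate poses sharing one chain composition.

    ``scores`` are externally supplied interface energies (lower = better).
    ``e3_selection`` names the frame used for superposition (the E3 is held
    fixed while poses vary the target's orientation); ``mobile_selection``
    names the subunit whose RMSD defines pose similarity.
    ``source_indices`` tracks each pose's index in the originally loaded set
    through filtering.
    """

    poses: list[Structure]
    scores: np.ndarray | None = None
    e3_selection: str = "chain A and name CA"
    mobile_selection: str = "chain B and name CA"
    source_indices: np.ndarray | None = None

    def __post_init__(self):
        if not self.poses:
            raise ValueError("PoseSet needs at least one pose")
        n0 = len(self.poses[0])
        for k, p in enumerate(self.poses):
            if len(p) != n0:
                raise ValueError(f"pose {k} has a different atom count")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if len(self.scores) != len(self.poses):
                raise ValueError("scores length must match pose count")
        if self.source_indices is None:
            self.source_indices = np.arange(len(self.poses))
        else:
            self.source_indices = np.asarray(self.source_indices, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.poses)


def anchor_distance_filter(poses: PoseSet, anchor_a: tuple[str, int, str],
                           anchor_b: tuple[str, int, str],
                           max_d: float = 50.0) -> PoseSet:
    """Keep poses whose anchor-atom distance is strictly below ``max_d``.

    Anchors are ``(chain_id, res_seq, atom_name)`` addresses resolved in every
    pose; a pose at exactly ``max_d`` is removed ("less than" is strict).
    Order is preserved.
    """
    keep = []
    for k, pose in enumerate(poses.poses):
        try:
            ia = pose.find_atom(*anchor_a)
            ib = pose.find_atom(*anchor_b)
        except KeyError as exc:
            raise KeyError(f"pose {k}: {exc}") from exc
        if np.linalg.norm(pose.coord[ia] - pose.coord[ib]) < max_d:
            keep.append(k)
    if not keep:
        return _empty_pose_set(poses)
    return PoseSet(
        poses=[poses.poses[k] for k in keep],
        scores=None if poses.scores is None else poses.scores[keep],
        e3_selection=poses.e3_selection,
        mobile_selection=poses.mobile_selection,
        source_indices=poses.source_indices[keep],
    )


def _empty_pose_set(template: PoseSet) -> "PoseSet":
    # PoseSet refuses to be empty; represent an empty filter result explicitly
    empty = PoseSet.__new__(PoseSet)
    empty.poses = []
    empty.scores = (None if template.scores is None
                    else template.scores[:0])
    empty.e3_selection = template.e3_selection
    empty.mobile_selection = template.mobile_selection
    empty.source_indices = np.array([], dtype=np.int64)
    return empty


def pose_rmsd_matrix(poses: PoseSet) -> np.ndarray:
    """Pairwise mobile-subunit CA RMSD after superposing every pose onto the
    first pose's E3 frame."""
    ref = poses.poses[0]
    ref_e3 = select(ref, poses.e3_selection)
    mobiles = []
    for pose in poses.poses:
        e3 = select(pose, poses.e3_selection)
        transform, _ = kabsch_fit(e3, ref_e3)
        mobile = select(pose, poses.mobile_selection)
        mobiles.append(transform.apply(mobile.coord))
    stack = np.asarray(mobiles)  # (P, M, 3)
    diff = stack[:, None, :, :] - stack[None, :, :, :]
    return np.sqrt(np.mean(np.sum(diff ** 2, axis=-1), axis=-1))


def cluster_poses(poses: PoseSet, eps: float, min_pts: int) -> np.ndarray:
    """Density-cluster poses (DBSCAN) on the mobile-subunit RMSD metric.

    Returns one label per pose; -1 marks noise. A core pose has at least
    ``min_pts`` neighbours within ``eps``, itself included.
    """
    if len(poses) == 0:
        return np.array([], dtype=int)
    if eps <= 0:
        return np.full(len(poses), -1, dtype=int)
    matrix = pose_rmsd_matrix(poses)
    labels = DBSCAN(eps=eps, min_samples=min_pts,
                    metric="precomputed").fit_predict(matrix)
    return labels


@dataclass
class CandidateSelection:
    """Outcome of candidate selection, with its justification."""

    found: bool
    pose_index: int | None = None       # index in the original pose set
    score: float | None = None
    anchor_distance: float | None = None
    cluster_label: int | None = None
    reason: str = ""


def select_candidate(poses: PoseSet, filtered: PoseSet,
                     anchor_a: tuple[str, int, str] | None = None,
                     anchor_b: tuple[str, int, str] | None = None,
                     cluster_labels: np.ndarray | None = None
                     ) -> CandidateSelection:
    """Lowest-score pose among those passing the anchor filter.

    Ties break toward the lower original pose index. When no pose passes,
    an explicit no-candidate result is returned, never an exception.
    """
    if poses.scores is None:
        raise ValueError("pose scores are required for candidate selection")
    if len(filtered) == 0:
        return CandidateSelection(found=False, reason="no pose passes the "
                                  "anchor-distance filter")
    scores = filtered.scores
    if scores is None:
        scores = poses.scores[filtered.source_indices]
    order = np.lexsort((filtered.source_indices, scores))
    best_local = int(order[0])
    best_original = int(filtered.source_indices[best_local])
    pose = filtered.poses[best_local]
    anchor_distance = None
    if anchor_a is not None and anchor_b is not None:
        anchor_distance = float(np.linalg.norm(
            pose.coord[pose.find_atom(*anchor_a)]
            - pose.coord[pose.find_atom(*anchor_b)]))
    cluster_label = None
    if cluster_labels is not None:
        cluster_label = int(cluster_labels[best_local])
    return CandidateSelection(
        found=True, pose_index=best_original, score=float(scores[best_local]),
        anchor_distance=anchor_distance, cluster_label=cluster_label,
        reason="lowest interface energy among filter-passing poses")
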