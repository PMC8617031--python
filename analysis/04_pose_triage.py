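"""Pose triage: anchor-distance filter, density clustering, candidate pick.

Loads the pose ensemble from step 01, attaches synthetic interface-energy
scores (in a real run these arrive from the docking package as a sidecar
table), filters poses whose anchor atoms exceed the 50 A tether bound,
clusters the survivors by mobile-chain RMSD, and selects the lowest-energy
filter-passing candidate.

Writes: results/pose_triage.tsv
"""
import glob
import json
import os
import sys

import numpy as np

from bandscan import anchor_distance_filter, cluster_poses, read_structure, select_candidate
from bandscan.pose_triage import PoseSet

HERE = os.path.dirname(__file__)
OUT = os.path.join(HERE, "..", "results")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

paths = sorted(glob.glob(os.path.join(OUT, "poses", "pose_*.pdb")))
poses = PoseSet(poses=[read_structure(p) for p in paths],
                scores=np.random.default_rng(SEED).uniform(-30.0, -10.0,
                                                           len(paths)))
ANCHOR_A = ("A", 1, "CA")
ANCHOR_B = ("B", 1, "CA")

kept = anchor_distance_filter(poses, ANCHOR_A, ANCHOR_B, max_d=50.0)
labels = cluster_poses(kept, eps=4.0, min_pts=3) if len(kept) else np.array([])
choice = select_candidate(poses, kept, ANCHOR_A, ANCHOR_B,
                          cluster_labels=labels if len(kept) else None)

print(f"{len(poses)} poses loaded, {len(kept)} pass the 50 A anchor filter")
if len(kept):
    n_clusters = len(set(labels) - {-1})
    print(f"{n_clusters} clusters, {int(np.sum(labels == -1))} noise poses")
if choice.found:
    print(f"candidate: pose {choice.pose_index}, score {choice.score:.2f}, "
          f"anchor distance {choice.anchor_distance:.1f} A, "
          f"cluster {choice.cluster_label}")
else:
    print("no candidate passes the filter")

with open(os.path.join(OUT, "pose_triage.tsv"), "w") as fh:
    fh.write("pose\tscore\tcluster\tpassed_filter\n")
    kept_set = set(kept.source_indices.tolist())
    cluster_of = dict(zip(kept.source_indices.tolist(),
                          labels.tolist() if len(kept) else []))
    for k in range(len(poses)):
        fh.write(f"{k}\t{poses.scores[k]:.3f}\t{cluster_of.get(k, '')}\t"
                 f"{k in kept_set}\n")
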