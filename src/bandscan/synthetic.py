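"""Synthetic toy complexes with known ground truth.

Real inputs to the band-region pipeline are multi-subunit Cullin-RING ligase
models assembled from crystal structures. For testing, this module builds
miniature stand-ins with the same mechanics: an anchored chain whose last
segment is a rigid "E2-like" body dangling from a flexible hinge loop and
carrying a catalytic probe atom, plus a static target chain with lysines
planted at geometries whose reachable / unreachable / chemically-excluded
labels are known by construction and re-verified at generation time.

All generators are deterministic given their seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import place_atom, rotation_about_axis
from .structure import (IDEAL_BACKBONE, IDEAL_SIDECHAIN, Structure,
                        build_lysine_side_chain)

__all__ = [
    "HingeComplexSpec",
    "make_ideal_chain",
    "make_hinge_complex",
    "make_pose_ensemble",
    "PRESET_TORSIONS",
]

PRESET_TORSIONS = {"extended": (180.0, 180.0), "helix": (-57.0, -47.0)}

# Side-chain build recipes: (atom, element, reference atoms, bond, angle, torsion).
# Extended rotamer throughout (chi = 180); carboxylates are planar (the second
# oxygen sits cis to the first).
_SC = IDEAL_SIDECHAIN
_SIDE_CHAINS: dict[str, list] = {
    "G": [],
    "A": [("CB", "C", ("C", "N", "CA"), _SC["CA-CB"], _SC["N-CA-CB"], _SC["C-N-CA-CB"])],
    "K": None,  # built by build_lysine_side_chain
    "D": [
        ("CB", "C", ("C", "N", "CA"), _SC["CA-CB"], _SC["N-CA-CB"], _SC["C-N-CA-CB"]),
        ("CG", "C", ("N", "CA", "CB"), _SC["C-C"], _SC["C-C-C"], 180.0),
        ("OD1", "O", ("CA", "CB", "CG"), _SC["C-O"], _SC["C-C-O"], 180.0),
        ("OD2", "O", ("CA", "CB", "CG"), _SC["C-O"], _SC["C-C-O"], 0.0),
    ],
    "E": [
        ("CB", "C", ("C", "N", "CA"), _SC["CA-CB"], _SC["N-CA-CB"], _SC["C-N-CA-CB"]),
        ("CG", "C", ("N", "CA", "CB"), _SC["C-C"], _SC["C-C-C"], 180.0),
        ("CD", "C", ("CA", "CB", "CG"), _SC["C-C"], _SC["C-C-C"], 180.0),
        ("OE1", "O", ("CB", "CG", "CD"), _SC["C-O"], _SC["C-C-O"], 180.0),
        ("OE2", "O", ("CB", "CG", "CD"), _SC["C-O"], _SC["C-C-O"], 0.0),
    ],
}
_THREE_LETTER = {"A": "ALA", "G": "GLY", "K": "LYS", "D": "ASP", "E": "GLU"}


def make_ideal_chain(sequence: str, torsions="extended", chain_id: str = "A",
                     start_res: int = 1) -> Structure:
    """Build a peptide with ideal backbone geometry at prescribed torsions.

    ``sequence`` uses one-letter codes from {A, G, K, D, E}. ``torsions`` is a
    preset name (``"extended"``: phi = psi = 180; ``"helix"``: -57/-47) or a
    per-residue list of (phi, psi) pairs; phi of the first residue has no
    upstream peptide bond and is not used. Omega is trans (180) throughout.
    Side chains are built in the extended rotamer.
    """
    if not sequence:
        raise ValueError("empty sequence")
    for letter in sequence:
        if letter not in _THREE_LETTER:
            raise ValueError(f"unsupported residue letter {letter!r}; "
                             f"supported: {sorted(_THREE_LETTER)}")
    n_res = len(sequence)
    if isinstance(torsions, str):
        try:
            phi_psi = [PRESET_TORSIONS[torsions]] * n_res
        except KeyError:
            raise ValueError(f"unknown torsion preset {torsions!r}") from None
    else:
        phi_psi = [tuple(t) for t in torsions]
        if len(phi_psi) != n_res:
            raise ValueError("need one (phi, psi) pair per residue")

    bb = IDEAL_BACKBONE
    # first residue in the xy-plane
    n_pos = np.zeros(3)
    ca_pos = np.array([bb["N-CA"], 0.0, 0.0])
    ang = np.radians(180.0 - bb["N-CA-C"])
    c_pos = ca_pos + bb["CA-C"] * np.array([np.cos(ang), np.sin(ang), 0.0])

    rows: list[tuple[str, str, int, np.ndarray]] = []  # (name, element, res_i, coord)
    for i, letter in enumerate(sequence):
        psi_i = phi_psi[i][1]
        rows.append(("N", "N", i, n_pos))
        rows.append(("CA", "C", i, ca_pos))
        rows.append(("C", "C", i, c_pos))
        rows.append(("O", "O", i, place_atom(n_pos, ca_pos, c_pos,
                                             bb["C-O"], bb["CA-C-O"], psi_i + 180.0)))
        if letter == "K":
            side = build_lysine_side_chain(n_pos, ca_pos, c_pos)
        else:
            side = []
            pos = {"N": n_pos, "CA": ca_pos, "C": c_pos}
            for name, elem, refs, bond, angle, torsion in _SIDE_CHAINS[letter]:
                coord = place_atom(pos[refs[0]], pos[refs[1]], pos[refs[2]],
                                   bond, angle, torsion)
                pos[name] = coord
                side.append((name, elem, coord))
        rows.extend((name, elem, i, coord) for name, elem, coord in side)
        if i + 1 < n_res:
            n_next = place_atom(n_pos, ca_pos, c_pos, bb["C-N"], bb["CA-C-N"], psi_i)
            ca_next = place_atom(ca_pos, c_pos, n_next, bb["N-CA"], bb["C-N-CA"], 180.0)
            c_next = place_atom(c_pos, n_next, ca_next, bb["CA-C"], bb["N-CA-C"],
                                phi_psi[i + 1][0])
            n_pos, ca_pos, c_pos = n_next, ca_next, c_next

    return Structure(
        serial=np.arange(1, len(rows) + 1),
        name=[r[0] for r in rows],
        element=[r[1] for r in rows],
        chain_id=[chain_id] * len(rows),
        res_name=[_THREE_LETTER[sequence[r[2]]] for r in rows],
        res_seq=[start_res + r[2] for r in rows],
        icode=[""] * len(rows),
        coord=np.array([r[3] for r in rows]),
        title=f"ideal chain {sequence}",
    )


# ---------------------------------------------------------------------------
# Hinge complex with planted ground truth
# ---------------------------------------------------------------------------

@dataclass
class HingeComplexSpec:
    """Recipe for a toy hinge complex.

    ``target_sites`` lists the intended labels; placements are derived from
    the construction rules below (reachable sites 5 A from the probe's
    initial position, unreachable sites beyond the hinge's maximal kinematic
    reach plus safety margins, excluded sites reachable but with a glutamate
    carboxylate oxygen planted 3.0 A from the lysine NZ).
    """

    pre_loop_length: int = 8
    loop_length: int = 5
    attached_group_size: int = 8
    probe_offset: tuple[float, float, float] = (6.0, 0.0, 0.0)
    target_sites: tuple[str, ...] = ("in_band", "out_of_band", "excluded")
    seed: int = 0
    reachable_distance: float = 5.0
    contact_threshold: float = 8.0
    margin: float = 2.0
    unreachable_headroom: float = 40.0  # extra slack for scaffold-mode motion
    n_check_draws: int = 200

    def __post_init__(self):
        if self.pre_loop_length < 1 or self.loop_length < 1 or self.attached_group_size < 1:
            raise ValueError("chain segment lengths must be >= 1")
        for label in self.target_sites:
            if label not in ("in_band", "out_of_band", "excluded"):
                raise ValueError(f"unknown intended label {label!r}")


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi), np.cos(phi)])


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    c = float(np.dot(u, v))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate 180 deg about any perpendicular axis
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return rotation_about_axis([0, 0, 0], perp, 180.0)[0]
    axis = axis / s
    return rotation_about_axis([0, 0, 0], axis, np.degrees(np.arctan2(s, c)))[0]


def _place_residue(letter: str, anchor_atom: str, target: np.ndarray,
                   direction: np.ndarray, chain_id: str, res_seq: int) -> Structure:
    """Build one ideal residue and rigidly pose it: ``anchor_atom`` lands on
    ``target`` with the residue body extending along ``direction``."""
    res = make_ideal_chain(letter, "extended", chain_id=chain_id, start_res=res_seq)
    anchor = res.coord[res.name == anchor_atom][0]
    body = res.coord[res.name == "CA"][0] - anchor
    R = _rotation_between(body, direction)
    coord = (res.coord - anchor) @ R.T + target
    return res.with_coord(coord)


def make_hinge_complex(spec: HingeComplexSpec) -> tuple[Structure, dict]:
    """Build the toy complex and its ground-truth labels.

    Returns ``(structure, truth)`` where ``truth`` carries one entry per site
    (label, chain, res_seq, intended verdict) plus the loop definition and
    probe-atom address needed to run the pipeline, and the kinematic reach
    bound used to certify unreachable placements.
    """
    rng = np.random.default_rng(spec.seed)
    pre, loop, att = spec.pre_loop_length, spec.loop_length, spec.attached_group_size
    n_res = pre + loop + att
    torsions = ([PRESET_TORSIONS["helix"]] * pre
                + [PRESET_TORSIONS["extended"]] * loop
                + [PRESET_TORSIONS["helix"]] * att)
    chain = make_ideal_chain("A" * n_res, torsions, chain_id="H", start_res=1)

    loop_start, loop_end = pre + 1, pre + loop
    pivot = chain.coord[chain.find_atom("H", loop_start, "CA")]

    # probe pseudo-atom, rigid with the attached group
    last_ca = chain.coord[chain.find_atom("H", n_res, "CA")]
    sg_pos = last_ca + np.asarray(spec.probe_offset, dtype=float)
    probe_seq = n_res + 1
    structure = _concat(chain, Structure(
        serial=[0], name=["SG"], element=["S"], chain_id=["H"], res_name=["PRB"],
        res_seq=[probe_seq], icode=[""], coord=sg_pos[None], is_hetero=[True]))

    # kinematic reach bound: backbone path length pivot -> loop end, plus the
    # rigid radius of the attached body about the loop's last carbonyl carbon
    reach = _kinematic_reach(structure, "H", loop_start, loop_end)

    h_coords = structure.coord
    centroid = h_coords.mean(axis=0)
    out_dir_bias = sg_pos - centroid
    out_dir_bias /= np.linalg.norm(out_dir_bias)

    directions = _fibonacci_sphere(64)
    rng.shuffle(directions)

    sites = []
    parts = [structure]
    placed_coords = [h_coords]
    placed_nz: list[np.ndarray] = []
    placed_carbox: list[np.ndarray] = []
    next_seq = 101
    for intended in spec.target_sites:
        placement_ok = False
        for d in directions:
            if intended in ("in_band", "excluded"):
                if np.dot(d, out_dir_bias) < 0.3:  # keep reachable sites probe-side
                    continue
                nz_target = sg_pos + spec.reachable_distance * d
            else:
                nz_target = pivot + (reach + spec.contact_threshold + spec.margin
                                     + spec.unreachable_headroom) * d
            lys = _place_residue("K", "NZ", nz_target, d, "P", next_seq)
            group = [lys]
            new_carbox = []
            if intended == "excluded":
                e_dir = _any_perpendicular(d, rng)
                oe_target = nz_target + 3.0 * e_dir
                glu = _place_residue("E", "OE1", oe_target, e_dir, "P", next_seq + 1)
                group.append(glu)
                new_carbox = [glu.coord[i] for i in np.flatnonzero(
                    np.isin(glu.name, ["OE1", "OE2"]))]
            # keep carboxylates out of salt-bridge range of every *other*
            # lysine, or planted exclusion labels would bleed across sites
            cross_ok = all(np.linalg.norm(nz_target - o) > 4.5
                           for o in placed_carbox)
            cross_ok &= all(np.linalg.norm(o - nz) > 4.5
                            for o in new_carbox for nz in placed_nz)
            if cross_ok and _clear_of(group, placed_coords, min_dist=3.5):
                parts.extend(group)
                placed_coords.extend(g.coord for g in group)
                placed_nz.append(nz_target)
                placed_carbox.extend(new_carbox)
                sites.append({"label": f"K{next_seq}", "chain_id": "P",
                              "res_seq": next_seq, "intended": intended,
                              "nz": nz_target})
                next_seq += 10
                placement_ok = True
                break
        if not placement_ok:
            raise ValueError(f"could not place a {intended} site consistent with "
                             "its intended label")

    full = _concat(*parts)
    full.serial = np.arange(1, len(full) + 1)
    truth = {
        "sites": sites,
        "loop": {"chain_id": "H", "res_range": (loop_start, loop_end),
                 "attached_selection": f"chain H and resseq {loop_end + 1}-{probe_seq}"},
        "cys_sg": {"chain_id": "H", "res_seq": probe_seq, "name": "SG"},
        "poi_selection": "chain P",
        "kinematic_reach": reach,
        "contact_threshold": spec.contact_threshold,
        "seed": spec.seed,
    }
    _verify_ground_truth(full, truth, spec)
    return full, truth


def _concat(*parts: Structure) -> Structure:
    fields = {f: np.concatenate([getattr(p, f) for p in parts])
              for f in Structure._FIELDS}
    coord = np.concatenate([p.coord for p in parts])
    return Structure(coord=coord, title=parts[0].title, **fields)


def _any_perpendicular(d: np.ndarray, rng) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        v -= np.dot(v, d) * d
        n = np.linalg.norm(v)
        if n > 1e-6:
            return v / n


def _clear_of(group: list[Structure], placed: list[np.ndarray],
              min_dist: float) -> bool:
    new = np.concatenate([g.coord for g in group])
    for other in placed:
        dmin = np.min(np.linalg.norm(new[:, None, :] - other[None, :, :], axis=-1))
        if dmin < min_dist:
            return False
    return True


def _kinematic_reach(s: Structure, chain_id: str, loop_start: int,
                     loop_end: int) -> float:
    """Upper bound on |moving atom - pivot CA| over all hinge conformations."""
    path = 0.0
    prev = s.coord[s.find_atom(chain_id, loop_start, "CA")]
    for seq in range(loop_start, loop_end + 1):
        for name in ("CA", "C") if seq == loop_start else ("N", "CA", "C"):
            cur = s.coord[s.find_atom(chain_id, seq, name)]
            path += float(np.linalg.norm(cur - prev))
            prev = cur
    anchor = prev  # loop-end carbonyl carbon
    downstream = (s.chain_id == chain_id) & (s.res_seq > loop_end)
    radius = float(np.max(np.linalg.norm(s.coord[downstream] - anchor, axis=1))) \
        if np.any(downstream) else 0.0
    return path + radius


# -- generation-time verification -------------------------------------------------

def _verify_ground_truth(s: Structure, truth: dict, spec: HingeComplexSpec) -> None:
    """Certify planted labels with an independent coarse conformational scan.

    Reachable sites must be in contact (threshold minus margin) and clash-free
    in the starting conformation; unreachable sites must stay beyond threshold
    plus margin across random hinge conformations and, more strongly, beyond
    the kinematic reach bound. Excluded sites must carry their planted
    carboxylate partner.
    """
    threshold, margin = spec.contact_threshold, spec.margin
    sg_idx = s.find_atom(**truth["cys_sg"])
    lo, hi = truth["loop"]["res_range"]
    moving = (s.chain_id == "H") & (s.res_seq > lo)  # C-side of the first phi axis
    poi = s.chain_id == "P"
    # clash-freedom of the start conformation (moving body vs target chain)
    d0 = np.linalg.norm(s.coord[moving][:, None, :] - s.coord[poi][None, :, :], axis=-1)
    if d0.min() < 3.0:
        raise ValueError("generated start conformation has steric overlap")

    sg_samples = _coarse_hinge_scan(s, lo, hi, sg_idx, spec.n_check_draws, spec.seed)
    for site in truth["sites"]:
        nz = s.coord[s.find_atom(site["chain_id"], site["res_seq"], "NZ")]
        start_dist = float(np.linalg.norm(s.coord[sg_idx] - nz))
        if site["intended"] in ("in_band", "excluded"):
            if start_dist > threshold - margin:
                raise ValueError(f"site {site['label']} intended reachable but "
                                 f"start distance is {start_dist:.1f} A")
        else:
            pivot = s.coord[s.find_atom("H", lo, "CA")]
            if np.linalg.norm(nz - pivot) - truth["kinematic_reach"] < threshold + margin:
                raise ValueError(f"site {site['label']} intended unreachable but "
                                 "lies within kinematic reach of the probe")
            scan_min = float(np.min(np.linalg.norm(sg_samples - nz, axis=1)))
            if scan_min <= threshold + margin:
                raise ValueError(f"site {site['label']} reached in the scan "
                                 f"({scan_min:.1f} A); placement inconsistent")
        carbox = (s.chain_id == "P") & np.isin(s.name, ["OE1", "OE2", "OD1", "OD2"])
        if site["intended"] == "excluded":
            dmin = float(np.min(np.linalg.norm(s.coord[carbox] - nz, axis=1)))
            if dmin > 4.0:
                raise ValueError(f"site {site['label']} intended excluded but no "
                                 "carboxylate oxygen within salt-bridge range")
        elif np.any(carbox):
            dmin = float(np.min(np.linalg.norm(s.coord[carbox] - nz, axis=1)))
            if dmin <= 4.0:
                raise ValueError(f"site {site['label']} not intended excluded "
                                 "but a carboxylate oxygen sits in salt-bridge "
                                 "range of its NZ")


def _coarse_hinge_scan(s: Structure, loop_start: int, loop_end: int,
                       probe_idx: int, n_draws: int, seed: int) -> np.ndarray:
    """Probe positions under random loop torsions; direct sequential rotation,
    independent of the sampling module."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0A5]))
    chain_mask = s.chain_id == s.chain_id[probe_idx]
    samples = [s.coord[probe_idx].copy()]
    axes = []
    for seq in range(loop_start, loop_end + 1):
        n_i = s.find_atom("H", seq, "N")
        ca_i = s.find_atom("H", seq, "CA")
        c_i = s.find_atom("H", seq, "C")
        moving_phi = chain_mask & (
            (s.res_seq > seq) | ((s.res_seq == seq) & ~np.isin(s.name, ["N", "CA"])))
        moving_psi = chain_mask & (
            (s.res_seq > seq) | ((s.res_seq == seq) & np.isin(s.name, ["O", "OXT"])))
        axes.append((n_i, ca_i, np.flatnonzero(moving_phi)))
        axes.append((ca_i, c_i, np.flatnonzero(moving_psi)))
    for _ in range(n_draws):
        coord = s.coord.copy()
        for a_idx, b_idx, moving in axes:
            angle = rng.uniform(-180.0, 180.0)
            R, t = rotation_about_axis(coord[a_idx], coord[b_idx] - coord[a_idx], angle)
            coord[moving] = coord[moving] @ R.T + t
        samples.append(coord[probe_idx].copy())
    return np.asarray(samples)


# ---------------------------------------------------------------------------
# Pose ensembles for triage tests
# ---------------------------------------------------------------------------

def make_pose_ensemble(n_clusters: int, poses_per_cluster: int,
                       intra_noise: float, inter_separation: float,
                       seed: int = 0):
    """Ternary-pose stand-ins: a fixed E3 chain and a mobile target chain
    translated to ``n_clusters`` well-separated centers with isotropic
    positional noise. Returns ``(PoseSet, true_labels)``.

    Pure translations are used so that every pairwise mobile-chain RMSD
    equals the corresponding translation distance exactly.
    """
    from .pose_triage import PoseSet  # local import to avoid a cycle

    if intra_noise > 0 and inter_separation <= 4 * intra_noise:
        raise ValueError("inter_separation must exceed 4 x intra_noise")
    rng = np.random.default_rng(seed)
    e3 = make_ideal_chain("A" * 10, "helix", chain_id="A", start_res=1)
    mobile = make_ideal_chain("A" * 8, "helix", chain_id="B", start_res=1)
    mobile = mobile.with_coord(mobile.coord + np.array([20.0, 0.0, 0.0]))
    base = _concat(e3, mobile)
    base.serial = np.arange(1, len(base) + 1)

    centers = [k * inter_separation * np.array([1.0, 0.0, 0.0])
               for k in range(n_clusters)]
    poses, labels = [], []
    mobile_mask = base.chain_id == "B"
    for k, center in enumerate(centers):
        for _ in range(poses_per_cluster):
            offset = center
            if intra_noise > 0:
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                offset = center + rng.uniform(0.0, intra_noise) * v
            coord = base.coord.copy()
            coord[mobile_mask] += offset
            poses.append(base.with_coord(coord))
            labels.append(k)
    return (PoseSet(poses=poses, scores=None,
                    e3_selection="chain A and name CA",
                    mobile_selection="chain B and name CA"),
            np.asarray(labels))
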