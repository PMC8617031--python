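"""Low-level vector geometry: torsions, axis rotations, internal-coordinate atom placement.

All angles are degrees at the API surface (the PDB world speaks degrees);
radians internally. Coordinates are Cartesian, in Angstrom.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral_angle",
    "dihedral_angle_batch",
    "rotation_about_axis",
    "rotate_about_axis_batch",
    "axis_rotation_matrices",
    "place_atom",
    "wrap_angle_deg",
]


def wrap_angle_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap an angle in degrees into the half-open interval [-180, 180)."""
    return (np.asarray(angle) + 180.0) % 360.0 - 180.0


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed torsion p0-p1-p2-p3 in degrees, IUPAC sign convention, in [-180, 180).

    Zero for cis (p0 and p3 eclipsed), positive for clockwise rotation of the
    far bond when sighting down p1->p2.
    """
    return float(
        dihedral_angle_batch(
            np.asarray(p0, dtype=float)[None],
            np.asarray(p1, dtype=float)[None],
            np.asarray(p2, dtype=float)[None],
            np.asarray(p3, dtype=float)[None],
        )[0]
    )


def dihedral_angle_batch(p0, p1, p2, p3) -> np.ndarray:
    """Vectorized signed torsion for stacked points of shape (..., 3). Degrees."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(n1, b1n)
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    return wrap_angle_deg(ang)


def rotation_about_axis(axis_point, axis_dir, angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotation by ``angle_deg`` about the line through ``axis_point`` along ``axis_dir``.

    Returns ``(R, t)`` such that the image of x is ``R @ x + t``.
    """
    k = np.asarray(axis_dir, dtype=float)
    nrm = np.linalg.norm(k)
    if nrm < 1e-12:
        raise ValueError("rotation axis has zero length")
    k = k / nrm
    theta = np.radians(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)
    p = np.asarray(axis_point, dtype=float)
    t = p - R @ p
    return R, t


def rotate_about_axis_batch(points, axis_point, axis_dir, angle_deg) -> np.ndarray:
    """Rodrigues rotation of ``points`` (B, M, 3) about per-batch axes.

    ``axis_point``/``axis_dir``: (B, 3); ``angle_deg``: (B,). Returns (B, M, 3).
    """
    k = np.asarray(axis_dir, dtype=float)
    k = k / np.linalg.norm(k, axis=-1, keepdims=True)
    theta = np.radians(np.asarray(angle_deg, dtype=float))[:, None, None]
    p = np.asarray(points, dtype=float) - axis_point[:, None, :]
    kx = np.cross(np.broadcast_to(k[:, None, :], p.shape), p)
    kdp = np.einsum("bj,bmj->bm", k, p)[:, :, None]
    rotated = (
        p * np.cos(theta)
        + kx * np.sin(theta)
        + k[:, None, :] * kdp * (1.0 - np.cos(theta))
    )
    return rotated + axis_point[:, None, :]


def axis_rotation_matrices(axis_dir: np.ndarray, angle_deg: np.ndarray) -> np.ndarray:
    """Batched Rodrigues rotation matrices about per-batch axes.

    ``axis_dir``: (B, 3) (not necessarily unit); ``angle_deg``: (B,).
    Returns (B, 3, 3).
    """
    k = np.asarray(axis_dir, dtype=float)
    k = k / np.linalg.norm(k, axis=-1, keepdims=True)
    theta = np.radians(np.asarray(angle_deg, dtype=float))
    c = np.cos(theta)[:, None, None]
    s = np.sin(theta)[:, None, None]
    B = len(k)
    K = np.zeros((B, 3, 3))
    K[:, 0, 1] = -k[:, 2]; K[:, 0, 2] = k[:, 1]
    K[:, 1, 0] = k[:, 2];  K[:, 1, 2] = -k[:, 0]
    K[:, 2, 0] = -k[:, 1]; K[:, 2, 1] = k[:, 0]
    return np.eye(3) + s * K + (1.0 - c) * np.einsum("bij,bjk->bik", K, K)


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d from internal coordinates relative to reference atoms a, b, c.

    ``bond`` = |c-d|, ``angle_deg`` = angle(b, c, d), ``torsion_deg`` = torsion(a, b, c, d).
    The natural extension reference frame (NeRF) construction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    # the -sin(chi) z-component makes the measured (IUPAC) torsion equal the
    # requested one in the right-handed frame built below
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(chi),
            -bond * np.sin(theta) * np.sin(chi),
        ]
    )
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms in place_atom")
    n = n / nn
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local
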