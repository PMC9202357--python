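"""Small geometry primitives: internal-coordinate atom placement, torsions,
and Kabsch superposition.

All coordinates are in Ångström, all angles in degrees at the API surface
(radians internally where noted).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "place_atom",
    "bond_angle",
    "dihedral",
    "kabsch_rotation",
    "superpose",
    "rmsd_after_superposition",
    "rotate_about_axis",
]


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D given atoms A, B, C (NeRF construction).

    D is at distance ``bond`` from C, with angle B-C-D equal to ``angle``
    (degrees) and dihedral A-B-C-D equal to ``torsion`` (degrees).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    theta = np.deg2rad(angle)
    phi = np.deg2rad(torsion)

    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)

    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(phi),
        bond * np.sin(theta) * np.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def bond_angle(a, b, c) -> float:
    """Angle A-B-C in degrees."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(a, b, c, d) -> float:
    """Signed dihedral A-B-C-D in degrees, in (-180, 180]."""
    b0 = np.asarray(a, float) - np.asarray(b, float)
    b1 = np.asarray(c, float) - np.asarray(b, float)
    b2 = np.asarray(d, float) - np.asarray(c, float)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = float(np.rad2deg(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix mapping centred ``p`` onto centred ``q``.

    Proper rotation only (determinant +1); inputs must already be centred.
    """
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares superposition of ``mobile`` onto ``target``.

    Returns ``(transformed_mobile, rotation, translation)`` such that
    ``transformed = mobile @ R.T + t``.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    r = kabsch_rotation(mobile - mc, target - tc)
    t = tc - mc @ r.T
    return mobile @ r.T + t, r, t


def rmsd_after_superposition(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal RMSD between two coordinate sets over rigid motions."""
    if a.shape != b.shape:
        raise ValueError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    fitted, _, _ = superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((fitted - b) ** 2, axis=1))))


def rotate_about_axis(coords: np.ndarray, origin: np.ndarray,
                      axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate coordinates about an arbitrary axis through ``origin``."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    theta = np.deg2rad(angle_deg)
    k = axis
    v = coords - origin
    # Rodrigues' formula, vectorised
    rotated = (v * np.cos(theta)
               + np.cross(k, v) * np.sin(theta)
               + np.outer(v @ k, k) * (1.0 - np.cos(theta)))
    return rotated + origin
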