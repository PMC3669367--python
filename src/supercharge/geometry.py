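"""Small 3-D geometry helpers: internal-coordinate atom placement and dihedrals.

All angles are in degrees, all distances in Angstrom.
"""

from __future__ import annotations

import numpy as np

Vec = np.ndarray


def normalize(v: Vec) -> Vec:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize zero vector")
    return v / n


def bond_angle(a: Vec, b: Vec, c: Vec) -> float:
    """Angle a-b-c in degrees."""
    u, w = normalize(a - b), normalize(c - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def dihedral(a: Vec, b: Vec, c: Vec, d: Vec) -> float:
    """Signed torsion a-b-c-d in degrees, in (-180, 180]."""
    b0, b1, b2 = a - b, c - b, d - c
    b1n = normalize(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a: Vec, b: Vec, c: Vec, bond: float, angle: float, torsion: float) -> Vec:
    """Place atom D so that |c-D| = bond, angle(b,c,D) = angle, torsion(a,b,c,D) = torsion.

    Standard natural-extension (NeRF) construction.
    """
    theta = np.radians(angle)
    phi = np.radians(torsion)
    bc = normalize(c - b)
    n = normalize(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(phi),
            bond * np.sin(theta) * np.sin(phi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def random_rigid_transform(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random rotation matrix and a translation vector."""
    # QR of a Gaussian matrix gives a Haar-random orthogonal matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=20.0, size=3)
    return q, t


def angular_difference(a: float, b: float) -> float:
    """Smallest absolute difference between two angles in degrees."""
    d = (a - b) % 360.0
    return min(d, 360.0 - d)
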