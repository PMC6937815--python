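"""Low-level 3D geometry: internal-coordinate atom placement and dihedrals.

Everything works in Angstroms and degrees. The placement routine is the
standard NeRF construction (natural extension of reference frame): given
three placed atoms a-b-c and the internal coordinates (bond length c-d,
bond angle b-c-d, torsion a-b-c-d), it returns the position of d such that
``dihedral(a, b, c, d)`` equals the requested torsion exactly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["place_atom", "dihedral", "angular_difference", "rmsda"]


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Place a fourth atom from three reference atoms and internal coordinates.

    Parameters
    ----------
    a, b, c : (3,) arrays
        Previously placed atoms; the new atom bonds to ``c``.
    bond : float
        c-d distance in A.
    angle : float
        b-c-d angle in degrees.
    torsion : float
        a-b-c-d dihedral in degrees (IUPAC sign convention).
    """
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-9:  # collinear reference frame: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        norm = np.linalg.norm(n)
    n = n / norm
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(ang),
            bond * np.cos(tor) * np.sin(ang),
            bond * np.sin(tor) * np.sin(ang),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1  # points away from the axis, IUPAC sign convention
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def angular_difference(a, b):
    """Smallest absolute difference between two angles in degrees (vectorised)."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)


def rmsda(a, b) -> float:
    """Root-mean-square deviation between two angle vectors with wrap-around.

    NaN entries in either vector are ignored (incomplete windows); returns
    inf if no angle pair is comparable.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mask = ~(np.isnan(a) | np.isnan(b))
    if not mask.any():
        return float("inf")
    d = angular_difference(a[mask], b[mask])
    return float(np.sqrt(np.mean(d**2)))
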