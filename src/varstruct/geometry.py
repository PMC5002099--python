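"""Internal-coordinate geometry: atom placement and torsion measurement.

``place_atom`` is the standard NeRF construction: given three reference
positions A, B, C it places D at the stated bond length |CD|, bond angle
B-C-D and torsion A-B-C-D.  Angles are in degrees throughout.
"""

from __future__ import annotations

import numpy as np


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("zero-length vector in geometry construction")
    return v / n


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Place atom D from references A, B, C (NeRF construction)."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = _unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = _unit(a - b)
    v = _unit(c - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
             bond: float = 1.53, angle_deg: float = 110.5,
             improper_deg: float = -120.0) -> np.ndarray:
    """Place a CB from backbone N, CA, C with L-amino-acid chirality.

    Uses the improper torsion C-N-CA-CB (about -120 deg for L residues, as in
    ideal residue geometry) with bond angle N-CA-CB.
    """
    return place_atom(c, n, ca, bond, angle_deg, improper_deg)
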