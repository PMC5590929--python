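"""Low-level peptide geometry: internal-coordinate atom placement and dihedrals.

Bond lengths and angles are standard Engh–Huber values for a trans peptide.
All angles at this level are in radians unless a name says degrees.
"""

from __future__ import annotations

import numpy as np

# Engh & Huber ideal backbone geometry (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521

ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_C_CA_CB = 110.1
TORSION_N_C_CA_CB = -122.6  # L-amino-acid branch convention
OMEGA_TRANS = 180.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D bonded to *c* given bond length, angle b-c-D and torsion a-b-c-D."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def build_backbone(phi_psi_deg: np.ndarray) -> dict[str, np.ndarray]:
    """Build an ideal-geometry backbone from per-residue (phi, psi) in degrees.

    Returns arrays of shape (n, 3) for N, CA, C, O and CB.  phi of the first
    residue is unused (no preceding carbonyl); psi of the last residue only
    orients its carbonyl oxygen.  The peptide bond is ideally trans.
    """
    pp = np.asarray(phi_psi_deg, dtype=float)
    n_res = pp.shape[0]
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))
    CB = np.zeros((n_res, 3))

    ang = np.deg2rad(ANGLE_N_CA_C)
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(n_res):
        if i > 0:
            C[i] = place_atom(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, pp[i, 0])
        if i < n_res - 1:
            N[i + 1] = place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, pp[i, 1])
            CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA,
                                   OMEGA_TRANS)
        O[i] = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, pp[i, 1] - 180.0)
        CB[i] = place_atom(N[i], C[i], CA[i], BOND_CA_CB, ANGLE_C_CA_CB,
                           TORSION_N_C_CA_CB)
    return {"N": N, "CA": CA, "C": C, "O": O, "CB": CB}


def phi_psi_from_backbone(N: np.ndarray, CA: np.ndarray, C: np.ndarray
                          ) -> np.ndarray:
    """Per-residue (phi, psi) in degrees; NaN where undefined (chain termini)."""
    n_res = len(N)
    out = np.full((n_res, 2), np.nan)
    for i in range(n_res):
        if i > 0:
            out[i, 0] = dihedral(C[i - 1], N[i], CA[i], C[i])
        if i < n_res - 1:
            out[i, 1] = dihedral(N[i], CA[i], C[i], N[i + 1])
    return out
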