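"""Backbone geometry primitives: NeRF atom placement, dihedrals, strand axes.

Standard backbone internal coordinates (Engh & Huber values) are used when
building idealized chains: N-CA 1.458 Å, CA-C 1.525 Å, C-N 1.329 Å,
C=O 1.231 Å.
"""

from __future__ import annotations

import numpy as np

# bond lengths (Å)
N_CA = 1.458
CA_C = 1.525
C_N = 1.329
C_O = 1.231
# bond angles (degrees)
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Place atom D given A-B-C, |C-D|, angle(B,C,D) and torsion(A,B,C,D)."""
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
        -bond * np.sin(angle) * np.cos(torsion),
        -bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def build_backbone(
    phi: np.ndarray, psi: np.ndarray, omega: np.ndarray | None = None
) -> list[dict[str, np.ndarray]]:
    """Build an n-residue backbone (N, CA, C, O) from dihedral arrays.

    ``phi[0]`` and the trailing ``psi``/``omega`` values past the last peptide
    bond are ignored by construction. Returns one atom dict per residue.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n = len(phi)
    if len(psi) != n:
        raise ValueError("phi and psi must have equal length")
    if omega is None:
        omega = np.full(n, 180.0)
    residues: list[dict[str, np.ndarray]] = []

    # seed first three atoms in a canonical frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([N_CA, 0.0, 0.0])
    c0 = place_atom(
        np.array([0.0, 1.0, 0.0]), n0, ca0, CA_C, ANGLE_N_CA_C, 0.0
    )
    residues.append({"N": n0, "CA": ca0, "C": c0})

    for i in range(1, n):
        prev = residues[-1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], C_N, ANGLE_CA_C_N, psi[i - 1])
        ca_i = place_atom(prev["CA"], prev["C"], n_i, N_CA, ANGLE_C_N_CA, omega[i - 1])
        c_i = place_atom(prev["C"], n_i, ca_i, CA_C, ANGLE_N_CA_C, phi[i])
        # carbonyl O of residue i-1: trans to N(i) across the C(i-1) sp2 plane
        prev["O"] = place_atom(ca_i, n_i, prev["C"], C_O, ANGLE_CA_C_O, 180.0)
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})

    # last residue: place O trans to an implied psi of 135 deg
    last = residues[-1]
    virtual_n = place_atom(last["N"], last["CA"], last["C"], C_N, ANGLE_CA_C_N, 135.0)
    last["O"] = place_atom(last["CA"], virtual_n, last["C"], C_O, ANGLE_CA_C_O, 180.0)
    return residues


def measure_dihedrals(residues: list[dict[str, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    """Recompute (phi, psi) from coordinates; NaN where undefined."""
    n = len(residues)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    for i in range(n):
        r = residues[i]
        if i > 0:
            p = residues[i - 1]
            phi[i] = dihedral(p["C"], r["N"], r["CA"], r["C"])
        if i < n - 1:
            nxt = residues[i + 1]
            psi[i] = dihedral(r["N"], r["CA"], r["C"], nxt["N"])
    return phi, psi


def strand_axis(ca_coords: np.ndarray) -> np.ndarray:
    """Least-squares direction of a strand's CA trace (unit vector)."""
    ca = np.asarray(ca_coords, dtype=float)
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    # orient along the chain
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis


def axis_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two axis vectors in degrees (0-180)."""
    c = np.clip(
        np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0
    )
    return float(np.degrees(np.arccos(c)))
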