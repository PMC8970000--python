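"""Rigid-body superposition, dihedral math and internal-coordinate atom
placement.

These primitives back the chain-growth merge step (Kabsch superposition of
junction backbones), the forward models (amide-H reconstruction, phi
dihedrals) and the synthetic backbone builder (NeRF placement).
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "kabsch_rotation",
    "superpose",
    "superposed_rmsd",
    "dihedral",
    "bond_angle",
    "place_atom",
]


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rotation matrices mapping ``mobile`` onto ``target``.

    Both arrays have shape (..., m, 3); broadcasting over leading batch
    dimensions is supported.  Returns ``(R, mobile_centroid,
    target_centroid)`` such that ``(x - mobile_centroid) @ R +
    target_centroid`` optimally superposes the mobile points (proper
    rotations only; reflections are corrected).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(f"shape mismatch: {mobile.shape} vs {target.shape}")
    cm = mobile.mean(axis=-2, keepdims=True)
    ct = target.mean(axis=-2, keepdims=True)
    p = mobile - cm
    q = target - ct
    h = np.einsum("...mi,...mj->...ij", p, q)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("...ij,...jk->...ik", u, vt)))
    u = u.copy()
    u[..., :, 2] *= d[..., None]
    r = np.einsum("...ij,...jk->...ik", u, vt)
    return r, cm, ct


def superpose(mobile_fit: np.ndarray, target_fit: np.ndarray, mobile_all: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Superpose ``mobile_fit`` onto ``target_fit`` and apply the same
    transform to ``mobile_all``.

    Returns ``(transformed_all, rmsd)`` where ``rmsd`` is the fit RMSD over
    the fitted atoms.  Batched over leading dimensions.
    """
    r, cm, ct = kabsch_rotation(mobile_fit, target_fit)
    fit = np.einsum("...mi,...ij->...mj", mobile_fit - cm, r) + ct
    rmsd = np.sqrt(np.mean(np.sum((fit - target_fit) ** 2, axis=-1), axis=-1))
    moved = np.einsum("...mi,...ij->...mj", mobile_all - cm, r) + ct
    return moved, rmsd


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float | np.ndarray:
    """RMSD after optimal rigid superposition of ``a`` onto ``b``.

    Symmetric in its arguments.  Batched over leading dimensions.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[-2] < 3:
        raise ValueError("need at least 3 atoms for a superposition")
    _, rmsd = superpose(a, b, a)
    return float(rmsd) if np.ndim(rmsd) == 0 else rmsd


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angle in degrees for points of shape (..., 3).

    Uses the IUPAC sign convention (cis = 0, trans = +/-180).
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.degrees(np.arctan2(y, x))


def bond_angle(p0, p1, p2) -> np.ndarray:
    """Bond angle at ``p1`` in degrees."""
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    v1 = p0 - p1
    v2 = p2 - p1
    cosang = np.sum(v1 * v2, axis=-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, dihed: float) -> np.ndarray:
    """Place atom D given atoms A, B, C and internal coordinates.

    ``bond`` is the C-D distance (Angstrom), ``angle`` the B-C-D bond angle
    and ``dihed`` the A-B-C-D dihedral, both in degrees (NeRF placement).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(dihed)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            -bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
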