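"""Rigid-body geometry helpers: Kabsch superposition and axis rotations."""

from __future__ import annotations

import numpy as np


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t minimizing ||(P @ R + t) - Q||.

    Returns (R, t, rmsd). Reflections are excluded (det R = +1), so a mirror
    image does not superpose onto its original through this path.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    pc, qc = P.mean(0), Q.mean(0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    t = qc - pc @ R
    diff = P @ R + t - Q
    rmsd = float(np.sqrt((diff * diff).sum() / len(P)))
    return R, t, rmsd


def superpose(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """P rigidly moved onto Q (proper rotation + translation)."""
    R, t, _ = kabsch(P, Q)
    return P @ R + t


def superposition_rmsd(P: np.ndarray, Q: np.ndarray, allow_mirror: bool = False) -> float:
    """Best-fit RMSD after proper superposition; optionally also try the mirror image."""
    _, _, rmsd = kabsch(P, Q)
    if allow_mirror:
        Pm = P.copy()
        Pm[:, 0] *= -1.0
        _, _, rm = kabsch(Pm, Q)
        rmsd = min(rmsd, rm)
    return rmsd


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis by ``angle`` radians."""
    a = np.asarray(axis, float)
    n = np.linalg.norm(a)
    if n < 1e-12:
        return np.eye(3)
    x, y, z = a / n
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def any_perpendicular(v: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to v."""
    v = np.asarray(v, float)
    probe = np.array([1.0, 0.0, 0.0]) if abs(v[0]) <= min(abs(v[1]), abs(v[2])) + 1e-12 \
        else (np.array([0.0, 1.0, 0.0]) if abs(v[1]) <= abs(v[2]) else np.array([0.0, 0.0, 1.0]))
    p = np.cross(v, probe)
    n = np.linalg.norm(p)
    if n < 1e-12:
        p = np.cross(v, np.array([0.0, 1.0, 0.0]))
        n = np.linalg.norm(p)
    return p / n
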