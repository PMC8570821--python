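"""Rigid-body superposition primitives (Kabsch) shared across modules."""

from __future__ import annotations

import numpy as np

from .errors import GeometryError


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation aligning centered ``mobile`` onto ``reference``.

    Both inputs are (n, 3) and assumed already centered.  The determinant of
    the returned matrix is +1 (reflections are disallowed).
    """
    cov = mobile.T @ reference
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, 1.0, d])
    return (u @ flip @ vt).T


def superpose_onto(
    mobile: np.ndarray, reference: np.ndarray, check_collinear: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Least-squares fit of ``mobile`` onto ``reference`` (both (n, 3)).

    Returns (rotation, mobile centroid, reference centroid, rmsd).  Apply as
    ``(x - mobile_centroid) @ R.T + reference_centroid``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("superposition inputs must be matching (n, 3) arrays")
    if len(mobile) < 3:
        raise GeometryError("superposition needs at least 3 atoms")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    a = mobile - cm
    b = reference - cr
    if check_collinear:
        for mat in (a, b):
            s = np.linalg.svd(mat, compute_uv=False)
            if s[0] == 0 or s[1] / s[0] < 1e-10:
                raise GeometryError("selection is (near-)collinear; fit is ill-posed")
    rot = kabsch_rotation(a, b)
    moved = a @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return rot, cm, cr, rmsd


def rmsd_after_superposition(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two (n, 3) coordinate sets over rigid motions."""
    _, _, _, value = superpose_onto(a, b, check_collinear=False)
    return value
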