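"""Rigid-body superposition utilities (Kabsch algorithm).

The optimal rotation minimising the least-squares deviation between two
point sets is obtained from the SVD of the covariance matrix, with a
determinant correction so that only proper rotations (no reflections)
are returned.
"""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch_rotation", "superpose", "superposition_rmsd"]


def _as_points(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"{name} must be an (n_atoms, 3) array, got {x.shape}")
    if not np.isfinite(x).all():
        raise ValueError(f"{name} contains NaN/Inf coordinates")
    return x


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation ``R`` such that ``mobile @ R.T`` best fits
    ``reference`` in the least-squares sense. Both inputs must already be
    centred at the origin.
    """
    H = mobile.T @ reference
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:  # degenerate covariance; fall back to proper branch
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rigid-body fit of ``mobile`` onto ``reference``.

    Returns ``(fitted, R, t)`` where ``fitted = mobile @ R.T + t``.
    """
    mobile = _as_points(mobile, "mobile")
    reference = _as_points(reference, "reference")
    if mobile.shape != reference.shape:
        raise ValueError(
            f"atom count mismatch: {mobile.shape[0]} vs {reference.shape[0]}"
        )
    if mobile.shape[0] < 3:
        raise ValueError("superposition requires at least 3 atoms")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    R = kabsch_rotation(mobile - cm, reference - cr)
    t = cr - cm @ R.T
    return mobile @ R.T + t, R, t


def superposition_rmsd(structure: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD between two structures over all rigid transforms.

    RMSD = sqrt( sum_i ||r0_i - U r_i||^2 / N ) with U the best-fit
    rotation+translation.  Symmetric in its arguments.
    """
    fitted, _, _ = superpose(structure, reference)
    return float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
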