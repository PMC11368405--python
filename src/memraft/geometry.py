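"""Rigid-body superposition (Kabsch) shared by the density, surface and PCA stages."""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["kabsch", "apply_rigid_transform", "superposed_rmsd"]


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal proper rotation + translation mapping ``mobile`` onto ``reference``.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` is the least-squares
    superposition.  Reflections are never returned: if the SVD optimum is
    improper (possible for degenerate planar/collinear sets) the smallest
    singular direction is flipped and a warning is emitted.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("kabsch requires two (N, 3) arrays of equal shape")
    if mobile.shape[0] < 3:
        raise ValueError("kabsch requires at least 3 points")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    H = (mobile - mu_m).T @ (reference - mu_r)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d < 0:
        warnings.warn("improper rotation optimum; applying proper-rotation correction")
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - R @ mu_m
    return R, t


def apply_rigid_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords, float) @ R.T + t


def superposed_rmsd(mobile: np.ndarray, reference: np.ndarray, fit: bool = True) -> float:
    """RMSD between two matched coordinate sets, optionally after superposition."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit:
        R, t = kabsch(mobile, reference)
        mobile = apply_rigid_transform(mobile, R, t)
    return float(np.sqrt(np.mean(np.sum((mobile - reference) ** 2, axis=1))))
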