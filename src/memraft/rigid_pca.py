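"""Relative rigid-body motion of one protein group with respect to another.

Each frame is superposed onto a reference by least-squares fitting a chosen
atom set (typically the C-alpha atoms of one tetramer); the remaining motion
of the other group is then its motion *relative* to the fitted one.  The
covariance matrix of the flattened 3N coordinates of the analysis atoms is
diagonalized; eigenvalues (nm^2) sorted descending give the principal
components, their fractions of the total variance, and projections of any
atom-compatible trajectory onto the leading modes.

Eigenvector signs follow a fixed convention (the largest-magnitude
coefficient is positive), so repeated runs are bit-identical.  No mass
weighting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import apply_rigid_transform, kabsch
from .io_core import Selection, Trajectory

__all__ = ["PCAResult", "superpose_onto_reference", "pca", "project"]


@dataclass
class PCAResult:
    mean_coords: np.ndarray       # (n_atoms, 3) time-mean of the analysis atoms
    eigenvectors: np.ndarray      # (3N, n_components), columns orthonormal
    eigenvalues: np.ndarray       # nm^2, descending
    variance_fractions: np.ndarray | None   # None when total variance is 0
    projections: np.ndarray       # (n_frames, n_components) of the input
    atom_indices: np.ndarray      # analysis selection into the topology

    @property
    def degenerate(self) -> bool:
        return self.variance_fractions is None


def superpose_onto_reference(
    traj: Trajectory,
    fit_selection: Selection,
    reference_coords: np.ndarray,
) -> Trajectory:
    """Rigid-fit every frame's fit atoms onto the reference; move all atoms.

    The optimal proper rotation + translation for the fit selection is
    applied to the entire frame, so any other group's residual motion is its
    motion relative to the fitted group.
    """
    reference_coords = np.asarray(reference_coords, dtype=float)
    if len(fit_selection) != len(reference_coords):
        raise ValueError("fit selection does not match reference atom count")
    aligned = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        R, t = kabsch(traj.coords[f, fit_selection.indices], reference_coords)
        aligned[f] = apply_rigid_transform(traj.coords[f], R, t)
    return Trajectory(topology=traj.topology, coords=aligned,
                      boxes=None if traj.boxes is None else traj.boxes.copy(),
                      times=traj.times.copy())


def _flatten(traj: Trajectory, indices: np.ndarray) -> np.ndarray:
    return traj.coords[:, indices, :].reshape(traj.n_frames, -1)


def pca(traj: Trajectory, analysis_selection: Selection) -> PCAResult:
    """Principal components of the analysis atoms' coordinate covariance."""
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    if len(analysis_selection) == 0:
        raise ValueError("empty analysis selection")
    X = _flatten(traj, analysis_selection.indices)
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / X.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: largest-magnitude coefficient positive
    for k in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, k]))
        if evecs[i, k] < 0:
            evecs[:, k] *= -1
    total = evals.sum()
    # a trajectory is static when its total variance is at rounding level
    # relative to the coordinate magnitude
    floor = 1e-12 * max(1.0, float(np.mean(X * X)))
    fractions = evals / total if total > floor else None
    projections = Xc @ evecs
    return PCAResult(
        mean_coords=mean.reshape(-1, 3),
        eigenvectors=evecs,
        eigenvalues=evals,
        variance_fractions=fractions,
        projections=projections,
        atom_indices=analysis_selection.indices.copy(),
    )


def project(traj: Trajectory, result: PCAResult, components=None) -> np.ndarray:
    """Project a trajectory onto principal components.

    The trajectory must provide the same number of analysis atoms as the
    PCA; coordinates are centered on the PCA mean.  ``components`` selects
    mode indices (default: all).
    """
    indices = result.atom_indices
    if traj.n_atoms <= int(indices.max()):
        raise ValueError("trajectory does not contain the PCA analysis atoms")
    X = _flatten(traj, indices)
    if X.shape[1] != result.eigenvectors.shape[0]:
        raise ValueError("atom mismatch with the PCA selection")
    Xc = X - result.mean_coords.ravel()
    vecs = result.eigenvectors
    if components is not None:
        vecs = vecs[:, list(components)]
    return Xc @ vecs
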