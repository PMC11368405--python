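"""Residue-residue contacts between two protein groups.

A residue pair (i from group 1, j from group 2) is in contact at a frame iff
the minimum-image minimum atom-atom distance between the residues is at or
below the cutoff (default 0.6 nm).  From the boolean pair-by-frame matrix
the module derives occupancies T_ij (fraction of frames in contact),
between-condition differences dT_ij in percentage points, mean contact
lifetimes <tau>_ij from maximal runs of consecutive contact frames (runs
truncated by the trajectory ends included), per-frame contact totals, and
the center-of-mass and minimum distances between the two groups.

All atoms of a residue enter the distance computation by default
(hydrogens included when present); pass ``heavy_only=True`` to drop
hydrogens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import Selection, Structure, Trajectory, min_image_distance_matrix, minimum_image

__all__ = [
    "ResidueKey",
    "split_residues",
    "contact_series",
    "ContactSeries",
    "occupancy",
    "delta_occupancy",
    "mean_lifetime",
    "group_distances",
]

ResidueKey = tuple[str, int, str]  # (chain, resid, resname)


def split_residues(topology: Structure, selection: Selection,
                   heavy_only: bool = False) -> list[tuple[ResidueKey, np.ndarray]]:
    """Group the selected atom indices by residue identity (chain, resid)."""
    groups: dict[ResidueKey, list[int]] = {}
    for i in selection.indices:
        a = topology.atoms[i]
        if heavy_only and a.element.upper() == "H":
            continue
        groups.setdefault((a.chain, a.resid, a.resname), []).append(int(i))
    return [(k, np.array(v)) for k, v in groups.items()]


@dataclass
class ContactSeries:
    """Boolean contact matrix (pairs x frames) with its residue-pair labels."""

    pairs: list[tuple[ResidueKey, ResidueKey]]
    matrix: np.ndarray
    cutoff: float
    times: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.shape[0] != len(self.pairs):
            raise ValueError("matrix rows must match the pair list")


def contact_series(
    traj: Trajectory,
    group1: Selection,
    group2: Selection,
    cutoff: float = 0.6,
    heavy_only: bool = False,
) -> ContactSeries:
    """Per-frame residue-pair contacts between two disjoint groups."""
    if len(group1) == 0 or len(group2) == 0:
        raise ValueError("both groups must be non-empty")
    if set(group1.indices) & set(group2.indices):
        raise ValueError("groups must be disjoint")
    res1 = split_residues(traj.topology, group1, heavy_only)
    res2 = split_residues(traj.topology, group2, heavy_only)
    if not res1 or not res2:
        raise ValueError("a group has no residues after filtering")
    idx1 = np.concatenate([v for _, v in res1])
    idx2 = np.concatenate([v for _, v in res2])
    # residue label per column/row of the atom-level distance matrix
    r1_of = np.concatenate([[k] * len(v) for k, (_, v) in enumerate(res1)])
    r2_of = np.concatenate([[k] * len(v) for k, (_, v) in enumerate(res2)])
    n1, n2 = len(res1), len(res2)
    F = traj.n_frames
    matrix = np.zeros((n1 * n2, F), dtype=bool)
    for f in range(F):
        box = traj.box_at(f)
        d = min_image_distance_matrix(traj.coords[f, idx1], traj.coords[f, idx2], box)
        # reduce atom-level distances to residue-pair minima
        dmin = np.full((n1, n2), np.inf)
        np.minimum.at(dmin, (r1_of[:, None], r2_of[None, :]), d)
        matrix[:, f] = (dmin <= cutoff).ravel()
    pairs = [(k1, k2) for k1, _ in res1 for k2, _ in res2]
    return ContactSeries(pairs=pairs, matrix=matrix, cutoff=cutoff, times=traj.times)


def occupancy(matrix: np.ndarray) -> np.ndarray:
    """T_ij: fraction of frames each pair is in contact (0 = never, 1 = always)."""
    matrix = np.asarray(matrix, dtype=bool)
    if matrix.ndim != 2 or matrix.shape[1] == 0:
        raise ValueError("matrix must be (pairs, frames) with at least one frame")
    return matrix.mean(axis=1)


def delta_occupancy(t_a: dict, t_b: dict, min_diff: float = 1.0):
    """dT_ij = T_A - T_B in percentage points, dropping |dT| < ``min_diff``.

    ``t_a`` and ``t_b`` map residue-pair keys to occupancies in [0, 1];
    pairs absent from one condition count as 0 there.  Returns a list of
    ``(pair, delta_points)`` sorted by decreasing |delta|.
    """
    out = []
    for pair in set(t_a) | set(t_b):
        delta = (t_a.get(pair, 0.0) - t_b.get(pair, 0.0)) * 100.0
        if abs(delta) >= min_diff:
            out.append((pair, delta))
    out.sort(key=lambda item: -abs(item[1]))
    return out


def mean_lifetime(matrix: np.ndarray, dt: float):
    """Mean contact-episode duration <tau>_ij (ps) and episode counts.

    An episode is a maximal run of consecutive contact frames; runs cut off
    by the trajectory ends are included.  Pairs with no episode get NaN.
    Returns ``(tau, n_events)`` arrays over pairs.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    matrix = np.asarray(matrix, dtype=bool)
    n_pairs, n_frames = matrix.shape
    tau = np.full(n_pairs, np.nan)
    n_events = np.zeros(n_pairs, dtype=int)
    padded = np.zeros((n_pairs, n_frames + 2), dtype=int)
    padded[:, 1:-1] = matrix
    d = np.diff(padded, axis=1)
    for p in range(n_pairs):
        starts = np.flatnonzero(d[p] == 1)
        ends = np.flatnonzero(d[p] == -1)
        if len(starts):
            runs = ends - starts
            n_events[p] = len(runs)
            tau[p] = runs.mean() * dt
    return tau, n_events


def group_distances(traj: Trajectory, group1: Selection, group2: Selection,
                    masses: np.ndarray | None = None):
    """Per-frame center-of-mass and minimum atom-atom distances (nm).

    Centers default to unweighted centroids; pass per-atom ``masses``
    (topology-length array) to mass-weight them.  Groups are assumed compact
    (not wrapped across the periodic boundary); the distance between the two
    centers and the atom-pair minima use the minimum-image convention.
    """
    if len(group1) == 0 or len(group2) == 0:
        raise ValueError("both groups must be non-empty")
    F = traj.n_frames
    d_cm = np.empty(F)
    d_min = np.empty(F)
    w1 = w2 = None
    if masses is not None:
        masses = np.asarray(masses, dtype=float)
        w1 = masses[group1.indices]
        w2 = masses[group2.indices]
    for f in range(F):
        box = traj.box_at(f)
        x1 = traj.coords[f, group1.indices]
        x2 = traj.coords[f, group2.indices]
        c1 = np.average(x1, axis=0, weights=w1)
        c2 = np.average(x2, axis=0, weights=w2)
        d_cm[f] = np.linalg.norm(minimum_image(c1 - c2, box))
        d_min[f] = np.min(min_image_distance_matrix(x1, x2, box))
    return d_cm, d_min
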