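"""Cholesterol insertion depth, ring-axis orientation, and flip-flop counting.

Insertion depth ``d`` is the signed z-offset of the cholesterol hydroxyl
oxygen from a dynamically recomputed reference plane: the mean z of the
extracellular-leaflet sphingomyelin phosphorus atoms that pass a proximity
filter (within 0.8 nm of the protein, or within 3.0 nm of the monitored
lipid when no protein is present).  Negative values lie below the plane,
toward the membrane center.  Orientation ``theta`` is the angle between the
sterol C17->C3 ring axis and the +z membrane normal, reported unfolded in
[0, 180] degrees so that flipped lipids read above 90 degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_core import Selection, Trajectory, min_image_distance_matrix

__all__ = [
    "DepthOrientationSeries",
    "select_leaflet",
    "insertion_depth_series",
    "orientation_series",
    "track_nearest_lipid",
    "histogram",
    "HistogramResult",
    "count_flip_flops",
]

PROTEIN_PROXIMITY_CUTOFF = 0.8  # nm, P atoms counted near any protein atom
LIPID_PROXIMITY_CUTOFF = 3.0    # nm, P atoms counted near the monitored lipid


@dataclass
class DepthOrientationSeries:
    """Per-frame depth (nm), tilt (deg), reference plane and tracked lipid."""

    times: np.ndarray
    depth: np.ndarray | None = None
    tilt: np.ndarray | None = None
    reference_z: np.ndarray | None = None
    tracked_lipid: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.times)
        for name in ("depth", "tilt", "reference_z", "tracked_lipid"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} length does not match frame count")
        if self.tilt is not None:
            finite = self.tilt[np.isfinite(self.tilt)]
            if np.any((finite < 0) | (finite > 180)):
                raise ValueError("tilt must lie in [0, 180] degrees")


def select_leaflet(
    traj: Trajectory,
    selection: Selection,
    which: str = "upper",
    split_z: float | None = None,
    frame: int = 0,
) -> Selection:
    """Restrict a selection (e.g. sphingomyelin P atoms) to one leaflet.

    Leaflets are assigned by the atoms' z at the given frame relative to
    ``split_z`` (default: the selection's mean z, i.e. the membrane
    midplane).  ``which`` is ``"upper"`` (extracellular in the usual
    convention; invert by choosing ``"lower"``).
    """
    if len(selection) == 0:
        raise ValueError("empty selection")
    if which not in {"upper", "lower"}:
        raise ValueError("which must be 'upper' or 'lower'")
    z = traj.coords[frame, selection.indices, 2]
    split = float(np.mean(z)) if split_z is None else split_z
    mask = z >= split if which == "upper" else z < split
    return Selection(indices=selection.indices[mask],
                     label=f"{selection.label} [{which} leaflet]")


def _oxygen_index_per_frame(traj, chol_oxygen):
    """Accept a 1-atom Selection or a per-frame index array."""
    if isinstance(chol_oxygen, Selection):
        if len(chol_oxygen) != 1:
            raise ValueError("chol_oxygen Selection must contain exactly one atom")
        return np.full(traj.n_frames, chol_oxygen.indices[0], dtype=int)
    idx = np.asarray(chol_oxygen, dtype=int)
    if idx.shape != (traj.n_frames,):
        raise ValueError("per-frame oxygen indices must have one entry per frame")
    return idx


def insertion_depth_series(
    traj: Trajectory,
    chol_oxygen,
    reference_P: Selection,
    mode: str = "near_protein",
    protein: Selection | None = None,
    cutoff: float | None = None,
) -> DepthOrientationSeries:
    """Signed insertion depth of the monitored cholesterol oxygen, per frame.

    ``chol_oxygen`` may be a one-atom :class:`Selection` or an array of
    per-frame atom indices (for dynamically tracked lipids).  ``reference_P``
    holds the extracellular-leaflet phosphorus atoms.  In ``near_protein``
    mode only P atoms within ``cutoff`` (default 0.8 nm) of any protein atom
    define the reference plane; in ``near_lipid`` mode only those within
    ``cutoff`` (default 3.0 nm) of the monitored oxygen.  Frames whose
    filtered reference set is empty get NaN and a warning.
    """
    if len(reference_P) == 0:
        raise ValueError("reference_P selection is empty")
    if mode not in {"near_protein", "near_lipid"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "near_protein":
        if protein is None or len(protein) == 0:
            raise ValueError("near_protein mode requires a protein selection")
        cutoff = PROTEIN_PROXIMITY_CUTOFF if cutoff is None else cutoff
    else:
        cutoff = LIPID_PROXIMITY_CUTOFF if cutoff is None else cutoff

    oxy_idx = _oxygen_index_per_frame(traj, chol_oxygen)
    F = traj.n_frames
    depth = np.full(F, np.nan)
    ref_z = np.full(F, np.nan)
    n_empty = 0
    for f in range(F):
        box = traj.box_at(f)
        p_xyz = traj.coords[f, reference_P.indices]
        o_xyz = traj.coords[f, oxy_idx[f]]
        if mode == "near_protein":
            d = min_image_distance_matrix(p_xyz, traj.coords[f, protein.indices], box)
            keep = np.min(d, axis=1) <= cutoff
        else:
            d = min_image_distance_matrix(p_xyz, o_xyz[None, :], box)
            keep = d[:, 0] <= cutoff
        if not np.any(keep):
            n_empty += 1
            continue
        ref_z[f] = np.mean(p_xyz[keep, 2])
        depth[f] = o_xyz[2] - ref_z[f]
    if n_empty:
        warnings.warn(
            f"{n_empty} frame(s) had an empty filtered reference set; emitted NaN"
        )
    return DepthOrientationSeries(
        times=traj.times, depth=depth, reference_z=ref_z,
        tracked_lipid=oxy_idx.astype(float),
    )


def orientation_series(traj: Trajectory, c17, c3) -> DepthOrientationSeries:
    """Tilt of the C17->C3 sterol ring axis against +z, in degrees [0, 180]."""
    i17 = _oxygen_index_per_frame(traj, c17)
    i3 = _oxygen_index_per_frame(traj, c3)
    v = traj.coords[np.arange(traj.n_frames), i3] - traj.coords[
        np.arange(traj.n_frames), i17
    ]
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length axis: C17 and C3 coincide")
    cos_t = np.clip(v[:, 2] / norms, -1.0, 1.0)
    tilt = np.degrees(np.arccos(cos_t))
    return DepthOrientationSeries(times=traj.times, tilt=tilt)


def track_nearest_lipid(
    traj: Trajectory,
    candidates: list[Selection],
    anchor: Selection,
) -> np.ndarray:
    """Per frame, the candidate lipid whose (first) atom is closest to the
    anchor centroid, minimum-image; ties break to the lowest candidate index.

    Each candidate Selection typically holds the lipid's oxygen atom.
    Returns an integer array of candidate list positions, one per frame.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    if len(anchor) == 0:
        raise ValueError("empty anchor selection")
    cand_idx = np.array([c.indices[0] for c in candidates])
    out = np.empty(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        box = traj.box_at(f)
        centroid = traj.coords[f, anchor.indices].mean(axis=0)
        d = min_image_distance_matrix(
            traj.coords[f, cand_idx], centroid[None, :], box
        )[:, 0]
        # argmin returns the first (lowest-id) minimum, the documented tie rule
        out[f] = int(np.argmin(d))
    return out


@dataclass
class HistogramResult:
    centers: np.ndarray
    heights: np.ndarray
    bin_width: float
    n_missing: int
    normalized: bool


def histogram(values, bin_width: float, value_range=None,
              normalize: bool = True) -> HistogramResult:
    """Fixed-width histogram; NaNs are excluded and counted as missing.

    With ``normalize`` the heights integrate (sum * bin_width) to 1.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(values, dtype=float).ravel()
    n_missing = int(np.sum(~np.isfinite(values)))
    values = values[np.isfinite(values)]
    if len(values) == 0:
        raise ValueError("no data to histogram")
    if value_range is None:
        lo = np.floor(values.min() / bin_width) * bin_width
        hi = np.ceil(values.max() / bin_width) * bin_width
        hi = max(hi, lo + bin_width)
    else:
        lo, hi = value_range
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, lo + n_bins * bin_width))
    centers = 0.5 * (edges[:-1] + edges[1:])
    if normalize:
        heights = counts / (counts.sum() * bin_width)
    else:
        heights = counts.astype(float)
    return HistogramResult(centers=centers, heights=heights, bin_width=bin_width,
                           n_missing=n_missing, normalized=normalize)


def count_flip_flops(tilt, enter_threshold: float = 150.0,
                     exit_threshold: float = 30.0) -> int:
    """Count leaflet flips as hysteretic excursions of the tilt series.

    An event is a transition from the low zone (tilt <= ``exit_threshold``)
    to the high zone (tilt >= ``enter_threshold``) or the reverse; the dead
    band in between prevents noise from double-counting.  NaNs are skipped.
    """
    if not exit_threshold < enter_threshold:
        raise ValueError("exit_threshold must be below enter_threshold")
    tilt = np.asarray(tilt, dtype=float)
    state = 0  # -1 low zone, +1 high zone, 0 not yet committed
    events = 0
    for t in tilt:
        if not np.isfinite(t):
            continue
        if t <= exit_threshold:
            if state == +1:
                events += 1
            state = -1
        elif t >= enter_threshold:
            if state == -1:
                events += 1
            state = +1
    return events
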