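"""Similarity alignment of landmark configurations.

Implements centroid size, generalized Procrustes analysis (GPA), bilateral
symmetrization for the dorsal head view, and the full Procrustes distance
between shapes.  Alignment is full Procrustes: every configuration is centred,
scaled to unit centroid size, and rotated by least squares onto the iteratively
re-estimated consensus.  Reflections are excluded by default since biological
specimens have a handedness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landmark_io import LandmarkConfiguration

__all__ = [
    "AlignedShapes",
    "centroid_size",
    "align_pair",
    "gpa",
    "symmetrize_bilateral",
    "procrustes_distance",
]


def centroid_size(config) -> float:
    """Square root of the summed squared distances of all points to their centroid."""
    pts = config.points if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centred = pts - pts.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs <= 0:
        raise ValueError("all points coincide: centroid size undefined")
    return cs


def _normalize(pts: np.ndarray) -> np.ndarray:
    centred = pts - pts.mean(axis=0)
    return centred / np.sqrt((centred**2).sum())


def _optimal_rotation(source: np.ndarray, target: np.ndarray, allow_reflection: bool) -> np.ndarray:
    """Rotation R minimizing ||source @ R - target||_F for centred configurations."""
    u, _, vt = np.linalg.svd(source.T @ target)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


@dataclass
class AlignedShapes:
    """Procrustes-superimposed coordinates with per-specimen size and metadata.

    ``coords`` is (n_specimens, p, 2); each specimen is centred and has unit
    centroid size.  ``centroid_sizes`` holds the sizes of the raw (pre-scaling)
    configurations.  ``meta`` is indexed like ``coords`` with at least columns
    ``specimen_id``; optional ``category`` and ``tank_id``.
    """

    coords: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    view: str = "dorsal"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[0] < 2:
            raise ValueError("coords must be (n >= 2, p, 2)")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    def flat(self) -> np.ndarray:
        """Coordinates as an (n, 2p) matrix of Procrustes coordinates."""
        return self.coords.reshape(self.n_specimens, -1)

    def to_frame(self) -> pd.DataFrame:
        p = self.coords.shape[1]
        cols = [f"{ax}{i + 1}" for i in range(p) for ax in ("x", "y")]
        df = pd.DataFrame(self.flat(), columns=cols)
        df.insert(0, "centroid_size", self.centroid_sizes)
        if not self.meta.empty:
            df = pd.concat([self.meta.reset_index(drop=True), df], axis=1)
        return df


def align_pair(a: np.ndarray, b: np.ndarray, allow_reflection: bool = False):
    """Ordinary (pairwise) full Procrustes superimposition of ``b`` onto ``a``.

    Returns the two unit-size centred configurations with ``b`` rotated onto
    ``a``.  This is the closed-form two-configuration solution used as the
    oracle for the iterative GPA.
    """
    a0, b0 = _normalize(np.asarray(a, float)), _normalize(np.asarray(b, float))
    r = _optimal_rotation(b0, a0, allow_reflection)
    return a0, b0 @ r


def gpa(
    configs,
    allow_reflection: bool = False,
    tol: float = 1e-10,
    max_iter: int = 100,
    meta: pd.DataFrame | None = None,
) -> AlignedShapes:
    """Generalized Procrustes analysis.

    Removes position (centering), size (unit centroid size) and orientation
    (iterative least-squares rotation to the consensus).  The objective -- the
    summed squared deviation from the consensus -- is non-increasing across
    iterations; iteration stops when its change falls below ``tol``.
    """
    pts_list, ids, view = [], [], "dorsal"
    for i, cfg in enumerate(configs):
        if isinstance(cfg, LandmarkConfiguration):
            pts_list.append(cfg.points)
            ids.append(cfg.specimen_id)
            view = cfg.view
        else:
            pts_list.append(np.asarray(cfg, float))
            ids.append(f"spec{i + 1}")
    n = len(pts_list)
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    p = pts_list[0].shape[0]
    for pts in pts_list:
        if pts.shape != (p, 2):
            raise ValueError("all configurations must share landmark count and ordering")

    sizes = np.array([centroid_size(pts) for pts in pts_list])
    x = np.stack([_normalize(pts) for pts in pts_list])

    # initial consensus: first specimen; then iterate rotate-all / re-average.
    # Convergence is judged on consensus movement, which tracks the residual
    # alignment error linearly (the objective is quadratic near the optimum).
    consensus = x[0]
    for _ in range(max_iter):
        for i in range(n):
            x[i] = x[i] @ _optimal_rotation(x[i], consensus, allow_reflection)
        new_consensus = _normalize(x.mean(axis=0))
        moved = float(np.abs(new_consensus - consensus).max())
        consensus = new_consensus
        if moved < tol:
            break

    meta_df = meta if meta is not None else pd.DataFrame({"specimen_id": ids})
    return AlignedShapes(
        coords=x, centroid_sizes=sizes, consensus=consensus, meta=meta_df, view=view
    )


def _midline_axis(pts: np.ndarray, midline_idx) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares body axis: a point on the axis and a unit direction."""
    if len(midline_idx) >= 2:
        sub = pts[list(midline_idx)]
    else:
        sub = pts
    centre = sub.mean(axis=0)
    centred = sub - centre
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    return centre, vt[0]


def _reflect_across(pts: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
    rel = pts - origin
    along = rel @ direction
    perp = rel - np.outer(along, direction)
    return origin + np.outer(along, direction) - perp


def symmetrize_bilateral(config: LandmarkConfiguration):
    """Average bilaterally paired points with their mirror images across the body axis.

    The axis is the total-least-squares line through the midline (unpaired)
    points, falling back to the configuration's principal axis when fewer than
    two midline points exist.  Returns ``(full, half)``: the full symmetric
    configuration (used for head centroid size) and the one-side-plus-midline
    configuration (used for shape analysis).
    """
    if not config.pair_map:
        raise ValueError("symmetrization requires a pair_map")
    pts = config.points.copy()
    origin, direction = _midline_axis(pts, config.midline)
    mirrored = _reflect_across(pts, origin, direction)
    out = pts.copy()
    for left, right in config.pair_map:
        avg_left = 0.5 * (pts[left] + mirrored[right])
        out[left] = avg_left
        out[right] = _reflect_across(avg_left[None, :], origin, direction)[0]
    # midline points projected onto the axis
    for i in config.midline:
        rel = pts[i] - origin
        out[i] = origin + (rel @ direction) * direction

    full = LandmarkConfiguration(
        specimen_id=config.specimen_id,
        view=config.view,
        points=out,
        point_roles=list(config.point_roles),
        pair_map=list(config.pair_map),
        midline=list(config.midline),
    )
    side_idx = sorted([left for left, _ in config.pair_map] + list(config.midline))
    half = LandmarkConfiguration(
        specimen_id=config.specimen_id,
        view=config.view,
        points=out[side_idx],
        point_roles=[config.point_roles[i] for i in side_idx],
    )
    return full, half


def procrustes_distance(mean_a: np.ndarray, mean_b: np.ndarray, allow_reflection: bool = False) -> float:
    """Full Procrustes distance: the minimal root-sum-of-squares difference
    between two centred unit-size configurations over rotations."""
    a = np.asarray(mean_a, float)
    b = np.asarray(mean_b, float)
    if a.shape != b.shape:
        raise ValueError("landmark count mismatch")
    a0, b0 = _normalize(a), _normalize(b)
    b0 = b0 @ _optimal_rotation(b0, a0, allow_reflection)
    return float(np.sqrt(((a0 - b0) ** 2).sum()))
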