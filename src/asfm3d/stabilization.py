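"""Rigid head stabilization via the helmet reference frame.

The reference helmet is rigidly fixed to the skull, so the least-squares
rigid transform (Kabsch/Umeyama, no scaling) that maps each frame's helmet
markers onto their positions in a reference frame removes head motion from
the facial trajectories. The reference instant is the first frame of the
"rest" segment in which all helmet markers are visible.

Coordinate convention for synthetic and reported data: +x toward the
subject's right, +y superior, +z anterior, origin free (the transform is
affine so the choice is immaterial to distances, speeds and ratios).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, ValidationError
from .io import REST, TrajectorySet

logger = logging.getLogger("asfm3d")

#: warn if the helmet deviates from rigidity by more than this after alignment
DEFAULT_RESIDUAL_WARN_MM = 1.0


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R·x + t (rotation in SO(3), t in mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, float)
        if R.shape != (3, 3):
            raise ValidationError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValidationError("rotation is not orthogonal within 1e-9")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValidationError("rotation determinant is not +1 (reflection?)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of points."""
        return np.asarray(points) @ np.asarray(self.rotation).T + np.asarray(self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def fit_rigid(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition: minimizes Σ‖fixed − (R·moving + t)‖².

    Requires ≥3 corresponding, non-collinear, non-missing point pairs.
    No scaling, no reflection.
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValidationError("point sets must be matching (n,3) arrays")
    n = moving.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need ≥3 point pairs for a rigid fit, got {n}")
    if not (np.isfinite(moving).all() and np.isfinite(fixed).all()):
        raise ValidationError("rigid fit requires finite, non-missing points")

    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    A, B = moving - mc, fixed - fc
    # collinear configurations leave a rotation about the common axis free
    if np.linalg.matrix_rank(A, tol=1e-8 * max(1.0, np.abs(A).max())) < 2:
        raise DegenerateGeometryError("helmet points are collinear; rotation is underdetermined")
    rot, _ = Rotation.align_vectors(B, A)  # Kabsch on centered clouds
    R = rot.as_matrix()
    t = fc - R @ mc
    return RigidTransform(R, t)


def stabilize(
    traj: TrajectorySet,
    *,
    missing_helmet: str = "flag",
    residual_warn_mm: float = DEFAULT_RESIDUAL_WARN_MM,
) -> TrajectorySet:
    """Express all markers in the helmet-fixed reference frame.

    For every frame the rigid transform mapping that frame's helmet markers
    onto the reference frame's helmet markers is applied to all markers.
    Frames where any helmet marker is missing are handled per
    ``missing_helmet``: "flag" (default) marks every facial landmark missing
    in that frame, "error" raises, "drop" behaves like flag (kept distinct
    for reporting).
    """
    if missing_helmet not in {"flag", "error", "drop"}:
        raise ValidationError(f"unknown missing-helmet policy {missing_helmet!r}")
    if len(traj.helmet_labels) < 3:
        raise ValidationError(
            f"stabilization needs ≥3 helmet markers, got {len(traj.helmet_labels)}"
        )
    helm_idx = np.array([traj.index(l) for l in traj.helmet_labels])
    helmet_ok = ~traj.missing[:, helm_idx].any(axis=1)

    # reference: first fully-visible helmet frame of the rest segment,
    # falling back to the first fully-visible frame of the session
    if traj.segments:
        seg = traj.segment(REST)
        candidates = np.flatnonzero(helmet_ok[seg.start_frame : seg.end_frame]) + seg.start_frame
    else:
        candidates = np.flatnonzero(helmet_ok)
        if candidates.size:
            logger.warning("no rest segment; using frame %d as stabilization reference", candidates[0])
    if candidates.size == 0:
        raise ValidationError("no frame with all helmet markers visible to use as reference")
    ref_frame = int(candidates[0])
    ref_helmet = traj.positions[ref_frame, helm_idx, :]

    out_pos = np.array(traj.positions)
    out_missing = np.array(traj.missing)
    worst_residual = 0.0
    for f in range(traj.n_frames):
        if not helmet_ok[f]:
            if missing_helmet == "error":
                raise ValidationError(f"helmet marker missing in frame {f}")
            out_missing[f, :] = True
            out_pos[f, :, :] = np.nan
            continue
        tf = fit_rigid(traj.positions[f, helm_idx, :], ref_helmet)
        out_pos[f] = tf.apply(traj.positions[f])
        resid = np.sqrt(
            np.mean(np.sum((out_pos[f, helm_idx, :] - ref_helmet) ** 2, axis=1))
        )
        worst_residual = max(worst_residual, resid)
    if worst_residual > residual_warn_mm:
        logger.warning(
            "helmet rigidity residual %.3f mm exceeds %.1f mm — possible helmet slippage",
            worst_residual,
            residual_warn_mm,
        )
    out_pos[out_missing] = np.nan
    return traj.with_positions(out_pos, out_missing)
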