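"""Confidence masking, gap interpolation and the body-length normalizer.

Detector noise is removed by masking keypoints whose confidence falls below
a threshold (strictly below 0.5 by default) and filling the gaps by linear
interpolation of x and y independently against frame index.  Boundary gaps,
which cannot be interpolated, are filled with the nearest valid value.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body25 import MID_HIP, NECK
from .errors import AllMaskedError, DegenerateBodyError
from .keypoint_io import TrialRecording


@dataclass
class Trajectory:
    """Per-frame x/y pixel positions of one keypoint plus a validity mask."""

    keypoint_id: int
    xs: np.ndarray
    ys: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (len(self.xs) == len(self.ys) == len(self.mask)):
            raise ValueError("xs, ys and mask must share length")

    def __len__(self) -> int:
        return len(self.xs)

    def slice(self, window: slice) -> "Trajectory":
        return Trajectory(self.keypoint_id, self.xs[window], self.ys[window], self.mask[window])


def extract_trajectory(recording: TrialRecording, keypoint_id: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pull one keypoint's (xs, ys, confidences) out of a recording."""
    return (
        recording.x[:, keypoint_id].copy(),
        recording.y[:, keypoint_id].copy(),
        recording.confidence[:, keypoint_id].copy(),
    )


def mask_low_confidence(
    xs: np.ndarray,
    ys: np.ndarray,
    confidences: np.ndarray,
    keypoint_id: int = -1,
    threshold: float = 0.5,
) -> Trajectory:
    """Mark frames whose detector confidence is strictly below ``threshold`` invalid.

    The comparison is strict, so a confidence of exactly 0.5 is kept.  The
    (0, 0, 0) undetected sentinel has confidence 0 and is masked by the same
    rule.
    """
    confidences = np.asarray(confidences, dtype=float)
    return Trajectory(keypoint_id=keypoint_id, xs=xs, ys=ys, mask=confidences >= threshold)


def interpolate_gaps(traj: Trajectory) -> Trajectory:
    """Fill masked frames by linear interpolation against frame index.

    x and y are interpolated independently.  Leading/trailing gaps are
    extended with the nearest valid value (no extrapolation).  The result is
    fully valid; valid input samples are passed through untouched, which
    makes the operation idempotent.

    Raises
    ------
    AllMaskedError
        If no frame of the trajectory is valid.
    """
    if traj.mask.all():
        return Trajectory(traj.keypoint_id, traj.xs.copy(), traj.ys.copy(), traj.mask.copy())
    valid = np.flatnonzero(traj.mask)
    if valid.size == 0:
        raise AllMaskedError(f"keypoint {traj.keypoint_id}: all {len(traj)} frames masked")
    idx = np.arange(len(traj), dtype=float)
    # np.interp clamps outside the valid range -> nearest-value edge fill.
    xs = np.interp(idx, idx[valid], traj.xs[valid])
    ys = np.interp(idx, idx[valid], traj.ys[valid])
    xs[valid] = traj.xs[valid]
    ys[valid] = traj.ys[valid]
    return Trajectory(traj.keypoint_id, xs, ys, np.ones(len(traj), dtype=bool))


def body_length(neck_traj: Trajectory, hip_traj: Trajectory, tolerance: float = 1e-6) -> float:
    """Mean neck-to-mid-hip Euclidean distance over all frames, in pixels.

    Used as the scale normalizer that removes body-size and camera-distance
    effects from moving distances.

    Raises
    ------
    DegenerateBodyError
        If the mean distance does not exceed ``tolerance`` pixels.
    """
    if len(neck_traj) != len(hip_traj):
        raise ValueError("neck and hip trajectories must share length")
    d = np.hypot(neck_traj.xs - hip_traj.xs, neck_traj.ys - hip_traj.ys)
    bl = float(np.mean(d))
    if bl <= tolerance:
        raise DegenerateBodyError(
            f"neck (kp {NECK}) and hip (kp {MID_HIP}) coincide: mean distance {bl:g} px"
        )
    return bl
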