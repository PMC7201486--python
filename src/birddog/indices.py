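"""Per-trial postural-control indices: DT, SPB and AG.

Three indices summarize one bird-dog trial:

* **DT** (duration time): seconds the posture was held before any lifted
  limb touched the floor, capped at the task maximum (60 s).

* **SPB** (static postural balance): the mean per-frame displacement of the
  extended limbs' wrist, elbow, ankle and knee keypoints, normalized by body
  length,

  .. math:: D = \\frac{1}{n-1} \\sum_{i=1}^{n-1} \\frac{d_{i-1}^{\\,i}}{bl},
            \\qquad D' = \\frac{D_w + D_e + D_a + D_k}{4},

  turned into a cohort z-score of :math:`\\log(1/D')` so that higher SPB
  means steadier posture.

* **AG** (antigravity posture): per frame, the absolute angles
  :math:`|\\varphi|, |\\theta|` between the floor (image horizontal) and the
  extended arm/leg vectors; :math:`a = -\\frac{1}{n}\\sum (|\\varphi| +
  |\\theta|)`, z-scored across the cohort so that higher AG means limbs held
  closer to horizontal.  By absolute values a raised limb scores the same as
  a drooping one.

Standardization (z-scoring with the sample standard deviation, n-1) is a
cohort-level operation: SPB and AG are only defined relative to the set of
trials analyzed together.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .body25 import MID_HIP, NECK, Side, extended_keypoints, supporting_keypoints
from .config import ScoringConfig
from .errors import (
    ConstantCohortError,
    DegenerateLimbError,
    MetadataError,
    NoPostureError,
    TooShortError,
)
from .keypoint_io import TrialIndices, TrialRecording, indices_to_frame
from .preprocess import (
    Trajectory,
    body_length,
    extract_trajectory,
    interpolate_gaps,
    mask_low_confidence,
)

__all__ = [
    "moving_distance",
    "combined_distance",
    "spb_standardize",
    "ag_standardize",
    "limb_angle",
    "limb_angles",
    "ag_raw",
    "duration_time",
    "PreparedTrial",
    "prepare_trial",
    "trial_metrics",
    "score_cohort",
]


# ---------------------------------------------------------------------------
# Moving distance and SPB
# ---------------------------------------------------------------------------

def moving_distance(traj: Trajectory, bl: float) -> float:
    """Mean per-frame Euclidean step of one keypoint, in body lengths/frame."""
    n = len(traj)
    if n < 2:
        raise TooShortError(f"keypoint {traj.keypoint_id}: need >= 2 frames, got {n}")
    steps = np.hypot(np.diff(traj.xs), np.diff(traj.ys))
    return float(np.mean(steps) / bl)


def combined_distance(d_w: float, d_e: float, d_a: float, d_k: float) -> float:
    """Average the wrist/elbow/ankle/knee moving distances of the extended limbs."""
    return (d_w + d_e + d_a + d_k) / 4.0


def _zscore(values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ConstantCohortError(f"{what}: need >= 2 trials to standardize, got {values.size}")
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        raise ConstantCohortError(f"{what}: zero variance across {values.size} trials")
    return (values - float(np.mean(values))) / sd


@dataclass(frozen=True)
class CohortStandardizer:
    """Frozen cohort mean/sd of a raw index, for z-scoring new values.

    For SPB the raw index is log(1/D'); for AG it is ``a``.  Lets a
    truncation analysis reuse the full-length cohort's mu/sigma instead of
    re-standardizing inside each truncated cohort.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ConstantCohortError(f"sigma must be positive, got {self.sigma}")

    @classmethod
    def fit(cls, values) -> "CohortStandardizer":
        values = np.asarray(values, dtype=float)
        sd = float(np.std(values, ddof=1)) if values.size >= 2 else 0.0
        if sd == 0.0:
            raise ConstantCohortError(f"zero variance across {values.size} trials")
        return cls(mu=float(np.mean(values)), sigma=sd)

    def __call__(self, values) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mu) / self.sigma


def spb_standardize(d_prime_per_trial, d_prime_floor: float = 1e-6) -> np.ndarray:
    """Cohort z-scores of log(1/D') (natural log, sample standard deviation).

    Each D' is floored at ``d_prime_floor`` before the log to guard
    log(1/0) for pathological stationary input.  By construction the
    returned scores have mean 0 and (sample) sd 1.
    """
    d_prime = np.maximum(np.asarray(d_prime_per_trial, dtype=float), d_prime_floor)
    return _zscore(np.log(1.0 / d_prime), "SPB")


def ag_standardize(a_per_trial) -> np.ndarray:
    """Cohort z-scores of the raw antigravity angle score ``a``."""
    return _zscore(np.asarray(a_per_trial, dtype=float), "AG")


# ---------------------------------------------------------------------------
# Limb angles and AG
# ---------------------------------------------------------------------------

def limb_angles(ox, oy, tx, ty) -> np.ndarray:
    """Absolute limb-floor angles in degrees, vectorized over frames.

    The floor is assumed parallel to the image horizontal, so the angle is
    atan(|dy| / |dx|) in [0, 90]; a vertical limb (dx = 0) scores 90.
    """
    dx = np.abs(np.asarray(tx, dtype=float) - np.asarray(ox, dtype=float))
    dy = np.abs(np.asarray(ty, dtype=float) - np.asarray(oy, dtype=float))
    degenerate = (dx == 0) & (dy == 0)
    if np.any(degenerate):
        frame = int(np.argmax(degenerate))
        raise DegenerateLimbError(f"limb origin and tip coincide at frame {frame}")
    return np.degrees(np.arctan2(dy, dx))


def limb_angle(origin: tuple[float, float], tip: tuple[float, float]) -> float:
    """Absolute angle (degrees, [0, 90]) between one limb vector and the floor."""
    return float(limb_angles(origin[0], origin[1], tip[0], tip[1]))


def ag_raw(
    neck: Trajectory,
    mid_hip: Trajectory,
    wrist: Trajectory,
    elbow: Trajectory,
    ankle: Trajectory,
    knee: Trajectory,
) -> float:
    """Raw antigravity score ``a`` (degrees, <= 0) over the given frames.

    The arm vector runs from the neck to the wrist/elbow midpoint, the leg
    vector from the mid-hip to the ankle/knee midpoint.
    """
    phi = limb_angles(neck.xs, neck.ys, (wrist.xs + elbow.xs) / 2.0, (wrist.ys + elbow.ys) / 2.0)
    theta = limb_angles(mid_hip.xs, mid_hip.ys, (ankle.xs + knee.xs) / 2.0, (ankle.ys + knee.ys) / 2.0)
    return float(-np.mean(np.abs(phi) + np.abs(theta)))


# ---------------------------------------------------------------------------
# Trial preparation and duration time
# ---------------------------------------------------------------------------

@dataclass
class PreparedTrial:
    """Interpolated trajectories plus resolved posture timing for one trial."""

    participant_id: str
    side: Side
    fps: float
    n_frames: int
    bl: float
    trajectories: dict[int, Trajectory]
    start_frame: int
    fall_frame: int | None

    @property
    def extended(self) -> dict[str, int]:
        return extended_keypoints(self.side)


def prepare_trial(recording: TrialRecording, config: ScoringConfig | None = None) -> PreparedTrial:
    """Mask, interpolate and time one recording; the entry point of scoring.

    Extracts the neck, mid-hip and extended-limb keypoints (plus the
    supporting wrist/ankle in heuristic mode), applies confidence masking and
    gap interpolation, computes the full-trial body length, and resolves the
    posture start and fall frames per ``config.dt_mode``.
    """
    config = config or ScoringConfig()
    ext = extended_keypoints(recording.side)
    sup = supporting_keypoints(recording.side)
    needed = {NECK, MID_HIP, *ext.values()}
    if config.dt_mode == "heuristic":
        needed |= set(sup.values())

    trajs: dict[int, Trajectory] = {}
    for kp in sorted(needed):
        xs, ys, conf = extract_trajectory(recording, kp)
        trajs[kp] = interpolate_gaps(
            mask_low_confidence(xs, ys, conf, keypoint_id=kp, threshold=config.confidence_threshold)
        )
    bl = body_length(trajs[NECK], trajs[MID_HIP])

    if config.dt_mode == "annotated":
        start = recording.annotated_start_frame or 0
        fall = recording.annotated_fall_frame
        if fall is not None and fall < start:
            raise MetadataError(
                f"{recording.participant_id}/{recording.side.value}: "
                f"annotated fall frame {fall} precedes start frame {start}"
            )
    else:
        start, fall = _heuristic_timing(recording, trajs, ext, sup, bl, config)

    return PreparedTrial(
        participant_id=recording.participant_id,
        side=recording.side,
        fps=recording.fps,
        n_frames=recording.n_frames,
        bl=bl,
        trajectories=trajs,
        start_frame=int(start),
        fall_frame=None if fall is None else int(fall),
    )


def _heuristic_timing(recording, trajs, ext, sup, bl, config):
    """Detect lift-off and floor contact from the keypoints themselves.

    The floor line is the lowest image point (maximum y) reached by the
    supporting wrist/ankle over the trial.  The posture starts at the first
    frame where both extended end-effectors clear the floor by
    ``lift_margin_bl`` body lengths *and* both limb-floor angles are below
    ``extension_angle_max``; it ends at the first later frame where either
    extended end-effector comes within ``floor_margin_bl`` body lengths of
    the floor.
    """
    floor_y = max(float(trajs[sup["wrist"]].ys.max()), float(trajs[sup["ankle"]].ys.max()))
    wrist, ankle = trajs[ext["wrist"]], trajs[ext["ankle"]]
    elbow, knee = trajs[ext["elbow"]], trajs[ext["knee"]]
    neck, hip = trajs[NECK], trajs[MID_HIP]

    phi = limb_angles(neck.xs, neck.ys, (wrist.xs + elbow.xs) / 2, (wrist.ys + elbow.ys) / 2)
    theta = limb_angles(hip.xs, hip.ys, (ankle.xs + knee.xs) / 2, (ankle.ys + knee.ys) / 2)
    lifted = (wrist.ys < floor_y - config.lift_margin_bl * bl) & (
        ankle.ys < floor_y - config.lift_margin_bl * bl
    )
    extended = (phi < config.extension_angle_max) & (theta < config.extension_angle_max)
    achieved = np.flatnonzero(lifted & extended)
    if achieved.size == 0:
        raise NoPostureError(
            f"{recording.participant_id}/{recording.side.value}: posture never achieved"
        )
    start = int(achieved[0])
    touching = (wrist.ys >= floor_y - config.floor_margin_bl * bl) | (
        ankle.ys >= floor_y - config.floor_margin_bl * bl
    )
    later = np.flatnonzero(touching[start + 1:])
    fall = int(start + 1 + later[0]) if later.size else None
    return start, fall


def duration_time(
    recording: TrialRecording,
    mode: str | None = None,
    config: ScoringConfig | None = None,
    prepared: PreparedTrial | None = None,
) -> float:
    """Seconds the posture was held, capped at the task maximum.

    DT = (fall_frame - start_frame) / fps, capped at ``task_cap_s``; if no
    fall occurs, DT is the capped remaining recording length.
    """
    config = config or ScoringConfig()
    if mode is not None and mode != config.dt_mode:
        import dataclasses

        config = dataclasses.replace(config, dt_mode=mode)
    prep = prepared if prepared is not None and config.dt_mode == "annotated" else None
    if prep is None:
        prep = prepare_trial(recording, config)
    end = prep.fall_frame if prep.fall_frame is not None else prep.n_frames
    dt = (end - prep.start_frame) / prep.fps
    return float(min(max(dt, 0.0), config.task_cap_s))


# ---------------------------------------------------------------------------
# Per-trial metrics and cohort scoring
# ---------------------------------------------------------------------------

def trial_metrics(
    prep: PreparedTrial,
    config: ScoringConfig | None = None,
    test_time_s: float | None = None,
) -> dict[str, float]:
    """Raw (pre-standardization) indices for one prepared trial.

    The analysis window runs from the posture start to the fall frame (if
    any), clipped at ``test_time_s`` (default: the task cap) after the
    start.  D', ``a`` and the window body length are all computed inside the
    window, so truncating the test time genuinely recomputes the indices
    instead of merely capping DT.
    """
    config = config or ScoringConfig()
    cap = config.task_cap_s
    t = cap if test_time_s is None else min(test_time_s, cap)
    start = prep.start_frame
    end = prep.n_frames if prep.fall_frame is None else min(prep.fall_frame, prep.n_frames)
    end = min(end, start + int(round(t * prep.fps)))
    if end - start < 2:
        raise TooShortError(
            f"{prep.participant_id}/{prep.side.value}: analysis window "
            f"[{start}, {end}) has fewer than 2 frames"
        )
    window = slice(start, end)

    trajs = {kp: traj.slice(window) for kp, traj in prep.trajectories.items()}
    bl = body_length(trajs[NECK], trajs[MID_HIP])
    ext = prep.extended
    d = {role: moving_distance(trajs[kp], bl) for role, kp in ext.items()}
    d_prime = combined_distance(d["wrist"], d["elbow"], d["ankle"], d["knee"])
    a = ag_raw(
        trajs[NECK], trajs[MID_HIP],
        trajs[ext["wrist"]], trajs[ext["elbow"]],
        trajs[ext["ankle"]], trajs[ext["knee"]],
    )
    full_end = prep.fall_frame if prep.fall_frame is not None else prep.n_frames
    dt_full = min(max((full_end - start) / prep.fps, 0.0), cap)
    return {
        "DT": float(min(dt_full, t)),
        "D_w": d["wrist"],
        "D_e": d["elbow"],
        "D_a": d["ankle"],
        "D_k": d["knee"],
        "D_prime": d_prime,
        "a_raw": a,
    }


def score_cohort(
    recordings: list[TrialRecording],
    config: ScoringConfig | None = None,
    prepared: list[PreparedTrial] | None = None,
    test_time_s: float | None = None,
) -> tuple[list[TrialIndices], pd.DataFrame]:
    """Score a cohort of trials and standardize SPB/AG across it.

    Returns the per-trial :class:`TrialIndices` rows and the same data as a
    DataFrame keyed by (participant_id, side).  The standardization cohort is
    all trials passed in (participant x side).
    """
    config = config or ScoringConfig()
    if prepared is None:
        prepared = [prepare_trial(rec, config) for rec in recordings]
    metrics = [trial_metrics(p, config, test_time_s) for p in prepared]
    spb = spb_standardize([m["D_prime"] for m in metrics], config.d_prime_floor)
    ag = ag_standardize([m["a_raw"] for m in metrics])
    rows = [
        TrialIndices(
            participant_id=p.participant_id,
            side=p.side,
            dt_s=m["DT"],
            d_prime=m["D_prime"],
            a_raw=m["a_raw"],
            spb=float(s),
            ag=float(g),
            d_w=m["D_w"],
            d_e=m["D_e"],
            d_a=m["D_a"],
            d_k=m["D_k"],
        )
        for p, m, s, g in zip(prepared, metrics, spb, ag)
    ]
    return rows, indices_to_frame(rows)
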