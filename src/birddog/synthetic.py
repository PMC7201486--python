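"""Synthetic bird-dog recordings and simulated therapist ratings.

Real study videos are not available, so every pipeline stage is exercised on
generated keypoint recordings with known ground truth.  One trial is a
side-view stick figure in the quadruped position: trunk horizontal, the
supporting wrist/ankle fixed on the floor line, and the extended arm and
contralateral leg held near horizontal.  Controllable ingredients:

* **sway** — mean-reverting (AR(1)) Gaussian jitter of the extended-limb
  keypoints, with per-frame step sd ``sway_sigma`` body lengths.  Mean
  reversion keeps the limbs from drifting off-body while the per-frame step
  still scales interpretably with ``sway_sigma``.
* **droop** — mean angular deviation of the extended limbs from horizontal,
  in degrees (ground truth for the antigravity score: a ~ -2 * droop).
* **fall** — at ``fall_time_s`` the extended wrist/ankle drop to the floor
  line (ground truth for duration time).
* **confidence dropout** — a fraction of (frame, keypoint) cells get
  confidence below 0.5 *and* a large position perturbation, so unmasked use
  of them would visibly corrupt the indices.

A cohort draws per-trial parameters from a shared latent "ability" per
participant (steadier children sway less, droop less and last longer — the
study's indices are correlated in real data), then simulates raters scoring
a latent quality on a 7-point Likert scale.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .body25 import (
    L_ANKLE, L_ELBOW, L_HIP, L_KNEE, L_SHOULDER, L_WRIST,
    MID_HIP, N_KEYPOINTS, NECK, NOSE,
    R_ANKLE, R_ELBOW, R_HIP, R_KNEE, R_SHOULDER, R_WRIST,
    Side, extended_keypoints, supporting_keypoints,
)
from .keypoint_io import TrialRecording

#: AR(1) pole of the sway process; per-frame step sd stays ~= sway_sigma.
SWAY_RHO = 0.95


@dataclass
class TrialParams:
    """Generator knobs for one synthetic trial."""

    sway_sigma: float = 0.003      # body-lengths/frame, per-frame step sd
    droop_deg: float = 10.0        # mean limb deviation from horizontal
    fall_time_s: float | None = None
    dropout_rate: float = 0.02     # fraction of cells with confidence < 0.5
    fps: float = 30.0
    duration_s: float = 60.0
    seed: int = 0
    image_width: int = 1280
    image_height: int = 720
    body_length_px: float = 200.0

    def __post_init__(self) -> None:
        if self.sway_sigma < 0 or self.droop_deg < 0:
            raise ValueError("sway_sigma and droop_deg must be >= 0")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration_s must be positive")


def _skeleton_template(side: Side, params: TrialParams) -> tuple[np.ndarray, float]:
    """Static (25, 2) keypoint layout for the bird-dog posture, plus floor y.

    The figure faces +x; droop tilts the extended arm (forward, past the
    head) and leg (backward) below horizontal by ``droop_deg``.
    """
    L = params.body_length_px
    floor_y = 0.9 * params.image_height
    hip_x, trunk_y = 0.42 * params.image_width, floor_y - 0.9 * L
    neck = np.array([hip_x + L, trunk_y])
    mid_hip = np.array([hip_x, trunk_y])

    delta = np.radians(params.droop_deg)
    arm_dir = np.array([np.cos(delta), np.sin(delta)])        # forward, y down = droop
    leg_dir = np.array([-np.cos(delta), np.sin(delta)])       # backward

    pts = np.zeros((N_KEYPOINTS, 2))
    ext, sup = extended_keypoints(side), supporting_keypoints(side)
    ext_shoulder = L_SHOULDER if side is Side.LEFT_EXTENDED else R_SHOULDER
    sup_shoulder = R_SHOULDER if side is Side.LEFT_EXTENDED else L_SHOULDER
    ext_hip = R_HIP if side is Side.LEFT_EXTENDED else L_HIP
    sup_hip = L_HIP if side is Side.LEFT_EXTENDED else R_HIP
    sup_elbow = R_ELBOW if side is Side.LEFT_EXTENDED else L_ELBOW
    sup_knee = L_KNEE if side is Side.LEFT_EXTENDED else R_KNEE

    pts[NECK] = neck
    pts[MID_HIP] = mid_hip
    pts[NOSE] = neck + (0.2 * L, -0.2 * L)
    # face points near the nose
    for k, off in zip(range(15, 19), ((0.02, -0.05), (-0.02, -0.05), (0.05, 0.0), (-0.05, 0.0))):
        pts[k] = pts[NOSE] + np.array(off) * L

    # extended arm: collinear elbow/wrist so the arm vector angle is exactly droop
    pts[ext_shoulder] = neck + (0.0, 0.05 * L)
    pts[ext["elbow"]] = neck + 0.55 * L * arm_dir
    pts[ext["wrist"]] = neck + 1.1 * L * arm_dir
    # extended leg
    pts[ext_hip] = mid_hip + (0.0, 0.05 * L)
    pts[ext["knee"]] = mid_hip + 0.55 * L * leg_dir
    pts[ext["ankle"]] = mid_hip + 1.1 * L * leg_dir

    # supporting limbs: wrist/ankle on the floor line
    pts[sup_shoulder] = neck + (-0.02 * L, 0.06 * L)
    pts[sup_elbow] = np.array([neck[0] - 0.02 * L, trunk_y + 0.45 * L])
    pts[sup["wrist"]] = np.array([neck[0] - 0.03 * L, floor_y - 1.0])
    pts[sup_hip] = mid_hip + (0.02 * L, 0.06 * L)
    pts[sup_knee] = np.array([mid_hip[0] - 0.05 * L, floor_y - 0.05 * L])
    pts[sup["ankle"]] = np.array([mid_hip[0] - 0.45 * L, floor_y - 1.0])

    # feet points near the respective ankles
    for k, anchor in ((19, L_ANKLE), (20, L_ANKLE), (21, L_ANKLE), (22, R_ANKLE), (23, R_ANKLE), (24, R_ANKLE)):
        pts[k] = pts[anchor] + ((k % 3 - 1) * 0.05 * L, 0.02 * L)
    return pts, floor_y


def generate_trial(
    params: TrialParams,
    participant_id: str = "sim",
    side: Side | str = Side.LEFT_EXTENDED,
) -> tuple[TrialRecording, dict]:
    """Generate one synthetic trial; deterministic given ``params.seed``.

    Returns the recording (annotated with start frame 0 and the fall frame,
    if any) and a ground-truth record of the generating parameters.
    """
    side = Side.parse(side)
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fps))
    L = params.body_length_px
    base, floor_y = _skeleton_template(side, params)

    x = np.tile(base[:, 0], (n, 1))
    y = np.tile(base[:, 1], (n, 1))

    ext = extended_keypoints(side)
    for kp in (ext["wrist"], ext["elbow"], ext["ankle"], ext["knee"]):
        eps = rng.normal(0.0, params.sway_sigma * L, size=(n, 2))
        off = lfilter([1.0], [1.0, -SWAY_RHO], eps, axis=0)
        x[:, kp] += off[:, 0]
        y[:, kp] += off[:, 1]

    fall_frame: int | None = None
    if params.fall_time_s is not None and params.fall_time_s < params.duration_s:
        fall_frame = int(round(max(params.fall_time_s, 2.0 / params.fps) * params.fps))
        fall_frame = max(fall_frame, 2)
        if fall_frame < n:
            for kp in (ext["wrist"], ext["ankle"]):
                y[fall_frame:, kp] = floor_y - 1.0 + y[fall_frame:, kp] - y[fall_frame:, kp].mean()
            for kp in (ext["elbow"], ext["knee"]):
                y[fall_frame:, kp] = (y[fall_frame:, kp] + floor_y) / 2.0
        else:
            fall_frame = None

    conf = rng.uniform(0.6, 1.0, size=(n, N_KEYPOINTS))
    drop = rng.random((n, N_KEYPOINTS)) < params.dropout_rate
    n_drop = int(drop.sum())
    if n_drop:
        conf[drop] = rng.uniform(0.0, 0.45, size=n_drop)
        x[drop] += rng.normal(0.0, 0.25 * L, size=n_drop)
        y[drop] += rng.normal(0.0, 0.25 * L, size=n_drop)

    rec = TrialRecording(
        participant_id=participant_id,
        side=side,
        fps=params.fps,
        x=x, y=y, confidence=conf,
        image_width=params.image_width,
        image_height=params.image_height,
        annotated_start_frame=0,
        annotated_fall_frame=fall_frame,
    )
    truth = {
        "participant_id": participant_id,
        "side": side.value,
        "sway_sigma": params.sway_sigma,
        "droop_deg": params.droop_deg,
        "fall_time_s": params.fall_time_s,
        "fall_frame": fall_frame,
        "dt_true_s": min(
            params.fall_time_s if params.fall_time_s is not None else np.inf,
            params.duration_s,
        ),
        "dropout_rate": params.dropout_rate,
        "seed": params.seed,
    }
    return rec, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study-design defaults: 34 participants x two sides, three raters.

    Per-trial sway/droop/fall parameters are drawn from log-normal spreads
    tied to a latent per-participant ability, so that steadier children also
    tend to last longer (correlated indices, as in real cohorts).  The fall
    log-mean/sd are chosen so that roughly a quarter of trials reach the
    60 s cap and about half last 20 s or more.
    """

    n_participants: int = 34
    sides_per_participant: int = 2
    rater_count: int = 3
    rater_noise_sd: float = 0.08
    quality_weights: tuple[float, float, float] = (0.25, 0.22, 0.69)
    fps: float = 30.0
    duration_s: float = 60.0
    dropout_rate: float = 0.02
    sway_sigma_median: float = 0.003
    sway_spread: float = 0.5
    droop_median_deg: float = 10.0
    droop_spread: float = 0.5
    fall_log_mean: float = 3.14
    fall_log_sd: float = 1.48
    ability_loading: float = 0.7
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.rater_count < 2:
            raise ValueError("rater_count must be >= 2")

    @property
    def n_trials(self) -> int:
        return self.n_participants * self.sides_per_participant


def _child_seed(master_seed: int, stream: int) -> int:
    # splittable counter scheme: every (master, stream) pair maps to an
    # independent, reproducible child seed
    return int(np.random.SeedSequence([int(master_seed), int(stream)]).generate_state(1)[0])


def _sample_trial_params(config: CohortConfig, rng: np.random.Generator, u_trial: float, seed: int) -> TrialParams:
    lam = config.ability_loading
    res = float(np.sqrt(max(1.0 - lam**2, 0.0)))
    sway = config.sway_sigma_median * np.exp(
        config.sway_spread * (-lam * u_trial + res * rng.standard_normal())
    )
    droop = config.droop_median_deg * np.exp(
        config.droop_spread * (-lam * u_trial + res * rng.standard_normal())
    )
    fall = float(np.exp(config.fall_log_mean + config.fall_log_sd * (lam * u_trial + res * rng.standard_normal())))
    fall_time = None if fall >= min(config.duration_s, 60.0) else max(fall, 2.0 / config.fps + 0.05)
    return TrialParams(
        sway_sigma=float(sway),
        droop_deg=float(droop),
        fall_time_s=fall_time,
        dropout_rate=config.dropout_rate,
        fps=config.fps,
        duration_s=config.duration_s,
        seed=seed,
    )


def _sample_z(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=1)
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[list[TrialRecording], pd.DataFrame, pd.DataFrame]:
    """Generate a full cohort: recordings, a ratings table and ground truth.

    Rater k's score of trial j is ``round(clip(1 + 6 (q_j + e_jk), 1, 7))``
    where q_j is the latent quality — a weighted combination of z-scored
    (-log sway), (-droop) and true capped duration, min-max rescaled to
    [0, 1] — and e_jk ~ N(0, rater_noise_sd) is independent rater noise.
    Fully deterministic given ``master_seed``.
    """
    config = config or CohortConfig()
    if config.sway_spread == 0 and config.droop_spread == 0 and config.fall_log_sd == 0:
        warnings.warn(
            "all trials share identical parameters; downstream standardization will fail",
            stacklevel=2,
        )
    param_rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 999_983]))
    rater_rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 1_000_003]))

    recordings: list[TrialRecording] = []
    truth_rows: list[dict] = []
    stream = 0
    for p in range(config.n_participants):
        pid = f"P{p:03d}"
        ability = param_rng.standard_normal()
        for s in range(config.sides_per_participant):
            side = Side.LEFT_EXTENDED if s % 2 == 0 else Side.RIGHT_EXTENDED
            u_trial = 0.85 * ability + 0.53 * param_rng.standard_normal()
            params = _sample_trial_params(
                config, param_rng, u_trial, seed=_child_seed(config.master_seed, stream)
            )
            rec, truth = generate_trial(params, participant_id=pid, side=side)
            recordings.append(rec)
            truth_rows.append(truth)
            stream += 1

    truth_df = pd.DataFrame(truth_rows)
    dt_true = truth_df["dt_true_s"].to_numpy(dtype=float)
    w_spb, w_ag, w_dt = config.quality_weights
    quality = (
        w_spb * _sample_z(-np.log(truth_df["sway_sigma"].to_numpy()))
        + w_ag * _sample_z(-truth_df["droop_deg"].to_numpy(dtype=float))
        + w_dt * _sample_z(dt_true)
    )
    span = quality.max() - quality.min()
    q = (quality - quality.min()) / span if span > 0 else np.full_like(quality, 0.5)
    truth_df["quality"] = q

    scores = {}
    for k in range(config.rater_count):
        noise = rater_rng.normal(0.0, config.rater_noise_sd, size=len(q))
        scores[f"r{k + 1}"] = np.clip(np.round(1.0 + 6.0 * (q + noise)), 1, 7).astype(int)
    ratings_df = pd.DataFrame(
        {
            "participant_id": truth_df["participant_id"],
            "side": truth_df["side"],
            **scores,
        }
    )
    rater_cols = [f"r{k + 1}" for k in range(config.rater_count)]
    ratings_df["TQCE"] = ratings_df[rater_cols].mean(axis=1)
    return recordings, ratings_df, truth_df


def generate_index_table(
    n_trials: int = 500,
    weights: tuple[float, float, float] = (0.25, 0.22, 0.69),
    noise_sd: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Trial-level table with TQCE a known linear function of the indices.

    SPB, AG and DT are drawn iid standard normal and
    ``TQCE = w_spb*SPB + w_ag*AG + w_dt*DT + noise``.  The default noise sd,
    sqrt(1 - |w|^2), gives the response unit variance so the generating
    weights *are* the standardized coefficients — a direct parameter-recovery
    target for :func:`birddog.cohort_stats.fit_model`.
    """
    rng = np.random.default_rng(seed)
    w = np.asarray(weights, dtype=float)
    if noise_sd is None:
        noise_sd = float(np.sqrt(max(1.0 - float(w @ w), 0.05)))
    X = rng.standard_normal((n_trials, 3))
    tqce = X @ w + rng.normal(0.0, noise_sd, size=n_trials)
    return pd.DataFrame(
        {"SPB": X[:, 0], "AG": X[:, 1], "DT": X[:, 2], "TQCE": tqce}
    )
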