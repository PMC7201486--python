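# Methods

## Scoring pipeline

One trial is a directory of per-frame OpenPose BODY_25 JSON files plus
metadata (extended side, frame rate, optional annotated posture-start and
fall frames).  Scoring proceeds:

1. **Parse.**  Each frame document carries a `people` list with a flat
   75-number `pose_keypoints_2d` list.  If several people are detected the
   person with the highest summed confidence is kept (the task records one
   child; the rule keeps batch runs deterministic).  Frames with no person
   are retained as fully undetected frames (all confidences 0), so they
   fall into the masking/interpolation path rather than being dropped.
   All index math runs in the original video orientation (participant
   horizontal, image origin top-left, y down); the 90° rotation applied
   for detection is inverted exactly by `rotate_frame` (cw90:
   (x, y) → (H−1−y, x); ccw90: (x, y) → (y, W−1−x)).

2. **Mask and interpolate.**  Keypoints with confidence strictly below 0.5
   are removed per frame (exactly 0.5 is kept) and filled by linear
   interpolation of x and y independently against frame index.  Boundary
   gaps cannot be interpolated and are filled with the nearest valid value
   — constant extension avoids extrapolation artifacts.  A keypoint with
   zero valid frames aborts the trial with `AllMaskedError`; batch runs
   report it per trial and continue.

3. **Body length.**  bl = mean Euclidean neck (keypoint 1) to mid-hip
   (keypoint 8) distance over the frames analyzed.  The mid-hip is used
   where the task definition says only "hip": it is the sagittal-plane
   trunk landmark.

4. **Indices.**  D per extended-limb keypoint (wrist/elbow of the lifted
   arm, ankle/knee of the contralateral lifted leg), D′ their mean, SPB the
   cohort z-score of log(1/D′); a the negated per-frame mean of the two
   absolute limb–floor angles, AG its cohort z-score.  Angles are measured
   in degrees (the z-score is unit-free, so the choice is cosmetic);
   the natural logarithm is used in log(1/D′) — any base yields identical
   z-scores.  All z-scores use the sample standard deviation (n−1), and
   the mean-0/sd-1 identity is asserted with the same estimator.  The
   standardization cohort is all trials scored together (participant ×
   side).

### Analysis window

D′ and a are computed on the frames from the posture start up to the fall
frame (or the end of the recording), further clipped at the allowed test
time.  Truncation to a test time T therefore *recomputes* the indices on
the truncated window — including bl — rather than merely capping DT; at
T = task cap this reproduces the untruncated pipeline bit for bit.
Masking/interpolation are performed once on the full recording and the
interpolated trajectories are sliced, so a gap spanning the truncation
boundary uses the full-recording interpolation (a deliberate and cheap
choice; it affects only frames that were invalid anyway).

### Duration time

DT = (fall − start)/fps, capped at `task_cap_s` (default 60 s); with no
fall event, the capped remaining recording length.  Two modes:

- **annotated** (default): start/fall frames are part of the trial
  metadata, mirroring event marking from video inspection.
- **heuristic**: the floor line is the lowest image point (max y) reached
  by the supporting wrist/ankle; the posture starts at the first frame
  where both extended end-effectors clear the floor by `lift_margin_bl`
  (0.1 bl) *and* both limb angles are below `extension_angle_max` (30°);
  it ends at the first later frame where either end-effector comes within
  `floor_margin_bl` (0.02 bl) of the floor.  The margins are intentionally
  conservative defaults for clean synthetic data; real recordings may need
  tuning via the config keys.

### Numerical guards

- `d_prime_floor` = 1e−6 body-lengths/frame floors D′ before log(1/D′);
  only a perfectly stationary synthetic trial reaches it.
- Degenerate geometry raises typed errors (`DegenerateBodyError`,
  `DegenerateLimbError` with frame index) rather than propagating NaNs.
- A vertical limb (Δx = 0) scores 90°.
- z-scoring a zero-variance cohort raises `ConstantCohortError`.

## Cohort statistics

- **Spearman** correlations (tie-averaged ranks; p from the t
  approximation with n−2 df, exact permutation available for n ≤ 10) relate
  each index to TQCE, the across-rater mean of 7-point Likert scores.
- **Model comparison**: OLS of TQCE on {SPB, AG, DT} vs DT alone.
  Response and predictors are z-scored before the fit, so the reported β
  are standardized (a single-predictor β equals the Pearson correlation);
  raw-scale coefficients are reported alongside.  Adjusted
  R² = 1 − (1 − R²)(n − 1)/(n − p − 1).  The comparison statistic is the
  Spearman correlation of each model's fitted values with TQCE.  A design
  matrix with condition number above 1e8 raises `CollinearityError`.  No
  multiple-testing correction is applied.
- **Truncation curves** rerun the comparison for test times 10…60 s.  TQCE
  keeps its full-observation value (ratings are not re-collected); SPB/AG
  are re-standardized within each truncated cohort by default, with a flag
  to reuse the full-length μ, σ instead.
- **ICC(2,1)** (two-way random effects, absolute agreement, single
  measure) summarizes interrater reliability; the implementation delegates
  to `pingouin.intraclass_corr` and is unit-tested against a from-scratch
  ANOVA mean-squares decomposition.

## Synthetic data

The generator emulates a sagittal-view bird-dog recording as a stick
figure: trunk horizontal (neck–mid-hip distance L = 200 px in a 1280×720
image at 30 fps — camera parameters are unreported for the task and
configurable), supporting wrist/ankle fixed on the floor line, extended
arm and contralateral leg as collinear segments at a controllable droop
angle below horizontal.

- **Sway** is a mean-reverting AR(1) offset (pole 0.95) on each extended
  keypoint with per-frame step sd `sway_sigma`·L, so the measured D′ scales
  almost linearly with `sway_sigma` (≈1.25·σ for 2-D Gaussian steps) and
  limbs do not random-walk off the body.  Non-extended keypoints are
  static: the indices only read the extended limbs, neck and hip, and
  keeping the normalizer noise-free makes ground-truth links exact.
- **Droop** δ tilts both extended limbs, giving a ≈ −2δ.
- **Fall**: at `fall_time_s` the extended wrist/ankle drop to the floor
  line (elbow/knee halfway); the fall frame is annotated in the metadata.
- **Confidence dropout**: a `dropout_rate` fraction of (frame, keypoint)
  cells get confidence in [0, 0.45) *and* a large position perturbation
  (sd 0.25 L), so failing to mask them visibly corrupts the indices — the
  masking rule is thereby testable.

A cohort (default 34 participants × 2 sides, the task's study design)
draws per-trial sway/droop/fall from log-normal spreads loaded on a latent
per-participant ability (loading 0.7), producing the correlated indices
seen in real cohorts.  The fall-time log-mean 3.14 and log-sd 1.48 are
chosen so that ≈26% of trials reach the 60 s cap and ≈54% last at least
20 s, matching the censoring pattern reported for this task.  Three
simulated raters score a latent quality q — the weighted combination
(0.25, 0.22, 0.69) of z-scored (−log sway), (−droop) and capped true
duration, min-max rescaled to [0, 1] — as
round(clip(1 + 6(q + ε), 1, 7)) with rater noise ε ~ N(0, 0.08).  The
weights mirror the relative importance of balance, antigravity posture and
duration in therapist judgement of the 60 s task.  Seeding uses a
splittable counter scheme (`SeedSequence([master_seed, stream])`), so the
cohort is byte-identical on regeneration and individual trials are
independently reproducible.

What the generator does *not* emulate: detector bias fields, correlated
multi-keypoint failures, camera motion, anatomical joint limits, or
children's compensatory strategies.  Passing tests therefore demonstrate
the correctness and internal consistency of the pipeline and the
qualitative behaviour of the indices, not clinical validity on real video.

## Problem sizes

The test suite runs cohorts of 8–34 participants at 5–30 fps and 2–61 s
per trial; the replicate study of the truncation ordering uses 50 cohorts
of 68 trials at the full 60 s × 30 fps, and parameter recovery uses a
500-trial table-level cohort.  These sizes give stable statistics while
keeping a full run in well under a minute on one core.

## Known limitations

- The heuristic DT mode assumes a camera-aligned floor (horizontal image
  line) and clean supporting-limb detections; annotated mode exists for
  recordings where event frames were marked by inspection.
- Whether the original truncation analysis re-standardized SPB/AG within
  each truncated cohort or reused the 60 s μ, σ is not documented;
  re-standardization is the default here, the frozen-μσ variant is a flag.
- Face/feet keypoints (15–24) are parsed but unused.
- SPB/AG are cohort-relative z-scores; scoring a single trial in isolation
  is deliberately undefined (needs ≥ 2 trials and nonzero variance).
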