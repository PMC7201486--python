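"""The three per-trial indices: moving distance/SPB, limb angles/AG, DT."""
import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from birddog import (
    ScoringConfig,
    TrialParams,
    ag_raw,
    ag_standardize,
    combined_distance,
    duration_time,
    generate_trial,
    limb_angle,
    moving_distance,
    prepare_trial,
    spb_standardize,
    trial_metrics,
)
from birddog.errors import (
    ConstantCohortError,
    DegenerateLimbError,
    MetadataError,
    NoPostureError,
    TooShortError,
)
from birddog.indices import CohortStandardizer, limb_angles
from birddog.preprocess import Trajectory


def traj(xs, ys, kp=0):
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    return Trajectory(keypoint_id=kp, xs=xs, ys=ys, mask=np.ones(len(xs), bool))


class TestMovingDistance:
    def test_stationary_keypoint_is_zero(self):
        assert moving_distance(traj(np.ones(10), np.ones(10)), bl=100.0) == 0.0

    def test_unit_steps(self):
        # 10 steps of 1 px over 11 frames, bl = 100 -> 0.01 body lengths/frame
        xs = np.arange(11, dtype=float)
        assert moving_distance(traj(xs, np.zeros(11)), bl=100.0) == pytest.approx(0.01)

    def test_translation_invariant(self, rng):
        xs, ys = rng.uniform(0, 50, 30), rng.uniform(0, 50, 30)
        base = moving_distance(traj(xs, ys), bl=80.0)
        shifted = moving_distance(traj(xs + 123.4, ys - 56.7), bl=80.0)
        assert shifted == pytest.approx(base, rel=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(TooShortError):
            moving_distance(traj([1.0], [1.0]), bl=10.0)

    @given(seed=st.integers(0, 2**16))
    def test_matches_naive_per_frame_loop(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 60))
        xs, ys = r.uniform(0, 500, n), r.uniform(0, 500, n)
        bl = float(r.uniform(50, 300))
        naive = sum(
            math.hypot(xs[i] - xs[i - 1], ys[i] - ys[i - 1]) for i in range(1, n)
        ) / ((n - 1) * bl)
        assert moving_distance(traj(xs, ys), bl) == pytest.approx(naive, abs=1e-12)


class TestCombinedDistance:
    @pytest.mark.parametrize(
        "ds,expected",
        [((0.01, 0.01, 0.01, 0.01), 0.01), ((0.01, 0.02, 0.03, 0.04), 0.025), ((0, 0, 0, 0), 0.0)],
    )
    def test_mean_of_four(self, ds, expected):
        assert combined_distance(*ds) == pytest.approx(expected)


class TestStandardization:
    def test_spb_hand_oracle(self):
        # s = log(1/D') = (1, 3); mean 2, sample sd sqrt(2) -> z = -+1/sqrt(2)
        spb = spb_standardize([math.exp(-1), math.exp(-3)])
        np.testing.assert_allclose(spb, [-1 / math.sqrt(2), 1 / math.sqrt(2)], atol=1e-12)

    def test_mean_zero_sd_one(self, rng):
        d = rng.uniform(1e-4, 1e-2, 50)
        spb = spb_standardize(d)
        assert np.mean(spb) == pytest.approx(0.0, abs=1e-12)
        assert np.std(spb, ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_zero_d_prime_uses_floor(self):
        spb = spb_standardize([0.0, 0.001, 0.01])
        assert np.isfinite(spb).all()

    def test_spb_rank_reverses_d_prime_rank(self, rng):
        d = rng.uniform(1e-4, 1e-2, 30)
        spb = spb_standardize(d)
        assert np.array_equal(np.argsort(spb), np.argsort(-d))

    def test_ag_hand_oracle(self):
        ag = ag_standardize([-10.0, -30.0])
        np.testing.assert_allclose(ag, [1 / math.sqrt(2), -1 / math.sqrt(2)], atol=1e-12)

    def test_ag_strictly_increasing_in_a(self, rng):
        a = -rng.uniform(0, 60, 30)
        ag = ag_standardize(a)
        assert np.array_equal(np.argsort(ag), np.argsort(a))

    def test_constant_cohort_raises(self):
        with pytest.raises(ConstantCohortError):
            ag_standardize([-10.0, -10.0, -10.0])

    def test_standardizer_round_trip(self):
        std = CohortStandardizer.fit([1.0, 2.0, 3.0])
        np.testing.assert_allclose(std([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])


class TestLimbAngle:
    @pytest.mark.parametrize(
        "origin,tip,expected",
        [
            ((0, 0), (100, 0), 0.0),          # horizontal limb
            ((0, 0), (100, 100), 45.0),       # drooping
            ((0, 0), (100, -100), 45.0),      # raised: same angle by absolute value
            ((0, 0), (100, 57.735), 30.0),    # arctangent oracle
            ((0, 0), (0, 50), 90.0),          # vertical limb
        ],
    )
    def test_examples(self, origin, tip, expected):
        assert limb_angle(origin, tip) == pytest.approx(expected, abs=1e-3)

    def test_degenerate_limb_raises(self):
        with pytest.raises(DegenerateLimbError):
            limb_angle((5.0, 5.0), (5.0, 5.0))

    def test_vectorized_names_frame(self):
        with pytest.raises(DegenerateLimbError, match="frame 1"):
            limb_angles([0.0, 1.0], [0.0, 1.0], [1.0, 1.0], [0.0, 1.0])


class TestAgRaw:
    def _limb_trajs(self, arm_deg, leg_deg, n=5):
        neck = traj(np.full(n, 200.0), np.full(n, 100.0))
        hip = traj(np.full(n, 100.0), np.full(n, 100.0))
        arm = math.radians(arm_deg)
        leg = math.radians(leg_deg)
        wrist = traj(neck.xs + 100 * math.cos(arm), neck.ys + 100 * math.sin(arm))
        elbow = traj(neck.xs + 50 * math.cos(arm), neck.ys + 50 * math.sin(arm))
        ankle = traj(hip.xs - 100 * math.cos(leg), hip.ys + 100 * math.sin(leg))
        knee = traj(hip.xs - 50 * math.cos(leg), hip.ys + 50 * math.sin(leg))
        return neck, hip, wrist, elbow, ankle, knee

    def test_horizontal_limbs_score_zero(self):
        assert ag_raw(*self._limb_trajs(0, 0)) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("arm_deg", [30.0, -30.0])  # drooping or raised
    def test_droop_and_raise_equivalent(self, arm_deg):
        assert ag_raw(*self._limb_trajs(arm_deg, 0)) == pytest.approx(-30.0, abs=1e-6)

    def test_matches_naive_per_frame_loop(self, rng):
        n = 40
        neck = traj(rng.uniform(150, 250, n), rng.uniform(90, 110, n))
        hip = traj(rng.uniform(50, 150, n), rng.uniform(90, 110, n))
        wrist = traj(neck.xs + rng.uniform(50, 150, n), neck.ys + rng.uniform(-80, 80, n))
        elbow = traj(neck.xs + rng.uniform(20, 80, n), neck.ys + rng.uniform(-40, 40, n))
        ankle = traj(hip.xs - rng.uniform(50, 150, n), hip.ys + rng.uniform(-80, 80, n))
        knee = traj(hip.xs - rng.uniform(20, 80, n), hip.ys + rng.uniform(-40, 40, n))
        total = 0.0
        for i in range(n):
            mw = ((wrist.xs[i] + elbow.xs[i]) / 2, (wrist.ys[i] + elbow.ys[i]) / 2)
            ml = ((ankle.xs[i] + knee.xs[i]) / 2, (ankle.ys[i] + knee.ys[i]) / 2)
            phi = limb_angle((neck.xs[i], neck.ys[i]), mw)
            theta = limb_angle((hip.xs[i], hip.ys[i]), ml)
            total += abs(phi) + abs(theta)
        naive = -total / n
        got = ag_raw(neck, hip, wrist, elbow, ankle, knee)
        assert got == pytest.approx(naive, abs=1e-12)

    def test_scale_and_translation_invariant(self):
        base = ag_raw(*self._limb_trajs(20, 10))
        scaled = [
            Trajectory(t.keypoint_id, t.xs * 3 + 7, t.ys * 3 - 4, t.mask)
            for t in self._limb_trajs(20, 10)
        ]
        assert ag_raw(*scaled) == pytest.approx(base, abs=1e-9)


class TestDurationTime:
    def _trial(self, fall_time_s, duration_s=70.0, fps=30.0):
        params = TrialParams(
            sway_sigma=0.002, droop_deg=8.0, fall_time_s=fall_time_s,
            dropout_rate=0.0, fps=fps, duration_s=duration_s, seed=2,
        )
        return generate_trial(params)[0]

    def test_capped_at_60_when_posture_held(self):
        rec = self._trial(None, duration_s=70.0)
        assert duration_time(rec) == 60.0

    def test_simple_arithmetic(self):
        rec = self._trial(10.0, duration_s=20.0)
        assert rec.annotated_fall_frame == 300
        assert duration_time(rec) == pytest.approx(10.0)

    def test_fall_equals_start_gives_zero(self):
        rec = self._trial(None, duration_s=20.0)
        rec.annotated_start_frame = 5
        rec.annotated_fall_frame = 5
        assert duration_time(rec) == 0.0

    def test_annotated_fall_before_start_raises(self):
        rec = self._trial(None, duration_s=20.0)
        rec.annotated_start_frame = 10
        rec.annotated_fall_frame = 3
        with pytest.raises(MetadataError):
            prepare_trial(rec)

    def test_heuristic_agrees_with_annotation(self):
        rec = self._trial(10.0, duration_s=20.0)
        cfg = ScoringConfig(dt_mode="heuristic")
        assert duration_time(rec, config=cfg) == pytest.approx(10.0, abs=0.5)

    def test_heuristic_no_fall_is_capped_recording_length(self):
        rec = self._trial(None, duration_s=20.0)
        cfg = ScoringConfig(dt_mode="heuristic")
        assert duration_time(rec, config=cfg) == pytest.approx(20.0, abs=0.5)

    def test_heuristic_posture_never_achieved(self):
        rec = generate_trial(
            TrialParams(droop_deg=60.0, sway_sigma=0.001, dropout_rate=0.0,
                        duration_s=10.0, seed=3)
        )[0]
        with pytest.raises(NoPostureError):
            prepare_trial(rec, ScoringConfig(dt_mode="heuristic"))

    @given(
        fall=st.one_of(st.none(), st.floats(0.2, 100.0)),
        duration=st.floats(5.0, 90.0),
    )
    def test_dt_always_in_unit_interval_of_cap(self, fall, duration):
        rec = generate_trial(
            TrialParams(fall_time_s=fall, duration_s=duration, fps=10.0,
                        dropout_rate=0.0, seed=1)
        )[0]
        dt = duration_time(rec)
        assert 0.0 <= dt <= 60.0


class TestTrialMetrics:
    def test_truncation_caps_dt_and_shrinks_window(self, still_trial):
        rec, _ = still_trial
        prep = prepare_trial(rec)
        full = trial_metrics(prep)
        short = trial_metrics(prep, test_time_s=5.0)
        assert full["DT"] == pytest.approx(10.0)
        assert short["DT"] == pytest.approx(5.0)
        # indices genuinely recomputed, not merely capped
        assert short["D_prime"] != pytest.approx(full["D_prime"], rel=1e-9)

    def test_window_after_fall_discarded(self):
        params = TrialParams(sway_sigma=0.002, droop_deg=5.0, fall_time_s=4.0,
                             dropout_rate=0.0, fps=30.0, duration_s=10.0, seed=9)
        rec, _ = generate_trial(params)
        prep = prepare_trial(rec)
        m = trial_metrics(prep)
        # after the fall the limbs lie on the floor (angle >> droop); the
        # window must exclude those frames
        assert m["a_raw"] == pytest.approx(-10.0, abs=3.0)
        assert m["DT"] == pytest.approx(4.0)
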