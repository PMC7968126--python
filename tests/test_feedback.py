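"""Step-length estimation, target setting, scoring, session replay."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from exogait import STUDY_COHORT, SessionConfig
from exogait.feedback import (
    compute_target,
    estimate_step_length,
    run_session,
    steps_from_events,
)
from exogait.events import detect_events_fsr, merge_events
from exogait.synth import GaitGenConfig, generate_trial

from conftest import noiseless_config


def offline_rescore(steps, target, update_every=2):
    """Brute-force offline re-scoring of an estimated step list:
    independent of the streaming state machine."""
    score = 0
    last = {"left": None, "right": None}
    done = 0
    for n, rec in enumerate(steps, start=1):
        last[rec.side] = rec.est_length_m
        strides = n // 2
        if strides > done and strides % update_every == 0:
            done = strides
            if (
                last["left"] is not None
                and last["right"] is not None
                and 0.5 * (last["left"] + last["right"]) > target
            ):
                score += 1
    return score


class TestEstimator:
    @pytest.mark.parametrize(
        "speed,t0,t1,expected",
        [
            (1.05, 0.0, 0.5, 0.525),   # P2's preferred belt speed
            (1.0, 1.0, 1.6, 0.600),
            (0.50, 2.0, 2.7, 0.35),    # P5's speed, 0.7 s step time
        ],
    )
    def test_product_rule(self, speed, t0, t1, expected):
        assert estimate_step_length(speed, t0, t1) == pytest.approx(
            expected, abs=1e-12
        )

    def test_out_of_order_events_rejected(self):
        with pytest.raises(ValueError, match="out-of-order"):
            estimate_step_length(1.0, 2.0, 2.0)
        with pytest.raises(ValueError, match="positive"):
            estimate_step_length(0.0, 1.0, 2.0)

    @given(
        speed=st.floats(0.3, 1.5),
        dt=st.floats(0.3, 1.0),
        n=st.integers(4, 50),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_telescoping_identity(self, speed, dt, n):
        """Constant cadence: every estimate equals speed*dt and the sum
        telescopes to speed x elapsed time."""
        times = np.arange(n) * dt
        ests = [
            estimate_step_length(speed, a, b)
            for a, b in zip(times, times[1:])
        ]
        np.testing.assert_allclose(ests, speed * dt, rtol=1e-12)
        assert sum(ests) == pytest.approx(speed * (times[-1] - times[0]),
                                          rel=1e-9)


class TestTarget:
    def test_ten_percent_rule(self):
        assert compute_target(0.50, 1.10) == pytest.approx(0.55, abs=1e-12)

    def test_identity_factor(self):
        assert compute_target(0.50, 1.0) == 0.50

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            compute_target(0.0)

    def test_target_from_simulated_baseline(self, noiseless_trial):
        """Target computed from an estimated baseline equals 1.10x the
        ground-truth mean within the estimator error (zero here)."""
        tr = noiseless_trial
        per_side = [
            detect_events_fsr(tr.t_fsr, tr.fsr[s], s) for s in ("left", "right")
        ]
        steps = steps_from_events(merge_events(*per_side), tr.walking_speed)
        baseline = float(np.mean([s.est_length_m for s in steps]))
        truth_mean = float(np.nanmean(tr.truth["true_step_length_m"]))
        assert compute_target(baseline) == pytest.approx(
            1.10 * truth_mean, abs=1e-9
        )


class TestScoringRule:
    @staticmethod
    def _session(trial, baseline):
        cfg = SessionConfig(
            walking_speed=trial.walking_speed, baseline_mean_step_m=baseline
        )
        return run_session(trial, cfg), cfg

    def test_pair_above_target_scores_one_point(self, noiseless_trial):
        """Steps at 0.35 m with target below them: every refresh scores."""
        (steps, timeline), cfg = self._session(noiseless_trial, 0.35 / 1.12)
        final = timeline[-1]
        refreshes = sum(st_.refreshed for st_ in timeline)
        assert final.score == refreshes
        assert refreshes == len(steps) // (2 * cfg.update_every_strides)

    def test_steps_equal_to_target_never_score(self):
        """The rule is strict inequality: exactly-on-target steps earn
        nothing (exact-arithmetic event list: 0.5 s cadence at 1 m/s,
        target factor 1, so every estimate equals the 0.5 m target)."""
        from exogait.events import FootContactEvent
        from exogait.feedback import (
            BiofeedbackState, step_feedback_update, steps_from_events,
        )

        events = [
            FootContactEvent("left" if i % 2 == 0 else "right",
                             0.5 * i, 0.5 * i + 0.4)
            for i in range(20)
        ]
        steps = steps_from_events(events, speed=1.0)
        assert all(s.est_length_m == 0.5 for s in steps)
        cfg = SessionConfig(walking_speed=1.0, baseline_mean_step_m=0.5,
                            target_factor=1.0)
        state = BiofeedbackState(time_s=0.0, n_steps=0, target_m=cfg.target_m)
        lh, rh = [], []
        for s in steps:
            (lh if s.side == "left" else rh).append(s.est_length_m)
            state = step_feedback_update(state, cfg, s, lh, rh)
            assert not state.hit
        assert state.score == 0

    def test_single_refresh_pair_rule(self):
        """One refresh with last (L, R) = (0.60, 0.56) against a 0.55 m
        target scores exactly one point."""
        from exogait.events import FootContactEvent
        from exogait.feedback import (
            BiofeedbackState, step_feedback_update, steps_from_events,
        )

        # speed 1.0; intervals chosen so estimates are .5,.5,.60,.56
        times = [0.0, 0.5, 1.0, 1.60, 2.16]
        sides = ["left", "right", "left", "right", "left"]
        events = [
            FootContactEvent(s, t, t + 0.3) for s, t in zip(sides, times)
        ]
        steps = steps_from_events(events, speed=1.0)
        cfg = SessionConfig(walking_speed=1.0, baseline_mean_step_m=0.5)
        state = BiofeedbackState(time_s=0.0, n_steps=0, target_m=cfg.target_m)
        lh, rh = [], []
        for s in steps:
            (lh if s.side == "left" else rh).append(s.est_length_m)
            state = step_feedback_update(state, cfg, s, lh, rh)
        # refresh occurred at step 4 with pair mean 0.58 > 0.55
        assert state.score == 1

    def test_score_monotone_nondecreasing(self, jitter_trial):
        (_, timeline), _ = self._session(jitter_trial, 0.5)
        scores = [st_.score for st_ in timeline]
        assert all(a <= b for a, b in zip(scores, scores[1:]))
        assert all(st_.score >= 0 for st_ in timeline)

    def test_refresh_cadence_every_two_strides(self, noiseless_trial):
        (_, timeline), _ = self._session(noiseless_trial, 0.30)
        refreshed_at = [st_.n_steps for st_ in timeline if st_.refreshed]
        assert refreshed_at == [n for n in refreshed_at if (n // 2) % 2 == 0]
        # consecutive refreshes are 2 strides (4 steps) apart
        assert all(b - a == 4 for a, b in zip(refreshed_at, refreshed_at[1:]))


class TestSessionReplay:
    def test_noiseless_estimates_equal_truth(self, noiseless_trial):
        tr = noiseless_trial
        cfg = SessionConfig(walking_speed=tr.walking_speed,
                            baseline_mean_step_m=0.35)
        steps, _ = run_session(tr, cfg)
        truth = tr.truth["true_step_length_m"].to_numpy()[1:]
        est = np.array([s.est_length_m for s in steps])
        n = min(len(est), len(truth))
        np.testing.assert_allclose(est[:n], truth[:n], rtol=0, atol=1e-12)

    def test_replay_is_deterministic(self, jitter_trial):
        cfg = SessionConfig(walking_speed=jitter_trial.walking_speed,
                            baseline_mean_step_m=0.5)
        s1, t1 = run_session(jitter_trial, cfg)
        s2, t2 = run_session(jitter_trial, cfg)
        assert s1 == s2
        assert [x.score for x in t1] == [x.score for x in t2]

    def test_matches_offline_rescoring_oracle(self):
        """Streaming score equals the brute-force offline re-score of
        the same detected step list across seeded noisy sessions."""
        for seed in range(10):
            cfg = noiseless_config(
                "P1", step_time_cv=0.05, contact_jitter_sd_s=0.005,
                fsr_noise_sd=0.02, duration_s=25.0, seed=seed,
            )
            trial = generate_trial(cfg)
            scfg = SessionConfig(
                walking_speed=trial.walking_speed,
                baseline_mean_step_m=0.5,
            )
            steps, timeline = run_session(trial, scfg)
            assert timeline[-1].score == offline_rescore(steps, scfg.target_m)

    def test_too_few_steps_invalid(self):
        cfg = noiseless_config("P1", duration_s=3.0)
        trial = generate_trial(cfg)
        scfg = SessionConfig(walking_speed=1.0, baseline_mean_step_m=0.5)
        with pytest.raises(ValueError, match="session invalid|steps"):
            run_session(trial, scfg)
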