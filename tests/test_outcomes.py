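"""Outcome pipeline: marker step length, support moment, positive
power, condition summaries."""

import dataclasses

import numpy as np
import pytest

from exogait.events import FootContactEvent, detect_events_force
from exogait.outcomes import (
    avg_positive_power,
    paired_step_series,
    step_length_from_markers,
    summarize_condition,
    support_moment,
)


def rectangle_rule_average(f, t0, t1, n=100_000):
    """Independent quadrature oracle: midpoint rectangle rule at high
    resolution."""
    ts = t0 + (np.arange(n) + 0.5) * (t1 - t0) / n
    return float(np.mean(np.clip(f(ts), 0.0, None)))


class TestMarkerStepLength:
    def test_noiseless_trial_exact(self, noiseless_trial):
        tr = noiseless_trial
        events = [
            e for s in ("left", "right")
            for e in detect_events_force(tr.t_force, tr.grf[s], s)
        ]
        out = step_length_from_markers(
            tr.t_marker, tr.heel["left"], tr.heel["right"], events
        )
        lengths = np.array([L for _, _, L in out])
        np.testing.assert_allclose(lengths[1:], 0.35, rtol=0, atol=1e-9)

    def test_marker_noise_error_bound(self, jitter_trial):
        """With 2 mm i.i.d. marker noise the per-step error of the heel
        separation is below 2*sqrt(2) mm on average (~200 steps)."""
        tr = jitter_trial
        events = [
            e for s in ("left", "right")
            for e in detect_events_force(tr.t_force, tr.grf[s], s)
        ]
        out = step_length_from_markers(
            tr.t_marker, tr.heel["left"], tr.heel["right"], events
        )
        truth = tr.truth["true_step_length_m"].to_numpy()
        n = min(len(out), len(truth))
        err = np.array([L for _, _, L in out[:n]])[1:] - truth[1:n]
        assert len(err) > 150
        assert np.abs(err).mean() <= 2 * np.sqrt(2) * 0.002 + 5e-4

    def test_coincident_heels_give_zero(self):
        t = np.arange(120) / 120.0
        x = -np.linspace(0, 1, 120)
        ev = [FootContactEvent("left", 0.5, 0.9)]
        out = step_length_from_markers(t, x, x.copy(), ev)
        assert out[0][2] == 0.0

    def test_event_outside_record_skipped_with_warning(self):
        t = np.arange(120) / 120.0
        x = np.zeros(120)
        ev = [FootContactEvent("left", 5.0, 5.4)]
        with pytest.warns(UserWarning, match="outside"):
            out = step_length_from_markers(t, x, x, ev)
        assert out == []


class TestSupportMoment:
    def test_pointwise_sum(self):
        out = support_moment([0.7], [0.3], [0.5])
        assert out[0] == pytest.approx(1.5, abs=1e-12)

    def test_additive_identity(self, rng):
        a, k = rng.standard_normal(100), rng.standard_normal(100)
        np.testing.assert_array_equal(
            support_moment(a, k, np.zeros(100)), a + k
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            support_moment(np.zeros(5), np.zeros(6), np.zeros(5))

    def test_peak_of_sum_bounded_by_sum_of_peaks(self, condition_set):
        tr = condition_set["baseline"]
        for s in ("left", "right"):
            total = support_moment(
                tr.moments[("ankle", s)],
                tr.moments[("knee", s)],
                tr.moments[("hip", s)],
            )
            assert total.max() <= (
                tr.moments[("ankle", s)].max()
                + tr.moments[("knee", s)].max()
                + tr.moments[("hip", s)].max()
            ) + 1e-12


class TestAveragePositivePower:
    def test_constant_power(self):
        t = np.arange(0, 2, 1e-3)
        p = np.full_like(t, 2.0)
        assert avg_positive_power(t, p, (0.5, 1.0)) == pytest.approx(2.0, rel=1e-9)

    def test_entirely_negative_power_is_zero(self):
        t = np.arange(0, 2, 1e-3)
        assert avg_positive_power(t, -np.ones_like(t), (0.5, 1.0)) == 0.0

    def test_sine_positive_lobe_closed_form(self):
        """Average positive part of sin(2*pi*t) over one period is
        1/pi."""
        t = np.arange(0, 1.0001, 1e-4)
        p = np.sin(2 * np.pi * t)
        got = avg_positive_power(t, p, (0.0, 1.0))
        assert got == pytest.approx(1 / np.pi, rel=5e-3)

    def test_agrees_with_rectangle_oracle(self):
        f = lambda ts: np.sin(2 * np.pi * ts) + 0.3 * np.cos(6 * np.pi * ts)
        t = np.arange(0, 2, 1 / 980.0)
        got = avg_positive_power(t, f(t), (0.2, 1.7))
        want = rectangle_rule_average(f, 0.2, 1.7)
        assert got == pytest.approx(want, rel=2e-3)

    def test_zero_length_window_rejected(self):
        t = np.arange(100) / 100.0
        with pytest.raises(ValueError, match="stance"):
            avg_positive_power(t, np.ones(100), (0.5, 0.5))


class TestConditionSummary:
    def test_unpowered_total_equals_biological(self, condition_set):
        s = summarize_condition(condition_set["baseline"])
        t, b = s["total"].as_dict(), s["biological"].as_dict()
        t.pop("variant"), b.pop("variant")
        assert t == b

    def test_powered_total_exceeds_biological_at_ankle(self, condition_set):
        s = summarize_condition(condition_set["assist"])
        assert (
            s["total"].peak_ankle_moment_nmkg
            > s["biological"].peak_ankle_moment_nmkg
        )
        assert (
            s["total"].avg_pos_power_summed_wkg
            >= s["biological"].avg_pos_power_summed_wkg
        )

    def test_identical_cycles_summary_equals_single_cycle(self, noiseless_trial):
        """Zero-variability gait: the windowed average equals any single
        cycle's outcomes."""
        # interior windows: zero-phase IIR filtering leaves edge
        # transients within a few seconds of the record boundaries
        full = summarize_condition(noiseless_trial,
                                   window_s=(10.0, 26.0))["total"]
        tr = noiseless_trial
        own = tr.truth_events("left")
        c0 = float(own.iloc[10]["contact_time_s"])
        c1 = float(own.iloc[12]["contact_time_s"])
        one = summarize_condition(tr, window_s=(c0 - 0.05, c1 + 0.05),
                                  min_cycles=1)["total"]
        for k in ("peak_pf_angle_deg", "peak_ankle_moment_nmkg",
                  "peak_support_moment_nmkg", "avg_pos_power_summed_wkg"):
            assert getattr(one, k) == pytest.approx(getattr(full, k), rel=1e-6)

    def test_window_invariance_for_stationary_gait(self, noiseless_trial):
        a = summarize_condition(noiseless_trial, window_s=(10.0, 18.0))["total"]
        b = summarize_condition(noiseless_trial, window_s=(18.0, 26.0))["total"]
        for k, v in a.as_dict().items():
            if isinstance(v, float):
                assert v == pytest.approx(getattr(b, k), rel=1e-6, abs=1e-9)

    def test_mass_normalization_linearity(self, condition_set):
        """Scaling the recorded mass by k with raw traces fixed scales
        every mass-normalized outcome by 1/k."""
        tr = condition_set["baseline"]
        prof2 = dataclasses.replace(tr.config.profile, mass_kg=2 * tr.mass_kg)
        cfg2 = dataclasses.replace(tr.config, profile=prof2)
        tr2 = dataclasses.replace(tr, config=cfg2)
        a = summarize_condition(tr)["total"]
        b = summarize_condition(tr2)["total"]
        for k in a.as_dict():
            if k.endswith(("_nmkg", "_wkg")):
                assert getattr(b, k) == pytest.approx(
                    0.5 * getattr(a, k), rel=1e-12
                )
            elif k.endswith("_deg") or k == "step_length_m":
                assert getattr(b, k) == getattr(a, k)

    def test_too_few_cycles_rejected(self, noiseless_trial):
        with pytest.raises(ValueError, match="cycles"):
            summarize_condition(noiseless_trial, window_s=(5.0, 7.0))

    def test_two_cycle_toy_trace_matches_hand_computation(self):
        """Brute-force mini-oracle: two identical triangular power
        cycles computed by hand equal the pipeline's stance average."""
        fs = 1000.0
        t = np.arange(int(fs * 2.0)) / fs
        # power: triangle 0 -> 4 W -> 0 over each 0.5 s stance
        p = np.zeros_like(t)
        for c in (0.1, 1.1):
            mask = (t >= c) & (t <= c + 0.5)
            u = (t[mask] - c) / 0.5
            p[mask] = 4.0 * (1 - np.abs(2 * u - 1))
        for c in (0.1, 1.1):
            got = avg_positive_power(t, p, (c, c + 0.5))
            assert got == pytest.approx(2.0, abs=1e-9)  # mean of triangle


class TestPairedValidationSeries:
    def test_noiseless_pairs_are_identical(self, noiseless_trial):
        est, meas = paired_step_series(noiseless_trial)
        assert len(est) > 30
        np.testing.assert_allclose(est, meas, rtol=0, atol=1e-9)

    def test_jittered_pairs_track_truth_scale(self, jitter_trial):
        est, meas = paired_step_series(jitter_trial)
        assert len(est) > 150
        assert np.corrcoef(est, meas)[0, 1] > 0.5
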