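"""Session summary statistics against hand computations and brute force."""

import math

import numpy as np
import pytest

from pvtsim import (DeviceModel, ProtocolConfig, Session, Trial,
                    count_lapses, mean_speed, rt_divergence, run_session,
                    summarize, tail_means)


class TestCountLapses:
    def test_strictly_greater_than_threshold(self):
        assert count_lapses([400.0, 501.0, 600.0], 500.0) == 2
        assert count_lapses([500.0], 500.0) == 0  # boundary excluded

    def test_empty_list(self):
        assert count_lapses([], 500.0) == 0

    def test_matches_brute_force_scan(self, satiated, rng):
        state = satiated.alertness(0.0, satiated.c_phase_h + 6.0)
        rts = satiated.sample_rts(state, rng, 10_000)
        brute = sum(1 for r in rts if r > 290.0)
        assert count_lapses(rts, 290.0) == brute


class TestMeanSpeed:
    def test_hand_examples(self):
        assert mean_speed([100.0, 200.0]) == pytest.approx(7.5)
        assert mean_speed([250.0]) == pytest.approx(4.0)

    def test_matches_brute_force_reciprocal_mean(self, rng):
        rts = rng.uniform(150.0, 900.0, size=500)
        brute = sum(1000.0 / r for r in rts) / len(rts)
        assert mean_speed(rts) == pytest.approx(brute, abs=1e-12)

    def test_zero_or_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_speed([])
        with pytest.raises(ValueError):
            mean_speed([100.0, 0.0])


class TestTailMeans:
    def test_ceil_rule_k2_of_20(self):
        rts = [100.0 * k for k in range(1, 21)]  # 100..2000
        fastest, slowest = tail_means(rts)
        assert fastest == pytest.approx(150.0)   # mean of 100, 200
        assert slowest == pytest.approx(1950.0)  # mean of 1900, 2000

    def test_degenerate_cases(self):
        assert tail_means([300.0] * 7) == (300.0, 300.0)
        assert tail_means([412.0]) == (412.0, 412.0)  # k = ceil(0.1) = 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tail_means([])


class TestRtDivergence:
    def test_identical_lists_give_zero(self):
        rts = [210.0, 340.0, 550.0, 212.0]
        assert rt_divergence(rts, rts) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric(self, rng):
        a = rng.uniform(150.0, 800.0, 60)
        b = rng.uniform(150.0, 800.0, 45)
        assert rt_divergence(a, b) == pytest.approx(rt_divergence(b, a))

    def test_disjoint_supports_reach_upper_bound(self):
        assert rt_divergence([210.0] * 10, [810.0] * 10) == pytest.approx(1.0)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            a = rng.uniform(50.0, 1500.0, 30)
            b = rng.uniform(50.0, 1500.0, 30)
            assert 0.0 <= rt_divergence(a, b) <= 1.0 + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rt_divergence([], [100.0])


def _hand_session(trials, config=None):
    return Session(study_id="t", subject_id="s", start_time="1970",
                   config=config or ProtocolConfig(),
                   device=DeviceModel.reference(), trials=tuple(trials),
                   rng_seed=0)


class TestSummarize:
    def _five_trial_session(self):
        trials = (
            Trial(0, 4.0, "valid", 4.0, 4.2, 200.0, 200.0),
            Trial(1, 5.0, "valid", 10.0, 10.6, 600.0, 600.0),
            Trial(2, 3.0, "false_start", None, 12.0, None, None),
            Trial(3, 6.0, "valid", 20.0, 23.2, 3200.0, 3200.0),
            Trial(4, 2.0, "no_response", 30.0, None, None, None),
        )
        return _hand_session(trials)

    def test_matches_hand_computation(self):
        st = summarize(self._five_trial_session())
        assert (st.n_valid, st.n_false_start, st.n_no_response) == (3, 1, 1)
        assert st.mean_rt_ms == pytest.approx((200 + 600 + 3200) / 3)
        assert st.mean_speed_per_s == pytest.approx(
            (1000 / 200 + 1000 / 600 + 1000 / 3200) / 3)
        assert st.minor_lapses == 2   # 600 and 3200 exceed 500
        assert st.major_lapses == 1   # 3200 exceeds 3000
        assert st.fastest10_mean_ms == pytest.approx(200.0)  # k = 1
        assert st.slowest10_mean_ms == pytest.approx(3200.0)
        assert math.isnan(st.divergence)  # no baseline supplied

    def test_minor_at_least_major_and_tail_ordering(
            self, tsd_subject, gaming_device):
        session = run_session(tsd_subject, gaming_device,
                              ProtocolConfig(session_duration_s=600.0),
                              wake_time_offset_h=50.0, seed=13)
        st = summarize(session)
        assert st.minor_lapses >= st.major_lapses
        assert st.fastest10_mean_ms <= st.mean_rt_ms <= st.slowest10_mean_ms

    def test_all_false_starts_leaves_rt_fields_undefined(self):
        trials = tuple(
            Trial(k, 3.0, "false_start", None, float(k + 1), None, None)
            for k in range(4))
        st = summarize(_hand_session(trials))
        assert st.n_valid == 0 and st.n_false_start == 4
        assert math.isnan(st.mean_rt_ms) and math.isnan(st.fastest10_mean_ms)

    def test_invariant_to_trial_order(self):
        session = self._five_trial_session()
        shuffled = _hand_session(tuple(reversed(session.trials)))
        a, b = summarize(session), summarize(shuffled)
        assert (a.mean_rt_ms, a.minor_lapses, a.fastest10_mean_ms) == (
            b.mean_rt_ms, b.minor_lapses, b.fastest10_mean_ms)

    def test_true_rt_flag_switches_basis(self, satiated, standard_device):
        session = run_session(satiated, standard_device,
                              ProtocolConfig(session_duration_s=300.0),
                              seed=21)
        recorded = summarize(session).mean_rt_ms
        true = summarize(session, use_true_rts=True).mean_rt_ms
        assert recorded > true  # device delay right-shifts recorded RTs

    def test_divergence_against_baseline_session(self, satiated,
                                                 reference_device):
        cfg = ProtocolConfig(session_duration_s=300.0)
        base = run_session(satiated, reference_device, cfg, seed=1)
        other = run_session(satiated, reference_device, cfg, seed=2)
        st = summarize(other, baseline_rts=base.recorded_rts())
        assert 0.0 <= st.divergence <= 1.0


class TestScalingProperties:
    def test_scaling_up_never_decreases_slow_tail_or_lapses(self, rng):
        rts = rng.uniform(150.0, 900.0, 80)
        scaled = 1.7 * rts
        assert tail_means(scaled)[1] >= tail_means(rts)[1]
        for thr in (300.0, 500.0, 800.0):
            assert count_lapses(scaled, thr) >= count_lapses(rts, thr)
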