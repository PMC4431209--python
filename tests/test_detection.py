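import itertools
import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vitalguard as vg
from vitalguard.detection import (VERDICT_FALSE_ALARM, VERDICT_NORMAL,
                                  VERDICT_TRUE_ALARM, ErrorRecord,
                                  PipelineConfig, ThresholdState,
                                  compute_error, flag_parameter,
                                  majority_vote, run_pipeline,
                                  update_threshold)
from vitalguard.synthetic_data import as_labeled


class TestUpdateThreshold:
    def test_zero_variance_window(self):
        st_ = ThresholdState(parameter="HR", w_t=30)
        for _ in range(30):
            update_threshold(st_, 80.0)
        assert st_.s_d == 0.0
        assert st_.t_d == 0.0

    def test_known_buffer_sd(self):
        # oracle: direct sample-SD formula on [2,4,4,4,5,5,7,9]
        st_ = ThresholdState(parameter="HR", w_t=8)
        for v in [2, 4, 4, 4, 5, 5, 7, 9]:
            update_threshold(st_, float(v))
        expected = statistics.stdev([2, 4, 4, 4, 5, 5, 7, 9])
        assert st_.s_d == pytest.approx(expected, rel=1e-12)
        assert st_.s_d == pytest.approx(2.1381, abs=1e-4)
        assert st_.t_d == st_.s_d  # k_mult = 1

    def test_fifo_eviction(self):
        st_ = ThresholdState(parameter="HR", w_t=5)
        for v in range(5):
            update_threshold(st_, float(v))
        update_threshold(st_, 99.0)
        assert len(st_.buffer) == 5
        assert list(st_.buffer) == [1.0, 2.0, 3.0, 4.0, 99.0]

    def test_non_finite_rejected_state_unchanged(self):
        st_ = ThresholdState(parameter="HR", w_t=5)
        for v in (1.0, 2.0, 3.0):
            update_threshold(st_, v)
        before = (list(st_.buffer), st_.s_d, st_.t_d)
        update_threshold(st_, math.nan)
        update_threshold(st_, math.inf)
        assert (list(st_.buffer), st_.s_d, st_.t_d) == before

    def test_k_mult_scales_threshold(self):
        st_ = ThresholdState(parameter="HR", w_t=4, k_mult=2.5)
        for v in (1.0, 2.0, 3.0, 4.0):
            update_threshold(st_, v)
        assert st_.t_d == pytest.approx(2.5 * st_.s_d, rel=1e-15)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(values=st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30))
    def test_sd_matches_independent_formula(self, values):
        st_ = ThresholdState(parameter="x", w_t=len(values))
        for v in values:
            update_threshold(st_, v)
        mean = sum(values) / len(values)
        var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
        assert st_.s_d == pytest.approx(math.sqrt(var),
                                        rel=1e-12, abs=1e-12)


class TestComputeError:
    def test_basic_residual_and_percent(self):
        residual, pct = compute_error(100.0, 90.0)
        assert residual == 10.0
        assert pct == pytest.approx(10.0)

    def test_identity(self):
        residual, pct = compute_error(80.0, 80.0)
        assert residual == 0.0
        assert pct == 0.0

    def test_zero_actual_percent_missing(self):
        residual, pct = compute_error(0.0, 5.0)
        assert residual == 5.0
        assert math.isnan(pct)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            compute_error(math.nan, 1.0)


class TestFlagParameter:
    @pytest.mark.parametrize("residual,t_d,expected", [
        (10.0, 2.1, 1),
        (0.0, 0.0, 0),     # strict boundary
        (2.1, 2.1, 0),     # tie is not a flag
        (2.1000001, 2.1, 1),
    ])
    def test_strict_threshold(self, residual, t_d, expected):
        state = ThresholdState(parameter="HR", w_t=2)
        state.t_d = t_d
        err = ErrorRecord(parameter="HR", t=0, residual=residual,
                          percent_error=0.0)
        assert flag_parameter(err, state) == expected


class TestMajorityVote:
    @pytest.mark.parametrize("flags,expected", [
        ([1, 1, 1, 0, 0], VERDICT_TRUE_ALARM),    # 3 > 2.5
        ([1, 1, 0, 0, 0], VERDICT_FALSE_ALARM),
        ([0, 0, 0, 0, 0], VERDICT_NORMAL),
        ([1, 1, 0, 0], VERDICT_FALSE_ALARM),      # even tie, conservative
        ([1], VERDICT_TRUE_ALARM),
        ([0], VERDICT_NORMAL),
    ])
    def test_examples(self, flags, expected):
        assert majority_vote(flags) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])

    def test_exhaustive_against_count_comparison(self):
        # brute-force oracle over all flag vectors, n = 1..8
        for n in range(1, 9):
            for flags in itertools.product((0, 1), repeat=n):
                y = sum(flags)
                if y == 0:
                    want = VERDICT_NORMAL
                elif 2 * y > n:
                    want = VERDICT_TRUE_ALARM
                else:
                    want = VERDICT_FALSE_ALARM
                assert majority_vote(list(flags)) == want


class TestRunPipeline:
    def test_constant_series_all_normal(self, constant_series):
        decisions = run_pipeline(constant_series)
        assert len(decisions) == 30  # 60 samples, warm-up 30
        assert all(d.verdict == VERDICT_NORMAL for d in decisions)

    def test_single_fault_is_false_alarm(self):
        # hand-traceable fixture: constant vitals, one 50% HR fault.
        # thresholds are exactly 0, so only the faulted parameter flags
        values = np.tile([85.0, 80.0, 80.0, 16.0, 97.5], (44, 1))
        s = vg.VitalSeries(
            parameter_names=["ABPmean", "HR", "Pulse", "Respiration",
                             "SpO2"], values=values)
        labeled = vg.inject_event(
            as_labeled(s),
            vg.EventSpec(kind="sensor_fault", start_index=32, duration=4,
                         affected_parameters=["HR"],
                         magnitude_fraction=0.50, direction={"HR": +1}))
        decisions = run_pipeline(labeled.series)
        by_t = {d.t: d for d in decisions}
        assert by_t[32].flags == {"ABPmean": 0, "HR": 1, "Pulse": 0,
                                  "Respiration": 0, "SpO2": 0}
        assert by_t[32].verdict == VERDICT_FALSE_ALARM

    def test_correlated_event_is_true_alarm(self):
        values = np.tile([85.0, 80.0, 80.0, 16.0, 97.5], (44, 1))
        s = vg.VitalSeries(
            parameter_names=["ABPmean", "HR", "Pulse", "Respiration",
                             "SpO2"], values=values)
        labeled = vg.inject_event(
            as_labeled(s),
            vg.EventSpec(kind="medical_event", start_index=32, duration=4,
                         affected_parameters=["ABPmean", "HR", "Pulse",
                                              "SpO2"],
                         magnitude_fraction=0.50,
                         direction={"ABPmean": +1, "HR": -1, "Pulse": -1,
                                    "SpO2": -1}))
        decisions = run_pipeline(labeled.series)
        by_t = {d.t: d for d in decisions}
        assert by_t[32].vote_count == 4
        assert by_t[32].verdict == VERDICT_TRUE_ALARM

    def test_verdict_partition_and_counts(self, benchmark_decisions):
        verdicts = {VERDICT_NORMAL, VERDICT_TRUE_ALARM, VERDICT_FALSE_ALARM}
        assert all(d.verdict in verdicts for d in benchmark_decisions)
        counts = {v: sum(d.verdict == v for d in benchmark_decisions)
                  for v in verdicts}
        assert sum(counts.values()) == len(benchmark_decisions)
        for d in benchmark_decisions:
            assert 0 <= d.vote_count <= d.n
            assert (d.verdict == VERDICT_NORMAL) == (d.vote_count == 0)

    def test_k_mult_monotonicity(self, clean_series):
        # a larger threshold multiplier can only unflag (accept_all keeps
        # the forecasts identical across runs)
        low = run_pipeline(clean_series, PipelineConfig(k_mult=1.0))
        high = run_pipeline(clean_series, PipelineConfig(k_mult=1.5))
        assert len(low) == len(high)
        for dl, dh in zip(low, high):
            assert dh.vote_count <= dl.vote_count
            for p, f in dh.flags.items():
                assert f <= dl.flags[p]

    def test_end_to_end_determinism(self, clean_series):
        a = run_pipeline(clean_series)
        b = run_pipeline(clean_series)
        assert len(a) == len(b)
        for da, db in zip(a, b):
            assert da.t == db.t
            assert da.verdict == db.verdict
            assert da.flags == db.flags
            assert da.residuals == db.residuals

    def test_missing_values_abstain(self):
        values = np.tile([85.0, 80.0, 80.0, 16.0, 97.5], (40, 1))
        values[34, 1] = np.nan  # HR drops out for one instant
        s = vg.VitalSeries(
            parameter_names=["ABPmean", "HR", "Pulse", "Respiration",
                             "SpO2"], values=values)
        decisions = run_pipeline(s)
        by_t = {d.t: d for d in decisions}
        assert by_t[34].n == 4
        assert "HR" not in by_t[34].flags
        # HR stays out until its window refills with consecutive samples
        assert "HR" not in by_t[39].flags

    def test_too_short_series_rejected(self):
        s = vg.VitalSeries(parameter_names=["HR"],
                           values=np.full((20, 1), 80.0))
        with pytest.raises(ValueError, match="warm-up"):
            run_pipeline(s)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            PipelineConfig(w_p=1)
        with pytest.raises(ValueError):
            PipelineConfig(k_mult=0.0)
        with pytest.raises(ValueError):
            PipelineConfig(update_policy="sometimes")
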