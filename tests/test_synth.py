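"""Synthetic-data generator: determinism, degenerate limits, injected structure."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ultradian import synth
from ultradian.synth import SynthConfig, generate_day, generate_longitudinal, generate_tsf_trace

from conftest import ZERO_NOISE


class TestGenerateDay:
    def test_same_seed_bit_identical(self, default_config):
        d1, g1 = generate_day(default_config, 0)
        d2, g2 = generate_day(default_config, 0)
        for ch in ("mr", "rer", "tb", "activity"):
            np.testing.assert_array_equal(getattr(d1, ch), getattr(d2, ch))
        assert g1.periods == g2.periods

    def test_different_days_differ(self, default_config):
        d1, _ = generate_day(default_config, 0)
        d2, _ = generate_day(default_config, 1)
        assert not np.array_equal(d1.mr, d2.mr)

    def test_degenerate_config_is_flat(self):
        cfg = SynthConfig(component_amplitudes=(0.0, 0.0, 0.0), noise_sd=ZERO_NOISE)
        day, truth = generate_day(cfg, 0)
        np.testing.assert_allclose(day.mr, cfg.rmr_level)
        np.testing.assert_allclose(day.tb, cfg.tb_base)
        np.testing.assert_allclose(day.activity, 0.0)
        assert truth.ultradian_fraction == 0.0

    def test_mean_mr_matches_pulse_areas(self):
        # jitter-free, ungated: mean MR = RMR * (1 + sum amp_i * area_i / period_i)
        cfg = SynthConfig(seed=3, spacing_cv=0.0, circadian_attenuation=0.0,
                          noise_sd=ZERO_NOISE)
        day, _ = generate_day(cfg, 0)
        expected = cfg.rmr_level
        for amp, rise, decay, p_h in zip(
            cfg.component_amplitudes, cfg.burst_rise_min, cfg.burst_decay_min,
            cfg.component_periods,
        ):
            area = 0.375 * (rise + decay) * amp * cfg.rmr_level
            expected += area / (p_h * 60.0)
        assert day.mr.mean() == pytest.approx(expected, rel=0.05)

    def test_ground_truth_events_inside_day(self, default_day):
        _, truth = default_day
        for ev in truth.bursts:
            assert 0 <= ev.t_peak < synth.N_MINUTES
            assert ev.t_start <= ev.t_peak <= ev.t_end

    def test_light_phase_bursts_attenuated(self):
        cfg = SynthConfig(seed=5, noise_sd=ZERO_NOISE)
        _, truth = generate_day(cfg, 0)
        larges = truth.events("large")
        light = [b for b in larges if 8 * 60 <= b.t_peak < 16 * 60]
        dark = [b for b in larges if not 8 * 60 <= b.t_peak < 16 * 60]
        assert light and dark
        ratio = np.mean([b.mr_amplitude for b in light]) / np.mean(
            [b.mr_amplitude for b in dark]
        )
        assert ratio == pytest.approx(1.0 - cfg.circadian_attenuation, abs=1e-9)

    def test_rer_dips_during_large_bursts_only(self):
        cfg = SynthConfig(seed=2, noise_sd=ZERO_NOISE,
                          component_amplitudes=(0.2, 0.5, 0.0))
        day, _ = generate_day(cfg, 0)
        np.testing.assert_allclose(day.rer, cfg.rer_base)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 2**16), amp=st.floats(0.0, 2.0))
    def test_output_invariants(self, seed, amp):
        cfg = SynthConfig(seed=seed, component_amplitudes=(0.2, 0.5, amp))
        day, truth = generate_day(cfg, 0)
        assert day.mr.shape == (synth.N_MINUTES,)
        assert day.mr.min() >= 0
        assert day.activity.min() >= 0
        assert 0.6 <= day.rer.min() and day.rer.max() <= 1.1
        assert all(p > 0 for p in truth.periods.values())


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"component_periods": (2.0, 1.0, 3.5)},       # not increasing
            {"component_periods": (0.1, 2.0, 3.5)},       # below band
            {"component_periods": (1.0, 2.0, 7.0)},       # above band
            {"component_amplitudes": (-0.1, 0.5, 1.2)},
            {"circadian_attenuation": 1.5},
            {"rer_base": 1.2},
            {"rer_burst_min": 0.5},
            {"noise_sd": {"mr": -1.0}},
            {"rmr_level": float("nan")},
            {"burst_rise_min": (0.0, 40.0, 70.0)},
        ],
    )
    def test_invalid_configs_raise(self, kwargs):
        with pytest.raises(ValueError):
            generate_day(SynthConfig(**kwargs), 0)


class TestLongitudinal:
    def test_zero_drift_periods_constant(self):
        cfg = SynthConfig(seed=1, period_drift=0.0)
        seq = generate_longitudinal(cfg, 5)
        base = seq[0][1].periods
        for _, truth in seq[1:]:
            assert truth.periods == base

    def test_single_day_matches_generate_day(self, default_config):
        (day_l, truth_l), = generate_longitudinal(default_config, 1)
        day_d, truth_d = generate_day(default_config, 0)
        np.testing.assert_array_equal(day_l.mr, day_d.mr)
        assert truth_l.periods == truth_d.periods

    def test_day_index_increments(self, default_config):
        seq = generate_longitudinal(default_config, 3)
        assert [d.day_index for d, _ in seq] == [0, 1, 2]

    def test_shared_drift_periods_covary(self):
        cfg = SynthConfig(seed=9, period_drift=0.05)
        seq = generate_longitudinal(cfg, 21)
        small = np.array([t.periods["small"] for _, t in seq])
        large = np.array([t.periods["large"] for _, t in seq])
        assert np.corrcoef(small, large)[0, 1] > 0

    def test_n_days_validation(self, default_config):
        with pytest.raises(ValueError):
            generate_longitudinal(default_config, 0)


class TestPhysioDayValidation:
    def test_wrong_length_rejected(self, default_day):
        day, _ = default_day
        with pytest.raises(ValueError):
            dataclasses.replace(day, mr=day.mr[:100])

    def test_negative_mr_rejected(self, default_day):
        day, _ = default_day
        with pytest.raises(ValueError):
            dataclasses.replace(day, mr=day.mr - 10.0)

    def test_missing_channel_allowed(self, default_day):
        day, _ = default_day
        partial = dataclasses.replace(day, tb=None)
        with pytest.raises(ValueError):
            partial.channel("tb")


class TestTsfTrace:
    def test_same_seed_identical(self, default_config, default_day):
        day, truth = default_day
        t1, _ = generate_tsf_trace(default_config, day, truth)
        t2, _ = generate_tsf_trace(default_config, day, truth)
        np.testing.assert_array_equal(t1.hamster_tsf, t2.hamster_tsf)
        np.testing.assert_array_equal(t1.cage_tsf_1, t2.cage_tsf_1)

    def test_zero_activity_trace_is_quiet(self):
        cfg = SynthConfig(component_amplitudes=(0.0, 0.0, 0.0), noise_sd=ZERO_NOISE)
        day, truth = generate_day(cfg, 0)
        trace, tgt = generate_tsf_trace(cfg, day, truth)
        per_min = trace.hamster_tsf.reshape(-1, 60).std(axis=1, ddof=1)
        assert per_min.max() < 0.1  # noise floor only
        assert trace.cage_tsf_1.max() < 16.0
        assert trace.cage_tsf_2.max() < 16.0
        assert tgt.outside_minutes == 0

    def test_explicit_episodes_respected(self, default_config, default_day):
        day, _ = default_day
        eps = [(100, 200), (500, 550), (1000, 1045)]  # 195 min total
        _, tgt = generate_tsf_trace(default_config, day, episodes=eps)
        assert tgt.outside_minutes == 195
        assert tgt.episodes == eps

    def test_temperatures_in_physical_range(self, default_config, default_day):
        day, truth = default_day
        trace, _ = generate_tsf_trace(default_config, day, truth)
        for arr in (trace.hamster_tsf, trace.cage_tsf_1, trace.cage_tsf_2):
            assert arr.min() >= 5.0 and arr.max() <= 45.0
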