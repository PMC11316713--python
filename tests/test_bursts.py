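"""Burst extraction: class assignment, per-burst statistics, phase split."""
import numpy as np
import pytest

from ultradian import bursts, energetics, synth
from ultradian.bursts import (
    Burst,
    URClassPeriods,
    burst_cooccurrence,
    classify_periods,
    count_peaks_above,
    detect_bursts,
    extract_bursts,
    percent_reduction,
    phase_split,
)
from ultradian.wavelet import PeriodPeak

from conftest import ZERO_NOISE, make_day, triangle_burst


def peaks_from(periods, powers=None):
    powers = powers or [1.0] * len(periods)
    return [
        PeriodPeak(period_h=p, avg_power=w, significant=True)
        for p, w in zip(periods, powers)
    ]


class TestClassifyPeriods:
    def test_three_peaks_assigned_ascending(self):
        cp = classify_periods(peaks_from([3.91, 0.98, 2.07]))
        assert (cp.small, cp.medium, cp.large) == (0.98, 2.07, 3.91)

    def test_single_peak_band_rule(self):
        cp = classify_periods(peaks_from([0.5]))
        assert cp.small == 0.5 and cp.medium is None and cp.large is None

    def test_two_peaks_same_band_split_ascending(self):
        # band compression: both fall in the medium band but occupy two classes
        cp = classify_periods(peaks_from([1.33, 1.91]))
        assert cp.small is None
        assert (cp.medium, cp.large) == (1.33, 1.91)

    def test_two_peaks_distinct_bands(self):
        cp = classify_periods(peaks_from([1.0, 3.0]))
        assert (cp.small, cp.medium, cp.large) == (1.0, None, 3.0)

    def test_more_than_three_keeps_strongest_per_band(self):
        peaks = peaks_from([0.9, 1.1, 2.0, 3.5], powers=[0.2, 0.5, 1.0, 2.0])
        cp = classify_periods(peaks)
        assert (cp.small, cp.medium, cp.large) == (1.1, 2.0, 3.5)

    def test_band_edge_peaks_ignored(self):
        # periods beyond 5 h are circadian leakage, not an ultradian class
        cp = classify_periods(peaks_from([1.0, 2.0, 5.8]))
        assert cp.large is None

    def test_insignificant_peaks_filtered(self):
        peaks = [PeriodPeak(period_h=2.0, avg_power=1.0, significant=False)]
        cp = classify_periods(peaks)
        assert cp.as_dict() == {"small": None, "medium": None, "large": None}

    def test_empty_input_empty_result(self):
        cp = classify_periods([])
        assert cp.as_dict() == {"small": None, "medium": None, "large": None}

    def test_ordering_invariant_enforced(self):
        with pytest.raises(ValueError):
            URClassPeriods(small=2.0, medium=1.0, large=3.0)


class TestDetectBursts:
    def test_single_triangular_pulse(self):
        x = triangle_burst(1440, t_min=580, t_peak=600, base=1.0, peak=3.0)
        day = make_day(mr=x)
        found = detect_bursts(day, "mr", period_h=3.0)
        assert len(found) == 1
        b = found[0]
        assert b.value_min == pytest.approx(1.0)
        assert b.value_peak == pytest.approx(3.0)
        assert b.amplitude == pytest.approx(2.0)
        assert b.rise_time == 20
        assert b.t_min == 580 and b.t_peak == 600

    def test_constant_series_no_bursts(self):
        day = make_day(mr=np.full(1440, 1.0))
        assert detect_bursts(day, "mr", period_h=3.0) == []

    def test_jitter_free_train_count_within_one(self):
        cfg = synth.SynthConfig(
            seed=1, component_amplitudes=(0.0, 0.0, 1.2), spacing_cv=0.0,
            circadian_attenuation=0.0, noise_sd=ZERO_NOISE,
        )
        day, _ = synth.generate_day(cfg, 0)
        found = detect_bursts(day, "mr", period_h=3.5)
        assert abs(len(found) - np.floor(1440 / 210)) <= 1

    def test_truncated_burst_dropped_by_default(self):
        x = triangle_burst(1440, t_min=20, t_peak=40, base=1.0, peak=3.0)
        day = make_day(mr=x)
        assert detect_bursts(day, "mr", period_h=3.0) == []
        kept = detect_bursts(day, "mr", period_h=3.0, keep_truncated=True)
        assert len(kept) == 1 and kept[0].truncated

    def test_missing_period_rejected(self, default_day):
        day, _ = default_day
        with pytest.raises(ValueError):
            detect_bursts(day, "mr", None)

    def test_phase_labels_follow_light_schedule(self):
        x = triangle_burst(1440, 560, 600, 1.0, 3.0)  # peak at 10:00, light phase
        day = make_day(mr=x)
        (b,) = detect_bursts(day, "mr", period_h=3.0)
        assert b.phase == "resting"


class TestExtractBursts:
    def test_amplitude_recovery_exact_noise_free(self):
        cfg = synth.SynthConfig(
            seed=4, component_amplitudes=(0.0, 0.0, 1.2), spacing_cv=0.0,
            circadian_attenuation=0.0, noise_sd=ZERO_NOISE,
        )
        day, truth = synth.generate_day(cfg, 0)
        found = detect_bursts(day, "mr", period_h=3.5)
        for b in found:
            assert b.amplitude == pytest.approx(1.2, abs=1e-12)
            assert b.rise_time == 70

    def test_large_peak_not_recounted_as_small(self, quiet_day):
        day, _ = quiet_day
        env, _ = energetics.estimate_rmr(day, 3.5)
        cp = URClassPeriods(small=1.0, medium=2.0, large=3.5)
        by_class = extract_bursts(day, cp, "mr", rmr_envelope=env)
        large_peaks = {b.t_peak for b in by_class["large"]}
        for cname in ("small", "medium"):
            for b in by_class[cname]:
                assert all(abs(b.t_peak - lp) > 5 for lp in large_peaks)

    def test_amplitude_ordering_pooled_over_days(self):
        amps = {"small": [], "medium": [], "large": []}
        for seed in range(6):
            day, _ = synth.generate_day(synth.SynthConfig(seed=seed), 0)
            env, _ = energetics.estimate_rmr(day, 3.5)
            cp = URClassPeriods(small=1.0, medium=2.0, large=3.5)
            for c, bs in extract_bursts(day, cp, "mr", rmr_envelope=env).items():
                amps[c].extend(b.amplitude for b in bs)
        assert np.mean(amps["small"]) < np.mean(amps["medium"]) < np.mean(amps["large"])

    def test_small_rise_time_exact_on_isolated_train(self):
        # isolated small-class bursts: min-to-peak equals the injected
        # 13-min rise exactly (superposition on larger bursts lengthens it)
        cfg = synth.SynthConfig(
            seed=2, component_amplitudes=(0.2, 0.0, 0.0), spacing_cv=0.0,
            circadian_attenuation=0.0, noise_sd=ZERO_NOISE,
        )
        day, _ = synth.generate_day(cfg, 0)
        small = detect_bursts(day, "mr", period_h=1.0, ur_class="small")
        assert small
        assert all(b.rise_time == 13 for b in small)


class TestPhaseSplit:
    def test_percent_reduction_printed_means(self):
        assert round(percent_reduction(2.31, 3.24), 1) == 28.7
        assert round(percent_reduction(1.35, 2.18), 1) == 38.1

    def test_identical_bursts_zero_reduction(self):
        bs = [
            Burst("large", 100, 150, 1.0, 3.0, 2.0, 50, "resting", co_amp_tb=1.0),
            Burst("large", 900, 950, 1.0, 3.0, 2.0, 50, "activity", co_amp_tb=1.0),
        ]
        out = phase_split(bs)
        assert out["comparison"]["peak_reduction_pct"] == pytest.approx(0.0)
        assert out["comparison"]["tb_amplitude_difference_c"] == pytest.approx(0.0)

    def test_empty_phase_reported_missing(self):
        bs = [Burst("large", 100, 150, 1.0, 3.0, 2.0, 50, "activity")]
        out = phase_split(bs)
        assert out["resting"]["n"] == 0
        assert out["comparison"]["peak_reduction_pct"] is None

    def test_generator_attenuation_recovered(self):
        """Resting-phase large bursts are ~40% weaker by construction."""
        pooled = []
        for seed in range(4):
            day, _ = synth.generate_day(
                synth.SynthConfig(seed=seed, noise_sd=ZERO_NOISE), 0
            )
            pooled.extend(detect_bursts(day, "mr", period_h=3.5))
        out = phase_split(pooled)
        assert out["comparison"]["amplitude_reduction_pct"] == pytest.approx(40.0, abs=12.0)


class TestCountPeaksAbove:
    def test_all_below_threshold(self):
        day = make_day(mr=np.full(1440, 0.5))
        assert count_peaks_above(day, threshold=2.0) == 0

    def test_threshold_zero_counts_all_bursts(self, quiet_day):
        day, _ = quiet_day
        n_all = len(detect_bursts(day, "mr", period_h=3.0))
        assert count_peaks_above(day, threshold=0.0) == n_all

    def test_constructed_peaks_counted(self):
        x = np.full(1440, 1.0)
        for i, t in enumerate([200, 420, 640, 860, 1080]):
            peak = 3.0 if i < 4 else 1.5  # four above 2.0
            x = np.maximum(x, triangle_burst(1440, t - 30, t, 1.0, peak))
        day = make_day(mr=x)
        assert count_peaks_above(day, threshold=2.0) == 4

    def test_window_restriction(self):
        x = np.full(1440, 1.0)
        x = np.maximum(x, triangle_burst(1440, 270, 300, 1.0, 3.0))
        x = np.maximum(x, triangle_burst(1440, 970, 1000, 1.0, 3.0))
        day = make_day(mr=x)
        assert count_peaks_above(day, 2.0, window_min=(0, 720)) == 1


class TestCooccurrence:
    def test_uncoupled_small_bursts_all_lack_activity(self):
        cfg = synth.SynthConfig(
            seed=3, noise_sd=ZERO_NOISE,
            activity_coupled_fraction=(0.0, 0.79, 1.0),
            tb_coupled_fraction=(0.0, 1.0, 1.0),
        )
        day, _ = synth.generate_day(cfg, 0)
        env, _ = energetics.estimate_rmr(day, 3.5)
        cp = URClassPeriods(small=1.0, medium=2.0, large=3.5)
        by_class = extract_bursts(day, cp, "mr", rmr_envelope=env)
        out = burst_cooccurrence(by_class)
        assert out["small"]["frac_lacking_activity"] == pytest.approx(1.0)

    def test_fully_coupled_large_bursts_lack_nothing(self, quiet_day):
        day, _ = quiet_day
        large = detect_bursts(day, "mr", period_h=3.5)
        out = burst_cooccurrence({"large": large})
        assert out["large"]["frac_lacking_activity"] == pytest.approx(0.0)
        assert out["large"]["frac_lacking_tb"] == pytest.approx(0.0)

    def test_mixed_coupling_fraction_recovered(self):
        lacking = []
        for seed in range(6):
            cfg = synth.SynthConfig(
                seed=seed, noise_sd=ZERO_NOISE,
                activity_coupled_fraction=(0.6, 0.79, 1.0),
            )
            day, _ = synth.generate_day(cfg, 0)
            env, _ = energetics.estimate_rmr(day, 3.5)
            cp = URClassPeriods(small=1.0, medium=2.0, large=3.5)
            small = extract_bursts(day, cp, "mr", rmr_envelope=env)["small"]
            lacking.extend(b.co_amp_activity <= 0 for b in small)
        assert np.mean(lacking) == pytest.approx(0.4, abs=0.2)
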