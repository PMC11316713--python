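"""Per-day and longitudinal analysis orchestration.

Composes wavelet period detection -> class assignment -> burst extraction ->
energy partitioning for one 24-h record, and the day loop + synchrony
analysis for longitudinal series.  Every number in a report traces to a
stage output; reports are deterministic given the configuration seed.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import bursts as bursts_mod
from . import energetics, synchrony, wavelet
from .synth import CLASS_NAMES, PhysioDay

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Analysis configuration shared by the per-day and longitudinal runs."""

    channels: tuple = ("mr", "tb", "activity")
    alpha_mask: float = 0.05
    alpha_peaks: float = 0.01
    n_shuffles: int = 150
    light_phase: tuple = (8.0, 16.0)
    torpor_tb_cutoff: float = 32.0
    min_period_h: float = wavelet.MIN_PERIOD_H
    max_period_h: float = wavelet.MAX_PERIOD_H
    dj: float = wavelet.DJ
    prominence_frac: float = 0.01
    min_separation: int = 12
    significant_only: bool = True
    seed: int = 0

    def validate(self) -> None:
        for a in (self.alpha_mask, self.alpha_peaks):
            if not (0.0 < a < 1.0):
                raise ValueError("alpha levels must lie in (0, 1)")
        if self.n_shuffles < 1:
            raise ValueError("shuffle count must be >= 1")


def _channel_rng(config: RunConfig, day_index: int, channel: str) -> np.random.Generator:
    stream = ("mr", "tb", "activity", "rer").index(channel)
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(day_index), 1000 + stream])
    )


def analyze_channel(config: RunConfig, day: PhysioDay, channel: str) -> dict:
    """Wavelet spectrum, surrogate significance and class periods for one channel."""
    series = day.channel(channel)
    kw = dict(min_period_h=config.min_period_h, max_period_h=config.max_period_h, dj=config.dj)
    spectrum = wavelet.morlet_cwt(series, **kw)
    threshold = wavelet.shuffle_significance(
        series,
        n_shuffles=config.n_shuffles,
        alpha=config.alpha_peaks,
        rng=_channel_rng(config, day.day_index, channel),
        **kw,
    )
    wavelet.attach_significance(spectrum, threshold)
    peaks = wavelet.find_period_peaks(
        spectrum,
        prominence_frac=config.prominence_frac,
        min_separation=config.min_separation,
    )
    classes = bursts_mod.classify_periods(
        peaks,
        significant_only=config.significant_only,
        subject_id=day.subject_id,
        day_index=day.day_index,
    )
    return {"spectrum": spectrum, "peaks": peaks, "classes": classes}


def run_day(config: RunConfig, day: PhysioDay) -> dict:
    """Full single-day report: per-channel periods, MR bursts, phase split,
    energy budget and RER dynamics.  Torpor days (T_b below the cutoff) are
    excluded with an explicit reason."""
    config.validate()
    if day.mr is None:
        raise ValueError("run_day requires the MR channel")
    if day.tb is not None and np.nanmin(day.tb) < config.torpor_tb_cutoff:
        return {
            "subject_id": day.subject_id,
            "day_index": day.day_index,
            "excluded": True,
            "reason": f"torpor: T_b fell below {config.torpor_tb_cutoff} degC",
        }

    t0 = time.perf_counter()
    channel_results = {}
    for ch in config.channels:
        if getattr(day, ch, None) is None:
            continue
        channel_results[ch] = analyze_channel(config, day, ch)
        logger.info("channel %s analysed in %.2f s", ch, time.perf_counter() - t0)

    mr_classes = channel_results["mr"]["classes"]
    envelope, rmr_mean = energetics.estimate_rmr(day, mr_classes.large)
    by_class = bursts_mod.extract_bursts(day, mr_classes, "mr", rmr_envelope=envelope)
    budget = energetics.partition_budget(day, envelope, large_period_h=mr_classes.large)
    all_bursts = [b for bs in by_class.values() for b in bs]
    split = bursts_mod.phase_split(by_class["large"], config.light_phase)
    rer_dyn = (
        energetics.rer_burst_dynamics(day, by_class["large"]) if day.rer is not None else None
    )

    report = {
        "subject_id": day.subject_id,
        "day_index": day.day_index,
        "excluded": False,
        "periods_h": {
            ch: res["classes"].as_dict() for ch, res in channel_results.items()
        },
        "rmr_mean": rmr_mean,
        "budget": dataclasses.asdict(budget),
        "bursts": {
            c: [dataclasses.asdict(b) for b in bs] for c, bs in by_class.items()
        },
        "burst_counts": {c: len(bs) for c, bs in by_class.items()},
        "n_bursts": len(all_bursts),
        "phase_split": split,
        "rer_dynamics": None
        if rer_dyn is None
        else {k: v for k, v in rer_dyn.items() if k.startswith("mean") or k == "n"},
        "cooccurrence": bursts_mod.burst_cooccurrence(by_class),
    }
    report["_channel_results"] = channel_results  # non-serialised stage outputs
    return report


def run_longitudinal(config: RunConfig, days: Sequence[PhysioDay]) -> dict:
    """Study report over a day sequence: period time-courses, synchrony table
    and Table-1-style class summaries.  Requires >= 5 analyzable days."""
    config.validate()
    reports = [run_day(config, d) for d in days]
    analyzable = [r for r in reports if not r.get("excluded")]
    if len(analyzable) < 5:
        raise ValueError(f"need >= 5 analyzable days, got {len(analyzable)}")

    per_day = [
        {ch: r["_channel_results"][ch]["classes"] for ch in r["_channel_results"]}
        for r in analyzable
    ]
    tc = synchrony.period_timecourse(per_day, subject_id=analyzable[0]["subject_id"])
    table = synchrony.pairwise_correlations(tc)
    summary = synchrony.synchrony_summary(table)

    class_stats = {}
    for cname in CLASS_NAMES:
        periods = [
            r["periods_h"]["mr"][cname]
            for r in analyzable
            if r["periods_h"]["mr"][cname] is not None
        ]
        amps = [
            b["amplitude"] for r in analyzable for b in r["bursts"][cname]
        ]
        peaks = [b["value_peak"] for r in analyzable for b in r["bursts"][cname]]
        counts = [r["burst_counts"][cname] for r in analyzable]
        class_stats[cname] = {
            "period_min_mean": float(np.mean(periods) * 60.0) if periods else None,
            "period_min_sem": (
                float(np.std(periods, ddof=1) / np.sqrt(len(periods)) * 60.0)
                if len(periods) > 1
                else None
            ),
            "bursts_per_day_mean": float(np.mean(counts)),
            "peak_mr_mean": float(np.mean(peaks)) if peaks else None,
            "amplitude_mean": float(np.mean(amps)) if amps else None,
        }

    return {
        "n_days": len(days),
        "n_analyzable": len(analyzable),
        "timecourse": tc,
        "synchrony_table": table,
        "synchrony_summary": summary,
        "class_summary": class_stats,
        "day_reports": reports,
    }


def report_to_json(report: dict) -> str:
    """Serialise a report deterministically (stage objects stripped)."""

    def _default(obj):
        if isinstance(obj, (np.floating, np.integer, np.bool_)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not serialisable: {type(obj)}")

    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    return json.dumps(clean, sort_keys=True, indent=2, default=_default)
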