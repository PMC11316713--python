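"""Resting-metabolic-rate envelope and energy-budget partitioning.

The resting metabolic rate (RMR) is tracked by the minima of ultradian
bursts: the MR trace is smoothed with 6-min averages, a rolling minimum with
a window equal to the day's large-class period anchors the burst minima, and
linear interpolation between anchors gives a per-minute lower envelope.  The
ultradian component is everything above the envelope, so by construction

    DEE = RMR energy + ultradian energy        (kJ day^-1, exact)
    mean MR = RMR mean + ultradian MR mean     (mL O2 min^-1, exact)
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import minimum_filter1d

from . import calorimetry


@dataclass
class EnergyBudget:
    """Daily (or 12-h) energy budget partitioned into resting and ultradian
    components.  All rates in mL O2 min^-1, energies in kJ per window."""

    dee: float
    rmr_energy: float
    ultradian_energy: float
    mean_mr: float
    rmr_mean: float
    ultradian_mr_mean: float
    ultradian_fraction: float          # % of mean MR
    window: str = "24 h"

    def __post_init__(self) -> None:
        for name in ("dee", "rmr_energy", "ultradian_energy", "mean_mr",
                     "rmr_mean", "ultradian_mr_mean"):
            if getattr(self, name) < -1e-9:
                raise ValueError(f"{name} must be non-negative")


def estimate_rmr(
    day,
    large_period_h: Optional[float] = None,
    *,
    smooth_min: int = 6,
    method: str = "envelope",
):
    """Per-minute RMR envelope and its daily mean.

    ``method='envelope'`` (default) interpolates linearly between the minima
    anchored by a rolling minimum; the daily RMR is the envelope mean.
    ``method='minima'`` averages only the anchored minima themselves.
    Returns ``(envelope, rmr_mean)``.
    """
    if getattr(day, "mr", None) is None:
        raise ValueError("estimate_rmr requires the MR channel")
    mr = np.asarray(day.mr, dtype=float)
    window = max(2, int(round((large_period_h or 3.0) * 60.0)))
    sm = calorimetry.running_average(mr, smooth_min)
    rolled = minimum_filter1d(sm, size=min(window, sm.size), mode="nearest")
    anchors = np.flatnonzero(sm <= rolled + 1e-12)
    # Prune anchors that sit well above the local floor: a window whose
    # minimum never reaches the inter-burst baseline (bursts overlapping all
    # through it) would otherwise drag the envelope upward.  The reference
    # floor is the rolling minimum over a doubled window, so a genuine slow
    # change of RMR (e.g. a step) is still tracked locally.
    floor = minimum_filter1d(sm, size=min(2 * window, sm.size), mode="nearest")
    slack = 0.01 * float(np.ptp(sm))
    kept = anchors[sm[anchors] <= floor[anchors] + slack]
    if kept.size:
        anchors = kept
    t = np.arange(mr.size)
    envelope = np.interp(t, anchors, sm[anchors])
    if method == "envelope":
        rmr_mean = float(envelope.mean())
    elif method == "minima":
        rmr_mean = float(sm[anchors].mean())
    else:
        raise ValueError("method must be 'envelope' or 'minima'")
    return envelope, rmr_mean


def partition_budget(
    day,
    rmr_envelope: Optional[np.ndarray] = None,
    *,
    large_period_h: Optional[float] = None,
    window_min: Optional[tuple] = None,
) -> EnergyBudget:
    """Partition a record's energy budget into resting and ultradian parts.

    The ultradian MR series is ``max(MR - envelope, 0)`` (the envelope can
    locally exceed noisy MR); the resting series is the remainder, so the
    budget closes exactly.  ``window_min`` restricts the partition to a
    half-open minute interval for 12-h analyses.
    """
    if day.mr is None or day.rer is None:
        raise ValueError("partition_budget requires MR and RER channels")
    if rmr_envelope is None:
        rmr_envelope, _ = estimate_rmr(day, large_period_h)
    mr = np.asarray(day.mr, dtype=float)
    rer = calorimetry.fill_rer(np.asarray(day.rer, dtype=float))
    env = np.asarray(rmr_envelope, dtype=float)
    label = "24 h"
    if window_min is not None:
        lo, hi = window_min
        mr, rer, env = mr[lo:hi], rer[lo:hi], env[lo:hi]
        label = f"{(hi - lo) / 60:g} h"
    ultra = np.maximum(mr - env, 0.0)
    rest = mr - ultra
    total = calorimetry.energy_from_series(mr, rer)
    resting = calorimetry.energy_from_series(rest, rer)
    mean_mr = float(mr.mean())
    ultra_mean = float(ultra.mean())
    return EnergyBudget(
        dee=total.dee_kj,
        rmr_energy=resting.dee_kj,
        ultradian_energy=total.dee_kj - resting.dee_kj,
        mean_mr=mean_mr,
        rmr_mean=mean_mr - ultra_mean,
        ultradian_mr_mean=ultra_mean,
        ultradian_fraction=ultradian_percentage(ultra_mean, mean_mr),
        window=label,
    )


def ultradian_percentage(ultradian_mr_mean: float, mean_mr: float) -> float:
    """Ultradian MR as a percentage of mean MR."""
    if mean_mr == 0:
        return 0.0
    return 100.0 * ultradian_mr_mean / mean_mr


def rer_burst_dynamics(day, large_bursts) -> dict:
    """RER dynamics across large-class metabolic bursts.

    Per burst: RER at the burst minimum (pre-burst), minimum RER within the
    burst span (rise window extended symmetrically past the peak), and the
    MR fold-change from minimum to peak.  Returns per-burst lists and means.
    """
    if day.rer is None:
        raise ValueError("rer_burst_dynamics requires the RER channel")
    rer = calorimetry.fill_rer(np.asarray(day.rer, dtype=float))
    n = rer.size
    pre, dip, fold = [], [], []
    for b in large_bursts:
        span_end = min(n, b.t_peak + max(1, b.rise_time) + 1)
        pre.append(float(rer[b.t_min]))
        dip.append(float(rer[b.t_min : span_end].min()))
        fold.append(float(b.value_peak / b.value_min) if b.value_min > 0 else np.nan)
    folds = np.asarray(fold, dtype=float)
    return {
        "n": len(pre),
        "rer_pre": pre,
        "rer_min": dip,
        "mr_fold_change": fold,
        "mean_rer_pre": float(np.mean(pre)) if pre else None,
        "mean_rer_min": float(np.mean(dip)) if dip else None,
        "mean_mr_fold_change": float(np.nanmean(folds)) if len(folds) else None,
    }
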