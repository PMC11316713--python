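"""Ultradian burst extraction and classification.

A day's significant periodogram peaks are assigned to the three ultradian
classes (small ~1 h, medium ~1.5-2.2 h, large ~2-5 h).  Individual bursts are
then extracted per class with a search window equal to the class period: the
window locates one peak, and the minimum preceding the peak (within one
period) defines the burst onset, amplitude and rise time.  Small- and
medium-class detections riding on the flank of a large burst are flagged as
superimposed and excluded from baseline statistics.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks as _find_peaks

CLASS_NAMES = ("small", "medium", "large")

#: fallback class bands in hours, used when fewer than three peaks are found
CLASS_BANDS = {"small": (0.3, 1.25), "medium": (1.25, 2.4), "large": (2.4, 6.0)}


@dataclass
class URClassPeriods:
    """Per-day period estimates (hours) for the three ultradian classes."""

    small: Optional[float] = None
    medium: Optional[float] = None
    large: Optional[float] = None
    subject_id: str = ""
    day_index: int = 0

    def get(self, name: str) -> Optional[float]:
        return getattr(self, name)

    def as_dict(self) -> dict:
        return {c: self.get(c) for c in CLASS_NAMES}

    def __post_init__(self) -> None:
        present = [self.get(c) for c in CLASS_NAMES if self.get(c) is not None]
        if any(not (0.3 <= p <= 6.0) for p in present):
            raise ValueError("class periods must lie within [0.3, 6] h")
        vals = [self.small, self.medium, self.large]
        known = [v for v in vals if v is not None]
        if len(known) == 3 and not (vals[0] < vals[1] < vals[2]):
            raise ValueError("when all three classes are present, small < medium < large")


@dataclass
class Burst:
    """One ultradian excursion from a local minimum to the following peak."""

    ur_class: str
    t_min: int
    t_peak: int
    value_min: float
    value_peak: float
    amplitude: float
    rise_time: int
    phase: str                       # "resting" (light phase) or "activity"
    co_amp_tb: Optional[float] = None
    co_amp_activity: Optional[float] = None
    superimposed: bool = False
    truncated: bool = False
    channel: str = "mr"

    def __post_init__(self) -> None:
        if self.t_min >= self.t_peak:
            raise ValueError("burst minimum must precede its peak")
        if self.rise_time != self.t_peak - self.t_min:
            raise ValueError("rise_time must equal t_peak - t_min")


def _band_of(period: float) -> Optional[str]:
    for name, (lo, hi) in CLASS_BANDS.items():
        if lo <= period < hi or (name == "large" and period == hi):
            return name
    return None


def classify_periods(
    peaks: Iterable,
    *,
    significant_only: bool = True,
    max_period_h: float = 5.0,
    subject_id: str = "",
    day_index: int = 0,
) -> URClassPeriods:
    """Assign periodogram peaks to the small/medium/large ultradian classes.

    Peaks with periods above ``max_period_h`` (default 5 h, the upper end of
    the large-class range) are ignored: power near the band edge of a 24-h
    record is dominated by leakage from the circadian cycle (its 4.8-h and
    6-h harmonics), not by an ultradian oscillator.

    With exactly three usable peaks they are assigned by ascending period.
    With more, the strongest peak per fallback band
    (small < 1.25 h <= medium < 2.4 h <= large) is retained first — a
    dominant class often splits into several near-by maxima, and keeping
    the global top three would discard a weak class entirely.  With fewer
    than three, peaks fall into the bands directly; two peaks colliding in
    one band are split by ascending period onto that band's class and the
    next one up.  Unassignable classes stay empty.
    """
    usable = [
        p
        for p in peaks
        if p.period_h <= max_period_h
        and not (significant_only and p.significant is False)
    ]

    def _strength(p):
        return p.snr if p.snr is not None else p.avg_power

    if len(usable) > 3:
        by_band = {}
        for p in usable:
            band = _band_of(p.period_h)
            if band is not None and (
                band not in by_band or _strength(p) > _strength(by_band[band])
            ):
                by_band[band] = p
        usable = list(by_band.values())
    usable = sorted(usable, key=lambda p: (-_strength(p), p.period_h))[:3]
    periods = sorted(p.period_h for p in usable)
    out = {c: None for c in CLASS_NAMES}
    if len(periods) == 3:
        out = dict(zip(CLASS_NAMES, periods))
    elif len(periods) == 2:
        b0, b1 = _band_of(periods[0]), _band_of(periods[1])
        if b0 != b1:
            out[b0], out[b1] = periods[0], periods[1]
        else:
            # same band: keep ascending order across adjacent classes
            i = CLASS_NAMES.index(b0)
            if i == len(CLASS_NAMES) - 1:
                out["medium"], out["large"] = periods
            else:
                out[CLASS_NAMES[i]], out[CLASS_NAMES[i + 1]] = periods
    elif len(periods) == 1:
        out[_band_of(periods[0])] = periods[0]
    return URClassPeriods(subject_id=subject_id, day_index=day_index, **out)


def detect_bursts(
    day,
    channel: str = "mr",
    period_h: Optional[float] = None,
    *,
    ur_class: str = "large",
    search_factor: float = 1.0,
    dedup_gap_factor: float = 0.5,
    rmr_envelope: Optional[np.ndarray] = None,
    large_amplitude: Optional[float] = None,
    baseline_slack_frac: float = 0.25,
    tb_lag_min: int = 10,
    exclude_peaks: Optional[Sequence] = None,
    exclude_tol_min: int = 5,
    keep_truncated: bool = False,
) -> list:
    """Extract individual bursts of one class from one channel.

    The search window has width ``search_factor * period``; candidate local
    maxima closer than ``dedup_gap_factor * period`` collapse onto the larger
    one, and a peak must be the maximum of its own window.  The burst minimum
    is the last occurrence of the lowest value within one search window
    before the peak; bursts whose minimum-search window is truncated by the
    day start are dropped.

    For small/medium classes, a burst whose minimum sits above
    ``rmr_envelope + baseline_slack_frac * large_amplitude`` is flagged
    ``superimposed`` (riding on a larger burst), as are peaks within
    ``exclude_tol_min`` minutes of a peak already claimed by a larger class
    (``exclude_peaks``) -- the same event must not be counted twice.
    """
    if period_h is None:
        raise ValueError("a class period is required to size the search window")
    x = day.channel(channel)
    n = x.size
    P = max(2, int(round(search_factor * period_h * 60.0)))
    gap = max(1, int(round(dedup_gap_factor * period_h * 60.0)))
    if np.ptp(x) == 0:
        return []
    cand, _ = _find_peaks(x, distance=gap)
    half = P // 2
    bursts = []
    for i in cand:
        lo, hi = max(0, i - half), min(n, i + half + 1)
        if x[i] < x[lo:hi].max():
            continue
        truncated = i - P < 0
        if truncated and not keep_truncated:
            continue  # minimum-search window truncated by the day edge
        seg = x[max(0, i - P) : i + 1]
        rev_arg = seg.size - 1 - int(np.argmin(seg[::-1]))  # last occurrence
        t_min = max(0, i - P) + rev_arg
        if t_min >= i:
            continue
        light = day.light_mask[i] if hasattr(day, "light_mask") else False
        co_tb = None
        if getattr(day, "tb", None) is not None:
            j = min(n - 1, i + int(tb_lag_min))
            co_tb = float(day.tb[j] - day.tb[t_min])
        co_act = None
        if getattr(day, "activity", None) is not None:
            co_act = float(day.activity[i] - day.activity[t_min])
        superimposed = False
        if ur_class in ("small", "medium"):
            if (
                rmr_envelope is not None
                and large_amplitude is not None
                and x[t_min] > rmr_envelope[t_min] + baseline_slack_frac * large_amplitude
            ):
                superimposed = True
            if exclude_peaks is not None and len(exclude_peaks):
                # same event already claimed by a larger class
                if np.min(np.abs(np.asarray(exclude_peaks) - i)) <= exclude_tol_min:
                    superimposed = True
        bursts.append(
            Burst(
                ur_class=ur_class,
                t_min=int(t_min),
                t_peak=int(i),
                value_min=float(x[t_min]),
                value_peak=float(x[i]),
                amplitude=float(x[i] - x[t_min]),
                rise_time=int(i - t_min),
                phase="resting" if light else "activity",
                co_amp_tb=co_tb,
                co_amp_activity=co_act,
                superimposed=superimposed,
                truncated=truncated,
                channel=channel,
            )
        )
    return bursts


def extract_bursts(
    day,
    class_periods: URClassPeriods,
    channel: str = "mr",
    *,
    rmr_envelope: Optional[np.ndarray] = None,
    include_superimposed: bool = False,
    **kwargs,
) -> dict:
    """Bursts for all assigned classes, large -> small, with cross-class
    de-duplication: a small/medium candidate whose peak falls inside an
    accepted larger-class burst span is flagged superimposed.

    Returns ``{class: [Burst, ...]}``; superimposed bursts are dropped unless
    ``include_superimposed`` is set.
    """
    out = {}
    large_amp = None
    claimed: list = []
    for cname in reversed(CLASS_NAMES):
        period = class_periods.get(cname)
        if period is None:
            out[cname] = []
            continue
        found = detect_bursts(
            day,
            channel,
            period,
            ur_class=cname,
            rmr_envelope=rmr_envelope,
            large_amplitude=large_amp,
            exclude_peaks=list(claimed),
            keep_truncated=True,
            **kwargs,
        )
        kept = [
            b
            for b in found
            if not b.truncated and (include_superimposed or not b.superimposed)
        ]
        out[cname] = kept
        if cname in ("large", "medium"):
            # claim every detected peak of this class -- including
            # edge-truncated ones -- so a smaller-class window cannot
            # re-count the same event
            claimed.extend(b.t_peak for b in found)
            if cname == "large" and kept:
                large_amp = float(np.mean([b.amplitude for b in kept]))
    return out


def percent_reduction(resting: float, activity: float) -> float:
    """Percent reduction of a burst statistic in the resting vs activity phase."""
    if activity == 0:
        raise ValueError("activity-phase mean is zero; reduction undefined")
    return 100.0 * (1.0 - resting / activity)


def phase_split(bursts: Sequence, light_phase=(8.0, 16.0)) -> dict:
    """Resting- vs activity-phase comparison of burst statistics.

    Means of peak value, amplitude and T_b/activity co-amplitudes per phase,
    plus the percent reduction (peak and amplitude) and the absolute T_b
    amplitude difference in degC.  A phase with zero bursts yields missing
    comparisons rather than fabricated ones.
    """
    groups = {"resting": [b for b in bursts if b.phase == "resting"],
              "activity": [b for b in bursts if b.phase == "activity"]}

    def _mean(bs, attr):
        vals = [getattr(b, attr) for b in bs if getattr(b, attr) is not None]
        return float(np.mean(vals)) if vals else None

    summary = {}
    for phase, bs in groups.items():
        summary[phase] = {
            "n": len(bs),
            "mean_peak": _mean(bs, "value_peak"),
            "mean_amplitude": _mean(bs, "amplitude"),
            "mean_co_amp_tb": _mean(bs, "co_amp_tb"),
            "mean_co_amp_activity": _mean(bs, "co_amp_activity"),
        }
    r, a = summary["resting"], summary["activity"]
    comparison = {"peak_reduction_pct": None, "amplitude_reduction_pct": None,
                  "tb_amplitude_difference_c": None}
    if r["n"] > 0 and a["n"] > 0:
        if a["mean_peak"]:
            comparison["peak_reduction_pct"] = percent_reduction(r["mean_peak"], a["mean_peak"])
        if a["mean_amplitude"]:
            comparison["amplitude_reduction_pct"] = percent_reduction(
                r["mean_amplitude"], a["mean_amplitude"]
            )
        if r["mean_co_amp_tb"] is not None and a["mean_co_amp_tb"] is not None:
            comparison["tb_amplitude_difference_c"] = a["mean_co_amp_tb"] - r["mean_co_amp_tb"]
    return {"resting": r, "activity": a, "comparison": comparison}


def count_peaks_above(
    day,
    threshold: float = 2.0,
    *,
    period_h: float = 3.0,
    window_min: Optional[tuple] = None,
    **kwargs,
) -> int:
    """Number of detected burst peaks exceeding ``threshold`` (mL O2 min^-1).

    ``window_min`` restricts counting to a half-open minute interval (e.g.
    the 12-h night window); ``threshold=0`` counts every detected burst.
    """
    bursts = detect_bursts(day, "mr", period_h, **kwargs)
    lo, hi = window_min if window_min is not None else (0, day.mr.size)
    return sum(1 for b in bursts if b.value_peak > threshold and lo <= b.t_peak < hi)


def burst_cooccurrence(bursts_by_class: dict) -> dict:
    """Fraction of MR bursts per class lacking a T_b / activity response.

    A burst "lacks" a response when the corresponding co-amplitude over the
    MR rise window is <= 0.
    """
    out = {}
    for cname, bursts in bursts_by_class.items():
        tb_vals = [b.co_amp_tb for b in bursts if b.co_amp_tb is not None]
        act_vals = [b.co_amp_activity for b in bursts if b.co_amp_activity is not None]
        out[cname] = {
            "n": len(bursts),
            "frac_lacking_tb": float(np.mean([v <= 0 for v in tb_vals])) if tb_vals else None,
            "frac_lacking_activity": (
                float(np.mean([v <= 0 for v in act_vals])) if act_vals else None
            ),
        }
    return out
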