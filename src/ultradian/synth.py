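"""Synthetic multichannel physiology generator.

Emulates 24-h, 1-min-resolution recordings of metabolic rate (MR), respiratory
exchange ratio (RER), core body temperature (T_b) and locomotor activity of a
small nocturnal rodent whose metabolism is organised by three superimposed
ultradian rhythms:

* a small-amplitude class (period ~1 h, ~+20% of resting metabolic rate),
* a medium class (~2 h, ~+50% of RMR),
* a large class (~3.5 h, >+100% of RMR).

Each class is a quasi-periodic train of asymmetric half-cosine bursts (fast
rise, slower decay) added on top of a flat resting baseline.  Large bursts
co-drive locomotor activity and (through a first-order thermal low-pass) body
temperature, and depress RER toward a lipid-oxidation value; small bursts are
purely metabolic.  Burst amplitudes are attenuated during the light (resting)
phase, emulating circadian gating of the ultradian system.  Day-to-day period
drift follows a multiplicative random walk shared across the three classes.

Every injected quantity is returned in a :class:`GroundTruth` record so the
downstream detection and energy-partitioning stages can be tested against
known truth.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

N_MINUTES = 1440
SECONDS_PER_MINUTE = 60
CLASS_NAMES = ("small", "medium", "large")
CHANNELS = ("mr", "rer", "tb", "activity")

_BASE_DATE = pd.Timestamp("2023-01-01")


def _default_noise_sd() -> dict:
    return {"mr": 0.05, "rer": 0.01, "tb": 0.05, "activity": 1.0}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic recording.

    Amplitudes are fractions of the resting baseline `rmr_level`; periods are
    in hours and must be strictly increasing within the ultradian band
    [0.3, 6] h.  `burst_rise_min`/`burst_decay_min` give the per-class pulse
    shape in minutes.  `circadian_attenuation` scales burst amplitudes down
    during the light phase (clock interval in hours, half-open).  Coupling
    fractions give the probability that a burst of each class drives T_b or
    activity at all; uncoupled bursts are purely metabolic.
    """

    rmr_level: float = 1.0                       # mL O2 min^-1
    component_periods: tuple = (1.0, 2.0, 3.5)   # h (small, medium, large)
    component_amplitudes: tuple = (0.2, 0.5, 1.2)  # fraction of RMR
    burst_rise_min: tuple = (13.0, 40.0, 70.0)
    burst_decay_min: tuple = (30.0, 55.0, 100.0)
    spacing_cv: float = 0.15                     # lognormal CV of inter-burst spacing
    circadian_attenuation: float = 0.4
    light_phase: tuple = (8.0, 16.0)             # clock hours, half-open
    tb_base: float = 36.0                        # degC
    tb_gain_per_class: tuple = (0.1, 0.3, 1.1)   # degC at full burst height
    tb_lag_min: float = 10.0                     # thermal low-pass time constant
    tb_coupled_fraction: tuple = (0.32, 1.0, 1.0)
    activity_gain_per_class: tuple = (1.0, 0.5, 15.0)  # counts min^-1 at peak
    activity_coupled_fraction: tuple = (0.56, 0.79, 1.0)
    rer_base: float = 0.96
    rer_burst_min: float = 0.84
    noise_sd: Mapping[str, float] = field(default_factory=_default_noise_sd)
    period_drift: float = 0.05                   # day-to-day random-walk SD (log scale)
    ta: float = 15.0                             # degC ambient, metadata
    seed: int = 0

    def validate(self) -> None:
        p = np.asarray(self.component_periods, dtype=float)
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise ValueError("component_periods must be three finite durations (h)")
        if not (np.all(np.diff(p) > 0)):
            raise ValueError("component_periods must be strictly increasing")
        if p.min() < 0.3 or p.max() > 6.0:
            raise ValueError("component_periods must lie within [0.3, 6] h")
        a = np.asarray(self.component_amplitudes, dtype=float)
        if a.shape != (3,) or not np.all(np.isfinite(a)) or np.any(a < 0):
            raise ValueError("component_amplitudes must be three non-negative fractions")
        if not (0.0 <= self.circadian_attenuation <= 1.0):
            raise ValueError("circadian_attenuation must be within [0, 1]")
        for name in ("rer_base", "rer_burst_min"):
            v = getattr(self, name)
            if not (0.7 <= v <= 1.0):
                raise ValueError(f"{name} must be within [0.7, 1.0]")
        for ch, sd in dict(self.noise_sd).items():
            if not np.isfinite(sd) or sd < 0:
                raise ValueError(f"noise_sd[{ch!r}] must be finite and non-negative")
        for name in ("rmr_level", "tb_base", "tb_lag_min", "spacing_cv", "period_drift"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        for tup in (self.burst_rise_min, self.burst_decay_min):
            t = np.asarray(tup, dtype=float)
            if t.shape != (3,) or not np.all(np.isfinite(t)) or np.any(t <= 0):
                raise ValueError("burst rise/decay durations must be three positive minutes")


@dataclass
class PhysioDay:
    """One 24-h multichannel record on a regular 1-min grid (n = 1440).

    Channels may individually be ``None`` (missing) but are never partially
    gapped beyond what the analysis interpolates.
    """

    timestamps: pd.DatetimeIndex
    mr: Optional[np.ndarray]
    rer: Optional[np.ndarray]
    tb: Optional[np.ndarray]
    activity: Optional[np.ndarray]
    ta: float = 15.0
    light_phase: tuple = (8.0, 16.0)
    subject_id: str = "synthetic"
    day_index: int = 0

    def __post_init__(self) -> None:
        if len(self.timestamps) != N_MINUTES:
            raise ValueError(f"a PhysioDay must have exactly {N_MINUTES} samples")
        steps = np.diff(self.timestamps.asi8)
        if len(steps) and not np.all(steps == 60 * 10**9):
            raise ValueError("timestamps must be a regular 1-min grid")
        for ch in CHANNELS:
            x = getattr(self, ch)
            if x is not None:
                x = np.asarray(x, dtype=float)
                if x.shape != (N_MINUTES,):
                    raise ValueError(f"channel {ch!r} must have {N_MINUTES} samples")
                setattr(self, ch, x)
        if self.mr is not None and np.nanmin(self.mr) < 0:
            raise ValueError("mr must be non-negative")
        if self.activity is not None and np.nanmin(self.activity) < 0:
            raise ValueError("activity must be non-negative")
        if self.rer is not None:
            r = self.rer[np.isfinite(self.rer)]
            if r.size and (r.min() < 0.6 or r.max() > 1.1):
                raise ValueError("rer must lie within [0.6, 1.1] where present")

    @property
    def clock_hours(self) -> np.ndarray:
        return np.arange(N_MINUTES) / 60.0

    @property
    def light_mask(self) -> np.ndarray:
        h = self.clock_hours
        lo, hi = self.light_phase
        return (h >= lo) & (h < hi)

    def channel(self, name: str) -> np.ndarray:
        x = getattr(self, name, None)
        if x is None:
            raise ValueError(f"channel {name!r} is missing from this record")
        return x

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "mr_mlo2_min": self.mr,
                "rer": self.rer,
                "tb_c": self.tb,
                "activity_counts": self.activity,
            }
        )


@dataclass
class BurstEvent:
    """One injected ultradian burst (ground truth)."""

    ur_class: str
    t_start: int
    t_peak: int
    t_end: int
    mr_amplitude: float
    tb_amplitude: float
    activity_amplitude: float
    tb_coupled: bool
    activity_coupled: bool


@dataclass
class GroundTruth:
    """Everything injected into one synthetic day."""

    periods: dict                      # class -> realized period (h)
    bursts: list                       # of BurstEvent
    rmr_trace: np.ndarray              # injected baseline, mL O2 min^-1
    mr_clean: np.ndarray               # noise-free MR
    ultradian_fraction: float          # injected (DEE - RMR)/DEE equivalent

    def events(self, ur_class: str) -> list:
        return [b for b in self.bursts if b.ur_class == ur_class]


def _burst_pulse(n: int, t_peak: int, rise: float, decay: float) -> np.ndarray:
    """Unit-height asymmetric raised-cosine-squared pulse on the minute grid.

    Fast rise, slower decay; the squared-Hann profile is continuously
    differentiable with long near-zero tails, so (a) its harmonic leakage in
    the wavelet periodogram stays well below the fundamental of the weakest
    class and (b) the summed trains still expose the resting baseline between
    bursts, which the RMR lower-envelope estimator depends on.  The pulse
    integral is 3/8 * (rise + decay).
    """
    t = np.arange(n, dtype=float)
    y = np.zeros(n)
    up = (t >= t_peak - rise) & (t <= t_peak)
    down = (t > t_peak) & (t <= t_peak + decay)
    y[up] = (0.5 * (1.0 + np.cos(np.pi * (t_peak - t[up]) / rise))) ** 2
    y[down] = (0.5 * (1.0 + np.cos(np.pi * (t[down] - t_peak) / decay))) ** 2
    return y


def _day_rng(config: SynthConfig, day_index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(day_index), int(stream)])
    )


def generate_day(
    config: SynthConfig,
    day_index: int = 0,
    *,
    periods: Optional[Sequence[float]] = None,
    subject_id: str = "synthetic",
):
    """Generate one synthetic 24-h record.

    Returns ``(PhysioDay, GroundTruth)``.  Identical ``(config, day_index)``
    yield bit-identical output.  ``periods`` overrides the configured class
    periods (used by :func:`generate_longitudinal` to apply day-to-day drift).
    """
    config.validate()
    rng = _day_rng(config, day_index)
    p_hours = np.asarray(periods if periods is not None else config.component_periods, float)
    if np.any(p_hours < 0.3) or np.any(p_hours > 6.0):
        raise ValueError("realized periods must lie within [0.3, 6] h")

    n = N_MINUTES
    clock = np.arange(n) / 60.0
    lo, hi = config.light_phase
    light = (clock >= lo) & (clock < hi)

    mr_clean = np.full(n, config.rmr_level, dtype=float)
    tb_drive = np.zeros(n)
    act_clean = np.zeros(n)
    rer_drive = np.zeros(n)
    bursts: list = []

    # Phase-stable timing jitter: each event is displaced independently from
    # a regular grid by a lognormal factor.  With displacement CV = cv/sqrt(2)
    # the inter-burst spacing has CV = cv around the class period, but phase
    # errors do not accumulate across the day, so the single-day periodogram
    # keeps a sharp peak at the class period (as real records do).
    if config.spacing_cv > 0:
        disp_cv = config.spacing_cv / math.sqrt(2.0)
        sigma = math.sqrt(math.log(1.0 + disp_cv**2))
    else:
        sigma = 0.0

    for ci, cname in enumerate(CLASS_NAMES):
        p_min = p_hours[ci] * 60.0
        amp = config.component_amplitudes[ci] * config.rmr_level
        if amp == 0.0:
            continue  # a silent class drives nothing
        rise = config.burst_rise_min[ci]
        decay = config.burst_decay_min[ci]
        t0 = rng.uniform(0.0, p_min)
        ks = np.arange(int(math.ceil((n - t0) / p_min)) + 1)
        if sigma > 0:
            disp = rng.lognormal(-0.5 * sigma**2, sigma, ks.size) - 1.0
        else:
            disp = np.zeros(ks.size)
        peaks = [int(round(x)) for x in t0 + ks * p_min + p_min * disp if 0 <= x < n]
        for tp in peaks:
            gate = 1.0 - config.circadian_attenuation if light[min(tp, n - 1)] else 1.0
            height = amp * gate
            unit = _burst_pulse(n, tp, rise, decay)
            mr_clean += height * unit
            tb_coupled = bool(rng.random() < config.tb_coupled_fraction[ci])
            act_coupled = bool(rng.random() < config.activity_coupled_fraction[ci])
            tb_amp = config.tb_gain_per_class[ci] * gate if tb_coupled else 0.0
            act_amp = config.activity_gain_per_class[ci] * gate if act_coupled else 0.0
            if tb_coupled:
                tb_drive += tb_amp * unit
            if act_coupled:
                act_clean += act_amp * unit
            if cname == "large":
                # RER dips to rer_burst_min at every large burst (not gated)
                rer_drive = np.maximum(rer_drive, unit)
            bursts.append(
                BurstEvent(
                    ur_class=cname,
                    t_start=max(0, int(round(tp - rise))),
                    t_peak=tp,
                    t_end=min(n - 1, int(round(tp + decay))),
                    mr_amplitude=height,
                    tb_amplitude=tb_amp,
                    activity_amplitude=act_amp,
                    tb_coupled=tb_coupled,
                    activity_coupled=act_coupled,
                )
            )

    # T_b: first-order low-pass of the drive (thermal inertia), lag in minutes
    if config.tb_lag_min > 0:
        a = math.exp(-1.0 / config.tb_lag_min)
        from scipy.signal import lfilter

        tb_clean = config.tb_base + lfilter([1.0 - a], [1.0, -a], tb_drive)
    else:
        tb_clean = config.tb_base + tb_drive

    rer_clean = config.rer_base - (config.rer_base - config.rer_burst_min) * np.minimum(
        rer_drive, 1.0
    )

    sd = dict(_default_noise_sd())
    sd.update(dict(config.noise_sd))
    mr = np.clip(mr_clean + rng.normal(0.0, sd["mr"], n) if sd["mr"] > 0 else mr_clean.copy(), 0.0, None)
    tb = tb_clean + rng.normal(0.0, sd["tb"], n) if sd["tb"] > 0 else tb_clean.copy()
    rer = np.clip(
        rer_clean + rng.normal(0.0, sd["rer"], n) if sd["rer"] > 0 else rer_clean.copy(),
        0.7,
        1.0,
    )
    activity = np.rint(
        np.clip(act_clean + rng.normal(0.0, sd["activity"], n) if sd["activity"] > 0 else act_clean.copy(), 0.0, None)
    )

    timestamps = pd.date_range(
        _BASE_DATE + pd.Timedelta(days=day_index), periods=n, freq="min"
    )
    day = PhysioDay(
        timestamps=timestamps,
        mr=mr,
        rer=rer,
        tb=tb,
        activity=activity,
        ta=config.ta,
        light_phase=config.light_phase,
        subject_id=subject_id,
        day_index=day_index,
    )
    rmr_trace = np.full(n, config.rmr_level)
    mean_clean = float(mr_clean.mean())
    frac = float((mr_clean - rmr_trace).mean() / mean_clean) if mean_clean > 0 else 0.0
    truth = GroundTruth(
        periods={c: float(p_hours[i]) for i, c in enumerate(CLASS_NAMES)},
        bursts=bursts,
        rmr_trace=rmr_trace,
        mr_clean=mr_clean,
        ultradian_fraction=frac,
    )
    return day, truth


def generate_longitudinal(config: SynthConfig, n_days: int, *, subject_id: str = "synthetic"):
    """Generate a day sequence with shared day-to-day period drift.

    The log-periods of all three classes follow one shared Gaussian random
    walk (SD ``period_drift`` per day) plus smaller independent per-class
    jitter (SD ``period_drift / 2``), so daily periods co-vary across classes
    without being exact harmonics.  Day 0 uses the configured base periods, so
    ``n_days=1`` reproduces :func:`generate_day` exactly.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2**20 + 11]))
    base = np.asarray(config.component_periods, dtype=float)
    out = []
    walk = 0.0
    for d in range(n_days):
        if d == 0:
            periods = base.copy()
        else:
            walk += rng.normal(0.0, config.period_drift)
            jitter = rng.normal(0.0, 0.5 * config.period_drift, size=3)
            periods = np.clip(base * math.exp(walk) * np.exp(jitter), 0.3, 6.0)
            periods = np.sort(periods)
        out.append(generate_day(config, d, periods=periods, subject_id=subject_id))
    return out


@dataclass
class TsfTrace:
    """1-s surface-temperature traces from IR thermovision.

    ``hamster_tsf`` follows the animal; the two cage traces monitor the cage
    floor outside the nest and rise above ~30 degC when the animal sits there.
    """

    timestamps: pd.DatetimeIndex
    hamster_tsf: np.ndarray
    cage_tsf_1: np.ndarray
    cage_tsf_2: np.ndarray

    def __post_init__(self) -> None:
        nsec = len(self.timestamps)
        for name in ("hamster_tsf", "cage_tsf_1", "cage_tsf_2"):
            x = np.asarray(getattr(self, name), dtype=float)
            if x.shape != (nsec,):
                raise ValueError(f"{name} must match the timestamp grid")
            if x.min() < 5.0 or x.max() > 45.0:
                raise ValueError(f"{name} must lie within [5, 45] degC")
            setattr(self, name, x)
        steps = np.diff(self.timestamps.asi8)
        if len(steps) and not np.all(steps == 10**9):
            raise ValueError("timestamps must be a regular 1-s grid")


@dataclass
class TsfGroundTruth:
    outside_mask: np.ndarray        # per minute, bool
    episodes: list                  # of (start_min, end_min) half-open

    @property
    def outside_minutes(self) -> int:
        return int(self.outside_mask.sum())


def generate_tsf_trace(
    config: SynthConfig,
    day: PhysioDay,
    ground_truth: Optional[GroundTruth] = None,
    *,
    episodes: Optional[Sequence] = None,
    noise_floor: float = 0.05,
    activity_sd_gain: float = 0.08,
):
    """Generate 1-s IR surface-temperature traces matched to a PhysioDay.

    The hamster trace's within-minute SD scales with the animal's activity;
    the two cage-floor traces sit near ambient and rise above 30 degC during
    outside-nest episodes.  Episodes default to the spans of injected
    large-class bursts (``ground_truth``) or, failing that, to minutes with
    non-zero activity.  Returns ``(TsfTrace, TsfGroundTruth)``.
    """
    rng = _day_rng(config, day.day_index, stream=777)
    n_min = N_MINUTES
    outside = np.zeros(n_min, dtype=bool)
    if episodes is not None:
        ep_list = [(int(a), int(b)) for a, b in episodes]
        for a, b in ep_list:
            outside[a:b] = True
    elif ground_truth is not None:
        for ev in ground_truth.events("large"):
            outside[ev.t_start : ev.t_end + 1] = True
    elif day.activity is not None:
        outside = day.activity > 0
    ep_list = _mask_to_episodes(outside)

    act = day.activity if day.activity is not None else np.zeros(n_min)
    sigma = noise_floor + activity_sd_gain * np.asarray(act, float)
    hamster = 28.0 + rng.normal(0.0, 1.0, size=(n_min, SECONDS_PER_MINUTE)) * sigma[:, None]

    cage1 = 0.0 + rng.normal(0.0, 0.1, size=(n_min, SECONDS_PER_MINUTE)) + day.ta
    cage2 = 0.0 + rng.normal(0.0, 0.1, size=(n_min, SECONDS_PER_MINUTE)) + day.ta
    for k, (a, b) in enumerate(ep_list):
        target = cage1 if k % 2 == 0 else cage2
        target[a:b, :] = 33.0 + rng.normal(0.0, 0.5, size=(b - a, SECONDS_PER_MINUTE))

    timestamps = pd.date_range(day.timestamps[0], periods=n_min * SECONDS_PER_MINUTE, freq="s")
    trace = TsfTrace(
        timestamps=timestamps,
        hamster_tsf=np.clip(hamster.ravel(), 5.0, 45.0),
        cage_tsf_1=np.clip(cage1.ravel(), 5.0, 45.0),
        cage_tsf_2=np.clip(cage2.ravel(), 5.0, 45.0),
    )
    return trace, TsfGroundTruth(outside_mask=outside, episodes=ep_list)


def _mask_to_episodes(mask: np.ndarray) -> list:
    """Contiguous True runs of a boolean mask as half-open (start, end) pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]] + 1
    return list(zip(starts.tolist(), ends.tolist()))


def cold_challenge_configs(base: Optional[SynthConfig] = None):
    """Paired scenarios emulating a thermoneutral vs moderate-cold contrast.

    The cold scenario raises the resting baseline (~70%) while keeping the
    absolute ultradian drive unchanged, which is the observed physiological
    response: burst energy stays constant while RMR carries the extra
    thermoregulatory load.
    """
    if base is None:
        base = SynthConfig()
    warm_rmr, cold_rmr = 0.845, 1.423
    warm_amp = np.asarray(base.component_amplitudes, float)
    warm = replace(base, rmr_level=warm_rmr, component_amplitudes=tuple(warm_amp), ta=24.0)
    cold = replace(
        base,
        rmr_level=cold_rmr,
        component_amplitudes=tuple(warm_amp * warm_rmr / cold_rmr),
        ta=16.0,
    )
    return warm, cold
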