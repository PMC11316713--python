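"""Unit conversions and energy computations for gas-exchange data.

Heat production follows the mixed carbohydrate/lipid combustion calibration

    HP [mW] = (4.44 + 1.43 * RER) * VO2 [mL O2 h^-1]

so a resting animal consuming 1 mL O2 min^-1 at RER 1.0 produces 352.2 mW and
spends 30.43 kJ over 24 h.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

MW_TO_KJ_PER_DAY = 86400.0 / 1e6  # 1 mW sustained for 24 h = 0.0864 kJ


def heat_production(vo2, rer):
    """Heat production in mW from VO2 (mL O2 h^-1) and RER.

    Vectorised; raises on negative or non-finite VO2 and warns when RER is
    outside the physiological range [0.7, 1.0].
    """
    vo2 = np.asarray(vo2, dtype=float)
    rer = np.asarray(rer, dtype=float)
    if not np.all(np.isfinite(vo2)) or not np.all(np.isfinite(rer)):
        raise ValueError("vo2 and rer must be finite")
    if np.any(vo2 < 0):
        raise ValueError("vo2 must be non-negative")
    if np.any(rer < 0.6) or np.any(rer > 1.1):
        raise ValueError("rer outside the plausible range [0.6, 1.1]")
    if np.any(rer < 0.7) or np.any(rer > 1.0):
        warnings.warn("RER outside [0.7, 1.0]; heat production extrapolated", stacklevel=2)
    hp = (4.44 + 1.43 * rer) * vo2
    return float(hp) if hp.ndim == 0 else hp


def running_average(series, window: int):
    """Centered moving mean with shrinking windows at the edges.

    Length-preserving; ``window=1`` is the identity.  Accepts arrays or
    pandas Series (returned as the same type).
    """
    if window < 1 or int(window) != window:
        raise ValueError("window must be a positive integer number of minutes")
    values = np.asarray(series, dtype=float)
    if window > values.size:
        raise ValueError("window larger than the series")
    sm = pd.Series(values).rolling(int(window), center=True, min_periods=1).mean()
    if isinstance(series, pd.Series):
        return pd.Series(sm.to_numpy(), index=series.index)
    return sm.to_numpy()


def fill_rer(rer: np.ndarray, window: int = 30) -> np.ndarray:
    """Fill missing RER samples with the day's running-average RER."""
    rer = np.asarray(rer, dtype=float)
    if not np.any(np.isnan(rer)):
        return rer
    if np.all(np.isnan(rer)):
        raise ValueError("RER channel is entirely missing")
    sm = pd.Series(rer).rolling(window, center=True, min_periods=1).mean()
    sm = sm.ffill().bfill()
    out = rer.copy()
    out[np.isnan(out)] = sm.to_numpy()[np.isnan(rer)]
    return out


@dataclass
class EnergySummary:
    """Integrated energy of one record: DEE in kJ over the window and the
    time-mean heat production in mW.  For a full 24-h record
    ``dee_kj == mean_hp_mw * 86400 / 1e6`` exactly."""

    dee_kj: float
    mean_hp_mw: float
    n_minutes: int


def energy_from_series(mr, rer, rer_fill_window: int = 30) -> EnergySummary:
    """Integrate per-minute heat production of an MR (mL O2 min^-1) series."""
    mr = np.asarray(mr, dtype=float)
    rer = fill_rer(np.asarray(rer, dtype=float), rer_fill_window)
    if mr.shape != rer.shape:
        raise ValueError("mr and rer must be aligned")
    hp_mw = heat_production(mr * 60.0, rer)  # per-minute VO2 -> hourly rate
    hp_mw = np.atleast_1d(hp_mw)
    mean_hp = float(hp_mw.mean())
    dee_kj = float(hp_mw.sum() * 60.0 / 1e6)  # mW * s -> mJ -> kJ
    return EnergySummary(dee_kj=dee_kj, mean_hp_mw=mean_hp, n_minutes=mr.size)


def daily_energy(day) -> EnergySummary:
    """Daily energy expenditure of a :class:`~ultradian.synth.PhysioDay`.

    Requires the MR and RER channels; missing RER samples are filled with the
    day's 30-min running average before integration.
    """
    if day.mr is None or day.rer is None:
        raise ValueError("daily_energy requires MR and RER channels")
    return energy_from_series(day.mr, day.rer)
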