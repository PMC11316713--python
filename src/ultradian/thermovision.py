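"""Activity index and nest occupancy from IR surface-temperature traces.

Body movements cause rapid changes of the surface temperature seen by an
overhead thermography camera, so the per-minute standard deviation of the
1-s hamster trace is an index of total activity.  The cage-floor traces sit
near ambient and rise above ~30 degC whenever the animal is active outside
its nest, which yields a nest-occupancy score.
"""
from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SECONDS_PER_MINUTE = 60


def _per_minute(x: np.ndarray) -> np.ndarray:
    n_full = x.size // SECONDS_PER_MINUTE
    if x.size % SECONDS_PER_MINUTE:
        logger.info("dropping incomplete trailing minute (%d samples)",
                    x.size % SECONDS_PER_MINUTE)
    return x[: n_full * SECONDS_PER_MINUTE].reshape(n_full, SECONDS_PER_MINUTE)


def activity_index(trace) -> pd.Series:
    """Per-minute sample SD (ddof=1) of the hamster surface temperature."""
    mins = _per_minute(np.asarray(trace.hamster_tsf, dtype=float))
    sd = mins.std(axis=1, ddof=1)
    return pd.Series(sd, name="tsf_sd_per_min")


def outside_nest_minutes(
    trace,
    threshold: float = 30.0,
    *,
    min_samples: int = 30,
):
    """Minutes spent outside the nest, scored from the cage-floor traces.

    A minute counts as outside-nest when either cage trace exceeds
    ``threshold`` degC for at least ``min_samples`` of its 60 samples;
    contiguous outside minutes merge into episodes.  Returns
    ``(total_minutes, episodes)`` with half-open minute intervals.
    """
    c1 = _per_minute(np.asarray(trace.cage_tsf_1, dtype=float))
    c2 = _per_minute(np.asarray(trace.cage_tsf_2, dtype=float))
    outside = ((c1 > threshold).sum(axis=1) >= min_samples) | (
        (c2 > threshold).sum(axis=1) >= min_samples
    )
    idx = np.flatnonzero(outside)
    episodes = []
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.r_[idx[0], idx[breaks + 1]]
        ends = np.r_[idx[breaks], idx[-1]] + 1
        episodes = list(zip(starts.tolist(), ends.tolist()))
    return int(outside.sum()), episodes


def activity_mr_relation(day, activity_series, *, standardize: bool = False) -> dict:
    """Least-squares relation between MR and a per-minute activity index.

    Returns the slope of MR on activity, the Pearson r and its p-value;
    computed identically for transmitter counts and the IR index so the two
    methods can be compared.  With ``standardize`` the activity series is
    z-scored first, so slopes are in MR units per SD of activity and are
    directly comparable across indices measured in different units.
    """
    if day.mr is None:
        raise ValueError("activity_mr_relation requires the MR channel")
    act = np.asarray(activity_series, dtype=float)
    mr = np.asarray(day.mr, dtype=float)
    m = min(act.size, mr.size)
    act, mr = act[:m], mr[:m]
    if np.ptp(act) == 0:
        raise ValueError("activity series has zero variance")
    if standardize:
        act = (act - act.mean()) / act.std()
    res = stats.linregress(act, mr)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r": float(res.rvalue), "p": float(res.pvalue), "n": m}
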