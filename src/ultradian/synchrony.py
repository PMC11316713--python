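"""Longitudinal synchrony of daily ultradian periods.

Day-by-day period estimates for the three ultradian classes and the three
recorded variables form a time-course; Pearson correlations over pairwise-
complete days quantify how strongly the classes (and variables) drift in
parallel.  Counting significant (p < 0.05) comparisons summarises the degree
of synchrony across a cohort.
"""
from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CLASS_NAMES = ("small", "medium", "large")
MIN_PAIRS = 5


def period_timecourse(per_day: Sequence[dict], subject_id: str = "") -> pd.DataFrame:
    """Build a day x (variable, class) period matrix.

    ``per_day`` is a sequence (one entry per day) of mappings
    ``variable -> URClassPeriods`` (or ``variable -> {class: period}``).
    Missing entries are NaN.
    """
    records = {}
    for d, entry in enumerate(per_day):
        for var, cp in entry.items():
            d_periods = cp.as_dict() if hasattr(cp, "as_dict") else dict(cp)
            for cname in CLASS_NAMES:
                records.setdefault((var, cname), {})[d] = d_periods.get(cname)
    tc = pd.DataFrame(records)
    tc.columns = pd.MultiIndex.from_tuples(tc.columns, names=["variable", "ur_class"])
    tc.index.name = "day"
    tc.attrs["subject_id"] = subject_id
    return tc.sort_index()


def default_pairs(tc: pd.DataFrame) -> list:
    """Class-vs-class pairs within each variable, then variable-vs-variable
    pairs within each class."""
    variables = sorted({v for v, _ in tc.columns})
    pairs = []
    for var in variables:
        for i, c1 in enumerate(CLASS_NAMES):
            for c2 in CLASS_NAMES[i + 1 :]:
                pairs.append(((var, c1), (var, c2)))
    if len(variables) > 1:
        for cname in CLASS_NAMES:
            for i, v1 in enumerate(variables):
                for v2 in variables[i + 1 :]:
                    pairs.append(((v1, cname), (v2, cname)))
    return pairs


def pairwise_correlations(
    tc: pd.DataFrame,
    pairs: Optional[Iterable] = None,
    *,
    min_pairs: int = MIN_PAIRS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson r and two-sided p for each requested column pair.

    Days where either series is missing are dropped pairwise.  Comparisons
    with fewer than ``min_pairs`` complete days, or zero variance, are
    reported missing (NaN r/p, significant=False) rather than fabricated.
    """
    if pairs is None:
        pairs = default_pairs(tc)
    rows = []
    for (a, b) in pairs:
        label = f"{a[0]}:{a[1]} vs {b[0]}:{b[1]}"
        xa = tc[a] if a in tc.columns else pd.Series(dtype=float)
        xb = tc[b] if b in tc.columns else pd.Series(dtype=float)
        joined = pd.concat([xa, xb], axis=1, keys=["a", "b"]).dropna()
        n = len(joined)
        r = p = np.nan
        if n >= min_pairs and joined["a"].std() > 0 and joined["b"].std() > 0:
            r, p = stats.pearsonr(joined["a"], joined["b"])
        rows.append(
            {
                "pair": label,
                "var_a": a[0], "class_a": a[1],
                "var_b": b[0], "class_b": b[1],
                "r": r, "p": p, "n": n,
                "significant": bool(np.isfinite(p) and p < alpha),
            }
        )
    return pd.DataFrame(rows)


def synchrony_summary(tables) -> dict:
    """Counts of significant comparisons across one or more synchrony tables.

    Comparisons whose correlation could not be computed (missing r) are
    excluded from the total.  The percentage is rendered at one decimal.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    total = 0
    significant = 0
    for t in tables:
        computed = t[np.isfinite(t["r"].astype(float))]
        total += len(computed)
        significant += int(computed["significant"].sum())
    pct = round(100.0 * significant / total, 1) if total else 0.0
    return {"total": total, "significant": significant, "percent": pct}
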