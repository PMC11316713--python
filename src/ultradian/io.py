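"""Tidy CSV / JSON-sidecar input and output for physiological records."""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .synth import GroundTruth, PhysioDay, TsfTrace

CSV_COLUMNS = ["timestamp", "mr_mlo2_min", "rer", "tb_c", "activity_counts"]


def write_physioday(
    day: PhysioDay,
    csv_path,
    *,
    sidecar_path=None,
    ground_truth: Optional[GroundTruth] = None,
) -> None:
    """Write a day as tidy CSV plus an optional JSON metadata sidecar."""
    frame = day.to_frame()
    frame["timestamp"] = frame["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    frame.to_csv(csv_path, index=False)
    if sidecar_path is not None:
        meta = {
            "subject_id": day.subject_id,
            "day_index": day.day_index,
            "ta_c": day.ta,
            "light_phase_h": list(day.light_phase),
        }
        if ground_truth is not None:
            meta["ground_truth"] = {
                "periods_h": ground_truth.periods,
                "ultradian_fraction": ground_truth.ultradian_fraction,
                "rmr_level": float(np.mean(ground_truth.rmr_trace)),
                "bursts": [dataclasses.asdict(b) for b in ground_truth.bursts],
            }
        Path(sidecar_path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_physioday(csv_path, sidecar_path=None) -> PhysioDay:
    """Read a day from the tidy CSV (and metadata sidecar when present)."""
    frame = pd.read_csv(csv_path, parse_dates=["timestamp"])
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"CSV is missing columns: {missing}")
    meta = {}
    if sidecar_path is not None:
        meta = json.loads(Path(sidecar_path).read_text())

    def _channel(col):
        x = frame[col].to_numpy(dtype=float)
        return None if np.all(np.isnan(x)) else x

    return PhysioDay(
        timestamps=pd.DatetimeIndex(frame["timestamp"]),
        mr=_channel("mr_mlo2_min"),
        rer=_channel("rer"),
        tb=_channel("tb_c"),
        activity=_channel("activity_counts"),
        ta=float(meta.get("ta_c", 15.0)),
        light_phase=tuple(meta.get("light_phase_h", (8.0, 16.0))),
        subject_id=str(meta.get("subject_id", "unknown")),
        day_index=int(meta.get("day_index", 0)),
    )


def write_spectrum(spectrum, out_dir, peaks=None) -> None:
    """Export a wavelet spectrum as CSV matrices plus a JSON peak summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        spectrum.power,
        index=pd.Index(spectrum.periods_h, name="period_h"),
        columns=spectrum.times_min.astype(int),
    ).to_csv(out / "power.csv")
    summary = pd.DataFrame(
        {
            "period_h": spectrum.periods_h,
            "avg_power": spectrum.avg_power,
            "sig_threshold": (
                spectrum.sig_threshold
                if spectrum.sig_threshold is not None
                else np.full_like(spectrum.avg_power, np.nan)
            ),
        }
    )
    summary.to_csv(out / "periodogram.csv", index=False)
    if peaks is not None:
        (out / "peaks.json").write_text(
            json.dumps([dataclasses.asdict(p) for p in peaks], indent=2)
        )


def write_burst_table(bursts_by_class: dict, csv_path) -> None:
    """One row per burst, all classes pooled."""
    rows = [
        dataclasses.asdict(b)
        for bursts in bursts_by_class.values()
        for b in bursts
    ]
    pd.DataFrame(rows).to_csv(csv_path, index=False)


def write_tsf_trace(trace: TsfTrace, csv_path) -> None:
    pd.DataFrame(
        {
            "timestamp": trace.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "hamster_tsf": trace.hamster_tsf,
            "cage1_tsf": trace.cage_tsf_1,
            "cage2_tsf": trace.cage_tsf_2,
        }
    ).to_csv(csv_path, index=False)


def read_tsf_trace(csv_path) -> TsfTrace:
    frame = pd.read_csv(csv_path, parse_dates=["timestamp"])
    return TsfTrace(
        timestamps=pd.DatetimeIndex(frame["timestamp"]),
        hamster_tsf=frame["hamster_tsf"].to_numpy(dtype=float),
        cage_tsf_1=frame["cage1_tsf"].to_numpy(dtype=float),
        cage_tsf_2=frame["cage2_tsf"].to_numpy(dtype=float),
    )
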