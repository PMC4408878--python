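"""Plain-text interchange formats: spike/burst/cycle TSV and timeline JSON.

All tables are UTF-8, tab-separated, '.' decimal, with a header line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .longterm import PreparationTimeline
from .synth import SpikeTrain

__all__ = [
    "write_spike_tsv",
    "read_spike_tsv",
    "write_burst_tsv",
    "read_burst_tsv",
    "write_cycle_tsv",
    "read_cycle_tsv",
    "write_timeline_json",
    "read_timeline_json",
]


def write_spike_tsv(path, trains: list[SpikeTrain]) -> None:
    """Spike table: ``prep_id, unit, time_s``, sorted within each train."""
    frames = [
        pd.DataFrame({"prep_id": tr.prep_id, "unit": tr.unit, "time_s": tr.times})
        for tr in trains
    ]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["prep_id", "unit", "time_s"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_spike_tsv(path) -> list[SpikeTrain]:
    df = pd.read_csv(path, sep="\t")
    trains = []
    for (prep, unit), sub in df.groupby(["prep_id", "unit"], sort=True):
        trains.append(SpikeTrain(str(prep), str(unit), np.sort(sub["time_s"].to_numpy())))
    return trains


def write_burst_tsv(path, bursts: pd.DataFrame, prep_id: str, unit: str) -> None:
    out = bursts.copy()
    out.insert(0, "unit", unit)
    out.insert(0, "prep_id", prep_id)
    out = out.rename(columns={"start": "start_s", "end": "end_s"})
    out.to_csv(path, sep="\t", index=False)


def append_burst_tsv(frames: list, bursts: pd.DataFrame, prep_id: str, unit: str) -> None:
    out = bursts.copy()
    out.insert(0, "unit", unit)
    out.insert(0, "prep_id", prep_id)
    frames.append(out.rename(columns={"start": "start_s", "end": "end_s"}))


def read_burst_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(columns={"start_s": "start", "end_s": "end"})


def write_cycle_tsv(path, cycles: pd.DataFrame, prep_id: str | None = None) -> None:
    out = cycles.copy()
    if prep_id is not None and "prep_id" not in out.columns:
        out.insert(0, "prep_id", prep_id)
    out.to_csv(path, sep="\t", index=False)


def read_cycle_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "invalid_reason" in df.columns:
        df["invalid_reason"] = df["invalid_reason"].fillna("")
    return df


def write_timeline_json(path, timelines: list[PreparationTimeline], extra: dict | None = None) -> None:
    payload = {
        "preparations": [
            {
                "prep_id": tl.prep_id,
                "condition": tl.condition,
                "recording_start": tl.recording_start,
                "decentralization_time": tl.decentralization_time,
                "saline_exchange_times": list(tl.saline_exchange_times),
                "baseline_duration": tl.baseline_duration,
            }
            for tl in timelines
        ]
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_timeline_json(path) -> list[PreparationTimeline]:
    payload = json.loads(Path(path).read_text())
    return [
        PreparationTimeline(
            prep_id=p["prep_id"],
            condition=p["condition"],
            recording_start=p["recording_start"],
            decentralization_time=p["decentralization_time"],
            saline_exchange_times=tuple(p["saline_exchange_times"]),
            baseline_duration=p.get("baseline_duration", 3600.0),
        )
        for p in payload["preparations"]
    ]
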