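"""Reading and writing recordings and analysis reports.

A recording is a CSV (`<prefix>.csv`) with columns ``time_s, lvp_mmhg,
lvv_ml, lvv_raw_ml, aop_mmhg, aoflow_ml_s, ecg_mv`` plus a JSON sidecar
(`<prefix>.json`) holding the simulator configuration, the protocol, the
annotations and the per-beat ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .synth_hemo import BeatTruth, Protocol, SignalRecording, SimConfig

_COLUMNS = {
    "lvp": "lvp_mmhg",
    "lvv": "lvv_ml",
    "lvv_raw": "lvv_raw_ml",
    "aop": "aop_mmhg",
    "aoflow": "aoflow_ml_s",
    "ecg": "ecg_mv",
}


def write_recording(recording: SignalRecording, prefix: str | Path) -> tuple[Path, Path]:
    """Write `<prefix>.csv` and the `<prefix>.json` sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"time_s": recording.time})
    for ch, col in _COLUMNS.items():
        df[col] = recording.channels[ch]
    csv_path = prefix.with_suffix(".csv")
    df.to_csv(csv_path, index=False, float_format="%.6g")

    sidecar = {
        "fs": recording.fs,
        "annotations": [list(a) for a in recording.annotations],
        "truth": [t.model_dump() for t in recording.truth] if recording.truth else None,
        "meta": recording.meta,
    }
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, json_path


def read_recording(prefix: str | Path) -> SignalRecording:
    """Load a recording written by :func:`write_recording`."""
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".csv"))
    side_path = prefix.with_suffix(".json")
    annotations: list = []
    truth: Optional[list[BeatTruth]] = None
    meta: dict = {}
    fs = None
    if side_path.exists():
        side = json.loads(side_path.read_text())
        fs = side.get("fs")
        annotations = [tuple(a) for a in side.get("annotations", [])]
        if side.get("truth"):
            truth = [BeatTruth(**t) for t in side["truth"]]
        meta = side.get("meta", {})
    if fs is None:
        dt = np.median(np.diff(df["time_s"].to_numpy()))
        fs = 1.0 / dt
    channels = {ch: df[col].to_numpy() for ch, col in _COLUMNS.items() if col in df}
    return SignalRecording(fs, channels, annotations=annotations, truth=truth, meta=meta)


def sim_config_from_meta(recording: SignalRecording) -> Optional[SimConfig]:
    cfg = recording.meta.get("config")
    return SimConfig(**cfg) if cfg else None


def protocol_from_meta(recording: SignalRecording) -> Optional[Protocol]:
    prot = recording.meta.get("protocol")
    return Protocol(**prot) if prot else None
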