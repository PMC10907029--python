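"""Reading and writing records and ground truth.

A subject is stored as a wide CSV of sampled channels
(``t, ecg, pressure, respiration, msna``) plus a JSON sidecar carrying
the sample rate, the generator parameters and, for synthetic subjects,
the ground-truth tables.  The ``t`` column is optional on read when the
sidecar provides ``fs``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .params import SubjectParams
from .records import CHANNEL_NAMES, GroundTruth, SignalRecord

__all__ = ["write_record", "read_record"]


def write_record(
    record: SignalRecord,
    path: str | Path,
    truth: GroundTruth | None = None,
) -> tuple[Path, Path]:
    """Write ``<path>.csv`` (channels) and ``<path>.json`` (metadata)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")

    df = pd.DataFrame({"t": record.time()})
    for name in CHANNEL_NAMES:
        if name in record:
            df[name] = record[name]
    df.to_csv(csv_path, index=False, float_format="%.8g")

    meta: dict = {"fs": record.fs, "start_time": record.start_time}
    if record.r_annotations is not None:
        meta["r_annotations"] = list(map(float, record.r_annotations))
    if truth is not None:
        meta["params"] = truth.params.to_dict()
        meta["ground_truth"] = {
            "r_times": list(map(float, truth.r_times)),
            "beats": truth.beats.to_dict(orient="list"),
            "resp_landmarks": truth.resp_landmarks.to_dict(orient="list"),
            "bursts": truth.bursts.to_dict(orient="list"),
        }
    with open(json_path, "w") as fh:
        json.dump(meta, fh)
    return csv_path, json_path


def read_record(path: str | Path) -> tuple[SignalRecord, GroundTruth | None]:
    """Read a record written by :func:`write_record`.

    Returns the record and, when the sidecar carries ground truth, the
    reconstructed :class:`GroundTruth` (else None).
    """
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")
    df = pd.read_csv(csv_path)
    meta: dict = {}
    if json_path.exists():
        with open(json_path) as fh:
            meta = json.load(fh)
    if "fs" in meta:
        fs = float(meta["fs"])
    elif "t" in df.columns and len(df) > 1:
        fs = 1.0 / float(np.median(np.diff(df["t"].to_numpy())))
    else:
        raise ValueError("cannot determine sample rate: no sidecar and no t column")
    start_time = float(meta.get("start_time", df["t"].iloc[0] if "t" in df else 0.0))
    channels = {
        name: df[name].to_numpy(dtype=float)
        for name in CHANNEL_NAMES
        if name in df.columns
    }
    if not channels:
        raise ValueError(f"no known channels in {csv_path}")
    ann = meta.get("r_annotations")
    record = SignalRecord(
        fs=fs,
        channels=channels,
        start_time=start_time,
        r_annotations=np.asarray(ann, dtype=float) if ann is not None else None,
    )

    truth = None
    if "ground_truth" in meta:
        gt = meta["ground_truth"]
        truth = GroundTruth(
            params=SubjectParams.from_dict(meta["params"]),
            r_times=np.asarray(gt["r_times"], dtype=float),
            beats=pd.DataFrame(gt["beats"]),
            resp_landmarks=pd.DataFrame(gt["resp_landmarks"]),
            bursts=pd.DataFrame(gt["bursts"]),
        )
    return record, truth
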