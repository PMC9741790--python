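"""CSV/JSON serialization of recordings, boundaries and processed signals."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from gaitent.errors import ParameterError
from gaitent.segmentation import StrideSegmentation
from gaitent.synthetic import GaitParams, GaitRecording


def write_recording_csv(
    recording: GaitRecording,
    path,
    params: GaitParams | None = None,
    sidecar: bool = False,
) -> None:
    """Write `time,copap,copml,vgrf` rows; optional JSON side-car with the
    generator params and ground-truth boundaries."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time": recording.time,
            "copap": recording.copap,
            "copml": recording.copml,
            "vgrf": recording.vgrf,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")
    if sidecar:
        meta = {
            "sampling_rate": recording.sampling_rate,
            "true_boundaries": None
            if recording.true_boundaries is None
            else [int(b) for b in recording.true_boundaries],
            "params": dataclasses.asdict(params) if params is not None else None,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_recording_csv(path, sampling_rate: float | None = None) -> GaitRecording:
    """Read a `time,copap,copml,vgrf` CSV; the rate is inferred from the
    time column unless given."""
    df = pd.read_csv(path)
    required = {"time", "copap", "copml", "vgrf"}
    if not required.issubset(df.columns):
        raise ParameterError("csv", f"missing columns {sorted(required - set(df.columns))}")
    if sampling_rate is None:
        dt = np.diff(df["time"].to_numpy())
        if len(dt) == 0 or not np.all(dt > 0):
            raise ParameterError("time", "cannot infer sampling rate from time column")
        sampling_rate = 1.0 / float(np.median(dt))
    return GaitRecording(
        sampling_rate=sampling_rate,
        copap=df["copap"].to_numpy(dtype=float),
        copml=df["copml"].to_numpy(dtype=float),
        vgrf=df["vgrf"].to_numpy(dtype=float),
    )


def write_boundaries_json(segmentation: StrideSegmentation, path) -> None:
    """0-based stride-start sample indices, half-open cycles [b_i, b_{i+1})."""
    Path(path).write_text(
        json.dumps(
            {
                "boundaries": [int(b) for b in segmentation.boundaries],
                "source_rate": segmentation.source_rate,
            },
            indent=2,
        )
    )


def read_boundaries_json(path) -> StrideSegmentation:
    meta = json.loads(Path(path).read_text())
    b = np.asarray(meta["boundaries"], dtype=int)
    rate = float(meta["source_rate"])
    return StrideSegmentation(boundaries=b, stride_durations=np.diff(b) / rate, source_rate=rate)
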