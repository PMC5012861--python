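"""Trace and event file formats.

Traces are stored in a fixed-column CSV dialect (UTF-8, decimal point,
header row)::

    time_s,eyeL_h,eyeL_v,eyeL_t,eyeR_h,eyeR_v,eyeR_t,valid_L,valid_R,phase,stimulus_state

Angles are degrees, times seconds; invalid positions are written as empty
fields.  Event logs and run manifests are JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from barmkit.types import BlinkRecord, EyeTraceBlock, FastPhaseRecord, GroundTruthLog

TRACE_COLUMNS = [
    "time_s",
    "eyeL_h", "eyeL_v", "eyeL_t",
    "eyeR_h", "eyeR_v", "eyeR_t",
    "valid_L", "valid_R",
    "phase", "stimulus_state",
]
PHASES = {"dark1", "flow1", "dark2", "flow2"}


class TraceFormatError(ValueError):
    pass


def write_trace(block: EyeTraceBlock, path) -> None:
    df = block.to_dataframe()
    df.to_csv(path, index=False, float_format="%.17g")


def read_trace(path, modality: str = "video") -> EyeTraceBlock:
    """Read a trace CSV, validating the dialect.

    Raises :class:`TraceFormatError` with a (1-based, header-inclusive) line
    number for a malformed header, non-monotone time or unknown phase label.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != TRACE_COLUMNS:
        raise TraceFormatError(
            f"{path}: line 1: malformed header; expected {','.join(TRACE_COLUMNS)}"
        )
    time = df["time_s"].to_numpy(dtype=float)
    if len(time) == 0:
        raise TraceFormatError(f"{path}: no data rows")
    bad = np.where(np.diff(time) <= 0)[0]
    if len(bad):
        # +3: 1 for the header, 1 for 0-based, 1 because the *second* of the
        # offending pair is the row that goes backwards
        raise TraceFormatError(
            f"{path}: line {int(bad[0]) + 3}: time_s not strictly increasing"
        )
    unknown = ~df["phase"].isin(PHASES)
    if unknown.any():
        row = int(np.where(unknown.to_numpy())[0][0])
        raise TraceFormatError(
            f"{path}: line {row + 2}: unknown phase label {df['phase'].iloc[row]!r}"
        )
    for col in ("valid_L", "valid_R"):
        if not df[col].isin((0, 1)).all():
            raise TraceFormatError(f"{path}: column {col} must contain only 0/1")
    dt = np.diff(time)
    fs = 1.0 / float(np.median(dt))
    return EyeTraceBlock(
        time=time,
        left={c: df[f"eyeL_{c}"].to_numpy(dtype=float) for c in ("h", "v", "t")},
        right={c: df[f"eyeR_{c}"].to_numpy(dtype=float) for c in ("h", "v", "t")},
        valid_left=df["valid_L"].to_numpy(dtype=bool),
        valid_right=df["valid_R"].to_numpy(dtype=bool),
        phase_label=df["phase"].to_numpy(dtype=object),
        stimulus_state=df["stimulus_state"].to_numpy(dtype=object),
        modality=modality,
        sampling_rate=float(round(fs)),
    )


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def write_ground_truth(log: GroundTruthLog, path) -> None:
    payload = {
        "gains_by_phase": dict(log.gains_by_phase),
        "plateau": log.plateau,
        "slow_phase_velocity": log.slow_phase_velocity,
        "flow_direction": log.flow_direction,
        "blinks": [_jsonable(dataclasses.asdict(b)) for b in log.blinks],
        "fast_phases": [_jsonable(dataclasses.asdict(f)) for f in log.fast_phases],
        "blanks": [list(b) for b in log.blanks],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_ground_truth(path) -> GroundTruthLog:
    with open(path) as fh:
        payload = json.load(fh)
    log = GroundTruthLog(
        gains_by_phase=payload["gains_by_phase"],
        plateau=payload["plateau"],
        slow_phase_velocity=payload["slow_phase_velocity"],
        flow_direction=payload["flow_direction"],
    )
    log.blinks = [
        BlinkRecord(**{k: (np.nan if v is None and k.startswith("torsion") else v) for k, v in b.items()})
        for b in payload["blinks"]
    ]
    log.fast_phases = [FastPhaseRecord(**f) for f in payload["fast_phases"]]
    log.blanks = [tuple(b) for b in payload["blanks"]]
    return log


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config, seed, files, extra=None) -> dict:
    import datetime

    from barmkit import __version__

    manifest = {
        "software_version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "files": {str(p): file_sha256(p) for p in files},
        "created": datetime.datetime.now().isoformat(timespec="seconds"),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
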