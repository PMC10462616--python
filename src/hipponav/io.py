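"""Deterministic readers/writers for sessions, behaviour and features.

A session bundle is a raw little-endian float32 channel-major matrix
(``<name>.dat``) plus a JSON sidecar (``<name>.json``) carrying the
sampling rate and channel metadata.  Behavioural traces and feature
tables travel as plain CSV.  All writers are byte-deterministic: floats
are formatted with 17 significant digits (lossless double round trip)
and sidecar keys have a fixed order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import FeatureTable
from .simulate import BehavioralTrace, RecordingSession

__all__ = [
    "FormatError",
    "write_session",
    "read_session",
    "write_behavior",
    "read_behavior",
    "write_feature_table",
    "read_feature_table",
]

log = logging.getLogger(__name__)

_FLOAT_FMT = "{:.17g}"


class FormatError(ValueError):
    """Raised when an on-disk artifact is inconsistent or malformed."""


def _fmt(x: float) -> str:
    return _FLOAT_FMT.format(float(x))


# -- session bundles ---------------------------------------------------------

def write_session(
    session: RecordingSession,
    prefix: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> tuple[Path, Path]:
    """Write ``<prefix>.dat`` (float32 channel-major) + ``<prefix>.json``."""
    prefix = Path(prefix)
    dat_path = prefix.with_suffix(".dat")
    json_path = prefix.with_suffix(".json")
    data = np.ascontiguousarray(session.data, dtype="<f4")
    if not np.all(np.isfinite(data)):
        raise FormatError("session data contains non-finite samples")
    dat_path.parent.mkdir(parents=True, exist_ok=True)
    data.tofile(dat_path)
    if config is not None and is_dataclass(config):
        config = asdict(config)
    sidecar = {
        "fs": session.fs,
        "n_channels": session.n_channels,
        "n_samples": session.n_samples,
        "channel_names": list(session.channel_names),
        "hippocampal_mask": [bool(m) for m in session.hippocampal_mask],
        "reference_note": session.reference_note,
        "seed": seed,
        "config": config,
    }
    json_path.write_text(json.dumps(sidecar, indent=2, sort_keys=False) + "\n")
    return dat_path, json_path


def read_session(prefix: str | Path) -> RecordingSession:
    """Read a session bundle; the inverse of :func:`write_session`."""
    prefix = Path(prefix)
    dat_path = prefix.with_suffix(".dat")
    json_path = prefix.with_suffix(".json")
    if not json_path.exists():
        raise FormatError(f"missing sidecar {json_path}")
    if not dat_path.exists():
        raise FormatError(f"missing data file {dat_path}")
    meta = json.loads(json_path.read_text())
    for key in ("fs", "n_channels", "n_samples", "channel_names",
                "hippocampal_mask"):
        if key not in meta:
            raise FormatError(f"sidecar missing required field {key!r}")
    fs = meta["fs"]
    if not (isinstance(fs, (int, float)) and fs > 0):
        raise FormatError(f"invalid sidecar field 'fs': {fs!r}")
    n_ch, n_s = int(meta["n_channels"]), int(meta["n_samples"])
    if n_ch < 1 or n_s < 1:
        raise FormatError("invalid sidecar field 'n_channels' or 'n_samples'")
    if len(meta["channel_names"]) != n_ch or len(meta["hippocampal_mask"]) != n_ch:
        raise FormatError("sidecar channel metadata length mismatch")
    raw = np.fromfile(dat_path, dtype="<f4")
    if raw.size != n_ch * n_s:
        raise FormatError(
            f"data file holds {raw.size} samples but sidecar declares "
            f"{n_ch} x {n_s} = {n_ch * n_s}"
        )
    data = raw.reshape(n_ch, n_s)
    if not np.all(np.isfinite(data)):
        raise FormatError("session data contains non-finite samples")
    return RecordingSession(
        data=data,
        fs=float(fs),
        channel_names=list(meta["channel_names"]),
        hippocampal_mask=np.asarray(meta["hippocampal_mask"], dtype=bool),
        reference_note=meta.get("reference_note", ""),
    )


# -- behavioural traces ------------------------------------------------------

def write_behavior(trace: BehavioralTrace, path: str | Path) -> Path:
    """CSV with header ``time_s,speed_units_per_s,event``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ev_at: dict[int, str] = {}
    for t_ev, tag in trace.events:
        i = int(np.argmin(np.abs(trace.t - t_ev)))
        ev_at[i] = tag
    lines = ["time_s,speed_units_per_s,event"]
    for i, (t, v) in enumerate(zip(trace.t, trace.speed)):
        lines.append(f"{_fmt(t)},{_fmt(v)},{ev_at.get(i, '')}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_behavior(path: str | Path) -> BehavioralTrace:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip", keep_default_na=False)
    expected = ["time_s", "speed_units_per_s", "event"]
    if list(df.columns) != expected:
        raise FormatError(
            f"behaviour CSV header {list(df.columns)} != {expected}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise FormatError("behaviour time stamps must be strictly increasing")
    events = [
        (float(t[i]), str(tag))
        for i, tag in enumerate(df["event"].tolist())
        if tag != ""
    ]
    return BehavioralTrace(
        t=t, speed=df["speed_units_per_s"].to_numpy(dtype=float), events=events
    )


# -- feature tables ----------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """CSV with header ``window_start_s,speed,<feature columns...>``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = ",".join(["window_start_s", "speed", *table.feature_names])
    lines = [header]
    for i in range(table.n_windows):
        row = [
            _fmt(table.window_start_s[i]),
            _fmt(table.speed[i]),
            *(_fmt(v) for v in table.features[i]),
        ]
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "window_start_s" not in df.columns:
        raise FormatError("feature CSV missing 'window_start_s' column")
    if "speed" not in df.columns:
        raise FormatError("feature CSV missing 'speed' column")
    starts = df["window_start_s"].to_numpy(dtype=float)
    if len(np.unique(starts)) != len(starts):
        raise FormatError("duplicate window_start_s values")
    if np.any(np.diff(starts) < 0):
        log.warning("feature rows unsorted on read; re-sorting by window_start_s")
        df = df.sort_values("window_start_s", kind="stable").reset_index(drop=True)
    table = FeatureTable.from_dataframe(df)
    if not np.all(np.isfinite(table.features)):
        raise FormatError("feature table contains non-finite values")
    return table
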