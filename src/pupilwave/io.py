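"""File-format adapters: raw TSV (native and Tobii-style), tidy CSV, JSON.

The native raw dialect is a UTF-8 tab-separated file with header
``participant_id  group  trial_id  timestamp_ms  pupil_left_mm
pupil_right_mm  validity_left  validity_right``; missing numeric fields are
empty, validity is 1/0.  The "tobii" dialect maps a Tobii-Studio-style text
export (0-4 validity codes, where <= 1 means valid) onto the same model.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .preprocess import CleanTimecourse, ExclusionReport
from .simulate import RawRecording

__all__ = [
    "write_raw_tsv",
    "read_raw_tsv",
    "write_clean_csv",
    "read_clean_csv",
    "write_exclusion_report",
    "write_windows_json",
    "write_pointwise_csv",
]

NATIVE_COLUMNS = [
    "participant_id", "group", "trial_id", "timestamp_ms",
    "pupil_left_mm", "pupil_right_mm", "validity_left", "validity_right",
]

TOBII_COLUMNS = {
    "ParticipantName": "participant_id",
    "RecordingTimestamp": "timestamp_ms",
    "PupilLeft": "pupil_left_mm",
    "PupilRight": "pupil_right_mm",
    "ValidityLeft": "validity_left",
    "ValidityRight": "validity_right",
}


def write_raw_tsv(recordings: Sequence[RawRecording], path) -> None:
    """Write recordings in the native raw TSV dialect.

    Values round-trip exactly through :func:`read_raw_tsv` (floats are
    written at full repr precision; missing pupils become empty fields with
    validity 0).
    """
    if not recordings:
        raise ValueError("no recordings to write")
    frames = []
    for rec in recordings:
        frames.append(pd.DataFrame({
            "participant_id": rec.participant_id,
            "group": rec.group_label,
            "trial_id": rec.trial_id,
            "timestamp_ms": rec.timestamp_ms,
            "pupil_left_mm": rec.pupil_left_mm,
            "pupil_right_mm": rec.pupil_right_mm,
            "validity_left": rec.valid_left.astype(int),
            "validity_right": rec.valid_right.astype(int),
        }))
    df = pd.concat(frames, ignore_index=True)[NATIVE_COLUMNS]
    # repr round-trips float64 exactly; pandas' default formatting does not
    for col in ("timestamp_ms", "pupil_left_mm", "pupil_right_mm"):
        df[col] = [("" if np.isnan(v) else repr(float(v))) for v in df[col]]
    df.to_csv(path, sep="\t", index=False, na_rep="", lineterminator="\n")


def _infer_rate(ts: np.ndarray) -> int:
    dt = np.median(np.diff(ts))
    return int(round(1000.0 / dt)) if dt > 0 else 60


def read_raw_tsv(path, dialect: str = "native") -> list[RawRecording]:
    """Read raw recordings from TSV in the ``native`` or ``tobii`` dialect."""
    if dialect not in ("native", "tobii"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if dialect == "tobii":
        missing = set(TOBII_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing Tobii columns: {sorted(missing)}")
        df = df.rename(columns=TOBII_COLUMNS)
        if "group" not in df.columns:
            df["group"] = "unknown"
        if "trial_id" not in df.columns:
            df["trial_id"] = 0
        # Tobii validity: 0-4, <=1 means usable
        df["validity_left"] = (df["validity_left"] <= 1).astype(int)
        df["validity_right"] = (df["validity_right"] <= 1).astype(int)
    else:
        missing = set(NATIVE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")

    recordings = []
    for (pid, group), sub in df.groupby(["participant_id", "group"], sort=False):
        ts = sub["timestamp_ms"].to_numpy(float)
        for tid in sub["trial_id"].unique():
            tsub = ts[sub["trial_id"].to_numpy() == tid]
            if np.any(np.diff(tsub) <= 0):
                raise ValueError(
                    f"non-monotone timestamps in trial {tid} of {pid}")
        left = sub["pupil_left_mm"].to_numpy(float)
        right = sub["pupil_right_mm"].to_numpy(float)
        vleft = sub["validity_left"].to_numpy(int).astype(bool)
        vright = sub["validity_right"].to_numpy(int).astype(bool)
        # invalid or non-positive pupil values are missing
        left = np.where(vleft & (left > 0), left, np.nan)
        right = np.where(vright & (right > 0), right, np.nan)
        recordings.append(RawRecording(
            participant_id=str(pid),
            group_label=str(group),
            trial_id=sub["trial_id"].to_numpy(int),
            timestamp_ms=ts,
            pupil_left_mm=left,
            pupil_right_mm=right,
            valid_left=~np.isnan(left),
            valid_right=~np.isnan(right),
            rate_hz=_infer_rate(ts),
        ))
    return recordings


def write_clean_csv(clean: Sequence[CleanTimecourse], path) -> None:
    """Emit tidy per-sample pupil-change CSV (empty field = missing)."""
    frames = []
    for c in clean:
        frames.append(pd.DataFrame({
            "participant_id": c.participant_id,
            "group": c.group_label,
            "block_id": c.block_id,
            "time_s": np.round(c.time_s, 6),
            "dpd_mm": c.dpd_mm,
        }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=["participant_id", "group", "block_id",
                                     "time_s", "dpd_mm"]))
    df.to_csv(path, index=False, na_rep="", lineterminator="\n")


def read_clean_csv(path) -> list[CleanTimecourse]:
    df = pd.read_csv(path)
    out = []
    for (pid, group, bid), sub in df.groupby(
            ["participant_id", "group", "block_id"], sort=False):
        out.append(CleanTimecourse(
            participant_id=str(pid), group_label=str(group), block_id=int(bid),
            time_s=sub["time_s"].to_numpy(float),
            dpd_mm=sub["dpd_mm"].to_numpy(float),
            baseline_mm=float("nan"),
        ))
    return out


def _json_default(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(payload, path) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default,
                   allow_nan=True) + "\n")


def write_exclusion_report(report: ExclusionReport, path) -> None:
    write_json(report.to_dict(), path)


def write_windows_json(report, path, config_hash: str | None = None) -> None:
    payload = report.to_dict()
    if config_hash:
        payload["config_hash"] = config_hash
    write_json(payload, path)


def write_pointwise_csv(report, path) -> None:
    """Per-timepoint CSV: time, group means, t, df, p, per-group n."""
    rows = [{
        "time_s": tp.time_s, "mean_A": tp.mean_A, "mean_B": tp.mean_B,
        "t": tp.t, "df": tp.df, "p": tp.p,
        "n_A": tp.n_A, "n_B": tp.n_B,
    } for tp in report.pointwise]
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")
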