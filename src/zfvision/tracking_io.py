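"""CSV input/output for speed traces and binned activity records.

Two plain-text dialects are defined here and used throughout the package:

``records`` CSV (long format, one row per well x bin)
    columns: ``well_id, genotype, batch, bin_start_s, bin_s, dur_inactive_s,
    dur_coast_s, dur_burst_s, dist_coast_mm, dist_burst_mm, n_bouts_coast,
    n_bouts_burst``.  Durations are serialized at millisecond precision and
    distances at 0.001 mm; reading back a written table is field-exact at
    that precision.

``trace`` CSV (long format, one row per well x frame)
    columns: ``well_id, t_s, speed_mm_s``; per-recording metadata (frame
    interval, genotype/batch maps, protocol name, seed) lives in a JSON
    sidecar ``<path>.meta.json`` with a ``schema_version`` field.

All times are relative to recording start; numeric formatting is
locale-independent (period decimal separator via pandas).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpeedTrace",
    "RECORD_COLUMNS",
    "RecordValidationError",
    "validate_records",
    "write_records",
    "read_records",
    "write_traces",
    "read_traces",
]

SCHEMA_VERSION = 1

RECORD_COLUMNS = [
    "well_id",
    "genotype",
    "batch",
    "bin_start_s",
    "bin_s",
    "dur_inactive_s",
    "dur_coast_s",
    "dur_burst_s",
    "dist_coast_mm",
    "dist_burst_mm",
    "n_bouts_coast",
    "n_bouts_burst",
]

_DUR_COLS = ["dur_inactive_s", "dur_coast_s", "dur_burst_s"]
_NUM_COLS = _DUR_COLS + ["bin_start_s", "bin_s", "dist_coast_mm", "dist_burst_mm"]


class RecordValidationError(ValueError):
    """Structured parse/validation failure naming the offending rows."""

    def __init__(self, message: str, rows=None):
        self.rows = list(rows) if rows is not None else []
        if self.rows:
            message = f"{message} (rows: {self.rows[:20]})"
        super().__init__(message)


@dataclass
class SpeedTrace:
    """Per-larva, per-frame swim speed series with well metadata."""

    well_id: str
    genotype: str
    batch: str
    frame_dt_s: float
    speeds: np.ndarray

    def __post_init__(self) -> None:
        self.speeds = np.asarray(self.speeds, dtype=float)
        if self.frame_dt_s <= 0:
            raise ValueError("frame_dt_s must be positive")
        if self.speeds.ndim != 1 or self.speeds.size == 0:
            raise ValueError("speeds must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.speeds)) or np.any(self.speeds < 0):
            raise ValueError("speeds must be finite and non-negative")

    @property
    def duration_s(self) -> float:
        return self.speeds.size * self.frame_dt_s

    @property
    def n_frames(self) -> int:
        return int(self.speeds.size)


# ---------------------------------------------------------------------------
# binned activity records


def validate_records(df: pd.DataFrame, dur_sum_tol_s: float = 0.101) -> None:
    """Validate a records table against the dialect contract.

    ``dur_sum_tol_s`` allows one frame of rounding (default: one 0.1 s frame
    plus serialization rounding) in the ``dur_* == bin_s`` partition check.
    """
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in RECORD_COLUMNS]
    if missing or extra:
        raise RecordValidationError(
            f"unknown record header: missing {missing}, unexpected {extra}"
        )
    if len(df) == 0:
        return
    if df["bin_s"].nunique() != 1:
        raise RecordValidationError("records mix different bin_s values")
    neg = df.index[(df[_NUM_COLS] < 0).any(axis=1)]
    if len(neg):
        raise RecordValidationError("negative values in numeric columns", rows=neg)
    bad = df.index[
        (df[_DUR_COLS].sum(axis=1) - df["bin_s"]).abs() > dur_sum_tol_s
    ]
    if len(bad):
        raise RecordValidationError(
            "class durations do not sum to bin_s within tolerance", rows=bad
        )


def write_records(records: pd.DataFrame, path) -> None:
    """Write a records table; durations/distances rounded to 3 decimals."""
    validate_records(records)
    out = records.loc[:, RECORD_COLUMNS].copy() if len(records) else pd.DataFrame(
        columns=RECORD_COLUMNS
    )
    for col in _NUM_COLS:
        if len(out):
            out[col] = out[col].round(3)
    out.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    """Read and validate a records table written by :func:`write_records`."""
    df = pd.read_csv(
        path,
        dtype={"well_id": str, "genotype": str, "batch": str},
    )
    validate_records(df)
    if len(df):
        df["n_bouts_coast"] = df["n_bouts_coast"].astype(int)
        df["n_bouts_burst"] = df["n_bouts_burst"].astype(int)
    return df


# ---------------------------------------------------------------------------
# speed traces


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_traces(traces: list[SpeedTrace], path, *, protocol_name: str = "",
                 seed: int | None = None) -> None:
    """Write traces in long format plus a JSON metadata sidecar.

    Speeds are serialized with the shortest round-tripping float repr, so
    ``read_traces(write_traces(x)) == x`` bit-exactly.
    """
    if not traces:
        raise ValueError("no traces to write")
    dts = {t.frame_dt_s for t in traces}
    if len(dts) != 1:
        raise ValueError("traces mix different frame_dt_s values")
    frame_dt = dts.pop()
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "well_id": tr.well_id,
                    "t_s": np.arange(tr.n_frames) * frame_dt,
                    "speed_mm_s": tr.speeds,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "frame_dt_s": frame_dt,
        "protocol_name": protocol_name,
        "seed": seed,
        "wells": {
            tr.well_id: {"genotype": tr.genotype, "batch": tr.batch}
            for tr in traces
        },
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_traces(path) -> list[SpeedTrace]:
    """Read traces written by :func:`write_traces` (requires the sidecar)."""
    meta_path = _sidecar_path(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise RecordValidationError(
            f"unsupported trace schema_version {meta.get('schema_version')}"
        )
    df = pd.read_csv(path, dtype={"well_id": str}, float_precision="round_trip")
    frame_dt = float(meta["frame_dt_s"])
    traces = []
    for well_id, sub in df.groupby("well_id", sort=False):
        info = meta["wells"].get(str(well_id), {})
        speeds = sub["speed_mm_s"].to_numpy()
        if np.any(speeds < 0) or not np.all(np.isfinite(speeds)):
            raise RecordValidationError(
                f"invalid speeds for well {well_id}", rows=sub.index[speeds < 0]
            )
        traces.append(
            SpeedTrace(
                well_id=str(well_id),
                genotype=info.get("genotype", ""),
                batch=info.get("batch", ""),
                frame_dt_s=frame_dt,
                speeds=speeds,
            )
        )
    return traces
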