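"""Activity classification, bout segmentation, and binning of speed traces.

Larval zebrafish swim in a burst-glide style: slow "coast" swimming
(speeds strictly between 0 and 20 mm/s, slow motor neuron circuit)
interleaved with fast "burst" bouts (>= 20 mm/s, Mauthner circuit) and
inactivity (0 mm/s).  The 20 mm/s boundary is assigned to the burst class
(a closed class for the headline burst-duration statistic); both the
threshold and its inclusivity are exposed as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking_io import RECORD_COLUMNS, SpeedTrace

__all__ = [
    "INACTIVE",
    "COAST",
    "BURST",
    "CLASS_NAMES",
    "Bout",
    "classify_speed",
    "classify_speeds",
    "segment_bouts",
    "bin_activity",
    "bin_activity_table",
]

INACTIVE, COAST, BURST = 0, 1, 2
CLASS_NAMES = ("inactive", "coast", "burst")

#: default coast/burst boundary (mm/s); speeds at the boundary are burst.
COAST_MAX_MM_S = 20.0
BURST_INCLUSIVE = True


@dataclass(frozen=True)
class Bout:
    """A maximal constant-class run of frames."""

    activity_class: str
    start_s: float
    duration_s: float
    distance_mm: float


def classify_speeds(
    speeds,
    coast_max_mm_s: float = COAST_MAX_MM_S,
    burst_inclusive: bool = BURST_INCLUSIVE,
) -> np.ndarray:
    """Vectorized class codes (0 inactive, 1 coast, 2 burst) for speeds."""
    v = np.asarray(speeds, dtype=float)
    if not np.all(np.isfinite(v)) or np.any(v < 0):
        raise ValueError("speeds must be finite and non-negative")
    codes = np.full(v.shape, COAST, dtype=np.int8)
    codes[v == 0.0] = INACTIVE
    if burst_inclusive:
        codes[v >= coast_max_mm_s] = BURST
    else:
        codes[v > coast_max_mm_s] = BURST
    return codes


def classify_speed(
    v: float,
    coast_max_mm_s: float = COAST_MAX_MM_S,
    burst_inclusive: bool = BURST_INCLUSIVE,
) -> str:
    """Class name for a single speed: 0 -> inactive, (0, 20) -> coast, >= 20 -> burst."""
    return CLASS_NAMES[
        int(classify_speeds(np.array([v]), coast_max_mm_s, burst_inclusive)[0])
    ]


def segment_bouts(trace: SpeedTrace, **classify_kw) -> list[Bout]:
    """Maximal constant-class runs of a trace.

    Bout durations sum to the trace duration and bout distances sum to the
    trace's total distance (sum of speed x frame interval).
    """
    codes = classify_speeds(trace.speeds, **classify_kw)
    dt = trace.frame_dt_s
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [codes.size]))
    dist_per_frame = trace.speeds * dt
    cum = np.concatenate(([0.0], np.cumsum(dist_per_frame)))
    return [
        Bout(
            activity_class=CLASS_NAMES[codes[s]],
            start_s=s * dt,
            duration_s=(e - s) * dt,
            distance_mm=float(cum[e] - cum[s]),
        )
        for s, e in zip(starts, ends)
    ]


def bin_activity(trace: SpeedTrace, bin_s: float, **classify_kw) -> pd.DataFrame:
    """Aggregate a trace into per-bin activity records.

    Per bin: class durations are (frames in class) x frame interval, class
    distances are the per-frame speed x dt sums, and bout counts tally
    coast/burst bouts *starting* in the bin.  Requires the frame interval
    to divide ``bin_s`` and ``bin_s`` to divide the trace duration.
    """
    dt = trace.frame_dt_s
    frames_per_bin = bin_s / dt
    if abs(frames_per_bin - round(frames_per_bin)) > 1e-9:
        raise ValueError(f"frame_dt_s {dt} does not divide bin_s {bin_s}")
    frames_per_bin = int(round(frames_per_bin))
    n_bins = trace.n_frames / frames_per_bin
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(
            f"bin_s {bin_s} does not divide the trace duration {trace.duration_s}"
        )
    n_bins = int(round(n_bins))

    codes = classify_speeds(trace.speeds, **classify_kw).reshape(n_bins, frames_per_bin)
    dist = (trace.speeds * dt).reshape(n_bins, frames_per_bin)

    rec = {
        "well_id": trace.well_id,
        "genotype": trace.genotype,
        "batch": trace.batch,
        "bin_start_s": np.arange(n_bins) * bin_s,
        "bin_s": float(bin_s),
        "dur_inactive_s": (codes == INACTIVE).sum(axis=1) * dt,
        "dur_coast_s": (codes == COAST).sum(axis=1) * dt,
        "dur_burst_s": (codes == BURST).sum(axis=1) * dt,
        "dist_coast_mm": np.where(codes == COAST, dist, 0.0).sum(axis=1),
        "dist_burst_mm": np.where(codes == BURST, dist, 0.0).sum(axis=1),
    }

    # bout starts: frame 0 plus every class change; attribute to containing bin
    flat = codes.ravel()
    starts = np.concatenate(([0], np.flatnonzero(np.diff(flat)) + 1))
    start_cls = flat[starts]
    start_bin = starts // frames_per_bin
    rec["n_bouts_coast"] = np.bincount(
        start_bin[start_cls == COAST], minlength=n_bins
    )
    rec["n_bouts_burst"] = np.bincount(
        start_bin[start_cls == BURST], minlength=n_bins
    )
    return pd.DataFrame(rec, columns=RECORD_COLUMNS)


def bin_activity_table(traces, bin_s: float, **classify_kw) -> pd.DataFrame:
    """Concatenate :func:`bin_activity` over a list of traces."""
    return pd.concat(
        [bin_activity(t, bin_s, **classify_kw) for t in traces], ignore_index=True
    )
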