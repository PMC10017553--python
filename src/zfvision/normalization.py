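"""Three-step activity normalization for well-plate behavioral records.

Per-well activity in a plate recording is confounded by (1) the light
intensity each well actually receives, (2) batch effects across
experimental replicates, and (3) each larva's idiosyncratic baseline
activity.  The three steps implemented here, applied to a chosen response
field of the binned activity records, are:

1. divide each well's response by its illumination factor — taken from the
   metadata when known, otherwise estimated as the well's mean activity
   over the whole recording divided by the plate mean;
2. divide by the batch factor — the batch mean of step-1 values over the
   recording divided by the grand mean;
3. subtract the well's mean step-2 value over a baseline window (by
   convention the final 5 min of the in-recording adaptation epoch).

Each step is independently switchable.  Degenerate (zero) denominators
set the factor to 1 and are flagged in the report.  The report holds every
factor applied, so normalization is exactly invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocols import AssayProtocol

__all__ = ["NormalizationReport", "baseline_window", "normalize", "denormalize"]


@dataclass
class NormalizationReport:
    """Every factor applied during :func:`normalize` (enables exact undo)."""

    response_field: str
    steps_applied: list[int]
    illumination_factors: dict[str, float] = field(default_factory=dict)
    batch_factors: dict[str, float] = field(default_factory=dict)
    baseline_values: dict[str, float] = field(default_factory=dict)
    baseline_window_s: tuple[float, float] | None = None
    warnings: list[str] = field(default_factory=list)


def baseline_window(protocol: AssayProtocol, minutes: float = 5.0) -> tuple[float, float]:
    """The final ``minutes`` of the protocol's first (adaptation) epoch."""
    first = protocol.epochs[0]
    span = min(minutes * 60.0, first.duration_s)
    return (first.end_s - span, first.end_s)


def _safe_factor(value: float, label: str, report: NormalizationReport) -> float:
    if value is None or not np.isfinite(value) or value == 0:
        report.warnings.append(f"degenerate denominator for {label}; factor set to 1")
        return 1.0
    return float(value)


def normalize(
    records: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    baseline_window_s: tuple[float, float] | None = None,
    response_field: str = "dur_burst_s",
    steps: tuple[int, ...] = (1, 2, 3),
) -> tuple[pd.DataFrame, NormalizationReport]:
    """Apply the three-step normalization to ``response_field``.

    ``metadata`` may carry per-well ``well_light_factor`` (known
    illumination multipliers) and must map every well to a batch when the
    records lack one.  ``baseline_window_s`` is the half-open time window
    ``[start, end)`` whose mean is subtracted in step 3.

    Returns the normalized records (same schema, transformed response
    column, plus a ``normalized`` flag) and a :class:`NormalizationReport`.
    """
    steps = tuple(sorted(set(steps)))
    if not set(steps) <= {1, 2, 3}:
        raise ValueError("steps must be a subset of {1, 2, 3}")
    if 3 in steps and baseline_window_s is None:
        raise ValueError("step 3 requires a baseline window")
    out = records.copy()
    report = NormalizationReport(
        response_field=response_field,
        steps_applied=list(steps),
        baseline_window_s=baseline_window_s,
    )
    if records["batch"].isna().any():
        raise ValueError("every record must map to a batch")
    if baseline_window_s is not None:
        lo, hi = baseline_window_s
        end = records["bin_start_s"] + records["bin_s"]
        if lo < 0 or hi > end.max() + 1e-9:
            raise ValueError("baseline window lies outside the recording")

    vals = out[response_field].astype(float)

    known_illum = None
    if metadata is not None and "well_light_factor" in metadata.columns:
        known_illum = metadata.set_index("well_id")["well_light_factor"].to_dict()

    if 1 in steps:
        if known_illum is not None:
            factors = {
                w: _safe_factor(known_illum.get(w), f"well {w}", report)
                for w in out["well_id"].unique()
            }
        else:
            well_means = vals.groupby(out["well_id"]).mean()
            plate_mean = well_means.mean()
            factors = {
                w: _safe_factor(
                    well_means[w] / plate_mean if plate_mean else np.nan,
                    f"well {w}",
                    report,
                )
                for w in well_means.index
            }
        report.illumination_factors = factors
        vals = vals / out["well_id"].map(factors)

    if 2 in steps:
        batch_means = vals.groupby(out["batch"]).mean()
        grand = vals.mean()
        factors = {
            b: _safe_factor(
                batch_means[b] / grand if grand else np.nan, f"batch {b}", report
            )
            for b in batch_means.index
        }
        report.batch_factors = factors
        vals = vals / out["batch"].map(factors)

    if 3 in steps:
        lo, hi = baseline_window_s
        in_base = (out["bin_start_s"] >= lo - 1e-9) & (out["bin_start_s"] < hi - 1e-9)
        base_means = vals[in_base].groupby(out.loc[in_base, "well_id"]).mean()
        baselines = {}
        for w in out["well_id"].unique():
            if w in base_means.index and np.isfinite(base_means[w]):
                baselines[w] = float(base_means[w])
            else:
                report.warnings.append(f"no baseline bins for well {w}; baseline 0")
                baselines[w] = 0.0
        report.baseline_values = baselines
        vals = vals - out["well_id"].map(baselines)

    out[response_field] = vals
    out["normalized"] = True
    return out, report


def denormalize(
    records: pd.DataFrame, report: NormalizationReport
) -> pd.DataFrame:
    """Invert :func:`normalize` using the report's factors."""
    out = records.copy()
    vals = out[report.response_field].astype(float)
    if 3 in report.steps_applied:
        vals = vals + out["well_id"].map(report.baseline_values)
    if 2 in report.steps_applied:
        vals = vals * out["batch"].map(report.batch_factors)
    if 1 in report.steps_applied:
        vals = vals * out["well_id"].map(report.illumination_factors)
    out[report.response_field] = vals
    if "normalized" in out.columns:
        out = out.drop(columns=["normalized"])
    return out
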