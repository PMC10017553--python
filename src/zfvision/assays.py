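"""Response statistics for the behavioral assays.

* **VMR** (visual motor response): burst duration in a short window
  (default 1 s) after each abrupt light-ON or light-OFF transition,
  averaged across trials per larva.
* **FSTR** (flash-stimulus threshold response): burst duration in windows
  (default 30 s) immediately before and after each light flash; the
  response is expressed as ``100 * post / pre`` percent, averaged over
  forward- and reverse-order presentations of the same cue length.
* **Free swim**: per-larva distance and class durations under constant
  illumination.
* **Color preference**: per-arm mean fish counts and percentages in the
  cross maze.

Group statistics are reported as mean +/- SEM over larvae (per-larva
averaging across trials precedes the group summary, so n counts larvae).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocols import AssayProtocol

__all__ = [
    "ResponseSummary",
    "percent_response",
    "vmr_response",
    "fstr_response",
    "freeswim_summary",
    "color_preference",
]


@dataclass
class ResponseSummary:
    """Per-group distribution of a per-larva response value."""

    assay: str
    group: str
    per_larva_values: np.ndarray

    def __post_init__(self) -> None:
        self.per_larva_values = np.asarray(self.per_larva_values, dtype=float)

    @property
    def n(self) -> int:
        return int(self.per_larva_values.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_larva_values)) if self.n else float("nan")

    @property
    def sem(self) -> float:
        if self.n < 2:
            return float("nan")
        return float(np.std(self.per_larva_values, ddof=1) / np.sqrt(self.n))

    def __repr__(self) -> str:  # compact, figure-caption style
        return (
            f"ResponseSummary({self.assay}, {self.group}: "
            f"{self.mean:.4g} +/- {self.sem:.2g}, n={self.n})"
        )


def percent_response(pre: float, post: float) -> float:
    """Post-stimulus activity as a percentage of pre-stimulus activity.

    Returns ``100 * post / pre``; a "178%" response means the activity rose
    to 1.78x its pre-stimulus level.  ``pre == 0`` yields NaN (undefined
    response), not an exception.
    """
    if pre < 0 or post < 0:
        raise ValueError("pre and post must be non-negative")
    if pre == 0:
        return float("nan")
    return 100.0 * post / pre


def _snap_down(t: float, bin_s: float) -> float:
    return np.floor(t / bin_s + 1e-9) * bin_s


def _window_sum(
    sub: pd.DataFrame, lo: float, hi: float, field: str, bin_s: float
) -> float | None:
    """Sum ``field`` over bins starting in [lo, hi); None if bins missing."""
    sel = (sub["bin_start_s"] >= lo - 1e-9) & (sub["bin_start_s"] < hi - 1e-9)
    expected = int(round((hi - lo) / bin_s))
    if sel.sum() != expected:
        return None
    return float(sub.loc[sel, field].sum())


def vmr_response(
    records: pd.DataFrame,
    protocol: AssayProtocol,
    direction: str = "ON",
    window_s: float = 1.0,
    response_field: str = "dur_burst_s",
) -> dict[str, ResponseSummary]:
    """Burst duration in ``window_s`` after each matching light transition.

    Per larva the window values are averaged across the protocol's trials;
    returns one :class:`ResponseSummary` per genotype.  Larvae with missing
    bins in any window are excluded with a warning.
    """
    if direction not in ("ON", "OFF"):
        raise ValueError("direction must be 'ON' or 'OFF'")
    bin_s = float(records["bin_s"].iloc[0])
    if bin_s > window_s + 1e-9:
        raise ValueError(f"records bin_s {bin_s} exceeds window_s {window_s}")
    times = [t.time_s for t in protocol.transitions() if t.direction == direction]
    if not times:
        raise ValueError(f"protocol has no {direction} transitions")

    values: dict[str, list[float]] = {}
    for (well, geno), sub in records.groupby(["well_id", "genotype"], sort=False):
        per_trial = []
        for T in times:
            lo = _snap_down(T, bin_s)
            s = _window_sum(sub, lo, lo + window_s, response_field, bin_s)
            if s is None:
                warnings.warn(f"well {well}: missing bins in window at t={T:g}s; excluded")
                per_trial = None
                break
            per_trial.append(s)
        if per_trial is not None:
            values.setdefault(geno, []).append(float(np.mean(per_trial)))
    return {
        g: ResponseSummary(assay=f"vmr_{direction.lower()}", group=g, per_larva_values=v)
        for g, v in values.items()
    }


def fstr_response(
    runs,
    window_s: float = 30.0,
    response_field: str = "dur_burst_s",
):
    """Pre/post flash burst durations and percent responses.

    ``runs`` is one ``(records, protocol)`` pair or a list of them (e.g. a
    forward-order and a reverse-order presentation).  Per larva and cue
    length, the burst duration in the ``window_s`` before and after the
    flash onset is averaged across runs, then converted to a percent
    response (``100 * post / pre``).

    Returns ``(per_larva, summaries)`` where ``per_larva`` has columns
    ``well_id, genotype, cue_ms, pre_s, post_s, percent`` and ``summaries``
    maps ``(genotype, cue_ms)`` to a :class:`ResponseSummary` of percents.
    Window edges snap down to the acquisition-bin grid.
    """
    if isinstance(runs, tuple) and len(runs) == 2 and isinstance(runs[1], AssayProtocol):
        runs = [runs]
    rows = []
    for records, protocol in runs:
        bin_s = float(records["bin_s"].iloc[0])
        flashes = [ep for ep in protocol.epochs if ep.intensity_pct > 0]
        onsets = []
        for ep in flashes:
            cue_ms = int(round(ep.duration_s * 1000))
            T = _snap_down(ep.start_s, bin_s)
            if T - window_s < -1e-9 or T + window_s > protocol.total_duration_s + 1e-9:
                raise ValueError(
                    f"flash at t={ep.start_s:g}s lacks {window_s:g}s of recording on both sides"
                )
            onsets.append((cue_ms, T))
        for (_, t1), (_, t0) in zip(onsets[1:], onsets):
            if t0 + window_s > t1 - window_s + 1e-9:
                raise ValueError(
                    "pre/post windows of consecutive cues overlap; "
                    "rest period too short for this window_s"
                )
        for (well, geno), sub in records.groupby(["well_id", "genotype"], sort=False):
            for cue_ms, T in onsets:
                pre = _window_sum(sub, T - window_s, T, response_field, bin_s)
                post = _window_sum(sub, T, T + window_s, response_field, bin_s)
                if pre is None or post is None:
                    warnings.warn(f"well {well}: missing bins around flash at t={T:g}s")
                    continue
                rows.append(
                    {"well_id": well, "genotype": geno, "cue_ms": cue_ms,
                     "pre_s": pre, "post_s": post}
                )
    raw = pd.DataFrame(rows)
    if raw.empty:
        raise ValueError("no flash windows could be extracted")
    per_larva = (
        raw.groupby(["well_id", "genotype", "cue_ms"], as_index=False)[["pre_s", "post_s"]]
        .mean()
    )
    per_larva["percent"] = [
        percent_response(p, q) for p, q in zip(per_larva["pre_s"], per_larva["post_s"])
    ]
    summaries = {}
    for (geno, cue), sub in per_larva.groupby(["genotype", "cue_ms"]):
        vals = sub["percent"].dropna().to_numpy()
        summaries[(geno, int(cue))] = ResponseSummary(
            assay=f"fstr_{int(cue)}ms", group=geno, per_larva_values=vals
        )
    return per_larva, summaries


def freeswim_summary(
    records: pd.DataFrame,
    condition: str = "light",
    protocol: AssayProtocol | None = None,
) -> dict[str, dict[str, ResponseSummary]]:
    """Spontaneous-swim summaries under constant illumination.

    Per larva: mean swum distance per 10 s and mean coast/burst durations
    per bin; grouped by genotype.  If a protocol is supplied it must be
    constant-intensity (no transitions).
    """
    if condition not in ("light", "dark"):
        raise ValueError("condition must be 'light' or 'dark'")
    if len(records) == 0:
        raise ValueError("empty record set")
    if protocol is not None and protocol.transitions():
        raise ValueError("free-swim summaries require a constant-intensity protocol")
    bin_s = float(records["bin_s"].iloc[0])
    per_larva = records.groupby(["well_id", "genotype"], sort=False).agg(
        dist=("dist_coast_mm", "mean"),
        dist_b=("dist_burst_mm", "mean"),
        coast=("dur_coast_s", "mean"),
        burst=("dur_burst_s", "mean"),
    )
    per_larva["distance_mm_per_10s"] = (per_larva["dist"] + per_larva["dist_b"]) * (
        10.0 / bin_s
    )
    metrics = {
        "distance_mm_per_10s": per_larva["distance_mm_per_10s"],
        "coast_dur_s_per_bin": per_larva["coast"],
        "burst_dur_s_per_bin": per_larva["burst"],
    }
    out: dict[str, dict[str, ResponseSummary]] = {}
    for name, series in metrics.items():
        out[name] = {}
        for geno, sub in series.groupby(level="genotype"):
            out[name][geno] = ResponseSummary(
                assay=f"freeswim_{condition}", group=geno,
                per_larva_values=sub.to_numpy(),
            )
    return out


def color_preference(
    counts: pd.DataFrame,
    arms: list[str] | None = None,
    n_fish: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-arm mean counts and percentages from cross-maze tallies.

    ``counts`` has a ``timepoint`` column plus one column per arm (four
    colors, or two colors plus a neutral center).  Counts must sum to the
    same total (the number of fish) at every timepoint.

    Returns ``(summary, series)``: the summary has per-arm ``mean_count``,
    ``percent`` (100 x mean / n_fish) and ``sem_percent`` across
    timepoints; the series is the percent time course per arm.
    """
    if arms is None:
        arms = [c for c in counts.columns if c != "timepoint"]
    tab = counts[arms]
    if (tab < 0).any().any():
        raise ValueError("counts must be non-negative")
    totals = tab.sum(axis=1)
    if n_fish is None:
        if totals.nunique() != 1:
            raise ValueError("counts per timepoint must sum to a constant n_fish")
        n_fish = int(totals.iloc[0])
    bad = counts.index[totals > n_fish]
    if len(bad):
        raise ValueError(f"row sums exceed n_fish={n_fish} at rows {list(bad[:10])}")
    pct = 100.0 * tab / n_fish
    summary = pd.DataFrame(
        {
            "arm": arms,
            "mean_count": tab.mean().to_numpy(),
            "percent": pct.mean().to_numpy(),
            "sem_percent": (pct.std(ddof=1) / np.sqrt(len(pct))).to_numpy(),
        }
    )
    series = pct.copy()
    series.insert(0, "timepoint", counts["timepoint"].to_numpy())
    return summary, series
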