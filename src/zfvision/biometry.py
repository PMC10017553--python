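"""Derived ocular metrics and larval morphometric ratios.

Ocular metrics from OCT-derived geometry (all lengths in micrometers
unless noted):

* ``lens_ratio`` — proximal-distal over anterior-posterior lens diameter,
  a circularity measure (1.0 for a perfectly spherical lens);
* ``normalized_axial_length`` — axial length (top of lens to retinal
  pigment epithelium) divided by body length, in um/mm;
* ``rre`` — Relative Refractive Error, ``1 - retinal_radius / F`` with the
  idealized focal length ``F = 2.324 x lens_radius``.  RRE > 0 is
  hyperopic (the retina sits closer than the focal surface), RRE < 0 is
  myopic, 0 is emmetropic.

Larval morphometrics: triplicate measurements of body length, head length
and midbrain diameter are averaged per fish before computing the
head-to-body ratio (head / body) and the head-to-midbrain ratio.  The
latter is conventionally reported as midbrain / head — the orientation
that matches the published cohort values — despite its name; both the
name and the formula are kept here to stay interoperable with that
reporting convention.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "FOCAL_LENGTH_FACTOR",
    "lens_ratio",
    "normalized_axial_length",
    "idealized_focal_length",
    "rre",
    "average_triplicate",
    "morpho_ratios",
    "derive_ocular_metrics",
    "ocular_cohort_summary",
]

#: Idealized focal length per unit lens radius for the teleost eye
#: (Matthiessen-type small-eye optics constant used in OCT biometry).
FOCAL_LENGTH_FACTOR = 2.324

MORPHO_TRAITS = ("body_mm", "head_mm", "midbrain_mm")


def _require_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        arr = np.asarray(value, dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(f"{name} must be positive and finite")


def lens_ratio(pd_um, ap_um):
    """Proximal-distal over anterior-posterior lens diameter."""
    _require_positive(pd_um=pd_um, ap_um=ap_um)
    return np.asarray(pd_um, float) / np.asarray(ap_um, float)


def normalized_axial_length(axial_um, body_mm):
    """Eye axial length normalized by body length (um/mm)."""
    _require_positive(axial_um=axial_um, body_mm=body_mm)
    return np.asarray(axial_um, float) / np.asarray(body_mm, float)


def idealized_focal_length(lens_radius_um, factor: float = FOCAL_LENGTH_FACTOR):
    """Idealized focal length F = factor x lens radius (um)."""
    _require_positive(lens_radius_um=lens_radius_um)
    return factor * np.asarray(lens_radius_um, float)


def rre(lens_radius_um, retinal_radius_um, factor: float = FOCAL_LENGTH_FACTOR):
    """Relative Refractive Error: 1 - retinal_radius / (factor x lens_radius).

    Positive values are hyperopic, negative myopic; always < 1.
    """
    _require_positive(lens_radius_um=lens_radius_um, retinal_radius_um=retinal_radius_um)
    F = idealized_focal_length(lens_radius_um, factor)
    return 1.0 - np.asarray(retinal_radius_um, float) / F


def average_triplicate(morphometry: pd.DataFrame) -> pd.DataFrame:
    """Average the three replicate measurements per trait and fish.

    Expects columns ``<trait>_1 .. <trait>_3`` for each trait in
    ``body_mm, head_mm, midbrain_mm``; returns one row per fish with the
    per-trait means.  Warns (without failing) when a fish's replicate
    coefficient of variation exceeds 50%.
    """
    out = morphometry[["fish_id", "genotype"]].copy()
    for trait in MORPHO_TRAITS:
        cols = [f"{trait}_{r}" for r in (1, 2, 3)]
        missing = [c for c in cols if c not in morphometry.columns]
        if missing:
            raise ValueError(f"missing replicate columns {missing}")
        reps = morphometry[cols].to_numpy(dtype=float)
        if np.any(reps <= 0):
            raise ValueError(f"replicates for {trait} must be positive")
        mean = reps.mean(axis=1)
        cv = reps.std(axis=1, ddof=0) / mean
        if np.any(cv > 0.5):
            warnings.warn(
                f"{trait}: replicate CV > 50% for fish "
                f"{list(morphometry.loc[cv > 0.5, 'fish_id'])}"
            )
        out[trait] = mean
    return out


def morpho_ratios(body_mm, head_mm, midbrain_mm):
    """Head-to-body and head-to-midbrain ratios.

    Returns ``(head / body, midbrain / head)`` — see the module docstring
    for the head-to-midbrain orientation convention.
    """
    _require_positive(body_mm=body_mm, head_mm=head_mm, midbrain_mm=midbrain_mm)
    head = np.asarray(head_mm, float)
    return head / np.asarray(body_mm, float), np.asarray(midbrain_mm, float) / head


def derive_ocular_metrics(
    biometry: pd.DataFrame, factor: float = FOCAL_LENGTH_FACTOR
) -> pd.DataFrame:
    """Per-fish derived metrics from an ocular biometry table.

    Adds ``lens_ratio``, ``norm_axial_um_per_mm``, ``idealized_focal_um``
    and ``rre`` columns.  Warns when a fish's tabulated lens radius
    disagrees with mean(diameters)/2 by more than 10%.
    """
    out = biometry.copy()
    half_mean_diam = (out["lens_diam_pd_um"] + out["lens_diam_ap_um"]) / 4.0
    rel = np.abs(out["lens_radius_um"] - half_mean_diam) / half_mean_diam
    if np.any(rel > 0.10):
        warnings.warn(
            "lens radius deviates >10% from mean(diameters)/2 for fish "
            f"{list(out.loc[rel > 0.10, 'fish_id'])}"
        )
    out["lens_ratio"] = lens_ratio(out["lens_diam_pd_um"], out["lens_diam_ap_um"])
    out["norm_axial_um_per_mm"] = normalized_axial_length(
        out["axial_length_um"], out["body_length_mm"]
    )
    out["idealized_focal_um"] = idealized_focal_length(out["lens_radius_um"], factor)
    out["rre"] = rre(out["lens_radius_um"], out["retinal_radius_um"], factor)
    return out


def ocular_cohort_summary(
    biometry: pd.DataFrame,
    method: str = "per_fish",
    factor: float = FOCAL_LENGTH_FACTOR,
) -> pd.DataFrame:
    """Cohort means of the derived metrics, per genotype.

    ``method="per_fish"`` computes each metric per fish and averages
    (the convention for reported cohort RREs); ``method="ratio_of_means"``
    plugs the cohort trait means into the point formulas instead — the two
    differ whenever traits covary across fish.
    """
    rows = []
    for geno, sub in biometry.groupby("genotype", sort=False):
        if method == "per_fish":
            derived = derive_ocular_metrics(sub, factor)
            rows.append(
                {
                    "genotype": geno,
                    "n": len(sub),
                    "lens_ratio": derived["lens_ratio"].mean(),
                    "norm_axial_um_per_mm": derived["norm_axial_um_per_mm"].mean(),
                    "rre": derived["rre"].mean(),
                }
            )
        elif method == "ratio_of_means":
            rows.append(
                {
                    "genotype": geno,
                    "n": len(sub),
                    "lens_ratio": float(
                        lens_ratio(sub["lens_diam_pd_um"].mean(), sub["lens_diam_ap_um"].mean())
                    ),
                    "norm_axial_um_per_mm": float(
                        normalized_axial_length(
                            sub["axial_length_um"].mean(), sub["body_length_mm"].mean()
                        )
                    ),
                    "rre": float(
                        rre(sub["lens_radius_um"].mean(), sub["retinal_radius_um"].mean(), factor)
                    ),
                }
            )
        else:
            raise ValueError("method must be 'per_fish' or 'ratio_of_means'")
    return pd.DataFrame(rows)
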