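"""Resampling statistics: bootstrap estimation, rank-sum tests, and
efficiency-corrected relative expression.

* :func:`bootstrap_mean_diff` — the estimation-statistics counterpart of a
  two-group comparison (as drawn in Gardner-Altman plots): the observed
  mean difference with a percentile bootstrap sampling distribution and
  95% confidence interval.
* :func:`rank_sum_test` — two-sided Wilcoxon-Mann-Whitney p-values from an
  exact enumeration (small samples), a Monte-Carlo permutation null, or
  the normal approximation.
* :func:`rest_ratio` — efficiency-corrected relative expression
  ``E_target^dCt_target / geomean_ref(E_ref^dCt_ref)`` with
  ``dCt = mean Ct(control) - mean Ct(treated)``, and a randomization test
  that reallocates group labels within genes.

Randomization p-values use ``(count + 1) / (n + 1)`` so they are never
exactly zero; all Monte-Carlo procedures are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EstimationResult",
    "bootstrap_mean_diff",
    "rank_sum_test",
    "validate_ct_table",
    "rest_ratio",
]


@dataclass
class EstimationResult:
    """Observed mean difference with a bootstrap 95% CI."""

    mean_diff: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None
    boot_mean: float
    boot_sd: float

    def __repr__(self) -> str:
        return (
            f"EstimationResult(mean_diff={self.mean_diff:.4g}, "
            f"95% CI [{self.ci_low:.4g}, {self.ci_high:.4g}], n_boot={self.n_boot})"
        )


def bootstrap_mean_diff(
    group_a,
    group_b,
    n_boot: int = 5000,
    seed: int | None = None,
    ci: float = 0.95,
) -> EstimationResult:
    """Percentile-bootstrap estimate of ``mean(B) - mean(A)``.

    Both groups are resampled with replacement ``n_boot`` times; the CI is
    the (2.5, 97.5) percentile interval of the bootstrap distribution.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    rng = np.random.default_rng(seed)
    boot_a = a[rng.integers(0, a.size, size=(n_boot, a.size))].mean(axis=1)
    boot_b = b[rng.integers(0, b.size, size=(n_boot, b.size))].mean(axis=1)
    dist = boot_b - boot_a
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(dist, [alpha, 1.0 - alpha])
    return EstimationResult(
        mean_diff=float(b.mean() - a.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
        boot_mean=float(dist.mean()),
        boot_sd=float(dist.std(ddof=1)),
    )


def _rank_sum(a, b):
    """Mid-rank sum of group A in the pooled sample, plus pooled ranks."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    return ranks[: len(a)].sum(), ranks


def rank_sum_test(
    group_a,
    group_b,
    mode: str = "permutation",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value.

    Modes: ``exact`` enumerates all label assignments (combined n <= 12,
    ties handled with mid-ranks), ``permutation`` samples ``n_perm`` random
    reallocations, ``asymptotic`` uses the tie-corrected normal
    approximation.  Degenerate all-equal data returns p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least 1 observation")
    if np.all(np.concatenate([a, b]) == a[0]):
        return 1.0
    na, n = a.size, a.size + b.size
    r_obs, ranks = _rank_sum(a, b)
    mu = na * (n + 1) / 2.0  # null expectation; distribution symmetric about mu

    if mode == "exact":
        if n > 12:
            raise ValueError("exact mode limited to combined n <= 12")
        d_obs = abs(r_obs - mu)
        count = sum(
            1
            for idx in combinations(range(n), na)
            if abs(ranks[list(idx)].sum() - mu) >= d_obs - 1e-12
        )
        return count / comb(n, na)
    if mode == "permutation":
        rng = np.random.default_rng(seed)
        d_obs = abs(r_obs - mu)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if abs(ranks[perm[:na]].sum() - mu) >= d_obs - 1e-12:
                count += 1
        return (count + 1) / (n_perm + 1)
    if mode == "asymptotic":
        return float(
            sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    raise ValueError("mode must be 'exact', 'permutation' or 'asymptotic'")


# ---------------------------------------------------------------------------
# relative expression


def validate_ct_table(ct: pd.DataFrame) -> None:
    """Contract checks for a Ct table (see :func:`rest_ratio`)."""
    required = {"gene", "role", "group", "ct", "efficiency"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    if not set(ct["group"]) <= {"control", "treated"}:
        raise ValueError("groups must be 'control' and 'treated'")
    if (ct["efficiency"] <= 1.0).any():
        raise ValueError("amplification efficiencies must exceed 1")
    if "reference" not in set(ct["role"]):
        raise ValueError("Ct table needs at least one reference gene")
    sizes = ct.groupby(["gene", "group"]).size()
    if (sizes < 2).any():
        raise ValueError("need >= 2 replicates per gene x group")


def _expression_ratio(ct: pd.DataFrame, target: str, refs: list[str]) -> float:
    def expr(gene):
        sub = ct[ct["gene"] == gene]
        eff = float(sub["efficiency"].iloc[0])
        dct = (
            sub.loc[sub["group"] == "control", "ct"].mean()
            - sub.loc[sub["group"] == "treated", "ct"].mean()
        )
        return eff**dct

    ref_expr = np.array([expr(g) for g in refs])
    return float(expr(target) / np.exp(np.log(ref_expr).mean()))


def rest_ratio(
    ct: pd.DataFrame,
    target: str,
    n_rand: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Efficiency-corrected relative expression ratio with randomization p.

    The ratio is the target's efficiency-corrected expression change
    normalized by the geometric mean of the reference (housekeeping)
    genes' changes.  The p-value comes from ``n_rand`` random reallocations
    of the control/treated labels within every gene, counting ratios at
    least as extreme as observed on the |log ratio| scale (two-sided),
    with the (count + 1)/(n_rand + 1) correction.
    """
    validate_ct_table(ct)
    refs = sorted(ct.loc[ct["role"] == "reference", "gene"].unique())
    if target not in set(ct["gene"]):
        raise ValueError(f"target gene {target!r} not in table")
    if target in refs:
        raise ValueError(f"{target!r} is a reference gene")

    ratio = _expression_ratio(ct, target, refs)

    rng = np.random.default_rng(seed)
    genes = [target] + refs
    obs = abs(np.log(ratio))
    count = 0
    # pre-extract per-gene arrays once; permute labels within each gene
    per_gene = {}
    for g in genes:
        sub = ct[ct["gene"] == g]
        per_gene[g] = (
            sub["ct"].to_numpy(dtype=float),
            (sub["group"] == "treated").to_numpy(),
            float(sub["efficiency"].iloc[0]),
        )
    for _ in range(n_rand):
        log_ref = []
        log_t = 0.0
        for g in genes:
            cts, treated, eff = per_gene[g]
            perm = rng.permutation(treated)
            dct = cts[~perm].mean() - cts[perm].mean()
            val = dct * np.log(eff)
            if g == target:
                log_t = val
            else:
                log_ref.append(val)
        log_r = log_t - float(np.mean(log_ref))
        if abs(log_r) >= obs - 1e-12:
            count += 1
    p = (count + 1) / (n_rand + 1)
    return ratio, float(p)
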