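"""Stochastic synthetic-data generators for every pipeline stage.

The locomotion model is a discrete-time Markov chain over three latent
activity states — inactive (0 mm/s), coast (0-20 mm/s), burst (>= 20 mm/s)
— chosen so that bout durations are well defined and approximately
geometric, matching the burst-glide swimming style of larval zebrafish.
Each frame the chain leaves its current state with probability
``frame_dt_s / dwell_s[state]``; the replacement state is drawn from the
illumination-conditional occupancy probabilities, with the burst weight
transiently inflated after every light transition by a startle kernel
``1 + g * exp(-dt / startle_decay_s)``.

The per-transition gain ``g`` is the direction-appropriate startle gain
(separate photopic and mesopic light-ON gains, plus a light-OFF gain)
scaled by a temporal-integration factor ``min(1, cue_s / 0.05 s)`` so that
millisecond flashes evoke proportionally weaker startles than sustained
light steps.

Speeds are drawn per frame from bounded state-conditional distributions:
coast is a scaled beta on (0, 20) mm/s, burst is 20 mm/s plus a
gamma-distributed excess, inactive is exactly 0.

Additional samplers generate correlated ocular-biometry tables,
triplicate morphometry tables, qPCR Ct tables with prescribed fold
changes, and cross-maze color-preference counts.  Every ``simulate_*``
output is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .protocols import AssayProtocol
from .tracking_io import SpeedTrace

__all__ = [
    "LocomotorParams",
    "GenotypeConfig",
    "PlateSpec",
    "wt_genotype",
    "ko_genotype",
    "simulate_trace",
    "simulate_cohort",
    "simulate_plate",
    "simulate_biometry",
    "simulate_morphometry",
    "simulate_ct_table",
    "simulate_color_maze",
]

_STARTLE_TAU_C_S = 0.05  # temporal integration constant for cue-length scaling
_MESOPIC_MAX_PCT = 10.0  # ON steps at or below this use the mesopic gain


@dataclass(frozen=True)
class LocomotorParams:
    """Parameters of the burst-glide locomotion model.

    Occupancies are baseline state probabilities (inactive, coast, burst)
    per illumination level; dwell times are per-state means in seconds.
    """

    occupancy_light: tuple[float, float, float] = (0.35, 0.60, 0.05)
    occupancy_dark: tuple[float, float, float] = (0.45, 0.52, 0.03)
    dwell_light_s: tuple[float, float, float] = (1.0, 1.0, 0.35)
    dwell_dark_s: tuple[float, float, float] = (1.0, 1.0, 0.35)
    coast_beta: tuple[float, float] = (2.0, 8.0)  # scaled to (0, 20) mm/s
    burst_gamma: tuple[float, float] = (2.0, 5.0)  # shape, scale of excess over 20
    startle_gain_on: float = 30.0
    startle_gain_on_mesopic: float = 15.0
    startle_gain_off: float = 160.0
    startle_decay_s: float = 0.8
    frame_dt_s: float = 0.1

    def __post_init__(self) -> None:
        for occ in (self.occupancy_light, self.occupancy_dark):
            if len(occ) != 3 or any(not 0 <= p <= 1 for p in occ):
                raise ValueError(f"occupancies must be 3 probabilities, got {occ}")
            if abs(sum(occ) - 1.0) > 1e-9:
                raise ValueError(f"occupancies must sum to 1, got {occ}")
        if any(d <= 0 for d in self.dwell_light_s + self.dwell_dark_s):
            raise ValueError("dwell times must be positive")
        if any(p <= 0 for p in self.coast_beta + self.burst_gamma):
            raise ValueError("speed-distribution parameters must be positive")
        for g in (
            self.startle_gain_on,
            self.startle_gain_on_mesopic,
            self.startle_gain_off,
        ):
            if g < 0:
                raise ValueError("startle gains must be >= 0")
        if self.startle_decay_s <= 0 or self.frame_dt_s <= 0:
            raise ValueError("startle_decay_s and frame_dt_s must be positive")


# cohort moments measured by OCT on n = 26 adult fish per genotype
_WT_BIOMETRY = {
    "body_length_mm": (24.33, 1.84),
    "axial_length_um": (217.0, 21.0),
    "lens_radius_um": (362.12, 20.50),
    "retinal_radius_um": (717.52, 66.23),
    "retinal_thickness_um": (196.07, 15.17),
    "lens_ratio": (1.01, 0.02),
}
_KO_BIOMETRY = {
    "body_length_mm": (24.94, 1.52),
    "axial_length_um": (198.8, 12.5),
    "lens_radius_um": (351.15, 17.99),
    "retinal_radius_um": (643.52, 78.40),
    "retinal_thickness_um": (204.16, 25.36),
    "lens_ratio": (1.02, 0.02),
}

# larval trait means and cohort SDs (mm); SDs back-computed from printed
# SEMs at n = 19
_WT_MORPHO = {"body_mm": (3.84, 0.26), "head_mm": (0.70, 0.044), "midbrain_mm": (0.52, 0.013)}
_KO_MORPHO = {"body_mm": (4.12, 0.13), "head_mm": (0.75, 0.044), "midbrain_mm": (0.52, 0.017)}


@dataclass(frozen=True)
class GenotypeConfig:
    """A genotype's locomotor parameters and cohort biometry moments."""

    label: str
    params: LocomotorParams = field(default_factory=LocomotorParams)
    biometry: dict = field(default_factory=lambda: dict(_WT_BIOMETRY))
    biometry_corr: float = 0.6  # lens radius vs retinal radius
    morphometry: dict = field(default_factory=lambda: dict(_WT_MORPHO))

    def __post_init__(self) -> None:
        if not -1.0 <= self.biometry_corr <= 1.0:
            raise ValueError("|biometry_corr| must be <= 1")


def wt_genotype() -> GenotypeConfig:
    """Wild-type (TL strain) defaults."""
    return GenotypeConfig(label="WT")


def ko_genotype() -> GenotypeConfig:
    """Cx35.1 knock-out defaults.

    Relative to wild type: photopic light-ON startle gain x1.125
    (hyperactive ON response), mesopic light-ON gain x0.95 (the
    hyperactivity reverses under dim light), and dark coast dwell x0.79
    (reduced coast duration in darkness).
    """
    wt = LocomotorParams()
    params = replace(
        wt,
        startle_gain_on=wt.startle_gain_on * 1.125,
        startle_gain_on_mesopic=wt.startle_gain_on_mesopic * 0.95,
        dwell_dark_s=(
            wt.dwell_dark_s[0],
            wt.dwell_dark_s[1] * 0.79,
            wt.dwell_dark_s[2],
        ),
    )
    return GenotypeConfig(
        label="KO",
        params=params,
        biometry=dict(_KO_BIOMETRY),
        morphometry=dict(_KO_MORPHO),
    )


@dataclass(frozen=True)
class PlateSpec:
    """Plate geometry and nuisance-variation magnitudes for an experiment."""

    n_wells: int = 48
    well_light_sd: float = 0.1
    batch_ids: tuple = ("batch1", "batch2")
    batch_effect_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wells not in (48, 96):
            raise ValueError("n_wells must be 48 or 96")
        if self.well_light_sd < 0 or self.batch_effect_sd < 0:
            raise ValueError("nuisance SDs must be >= 0")
        if not self.batch_ids:
            raise ValueError("need at least one batch")


# ---------------------------------------------------------------------------
# locomotion


def _frame_context(protocol: AssayProtocol, frame_dt_s: float, n_frames: int):
    """Per-frame illumination flag and startle-kernel descriptors.

    Returns ``light`` (bool array), ``dt_since`` (seconds since the most
    recent transition, inf before the first), ``kind`` (0 none, 1 photopic
    ON, 2 mesopic ON, 3 OFF) and ``cue_w`` (temporal-integration weight of
    the most recent transition).
    """
    mid = (np.arange(n_frames) + 0.5) * frame_dt_s
    bounds = np.array([ep.start_s for ep in protocol.epochs] + [protocol.total_duration_s])
    intens = np.array([ep.intensity_pct for ep in protocol.epochs])
    idx = np.clip(np.searchsorted(bounds, mid, side="right") - 1, 0, len(intens) - 1)
    light = intens[idx] > 0.0

    dt_since = np.full(n_frames, np.inf)
    kind = np.zeros(n_frames, dtype=np.int8)
    cue_w = np.zeros(n_frames)
    durs_entered = {ep.start_s: ep.duration_s for ep in protocol.epochs}
    durs_exited = {ep.end_s: ep.duration_s for ep in protocol.epochs}
    for tr in protocol.transitions():
        after = mid >= tr.time_s
        dt_since[after] = mid[after] - tr.time_s
        if tr.direction == "ON":
            k = 2 if tr.to_pct <= _MESOPIC_MAX_PCT else 1
            # startle integrates over the light step itself (a ms flash
            # ends before the response fully builds up)
            cue_s = durs_entered.get(tr.time_s, np.inf)
        else:
            k = 3
            # the OFF startle scales with the light exposure just exited
            cue_s = durs_exited.get(tr.time_s, np.inf)
        kind[after] = k
        cue_w[after] = min(1.0, cue_s / _STARTLE_TAU_C_S)
    return light, dt_since, kind, cue_w


def _validate_frame_grid(protocol: AssayProtocol, frame_dt_s: float) -> int:
    n = protocol.total_duration_s / frame_dt_s
    if abs(n - round(n)) > 1e-6:
        raise ValueError(
            f"frame_dt_s {frame_dt_s} does not divide the protocol duration"
        )
    ratio = protocol.bin_s / frame_dt_s
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"frame_dt_s {frame_dt_s} does not divide bin_s {protocol.bin_s}")
    return int(round(n))


def _simulate_speed_matrix(
    protocol: AssayProtocol,
    params_list: list[LocomotorParams],
    rng: np.random.Generator,
    activity_mult=None,
) -> np.ndarray:
    """Simulate ``len(params_list)`` traces at once; returns (n, T) speeds.

    ``activity_mult`` (per trace) tilts the occupancy weights toward the
    active states — the generative hook for well-illumination and batch
    nuisance effects.
    """
    n = len(params_list)
    dts = {p.frame_dt_s for p in params_list}
    if len(dts) != 1:
        raise ValueError("all traces in a cohort must share frame_dt_s")
    dt = dts.pop()
    n_frames = _validate_frame_grid(protocol, dt)
    light, dt_since, kind, cue_w = _frame_context(protocol, dt, n_frames)

    m = np.ones(n) if activity_mult is None else np.asarray(activity_mult, float)

    def _tilt(occ):
        w = occ * np.column_stack([np.ones(n), m, m])
        return w / w.sum(axis=1, keepdims=True)

    occ_light = _tilt(np.array([p.occupancy_light for p in params_list]))
    occ_dark = _tilt(np.array([p.occupancy_dark for p in params_list]))
    dwell_light = np.array([p.dwell_light_s for p in params_list])
    dwell_dark = np.array([p.dwell_dark_s for p in params_list])
    gains = np.column_stack(
        [
            np.zeros(n),
            [p.startle_gain_on for p in params_list],
            [p.startle_gain_on_mesopic for p in params_list],
            [p.startle_gain_off for p in params_list],
        ]
    )
    decay = np.array([p.startle_decay_s for p in params_list])
    beta_a = np.array([p.coast_beta[0] for p in params_list])
    beta_b = np.array([p.coast_beta[1] for p in params_list])
    gam_k = np.array([p.burst_gamma[0] for p in params_list])
    gam_th = np.array([p.burst_gamma[1] for p in params_list])

    p_switch_light = np.clip(dt / dwell_light, 0.0, 1.0)  # (n, 3)
    p_switch_dark = np.clip(dt / dwell_dark, 0.0, 1.0)
    speeds = np.empty((n, n_frames))
    rows = np.arange(n)

    def _draw_state(occ, t):
        w = occ.copy()
        if kind[t]:
            mult = 1.0 + gains[:, kind[t]] * cue_w[t] * np.exp(-dt_since[t] / decay)
            w[:, 2] = w[:, 2] * mult
            w = w / w.sum(axis=1, keepdims=True)
        u = rng.random(n)
        return (u[:, None] > np.cumsum(w, axis=1)).sum(axis=1).astype(np.int8)

    state = _draw_state(occ_light if light[0] else occ_dark, 0)
    for t in range(n_frames):
        if t:
            p_switch = p_switch_light if light[t] else p_switch_dark
            switch = rng.random(n) < p_switch[rows, state]
            new = _draw_state(occ_light if light[t] else occ_dark, t)
            state = np.where(switch, new, state)
        coast_v = np.clip(20.0 * rng.beta(beta_a, beta_b), 1e-6, 20.0 - 1e-9)
        burst_v = 20.0 + rng.gamma(gam_k, gam_th)
        speeds[:, t] = np.where(state == 1, coast_v, np.where(state == 2, burst_v, 0.0))
    return speeds


def simulate_trace(
    protocol: AssayProtocol,
    params: LocomotorParams,
    seed: int,
    *,
    well_id: str = "W01",
    genotype: str = "WT",
    batch: str = "batch1",
) -> SpeedTrace:
    """Simulate one larva's speed trace under the given schedule."""
    rng = np.random.default_rng(seed)
    speeds = _simulate_speed_matrix(protocol, [params], rng)[0]
    return SpeedTrace(
        well_id=well_id,
        genotype=genotype,
        batch=batch,
        frame_dt_s=params.frame_dt_s,
        speeds=speeds,
    )


def simulate_cohort(
    protocol: AssayProtocol,
    params: LocomotorParams,
    n: int,
    seed: int,
    *,
    genotype: str = "WT",
    batch: str = "batch1",
    well_prefix: str = "W",
) -> list[SpeedTrace]:
    """Simulate ``n`` i.i.d. larvae (one shared RNG stream, vectorized)."""
    rng = np.random.default_rng(seed)
    speeds = _simulate_speed_matrix(protocol, [params] * n, rng)
    return [
        SpeedTrace(
            well_id=f"{well_prefix}{i + 1:03d}",
            genotype=genotype,
            batch=batch,
            frame_dt_s=params.frame_dt_s,
            speeds=speeds[i],
        )
        for i in range(n)
    ]


def simulate_plate(
    protocol: AssayProtocol,
    genotypes: list[GenotypeConfig],
    n_per_genotype: int,
    plate: PlateSpec,
) -> tuple[list[SpeedTrace], pd.DataFrame]:
    """Simulate a multi-batch plate experiment with nuisance variation.

    Each larva is assigned a well and batch, with genotypes interleaved
    across wells so that no batch is confounded with genotype (as a
    randomized plate layout would ensure).  A per-well illumination
    multiplier and a per-batch activity multiplier are drawn once
    (lognormal, so SD 0 gives multipliers of exactly 1) and recorded in the
    metadata table as ground truth for normalization tests.
    """
    total = n_per_genotype * len(genotypes)
    capacity = plate.n_wells * len(plate.batch_ids)
    if total > capacity:
        raise ValueError(
            f"{total} larvae exceed capacity {capacity} "
            f"({plate.n_wells} wells x {len(plate.batch_ids)} batches)"
        )
    rng = np.random.default_rng(plate.seed)

    batch_factor = {
        b: float(np.exp(rng.normal(0.0, plate.batch_effect_sd)))
        if plate.batch_effect_sd > 0
        else 1.0
        for b in plate.batch_ids
    }

    rows = []
    params_list = []
    mults = []
    # interleave genotypes so batches stay balanced
    order = [
        geno
        for pair in zip(*[[g] * n_per_genotype for g in genotypes])
        for geno in pair
    ]
    for slot, geno in enumerate(order):
        batch = plate.batch_ids[slot // plate.n_wells]
        well = f"{batch}:W{slot % plate.n_wells + 1:02d}"
        wf = (
            float(np.exp(rng.normal(0.0, plate.well_light_sd)))
            if plate.well_light_sd > 0
            else 1.0
        )
        rows.append(
            {
                "well_id": well,
                "genotype": geno.label,
                "batch": batch,
                "well_light_factor": wf,
                "batch_factor": batch_factor[batch],
            }
        )
        params_list.append(geno.params)
        mults.append(wf * batch_factor[batch])

    meta = pd.DataFrame(rows)
    speeds = _simulate_speed_matrix(protocol, params_list, rng, activity_mult=mults)
    traces = [
        SpeedTrace(
            well_id=r["well_id"],
            genotype=r["genotype"],
            batch=r["batch"],
            frame_dt_s=params_list[i].frame_dt_s,
            speeds=speeds[i],
        )
        for i, r in enumerate(rows)
    ]
    return traces, meta


# ---------------------------------------------------------------------------
# biometry / morphometry / Ct / maze tables


def simulate_biometry(n: int, genotype: GenotypeConfig, seed: int) -> pd.DataFrame:
    """Per-fish correlated Gaussian ocular-biometry draws.

    Lens radius and retinal radius are drawn jointly with correlation
    ``genotype.biometry_corr``; the anterior-posterior lens diameter is
    twice the lens radius and the proximal-distal diameter is that times an
    independently drawn lens-circularity ratio.  Values are truncated just
    above 0.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    bio = genotype.biometry
    if any(sd <= 0 for _, sd in bio.values()):
        raise ValueError("biometry SDs must be > 0")
    rho = genotype.biometry_corr
    rng = np.random.default_rng(seed)

    lm, ls = bio["lens_radius_um"]
    rm, rs = bio["retinal_radius_um"]
    cov = np.array(
        [[ls**2, rho * ls * rs], [rho * ls * rs, rs**2]]
    )
    lens_r, ret_r = rng.multivariate_normal([lm, rm], cov, size=n).T

    def _norm(key):
        mu, sd = bio[key]
        return rng.normal(mu, sd, size=n)

    eps = 1e-6
    body = np.maximum(_norm("body_length_mm"), eps)
    axial = np.maximum(_norm("axial_length_um"), eps)
    thick = np.maximum(_norm("retinal_thickness_um"), eps)
    ratio = np.maximum(_norm("lens_ratio"), eps)
    lens_r = np.maximum(lens_r, eps)
    ret_r = np.maximum(ret_r, eps)
    ap = 2.0 * lens_r
    pd_diam = ap * ratio

    return pd.DataFrame(
        {
            "fish_id": [f"{genotype.label}_{i + 1:03d}" for i in range(n)],
            "genotype": genotype.label,
            "body_length_mm": body,
            "axial_length_um": axial,
            "lens_diam_pd_um": pd_diam,
            "lens_diam_ap_um": ap,
            "lens_radius_um": lens_r,
            "retinal_radius_um": ret_r,
            "retinal_thickness_um": thick,
        }
    )


def simulate_morphometry(
    n: int,
    genotype: GenotypeConfig,
    replicate_sd: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-fish true trait values plus three noisy replicate measurements.

    Columns are ``<trait>_1 .. <trait>_3`` for body length, head length and
    midbrain diameter (mm), emulating triplicate manual measurements.
    """
    if replicate_sd < 0:
        raise ValueError("replicate_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = {
        "fish_id": [f"{genotype.label}_{i + 1:03d}" for i in range(n)],
        "genotype": genotype.label,
    }
    for trait, (mu, sd) in genotype.morphometry.items():
        true = np.maximum(rng.normal(mu, sd, size=n), 1e-6)
        for r in range(3):
            noisy = true + rng.normal(0.0, replicate_sd, size=n) if replicate_sd else true
            out[f"{trait}_{r + 1}"] = np.maximum(noisy, 1e-6)
    return pd.DataFrame(out)


def simulate_ct_table(
    genes: list[str],
    fold_changes: dict[str, float],
    efficiencies: dict[str, float],
    references: list[str],
    n_reps: int = 9,
    ct_noise_sd: float = 0.1,
    seed: int = 0,
    baseline_ct: float | dict[str, float] = 22.0,
) -> pd.DataFrame:
    """qPCR Ct table with prescribed treated/control fold changes.

    Control Cts are drawn around each gene's baseline; treated Cts are
    shifted by ``-log_E(fold)`` cycles so that the efficiency-corrected
    expression ratio of the noiseless table equals the prescribed fold.
    Reference (housekeeping) genes must have fold change 1.
    """
    if not set(references) <= set(genes):
        raise ValueError("references must be a subset of genes")
    if not references:
        raise ValueError("need at least one reference gene")
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        fold = float(fold_changes.get(gene, 1.0))
        eff = float(efficiencies.get(gene, 2.0))
        if fold <= 0:
            raise ValueError(f"fold change for {gene} must be > 0")
        if eff <= 1.0:
            raise ValueError(f"efficiency for {gene} must exceed 1")
        role = "reference" if gene in references else "target"
        if role == "reference" and fold != 1.0:
            raise ValueError(f"reference gene {gene} must have fold change 1")
        base = baseline_ct[gene] if isinstance(baseline_ct, dict) else baseline_ct
        shift = -math.log(fold, eff)  # treated Ct minus control Ct
        for group, offset in (("control", 0.0), ("treated", shift)):
            noise = rng.normal(0.0, ct_noise_sd, size=n_reps) if ct_noise_sd else np.zeros(n_reps)
            for rep in range(n_reps):
                rows.append(
                    {
                        "gene": gene,
                        "role": role,
                        "group": group,
                        "replicate": rep + 1,
                        "ct": base + offset + noise[rep],
                        "efficiency": eff,
                    }
                )
    return pd.DataFrame(rows)


def simulate_color_maze(
    n_fish: int,
    arm_weights: dict[str, float],
    n_timepoints: int = 18,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-maze counts: per timepoint, fish distribute multinomially.

    ``arm_weights`` are relative preference weights (e.g. the four colored
    arms, optionally plus a neutral center); counts sum to ``n_fish`` at
    every timepoint.
    """
    if not 0 < n_fish <= 20:
        raise ValueError("n_fish must be in 1..20")
    arms = list(arm_weights)
    w = np.array([arm_weights[a] for a in arms], dtype=float)
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("arm weights must be >= 0 and not all zero")
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_fish, p, size=n_timepoints)
    df = pd.DataFrame(counts, columns=arms)
    df.insert(0, "timepoint", np.arange(n_timepoints))
    return df
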