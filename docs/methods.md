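# Methods

`zfvision` quantifies visually guided locomotor behavior and ocular
biometry in larval zebrafish.  This note records the models, conventions,
and numerical choices the package is built on, and what its synthetic-data
generator does and does not emulate.

## Activity classes and bout analysis

Per-frame swim speed is classified as **inactive** (exactly 0 mm/s),
**coast** (0–20 mm/s, slow rhythmic swimming driven by slow motor
neurons), or **burst** (≥ 20 mm/s, fast Mauthner-circuit escapes).  The
20 mm/s boundary is assigned to the burst class so that the headline
burst statistic is a closed class; both the threshold
(`coast_max_mm_s`) and its inclusivity (`burst_inclusive`) are
parameters of every classification entry point.

A *bout* is a maximal run of frames in one class.  Binned activity
records report, per well and acquisition bin (1, 10, 60 or 300 s): the
time spent in each class (frames × frame interval), the distance swum per
class (Σ speed × frame interval), and the number of coast/burst bouts
*starting* in the bin (ties are impossible on a frame grid).  Three exact
invariants follow from these definitions and are enforced by tests:
class durations partition each bin; summed bin distances equal the trace
total to 10⁻⁹ mm; and 1 s records aggregated ×10 equal direct 10 s
records.

## Illumination protocols

A protocol is a contiguous, non-overlapping list of constant-intensity
epochs starting at `t = 0` (recording start).  Pre-recording adaptation
(typically 2 h of darkness) is metadata — `adaptation_s` and
`adaptation_intensity_pct` — not epochs; consequently, when the first
epoch's intensity differs from the adaptation intensity, `t = 0` itself
is a transition (a flash presented to a dark-adapted larva at recording
start is a light-ON event).  Intensity is percent of the enclosure
maximum (100 % ≡ 8,000 lux nominal, assumed linear); only relative
percent is used downstream.

Builders cover the standard designs:

* **VMR**: an in-recording pre-dark period (default 30 min) followed by
  2–3 trials of 30 min light-ON / 30 min light-OFF.  Three trials at 30 %
  give the standard 3.5 h recording; two trials at 5 % give the 2.5 h
  mesopic variant.  The trial count is configurable because both designs
  are in use; the default is 3 (matching the 3.5 h total).
* **FSTR**: light cues of configurable millisecond lengths (default 10,
  20, 50, 100, 250, 500, 1000 ms) alternating with 20 min dark rests,
  presented in forward or reverse order.  Flash boundaries generally do
  not land on the acquisition-bin grid; the final rest epoch is padded so
  the total recording is a whole number of bins, and all window
  extraction snaps to bin edges (see below).
* **Free swim**: a single constant epoch at 30 % (light) or 0 % (dark).

## Burst–glide locomotion simulator

The generator is a discrete-time Markov chain over the three latent
activity states, chosen over i.i.d. per-frame states so that bout
durations are well defined and approximately geometric.  Each frame
(default `frame_dt_s = 0.1 s`) the chain leaves its state with
probability `frame_dt / dwell[state]`; the replacement state is drawn
from illumination-conditional occupancy probabilities.  Speeds are drawn
per frame from bounded state-conditional distributions — coast is
20 × Beta(2, 8) mm/s (mean 4 mm/s, support (0, 20)), burst is
20 + Gamma(2, 5) mm/s (mean 30) — matching the class supports by
construction.

**Startle kernel.**  After every light transition the burst occupancy
weight is multiplied by `1 + g·w·exp(−Δt / τ)` with decay `τ = 0.8 s`.
`g` is the direction-appropriate gain and `w = min(1, T / 0.05 s)` is a
temporal-integration weight, where `T` is the duration of the light step
entered (for ON) or exited (for OFF).  `w` makes millisecond flashes
evoke proportionally weaker startles than sustained steps in both
directions — a 10 ms flash neither builds a full ON response nor
constitutes a sustained light exposure whose offset would drive a full
OFF response.

**Default parameters** (wild type), calibrated once so the simulated
responses sit on the scale of published cohort values:

| parameter | default | rationale |
| --- | --- | --- |
| occupancy (light) | (0.35, 0.60, 0.05) | active, mostly coasting in light |
| occupancy (dark) | (0.45, 0.52, 0.03) | reduced activity in darkness |
| dwell (both) | (1.0, 1.0, 0.35) s | sub-second bursts, ~1 s coast/pause bouts |
| ON gain (photopic) | 30 | light-ON response ≈ 0.16 s per 1 s window at n = 48 |
| ON gain (mesopic, ≤ 10 %) | 15 | mesopic ON response ≈ 0.12 s |
| OFF gain | 160 | OFF response larger than ON (≈ 0.26 s) |
| startle decay | 0.8 s | startle largely over within the 1 s window |

The knock-out configuration applies three multipliers to wild type:
photopic ON gain ×1.125 (light-ON hyperactivity), mesopic ON gain ×0.95
(the hyperactivity reverses under dim light), and dark coast dwell ×0.79
(the dark-specific coast-duration deficit).  All are overridable.

**Nuisance structure.**  `simulate_plate` draws one lognormal per-well
illumination multiplier and one per-batch activity multiplier (SD 0 gives
exactly 1) and tilts each larva's occupancy odds toward the active states
by their product, recording both in the metadata table as ground truth
for normalization tests.  Genotypes are interleaved across wells so
batches are never confounded with genotype, as a randomized plate layout
would ensure.

**What the generator does not emulate.**  No positional information
(thigmotaxis, turning), no habituation or circadian drift, no
inter-larva heterogeneity beyond the nuisance multipliers, and no
biophysics of swimming.  Sub-frame (10–50 ms) flashes are rendered only
through the startle weight `w`, not as an illumination change visible to
the occupancy conditioning.  One consequence of the specified startle
mechanism (burst-weight multiplication at switch events) is saturation:
at gains large enough to reproduce the absolute response scale, a +12.5 %
gain difference compresses to a few percent of response difference.
Recovery tests therefore compare estimates against the *generative* truth
(a large simulated cohort pushed through the same pipeline), not against
the published group difference; passing them shows the pipeline is
unbiased and calibrated on data of this structure, not that real effect
sizes are reproduced.

## Three-step normalization

The published analysis normalizes well activity for (1) per-well
received light intensity, (2) batch effects, and (3) baseline activity in
the final 5 min of adaptation.  The underlying formulas are not
reproduced in the source literature, so the package fixes an explicit
contract: step 1 divides the response field by the well's illumination
factor (from metadata when known, otherwise the well's recording-wide
mean over the plate mean); step 2 divides by the batch mean of step-1
values over the grand mean; step 3 subtracts the well's mean step-2 value
over the baseline window.  Each step is independently switchable, every
factor is recorded in a report that makes normalization exactly
invertible (to 10⁻⁹), and degenerate zero denominators fall back to a
factor of 1 with a logged warning rather than failing.  Downstream
comparisons use group contrasts, which are robust to the exact scheme; a
common positive rescaling of all wells rescales contrasts without
changing their order.

Note that step 3 deliberately re-centers each well and therefore adds
per-well baseline noise to batch means; between-batch variance reduction
is assessed after steps 1–2 (the batch-correcting steps), baseline
zeroing after step 3.

## Assay statistics

* **VMR response**: per larva, burst duration within a window (default
  1 s) after each matching ON or OFF transition, averaged across trials;
  groups are summarized as mean ± SEM over larvae (n counts larvae, so
  per-larva trial averaging always precedes group statistics).
* **FSTR response**: burst duration in the 30 s before and after each
  flash onset; the 1 s-window variant is available via `window_s=1`
  (both window conventions appear in the assay literature; neither is
  canonical here).  The percent response is `100 × post / pre` — the
  convention under which the published pre/post means (0.0046 →
  0.0082 s) reproduce the printed 178 % — with `pre = 0` yielding an
  undefined (NaN) response rather than an exception.  Forward- and
  reverse-order presentations of the same cue length are averaged per
  larva before the percent is formed.  Window edges snap *down* to the
  acquisition-bin grid, so a flash at t = 1200.01 s is analyzed on
  [1170, 1200) vs [1200, 1230); windows of consecutive cues must not
  overlap.
* **Free swim**: per-larva mean distance per 10 s and mean coast/burst
  durations per bin under a constant-intensity protocol.
* **Color preference**: per-arm mean counts over timepoints and
  percentages of the (constant) total fish count; supports the 4-color
  and the 2-color-plus-neutral maze variants.

## Ocular biometry and morphometry

Derived metrics: lens ratio (proximal–distal / anterior–posterior
diameter), normalized axial length (µm of axial length per mm body
length), and the Relative Refractive Error
`RRE = 1 − retinal_radius / (2.324 × lens_radius)`, positive for
hyperopic eyes.  The 2.324 focal-length factor (an idealized
Matthiessen-type small-eye optics constant) is exposed as a parameter.
Cohort summaries compute per-fish metrics first and average
(`method="per_fish"`); the ratio-of-means variant is also exposed because
the two differ whenever traits covary across fish — on published cohort
means the point formula gives 0.147 (wild type) and 0.211 (knock-out),
which underlines that published per-fish cohort RRE means cannot be
reconstructed from trait means alone.

Morphometry averages the three replicate measurements per trait before
any ratio is formed.  The head-to-body ratio is head/body; the
"head-to-midbrain ratio" is computed as midbrain/head because only that
orientation reproduces the conventional cohort values (0.74 wild type,
0.69 knock-out from trait means 0.52/0.70 and 0.52/0.75) — the name
follows the field's labeling, the formula follows its numbers.

## Resampling statistics

* **Bootstrap mean difference**: percentile bootstrap (not BCa) of
  `mean(B) − mean(A)` with a 95 % percentile CI, matching the
  estimation-plot convention; deterministic given a seed.
* **Rank-sum test**: two-sided Wilcoxon–Mann–Whitney with mid-ranks for
  ties.  Exact mode enumerates all label assignments (combined n ≤ 12);
  permutation mode samples reallocations with the `(count+1)/(n_perm+1)`
  correction so p is never 0; asymptotic mode uses the tie-corrected
  normal approximation.  All-equal data returns p = 1.
* **Relative expression**: efficiency-corrected ratio
  `E_t^ΔCt_t / geomean_ref(E_r^ΔCt_r)` with
  `ΔCt = mean Ct(control) − mean Ct(treated)`; the geometric mean over
  the (typically three) housekeeping genes is the standard multi-reference
  normalization.  The p-value randomizes group labels within every gene
  and counts |log ratio| exceedances two-sidedly, again with the +1
  correction.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale versions of the study
designs: VMR-like schedules of 1 min pre-dark plus 2 × (30 s ON / 30 s
OFF) at a 0.1 s frame interval, cohorts of 48 larvae per genotype (the
lower end of the published range), 200 null replicates for p-value
calibration, 100 replicates for CI-coverage checks, and ground-truth
cohorts of 3,000–4,000 larvae.  Epoch contiguity is checked to 1 ms;
record CSVs serialize durations at ms precision and distances at
0.001 mm (speed traces round-trip bit-exactly); coast speed draws are
clipped away from the open-interval endpoints so latent states and
classified speeds agree exactly.  Duration-sum validation of records
allows one frame plus serialization rounding (0.101 s at the default
frame interval).

## Known limitations

* The gain-to-response saturation described above: simulator genotype
  contrasts are smaller than published ones at matched absolute response
  levels.
* The units of published cohort coast durations (tens of seconds) are
  not fully specified in the assay literature; the simulator treats them
  as relative calibration only, and free-swim summaries report seconds
  per bin explicitly.
* Published per-fish cohort RRE means are not reproducible from trait
  means (per-fish covariance is required); the package exposes both
  summary methods but makes no attempt to guess the covariance.
* The exact formulas of the original three-step normalization and of the
  reference tool's "pairwise fixed reallocation" randomization are not
  public; the contracts implemented here are explicit stand-ins whose
  group contrasts are insensitive to the difference.
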