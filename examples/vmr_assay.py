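"""Visual motor response (VMR): simulate a plate, normalize, and compare
light-ON startle responses between wild-type and knock-out larvae.

The VMR assay measures the burst-swimming startle evoked by abrupt light
transitions.  Here a desk-scale schedule (1 min dark, then two 30 s ON /
30 s OFF trials) is simulated for 48 larvae per genotype across two
batches with nuisance variation, the activity is normalized, and the
light-ON response (burst duration in the 1 s after each ON transition) is
summarized per genotype with a bootstrap estimate of the group difference.
"""

from zfvision.assays import vmr_response
from zfvision.bout_analysis import bin_activity_table
from zfvision.normalization import baseline_window, normalize
from zfvision.protocols import AssayProtocol, LightEpoch
from zfvision.simulator import PlateSpec, ko_genotype, simulate_plate, wt_genotype
from zfvision.stats import bootstrap_mean_diff

protocol = AssayProtocol(
    "vmr",
    (
        LightEpoch(0, 60, 0),
        LightEpoch(60, 30, 30),
        LightEpoch(90, 30, 0),
        LightEpoch(120, 30, 30),
        LightEpoch(150, 30, 0),
    ),
    bin_s=1.0,
)

plate = PlateSpec(
    n_wells=48, well_light_sd=0.1, batch_ids=("b1", "b2"), batch_effect_sd=0.2, seed=1
)
traces, metadata = simulate_plate(protocol, [wt_genotype(), ko_genotype()], 48, plate)
records = bin_activity_table(traces, bin_s=1.0)

normalized, report = normalize(
    records, metadata, baseline_window(protocol, minutes=1), "dur_burst_s"
)

summaries = vmr_response(normalized, protocol, direction="ON", window_s=1.0)
for genotype, s in summaries.items():
    print(f"{genotype}: light-ON burst {s.mean:.3f} +/- {s.sem:.3f} s (n={s.n})")

est = bootstrap_mean_diff(
    summaries["WT"].per_larva_values, summaries["KO"].per_larva_values, seed=1
)
print(
    f"KO - WT mean difference: {est.mean_diff:.3f} s, "
    f"95% CI [{est.ci_low:.3f}, {est.ci_high:.3f}]"
)
print(
    "A positive difference would mean the knock-out startles harder at "
    "light-ON (cone-pathway hypersensitivity).  At this desk scale the "
    "generative effect is small, so a 95% CI spanning zero is the expected "
    "outcome for a single plate; the full-length protocol and pooled "
    "replicates are needed to resolve it."
)
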