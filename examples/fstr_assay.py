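"""Flash-stimulus threshold response (FSTR): percent response to brief
light flashes, averaged over forward and reverse cue order.

Dark-adapted larvae receive light cues of different lengths separated by
dark rests.  The response to each cue is the burst duration in the 30 s
after flash onset expressed as a percentage of the 30 s before; 100%
means no change.  Presenting the cue series in forward and reverse order
and averaging cancels habituation.
"""

from zfvision.assays import fstr_response
from zfvision.bout_analysis import bin_activity_table
from zfvision.protocols import make_fstr_protocol
from zfvision.simulator import simulate_cohort, wt_genotype

runs = []
for i, order in enumerate(("forward", "reverse")):
    protocol = make_fstr_protocol(
        [10, 1000], rest_min=2.0, order=order, pre_dark_min=1.0
    )
    traces = simulate_cohort(protocol, wt_genotype().params, 48, seed=10 + i)
    runs.append((bin_activity_table(traces, 1.0), protocol))

per_larva, summaries = fstr_response(runs, window_s=30.0)
for (genotype, cue_ms), s in sorted(summaries.items(), key=lambda kv: kv[0][1]):
    print(
        f"{genotype}, {cue_ms:>4d} ms flash: {s.mean:.0f}% +/- {s.sem:.0f}% "
        f"(n={s.n})"
    )
print(
    "Values above 100% show the flash was detected; a millisecond-scale cue "
    "evokes a much weaker startle than a sustained 1 s cue, so the percent "
    "response grows with cue length.  Larvae with no pre-flash bursting have "
    "an undefined percent and are dropped, which is why n can fall below 48."
)
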