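"""Super-state collapse, 19-sample consensus and donut-style composition.

Simulates noisy 18-label segmentations for a 19-patient cohort, collapses
them to 6 super states, calls the >=50% consensus and summarizes which
states the up/down regions fall into.
"""

from spikewin.chromatin_states import (
    call_consensus,
    collapse_states,
    load_super_state_map,
    simulate_segmentations,
    state_composition,
)
from spikewin.genomic_io import GenomicInterval

super_map = load_super_state_map()
segs = simulate_segmentations(
    {"chr1": 100_000}, n_samples=19, labels_18=sorted(super_map.mapping),
    agreement=0.8, seed=4,
)
collapsed = collapse_states(segs, super_map)
consensus = call_consensus(collapsed, min_fraction=0.5)

called = sum(s is not None for s in consensus.states)
print(f"atomic intervals: {len(consensus.intervals)}; with consensus: {called} "
      f"({100 * called / len(consensus.intervals):.0f}%)")

up = [GenomicInterval("chr1", s, s + 2000) for s in range(0, 40_000, 10_000)]
down = [GenomicInterval("chr1", s, s + 2000) for s in range(50_000, 90_000, 10_000)]
comp = state_composition(up, down, consensus)
print("\nstate composition of trended regions (the donut-plot numbers):")
print(comp.table.to_string(index=False))
print(f"unassigned: {comp.n_unassigned}")
print(
    "\nA consensus needs >= ceil(0.5 * 19) = 10 agreeing patients and a "
    "strict plurality; regions are annotated by majority-bp overlap."
)
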