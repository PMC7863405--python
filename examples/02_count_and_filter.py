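"""Window counting, background estimation and the retention filter.

Counts fragments into 150 bp / 50 bp sliding windows (500 bp fragment cap),
estimates per-sample background from 1 kb bins and keeps windows whose
pooled rate exceeds 3x the background -- the windows worth testing.
"""

import numpy as np

import spikewin

cfg = spikewin.default_config(n_replicates=3, seed=11)
fragments, _ = spikewin.simulate_experiment(cfg)
sizes = cfg.chrom_sizes()
samples = sorted(fragments)

grid = spikewin.tile_windows(sizes, width=150, step=50, spike_tile=5000)
counts = spikewin.count_fragments(fragments, grid, max_fragment=500, sample_order=samples)
background = spikewin.estimate_background(fragments, sizes, bin_width=1000, sample_order=samples)
retention = spikewin.filter_by_background(counts, background, min_fold=3)

print(f"host windows tiled:   {retention.n_input}")
print(f"windows retained:     {retention.n_retained} "
      f"({100 * retention.n_retained / retention.n_input:.1f}%)")
print(f"background rates/bp:  {np.round(background.global_rate, 4)}")
print(
    "\nRetained windows sit over the planted promoter/enhancer/CTCF regions; "
    "background and heterochromatin fall below the 3-fold rule."
)
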