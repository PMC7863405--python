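# Methods

## Model overview

The counting unit is the sequenced fragment, represented as a 0-based
half-open interval. For window `g` in sample `n` the count is modelled as

    y_gn ~ NB(mu_gn, phi_g),    log mu_gn = o_n + x_n' beta_g

with `o_n` the log host library size and `x_n` the design row: an intercept,
treatment-arm indicators (solvent reference; 8 h and 18 h arms), and optional
nuisance covariates (spike-derived unwanted-variation factors, PC1 batch
scores). `phi_g` is the NB dispersion; quasi-likelihood moderation
additionally scales the deviance by a window-specific quasi-dispersion.

## Windowing, background and retention

- Windows: width 150 bp, step 50 bp, fully inside each host contig. A
  fragment contributes to every window it overlaps by >= 1 bp (midpoint
  assignment is available as an option). Fragments longer than the cap
  (default 500 bp; 800 bp is the conventional ChIP setting) are discarded,
  not truncated — the cap is a QC filter on fragment calls.
- Background: the host genome is tiled into non-overlapping bins (1 kb
  default; 5 kb for ChIP-style data) and each fragment is assigned once by
  midpoint; the per-sample global rate is the **median** bin rate, robust to
  peaks. The phrase "sliding" background is implemented as non-overlapping
  bins because the estimate is a single median — overlap adds cost, not
  information; a stepped variant can be built by passing overlapping bins.
  Only complete bins are used; a trailing partial bin is dropped.
- Retention: a window is kept iff its pooled rate
  `sum_n y_gn / (width * N)` strictly exceeds `min_fold` (default 3) times
  the mean per-sample background rate. Aggregating across samples avoids
  retaining on single-sample noise; a per-sample "any" mode is available.
- Blacklist: any window or background bin overlapping a blacklist interval
  by >= 1 bp is removed, for ATAC-style data as well as ChIP (uniformity
  aids comparability).
- Spike contigs are never tiled into the analysis grid; each is carried as a
  whole-contig pseudo-window, optionally split into fixed tiles (default
  5 kb) so factor estimation sees several control features.

## Spike-in normalization

Lambda is added to nuclei before transposition, so lambda fragment yield
carries the per-sample transposition-efficiency factor; phiX is added after
transposition and is used for QC only, never as a control. Factors are
estimated RUV-style: `log(count + 0.5)` on lambda rows, centered within each
row across samples, and the first `k` left singular directions of the
resulting samples x controls matrix are the factor scores `W` (unit-norm
columns; sign fixed so the largest-magnitude element is positive, making all
outputs platform-deterministic). Defaults: `k = 1`, with explained-variance
diagnostics for larger `k`.

`W` enters the GLM **as design covariates** rather than by correcting
counts: correction would distort the count distribution the NB model
assumes, while covariates preserve it. Offsets always remain log host
library sizes. The pseudo-count is 0.5 everywhere a log of counts is taken.

PC1 batch scores come from an SVD of the centered log counts of retained
host windows (samples as observations), centered to sum zero, same sign
convention.

## Quasi-likelihood testing

1. **Dispersion.** Per window, the Cox-Reid adjusted profile likelihood
   `APL_g(phi) = loglik(y_g; mu_g, phi) - 0.5 log|X' W X|` is evaluated on a
   fixed log-spaced grid (fitted means from a provisional fit; for balanced
   designs the means are essentially free of `phi`). Per-window maximizers
   at few residual df are severely right-skewed — their median runs well
   below truth — so the **trend** maximizes the locally *pooled* APL (sum
   over an abundance-ordered neighbourhood, ~10% of windows), smoothed by
   lowess, and the per-window ("tagwise") estimate maximizes
   `APL_g + (d_prior/d_res) * local mean APL` with prior df 10, the classic
   weighted-likelihood empirical-Bayes form. Grid maxima are sharpened by
   parabolic interpolation in log phi. On simulated NB data this recovers
   the truth to within a few percent at 6 samples, matching reference
   implementations of the same moderation idea.
2. **Quasi-dispersion.** Windows are refit at the trended dispersion; the
   quasi-dispersion is residual deviance / residual df, shrunk toward its
   central value by moment-matching `log s^2` to a scaled-F distribution
   (digamma/trigamma matching with 10% trimming; the prior df may be
   infinite, collapsing to a common value).
3. **Test.** The ANOVA-like test drops all treatment coefficients from the
   design and refers `F = (deviance drop / q) / s^2_post` to
   `F(q, d_prior + d_res)`; a contrast vector `c` is tested by refitting on
   a basis of the null space of `c'`. Non-converged and all-zero windows are
   excluded and counted, never imputed.
4. **Clusters.** Retained windows within 100 bp are chained, split greedily
   left-to-right at 5 kb (both are parameters; the defaults keep clusters
   sub-gene-scale). Member p-values combine by Simes' rule; cluster
   p-values are BH-adjusted. The representative log2FC is the member with
   the smallest p-value; direction is its sign, demoted to "mixed" when
   members at least as significant disagree.
5. **Trend classes.** A cluster is "up" when q < 0.05, log2FC(18 h) >=
   log2(1.5) and log2FC(8 h) >= 0 (mirrored for "down"). Requiring the same
   sign at 8 h operationalizes a *trended* change from 8 to 18 h; an
   18 h-only mode is a flag.

Null calibration measured by the test suite: window-level P(p < 0.05) ~
0.043-0.047 at phi = 0.05 with 6 samples; cluster-level q < 0.05 rate ~ 0.

## Compartments

Fragments are binned (midpoint) into fixed-width bins (default 100 kb;
smaller for toy genomes), log-transformed with the 0.5 pseudo-count and
adjusted by centered log library size. Within a sample group the bins x bins
Pearson correlation matrix is computed **across the group's samples** (the
alternative sample-pair reading yields no per-bin state and is rejected);
the leading eigenvector of that matrix, oriented so its correlation with
mean abundance is non-negative (open chromatin carries more signal), gives
per-bin signs; zero-variance bins get sign 0 and are excluded. Dissimilarity
between groups is `1 - Pearson r` over shared signed bins. No correlation
shrinkage is applied; groups below 5 samples trigger a warning. At least 3
samples and 4 bins are required.

## Chromatin states

The 18-to-6 super-state grouping is data, not code
(`src/spikewin/data/superstates_18to6.tsv`, echoed into output metadata):
promoter-flank mnemonics to Promoter, transcription to Transcription,
enhancer classes to Enhancer, ZNF/repeats and Het to Heterochromatin,
bivalent and Polycomb classes to Bivalent/Polycomb, Quies to Quiescent.
Adjacent same-label records merge after collapsing. Consensus is called on
the atomic partition at the union of all samples' breakpoints: a state needs
`ceil(min_fraction * n)` supporters **and** a strict plurality (an even
split is not a consensus — with n = 19 and the default 0.5 this means 10
samples). Regions are annotated by majority-bp overlap with consensus
intervals, ties broken by a fixed promoter-first priority; regions touching
only no-consensus intervals are "unassigned" and excluded from the
percentage base of the composition tables (reported separately). Regions
receive a single state; a multi-count mode is a flag.

## The simulator

The generator emulates the study design end to end: three arms (solvent,
8 h, 18 h), a multi-chromosome host genome (defaults: 800/600/600 kb), and
spike contigs at the true lambda (48,502 bp) and phiX (5,386 bp) lengths.

- **Regions.** Archetypes with per-arm multiplicative folds: promoters that
  gain (2x at 8 h, 4x at 18 h), promoters that lose (0.8x, 0.3x), CTCF
  sites that trend down to exactly 1.5-fold loss at 18 h (0.85x, 1/1.5x),
  null promoters/enhancers, and near-silent heterochromatin. Gains and
  losses are mass-balanced and regions are widely spaced (~half of each
  library is background), so the host library barely shifts between arms —
  mirroring perturbations that change few regions genome-wide and keeping
  library-size offsets meaningful.
- **Counts.** Region fragment counts are Poisson with mean
  `base_rate * width * depth * technical_factor * fold`; midpoints uniform
  in the region, lengths truncated-normal (mean 120, sd 40, range 30-500),
  no Tn5 sequence bias. Default depth 40,000 gives promoter windows ~60
  fragments/sample.
- **Technical factor.** Default mode models transposition efficiency as an
  *enrichment* factor: it scales open-chromatin regions and lambda (naked,
  fully accessible DNA) but not closed-chromatin fragments (background,
  heterochromatin) — efficiency moves signal-to-background, which is what
  makes it dangerous and what the lambda spike can see. A "global" mode
  scales every host fragment instead (a depth-like multiplier fully
  absorbed by library-size offsets). phiX never carries the factor.
- **Duplicates.** A `duplication_rate` fraction (default 0.10) of emitted
  fragments are exact copies of earlier ones across all contigs, emulating
  PCR amplification; no UMIs are modelled.
- **Truth.** Region tables carry true folds and the 1.5-fold direction
  class; sample tables carry the hidden technical factor. Identical seeds
  give byte-identical outputs.

What the simulator does **not** emulate: sequence-level reads, alignment or
mapping artifacts, Tn5 insertion bias, fragment-size periodicity,
copy-number variation, or peak-shape structure. Passing tests therefore
demonstrate the statistical machinery under the declared generative model,
not robustness to alignment-level artifacts in real libraries.

## Numerical choices

- IRLS with a 1e-8 ridge on the normal equations, linear predictor clipped
  at +-30, convergence on relative deviance change < 1e-8, 60 iterations.
- Dispersion grid: 0 plus 30 log-spaced points in [1e-4, 5].
- Sign conventions (factors, PC1, eigenvectors) are fixed as described so
  every output is deterministic across platforms and BLAS builds.
- Degenerate inputs fail loudly: zero-variance controls, < 3 samples for
  PCA/compartments, rank-deficient designs, zero-count samples, empty
  clusters. All-zero windows are flagged and excluded from testing.

## Problem sizes

The test suite and acceptance script run on deliberately small instances —
1-2 Mb genomes, 6-18 samples, 5,000-10,000 windows, 10-20 seeds — chosen so
the full chain is exercised end to end with tight statistical tolerances
while remaining quick to verify on a laptop.

## Known limitations

- The QL machinery is an independent implementation of the moderated
  quasi-likelihood idea; it is validated by calibration and recovery, not by
  numeric equality to any existing package.
- At 3 replicates per arm, losses planted exactly at the 1.5-fold
  classification boundary are recovered only partially (the estimate must
  cross the threshold); 6 replicates recover essentially all of them.
- Compartment inference assumes the group's samples share one structure;
  with < 5 samples the bin correlations (and hence signs) are noisy.
- The consensus caller is exact but O(breakpoints x samples); it is meant
  for segmentations, not base-pair resolution inputs.
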