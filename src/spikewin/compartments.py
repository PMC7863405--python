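"""A/B-compartment-style inference from binned accessibility.

Counts are summarized in large fixed-width bins (default 100 kb), log
transformed with a 0.5 pseudo-count and adjusted for library size.  Within a
sample group, pairwise Pearson correlations between bins are computed across
the group's samples; the leading eigenvector of that bin-correlation matrix
assigns each bin a compartment sign (open/accessible = positive, after
orienting the eigenvector to correlate non-negatively with mean abundance).
Chromosome-wide dissimilarity between a treatment group and solvent is
``1 - Pearson r`` between the two oriented eigenvectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import ChromSizes, FragmentRecord, GenomicInterval
from .normalization import PSEUDOCOUNT
from .window_counting import fragments_to_frames


@dataclass
class BinMatrix:
    """Fixed-width bins x samples log-scale abundance."""

    bin_width: int
    chroms: np.ndarray
    starts: np.ndarray
    samples: list[str]
    abundance: np.ndarray  # bins x samples, log(count+0.5) - centered log lib

    def chromosome_mask(self, chrom: str) -> np.ndarray:
        return self.chroms == chrom


@dataclass
class CompartmentProfile:
    chromosome: str
    group: str
    bin_starts: np.ndarray
    eigenvector: np.ndarray  # unit norm, oriented
    signs: np.ndarray  # +1 / -1 / 0 (zero-variance bins)
    orientation_anchor: str = "mean_abundance"


@dataclass
class DissimilarityScore:
    chromosome: str
    group: str
    reference: str
    score: float  # 1 - Pearson r, in [0, 2]
    n_bins: int


def bin_counts(
    fragments: Iterable[FragmentRecord] | Mapping[str, pd.DataFrame],
    chrom_sizes: ChromSizes,
    bin_width: int = 100_000,
    blacklist: Sequence[GenomicInterval] = (),
    sample_order: Sequence[str] | None = None,
) -> BinMatrix:
    """Bin fragments (by midpoint) and return library-adjusted log abundance."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    frames = fragments_to_frames(fragments)
    samples = list(sample_order) if sample_order is not None else sorted(frames)

    chroms_l: list[np.ndarray] = []
    starts_l: list[np.ndarray] = []
    for contig in chrom_sizes.host_contigs:
        n_bins = chrom_sizes[contig] // bin_width
        chroms_l.append(np.repeat(contig, n_bins))
        starts_l.append(np.arange(n_bins) * bin_width)
    chroms = np.concatenate(chroms_l).astype(object)
    starts = np.concatenate(starts_l).astype(np.int64)

    counts = np.zeros((len(chroms), len(samples)), dtype=np.int64)
    off = 0
    offsets = {}
    for contig in chrom_sizes.host_contigs:
        n_bins = chrom_sizes[contig] // bin_width
        offsets[contig] = (off, n_bins)
        off += n_bins
    for j, sid in enumerate(samples):
        df = frames[sid]
        host = df[~df["chrom"].isin(chrom_sizes.spike_contigs)]
        if len(host) == 0:
            continue
        mid = (host["start"].to_numpy() + host["end"].to_numpy()).astype(np.int64) // 2
        for contig, (o, n_bins) in offsets.items():
            if n_bins == 0:
                continue
            idx = mid[host["chrom"].to_numpy() == contig] // bin_width
            idx = idx[idx < n_bins]
            np.add.at(counts[o : o + n_bins, j], idx, 1)

    keep = np.ones(len(chroms), dtype=bool)
    for bl in blacklist:
        keep &= ~(
            (chroms == bl.chrom) & (starts < bl.end) & (starts + bin_width > bl.start)
        )
    chroms, starts, counts = chroms[keep], starts[keep], counts[keep]

    lib = counts.sum(axis=0).astype(float)
    lib = np.maximum(lib, 1.0)
    log_lib = np.log(lib) - np.mean(np.log(lib))
    abundance = np.log(counts.astype(float) + PSEUDOCOUNT) - log_lib[None, :]
    return BinMatrix(
        bin_width=bin_width, chroms=chroms, starts=starts,
        samples=samples, abundance=abundance,
    )


def compartment_profile(
    bin_matrix: BinMatrix,
    group_samples: Sequence[str],
    chromosome: str,
) -> CompartmentProfile:
    """Leading eigenvector of the bin-bin correlation matrix for one group.

    Correlation between bins is computed across the group's samples, so at
    least 3 samples are required; bins without variance get sign 0 and do
    not enter the eigen-decomposition.
    """
    idx = [bin_matrix.samples.index(s) for s in group_samples]
    if len(idx) < 3:
        raise ValueError("compartment inference needs >= 3 samples in the group")
    mask = bin_matrix.chromosome_mask(chromosome)
    if mask.sum() < 4:
        raise ValueError(f"need >= 4 bins on {chromosome!r}")
    A = bin_matrix.abundance[np.ix_(np.flatnonzero(mask), idx)]  # bins x samples
    sd = A.std(axis=1)
    ok = sd > 1e-12
    if ok.sum() < 2:
        raise ValueError("bin abundances constant across samples; profile undefined")
    C = np.corrcoef(A[ok])
    C = np.nan_to_num(C, nan=0.0)
    vals, vecs = np.linalg.eigh(C)
    lead = vecs[:, -1]
    mean_ab = A[ok].mean(axis=1)
    anchor = mean_ab - mean_ab.mean()
    if float(lead @ anchor) < 0:
        lead = -lead
    ev = np.zeros(int(mask.sum()))
    ev[ok] = lead
    norm = np.linalg.norm(ev)
    if norm > 0:
        ev = ev / norm
    signs = np.zeros(len(ev), dtype=np.int64)
    signs[ok] = np.sign(ev[ok]).astype(np.int64)
    if len(idx) < 5:
        warnings.warn("fewer than 5 samples in group: compartment signs are noisy")
    return CompartmentProfile(
        chromosome=chromosome,
        group=",".join(group_samples),
        bin_starts=bin_matrix.starts[mask],
        eigenvector=ev,
        signs=signs,
    )


def compartment_dissimilarity(
    profile_a: CompartmentProfile, profile_b: CompartmentProfile
) -> DissimilarityScore:
    """1 - Pearson r between two oriented eigenvectors (shared signed bins)."""
    if profile_a.chromosome != profile_b.chromosome:
        raise ValueError("profiles are on different chromosomes")
    if len(profile_a.eigenvector) != len(profile_b.eigenvector) or np.any(
        profile_a.bin_starts != profile_b.bin_starts
    ):
        raise ValueError("profiles use different binnings")
    shared = (profile_a.signs != 0) & (profile_b.signs != 0)
    if shared.sum() < 3:
        raise ValueError("fewer than 3 shared signed bins")
    a = profile_a.eigenvector[shared]
    b = profile_b.eigenvector[shared]
    r = float(np.corrcoef(a, b)[0, 1])
    return DissimilarityScore(
        chromosome=profile_a.chromosome,
        group=profile_b.group,
        reference=profile_a.group,
        score=1.0 - r,
        n_bins=int(shared.sum()),
    )
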