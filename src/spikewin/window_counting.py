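"""Sliding-window tiling, fragment counting, background estimation and the
fold-over-background retention filter.

Analysis windows are 150 bp sliding windows with a 50 bp step by default; a
fragment contributes one count to every window it overlaps by at least 1 bp,
after discarding fragments longer than the ``max_fragment`` cap (800 bp for
ChIP-style data, 500 bp for ATAC-style data).  Background abundance is the
per-sample median rate over large non-overlapping bins (5 kb ChIP / 1 kb
ATAC), and windows are retained when their pooled rate exceeds ``min_fold``
(default 3, i.e. log2(3) on the log scale) times the mean background rate.

Spike-in contigs are never tiled into the analysis grid; each is carried as a
whole-contig pseudo-window (optionally split into fixed tiles so that factor
analysis has several control features).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import ChromSizes, FragmentRecord, GenomicInterval

FRAGMENT_COLUMNS = ("chrom", "start", "end")


@dataclass
class WindowGrid:
    """Regular sliding-window tiling of the host genome.

    Host contig ``c`` of length L carries windows ``[k*step, k*step+width)``
    for ``k = 0 .. floor((L-width)/step)``.  Spike contigs are represented as
    whole-contig pseudo-windows (or non-overlapping tiles of
    ``spike_tile`` bp when set).
    """

    chrom_sizes: ChromSizes
    width: int = 150
    step: int = 50
    spike_tile: int | None = None
    n_windows: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.step <= 0:
            raise ValueError("width and step must be positive")
        self.n_windows = {}
        for contig in self.chrom_sizes.host_contigs:
            length = self.chrom_sizes[contig]
            if length < self.width:
                warnings.warn(
                    f"contig {contig!r} (length {length}) shorter than window "
                    f"width {self.width}: zero windows"
                )
                self.n_windows[contig] = 0
            else:
                self.n_windows[contig] = (length - self.width) // self.step + 1

    def windows_for(self, contig: str) -> list[GenomicInterval]:
        n = self.n_windows[contig]
        return [
            GenomicInterval(contig, k * self.step, k * self.step + self.width)
            for k in range(n)
        ]

    def spike_windows(self) -> list[GenomicInterval]:
        out: list[GenomicInterval] = []
        for contig in sorted(self.chrom_sizes.spike_contigs):
            length = self.chrom_sizes[contig]
            if self.spike_tile is None:
                out.append(GenomicInterval(contig, 0, length))
            else:
                for s in range(0, length, self.spike_tile):
                    out.append(GenomicInterval(contig, s, min(s + self.spike_tile, length)))
        return out

    @property
    def total_host_windows(self) -> int:
        return sum(self.n_windows.values())


def tile_windows(
    chrom_sizes: ChromSizes,
    width: int = 150,
    step: int = 50,
    spike_tile: int | None = None,
) -> WindowGrid:
    """Build the sliding-window grid over the host contigs."""
    return WindowGrid(chrom_sizes, width=width, step=step, spike_tile=spike_tile)


@dataclass
class CountMatrix:
    """Windows/bins x samples fragment counts with row metadata.

    ``chroms``/``starts``/``ends`` are parallel row arrays; ``is_spike``
    marks spike pseudo-window rows, which are excluded from retention
    filtering and host library sizes.
    """

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    samples: list[str]
    counts: np.ndarray
    is_spike: np.ndarray
    max_fragment: int | None = None
    retained: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.samples) != len(set(self.samples)):
            raise ValueError("duplicate sample ids")

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(c, int(s), int(e))
            for c, s, e in zip(self.chroms, self.starts, self.ends)
        ]

    def host_library_sizes(self) -> np.ndarray:
        """Total host-contig count per sample."""
        return self.counts[~self.is_spike].sum(axis=0)

    def subset_rows(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            chroms=self.chroms[mask],
            starts=self.starts[mask],
            ends=self.ends[mask],
            samples=list(self.samples),
            counts=self.counts[mask],
            is_spike=self.is_spike[mask],
            max_fragment=self.max_fragment,
            retained=None if self.retained is None else self.retained[mask],
        )

    def spike_total(self, contig: str) -> np.ndarray:
        mask = self.chroms == contig
        return self.counts[mask].sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.samples)
        df.insert(0, "chrom", self.chroms)
        df.insert(1, "start", self.starts)
        df.insert(2, "end", self.ends)
        return df


def fragments_to_frames(
    fragments: Iterable[FragmentRecord] | Mapping[str, pd.DataFrame],
) -> dict[str, pd.DataFrame]:
    """Normalize fragment input to ``{sample_id: DataFrame(chrom,start,end)}``."""
    if isinstance(fragments, Mapping):
        out = {}
        for sid, df in fragments.items():
            missing = set(FRAGMENT_COLUMNS) - set(df.columns)
            if missing:
                raise ValueError(f"fragment frame for {sid!r} lacks columns {missing}")
            out[sid] = df
        return out
    rows: dict[str, list[tuple[str, int, int]]] = {}
    for rec in fragments:
        rows.setdefault(rec.sample_id, []).append(
            (rec.interval.chrom, rec.interval.start, rec.interval.end)
        )
    return {
        sid: pd.DataFrame(data, columns=list(FRAGMENT_COLUMNS))
        for sid, data in rows.items()
    }


def _count_on_grid(
    starts: np.ndarray, ends: np.ndarray, width: int, step: int, n: int
) -> np.ndarray:
    """Counts per window for fragments on one contig (closed-form overlap).

    Window k = [k*step, k*step+width) overlaps [s,e) iff
    k*step < e and k*step + width > s.
    """
    if n == 0 or len(starts) == 0:
        return np.zeros(n, dtype=np.int64)
    k_lo = np.maximum((starts - width) // step + 1, 0)
    k_hi = np.minimum((ends - 1) // step, n - 1)
    valid = k_lo <= k_hi
    diff = np.zeros(n + 1, dtype=np.int64)
    np.add.at(diff, k_lo[valid], 1)
    np.add.at(diff, k_hi[valid] + 1, -1)
    return np.cumsum(diff)[:n]


def count_fragments(
    fragments: Iterable[FragmentRecord] | Mapping[str, pd.DataFrame],
    grid: WindowGrid,
    max_fragment: int,
    sample_order: Sequence[str] | None = None,
) -> CountMatrix:
    """Count fragments into the window grid (>=1 bp overlap rule).

    Fragments longer than ``max_fragment`` are discarded (not truncated)
    before counting.  Spike pseudo-windows are counted identically.
    """
    if max_fragment <= 0:
        raise ValueError("max_fragment must be positive")
    frames = fragments_to_frames(fragments)
    samples = list(sample_order) if sample_order is not None else sorted(frames)
    for sid in samples:
        if sid not in frames:
            frames[sid] = pd.DataFrame(columns=list(FRAGMENT_COLUMNS))

    host_contigs = [c for c in grid.chrom_sizes.host_contigs]
    spike_ivs = grid.spike_windows()
    row_chroms: list[np.ndarray] = []
    row_starts: list[np.ndarray] = []
    row_ends: list[np.ndarray] = []
    for contig in host_contigs:
        n = grid.n_windows[contig]
        ks = np.arange(n)
        row_chroms.append(np.repeat(contig, n))
        row_starts.append(ks * grid.step)
        row_ends.append(ks * grid.step + grid.width)
    row_chroms.append(np.array([iv.chrom for iv in spike_ivs], dtype=object))
    row_starts.append(np.array([iv.start for iv in spike_ivs], dtype=np.int64))
    row_ends.append(np.array([iv.end for iv in spike_ivs], dtype=np.int64))
    chroms = np.concatenate([np.asarray(a, dtype=object) for a in row_chroms])
    starts = np.concatenate(row_starts).astype(np.int64)
    ends = np.concatenate(row_ends).astype(np.int64)
    n_host = sum(grid.n_windows[c] for c in host_contigs)
    is_spike = np.zeros(len(chroms), dtype=bool)
    is_spike[n_host:] = True

    counts = np.zeros((len(chroms), len(samples)), dtype=np.int64)
    for j, sid in enumerate(samples):
        df = frames[sid]
        if len(df) == 0:
            continue
        lengths = df["end"].to_numpy() - df["start"].to_numpy()
        keep = df[lengths <= max_fragment]
        offset = 0
        for contig in host_contigs:
            n = grid.n_windows[contig]
            sub = keep[keep["chrom"] == contig]
            counts[offset : offset + n, j] = _count_on_grid(
                sub["start"].to_numpy(), sub["end"].to_numpy(), grid.width, grid.step, n
            )
            offset += n
        for i, iv in enumerate(spike_ivs):
            sub = keep[keep["chrom"] == iv.chrom]
            if len(sub) == 0:
                continue
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            counts[n_host + i, j] = int(np.sum((s < iv.end) & (e > iv.start)))

    return CountMatrix(
        chroms=chroms,
        starts=starts,
        ends=ends,
        samples=samples,
        counts=counts,
        is_spike=is_spike,
        max_fragment=max_fragment,
    )


@dataclass
class BackgroundEstimate:
    """Per-sample global background rate (fragments / bp) from large bins."""

    bin_width: int
    samples: list[str]
    global_rate: np.ndarray  # fragments per bp per sample
    bin_chroms: np.ndarray
    bin_starts: np.ndarray
    bin_rates: np.ndarray  # bins x samples, diagnostic


def estimate_background(
    fragments: Iterable[FragmentRecord] | Mapping[str, pd.DataFrame],
    chrom_sizes: ChromSizes,
    bin_width: int,
    blacklist: Sequence[GenomicInterval] = (),
    sample_order: Sequence[str] | None = None,
) -> BackgroundEstimate:
    """Median background rate over non-overlapping ``bin_width`` bins.

    Fragments are assigned to bins by midpoint so each contributes once;
    bins overlapping the blacklist are excluded before taking the median.
    Only complete bins are used (a trailing partial bin is dropped).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    frames = fragments_to_frames(fragments)
    samples = list(sample_order) if sample_order is not None else sorted(frames)

    bin_chroms: list[str] = []
    bin_starts: list[int] = []
    for contig in chrom_sizes.host_contigs:
        n_bins = chrom_sizes[contig] // bin_width
        for b in range(n_bins):
            bin_chroms.append(contig)
            bin_starts.append(b * bin_width)
    bchroms = np.asarray(bin_chroms, dtype=object)
    bstarts = np.asarray(bin_starts, dtype=np.int64)

    keep_bin = np.ones(len(bchroms), dtype=bool)
    for bl in blacklist:
        mask = (bchroms == bl.chrom) & (bstarts < bl.end) & (bstarts + bin_width > bl.start)
        keep_bin &= ~mask
    if not np.any(keep_bin):
        raise ValueError("no non-blacklisted background bins remain")

    bin_counts = np.zeros((len(bchroms), len(samples)), dtype=np.int64)
    offsets = {}
    off = 0
    for contig in chrom_sizes.host_contigs:
        n_bins = chrom_sizes[contig] // bin_width
        offsets[contig] = (off, n_bins)
        off += n_bins
    for j, sid in enumerate(samples):
        df = frames.get(sid)
        if df is None or len(df) == 0:
            warnings.warn(f"sample {sid!r} has no fragments; background rate 0")
            continue
        mid = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
        for contig, (o, n_bins) in offsets.items():
            if n_bins == 0:
                continue
            sel = df["chrom"].to_numpy() == contig
            idx = mid[sel] // bin_width
            idx = idx[idx < n_bins]
            np.add.at(bin_counts[o : o + n_bins, j], idx, 1)

    rates = bin_counts / float(bin_width)
    global_rate = np.median(rates[keep_bin], axis=0)
    return BackgroundEstimate(
        bin_width=bin_width,
        samples=samples,
        global_rate=global_rate,
        bin_chroms=bchroms[keep_bin],
        bin_starts=bstarts[keep_bin],
        bin_rates=rates[keep_bin],
    )


@dataclass
class RetentionFilter:
    """Result of the fold-over-background retention rule."""

    min_fold: float
    retained: np.ndarray  # bool per CountMatrix row (spike rows always False)
    n_input: int
    n_retained: int
    mode: str = "pooled"


def filter_by_background(
    counts: CountMatrix,
    background: BackgroundEstimate,
    min_fold: float = 3.0,
    mode: str = "pooled",
) -> RetentionFilter:
    """Retain windows whose rate strictly exceeds ``min_fold`` x background.

    ``pooled`` (default): pooled window rate
    ``sum(counts)/(width*n_samples)`` against the mean of the per-sample
    global background rates.  ``per_sample_any``: retain if the rule holds in
    at least one sample against that sample's own background rate.
    """
    if min_fold <= 0:
        raise ValueError("min_fold must be positive")
    if list(counts.samples) != list(background.samples):
        raise ValueError("counts and background cover different samples")
    if mode not in ("pooled", "per_sample_any"):
        raise ValueError(f"unknown filter mode {mode!r}")

    widths = (counts.ends - counts.starts).astype(float)
    host = ~counts.is_spike
    retained = np.zeros(counts.n_rows, dtype=bool)
    if mode == "pooled":
        rate = counts.counts.sum(axis=1) / (widths * counts.n_samples)
        threshold = min_fold * float(np.mean(background.global_rate))
        retained[host] = rate[host] > threshold
    else:
        per = counts.counts / widths[:, None]
        hits = per > min_fold * background.global_rate[None, :]
        retained[host] = hits[host].any(axis=1)
    n_input = int(host.sum())
    return RetentionFilter(
        min_fold=min_fold,
        retained=retained,
        n_input=n_input,
        n_retained=int(retained.sum()),
        mode=mode,
    )


def apply_blacklist(
    obj: CountMatrix,
    blacklist: Sequence[GenomicInterval],
) -> tuple[CountMatrix, int]:
    """Drop rows overlapping any blacklist interval by >= 1 bp.

    Returns the filtered matrix and the number of rows removed.
    """
    if not blacklist:
        return obj, 0
    keep = np.ones(obj.n_rows, dtype=bool)
    for bl in blacklist:
        hit = (obj.chroms == bl.chrom) & (obj.starts < bl.end) & (obj.ends > bl.start)
        keep &= ~hit
    n_removed = int((~keep).sum())
    filtered = obj.subset_rows(keep)
    if not np.any(~filtered.is_spike):
        warnings.warn("blacklist removed every host window")
    return filtered, n_removed
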