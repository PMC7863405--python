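"""Readers and writers for the interval and fragment formats used throughout.

All coordinates in this package are 0-based half-open ``[start, end)``.  The
single place where 1-based arithmetic is allowed is :func:`to_one_based` /
:func:`from_one_based`.

Supported formats: UCSC two-column chrom.sizes, BED3 fragments (extra columns
ignored), chromHMM dense-segmentation BED (state label in column 4), bedGraph
and TSV for scored intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence


class GenomicIOError(ValueError):
    """Raised for malformed genomic files or invariant violations."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise GenomicIOError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise GenomicIOError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class FragmentRecord:
    """A sequenced fragment assigned to a sample."""

    interval: GenomicInterval
    sample_id: str


@dataclass(frozen=True)
class SegmentationRecord:
    """One chromHMM-style segmentation interval with its state label."""

    interval: GenomicInterval
    sample_id: str
    state_label: str


@dataclass
class ChromSizes:
    """Contig name -> length, with a subset flagged as spike-in contigs."""

    sizes: dict[str, int]
    spike_contigs: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name, length in self.sizes.items():
            if length <= 0:
                raise GenomicIOError(f"contig {name!r} has non-positive length {length}")
        missing = set(self.spike_contigs) - set(self.sizes)
        if missing:
            raise GenomicIOError(
                f"spike contig(s) absent from chrom.sizes: {sorted(missing)}"
            )
        self.spike_contigs = frozenset(self.spike_contigs)

    @property
    def host_contigs(self) -> list[str]:
        return [c for c in self.sizes if c not in self.spike_contigs]

    def __contains__(self, contig: str) -> bool:
        return contig in self.sizes

    def __getitem__(self, contig: str) -> int:
        return self.sizes[contig]


def to_one_based(interval: GenomicInterval) -> tuple[str, int, int]:
    """Convert to 1-based fully-closed coordinates (e.g. for display)."""
    return interval.chrom, interval.start + 1, interval.end


def from_one_based(chrom: str, start1: int, end1: int) -> GenomicInterval:
    """Build an interval from 1-based fully-closed coordinates."""
    return GenomicInterval(chrom, start1 - 1, end1)


def read_chrom_sizes(path: str | Path, spike_names: Sequence[str] = ()) -> ChromSizes:
    """Parse a UCSC two-column chrom.sizes file.

    Parameters
    ----------
    path
        Whitespace-delimited file of ``name  length`` rows.
    spike_names
        Contig names to flag as spike-in controls; each must be present.
    """
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise GenomicIOError(f"{path}:{lineno}: expected 'name length', got {line!r}")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise GenomicIOError(f"{path}:{lineno}: length not an integer: {parts[1]!r}") from exc
            if length <= 0:
                raise GenomicIOError(f"{path}:{lineno}: non-positive length {length} for {name!r}")
            if name in sizes:
                raise GenomicIOError(f"{path}:{lineno}: duplicate contig {name!r}")
            sizes[name] = length
    return ChromSizes(sizes=sizes, spike_contigs=frozenset(spike_names))


def read_fragments(
    path: str | Path,
    chrom_sizes: ChromSizes,
    sample_id: str | None = None,
) -> Iterator[FragmentRecord]:
    """Stream FragmentRecords from a BED3+ file.

    Only the first three columns are interpreted; extra columns are ignored.
    Fragments on contigs absent from ``chrom_sizes`` are hard errors, as are
    empty/inverted intervals and intervals past the contig end.
    """
    sid = sample_id if sample_id is not None else Path(path).stem
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise GenomicIOError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise GenomicIOError(f"{path}:{lineno}: non-integer coordinates") from exc
            if chrom not in chrom_sizes:
                raise GenomicIOError(f"{path}:{lineno}: unknown contig {chrom!r}")
            if start >= end:
                raise GenomicIOError(f"{path}:{lineno}: start {start} >= end {end}")
            if start < 0 or end > chrom_sizes[chrom]:
                raise GenomicIOError(
                    f"{path}:{lineno}: interval [{start},{end}) outside contig "
                    f"{chrom!r} of length {chrom_sizes[chrom]}"
                )
            yield FragmentRecord(GenomicInterval(chrom, start, end), sid)


def read_segmentations(
    paths_by_sample: Mapping[str, str | Path],
) -> list[SegmentationRecord]:
    """Read chromHMM dense/segmentation BEDs, one file per sample.

    The 4th column carries the state label, preserved verbatim.  Within each
    sample, records on the same chromosome must not overlap.
    """
    records: list[SegmentationRecord] = []
    for sample_id, path in paths_by_sample.items():
        per_chrom: dict[str, list[GenomicInterval]] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 4:
                    raise GenomicIOError(
                        f"{path}:{lineno}: segmentation BED needs >=4 columns (state in col 4)"
                    )
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
                per_chrom.setdefault(iv.chrom, []).append(iv)
                records.append(SegmentationRecord(iv, sample_id, parts[3]))
        for chrom, ivs in per_chrom.items():
            ivs.sort(key=lambda i: i.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise GenomicIOError(
                        f"sample {sample_id!r}: overlapping segmentation records "
                        f"{chrom}:{a.start}-{a.end} and {chrom}:{b.start}-{b.end}"
                    )
    return records


_FORMATS = ("BED", "bedGraph", "TSV")


def write_scored_intervals(
    intervals_with_scores: Iterable[tuple[GenomicInterval, float]],
    path: str | Path,
    format: str = "TSV",
) -> None:
    """Write ``(interval, score)`` pairs in BED, bedGraph, or TSV form.

    bedGraph requires sorted, non-overlapping, finite-scored intervals; TSV
    writes a header and accepts NaN.  Scores round-trip to 6 significant
    digits via the matching :func:`read_scored_intervals`.
    """
    if format not in _FORMATS:
        raise GenomicIOError(f"unknown format {format!r}; expected one of {_FORMATS}")
    items = list(intervals_with_scores)
    if format == "bedGraph":
        for _, score in items:
            if not math.isfinite(score):
                raise GenomicIOError("bedGraph scores must be finite")
        ordered = sorted(items, key=lambda t: (t[0].chrom, t[0].start, t[0].end))
        for (a, _), (b, _) in zip(ordered, ordered[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise GenomicIOError(
                    f"overlapping bedGraph intervals {a.chrom}:{a.start}-{a.end} "
                    f"and {b.chrom}:{b.start}-{b.end}"
                )
        items = ordered
    with open(path, "w") as fh:
        if format == "TSV":
            fh.write("chrom\tstart\tend\tscore\n")
        for iv, score in items:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{score:.6g}\n")


def read_scored_intervals(
    path: str | Path, format: str = "TSV"
) -> list[tuple[GenomicInterval, float]]:
    """Inverse of :func:`write_scored_intervals`."""
    if format not in _FORMATS:
        raise GenomicIOError(f"unknown format {format!r}; expected one of {_FORMATS}")
    out: list[tuple[GenomicInterval, float]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if format == "TSV" and lines and lines[0].startswith("chrom\t"):
        lines = lines[1:]
    for line in lines:
        if not line:
            continue
        chrom, start, end, score = line.split("\t")[:4]
        out.append((GenomicInterval(chrom, int(start), int(end)), float(score)))
    return out


def read_blacklist(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3 blacklist file into intervals (no contig validation)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return out
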