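"""Chromatin-state super-state collapse, multi-sample consensus, region
annotation and state-composition summaries.

18-state Roadmap-style mnemonics are collapsed to 6 coarse "super states"
(the grouping ships as a data file, not code), a consensus label is called
wherever at least half the samples (configurable) agree and strictly
out-vote every other state, and differential regions are annotated by
majority-bp overlap with the consensus for donut-style composition tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import GenomicInterval, SegmentationRecord

SUPER_STATES = (
    "Promoter",
    "Enhancer",
    "Transcription",
    "Bivalent/Polycomb",
    "Heterochromatin",
    "Quiescent",
)

# Tie-break priority for region annotation (promoter-centric reporting).
STATE_PRIORITY = {name: i for i, name in enumerate(SUPER_STATES)}


@dataclass
class SuperStateMap:
    """Total mapping of 18 mnemonic labels onto the 6 super states."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        outputs = set(self.mapping.values())
        unknown = outputs - set(SUPER_STATES)
        if unknown:
            raise ValueError(f"mapped to unknown super state(s): {sorted(unknown)}")
        if outputs != set(SUPER_STATES):
            raise ValueError(
                f"map must cover all 6 super states; missing {set(SUPER_STATES) - outputs}"
            )

    def __getitem__(self, label: str) -> str:
        try:
            return self.mapping[label]
        except KeyError:
            raise KeyError(f"state label {label!r} is not in the super-state map") from None


def load_super_state_map(path: str | Path | None = None) -> SuperStateMap:
    """Load a two-column (mnemonic, super state) map; default ships with the
    package."""
    if path is None:
        ref = resources.files("spikewin.data").joinpath("superstates_18to6.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, super_state = line.split("\t")[:2]
        mapping[label] = super_state
    return SuperStateMap(mapping)


def collapse_states(
    segmentations: Sequence[SegmentationRecord], super_map: SuperStateMap
) -> list[SegmentationRecord]:
    """Replace labels via the map and merge adjacent same-label records."""
    by_sample: dict[str, list[SegmentationRecord]] = {}
    for rec in segmentations:
        collapsed = SegmentationRecord(rec.interval, rec.sample_id, super_map[rec.state_label])
        by_sample.setdefault(rec.sample_id, []).append(collapsed)
    out: list[SegmentationRecord] = []
    for sample_id, recs in by_sample.items():
        recs.sort(key=lambda r: (r.interval.chrom, r.interval.start))
        merged: list[SegmentationRecord] = []
        for rec in recs:
            if (
                merged
                and merged[-1].interval.chrom == rec.interval.chrom
                and merged[-1].interval.end == rec.interval.start
                and merged[-1].state_label == rec.state_label
            ):
                prev = merged.pop()
                merged.append(
                    SegmentationRecord(
                        GenomicInterval(prev.interval.chrom, prev.interval.start, rec.interval.end),
                        sample_id,
                        rec.state_label,
                    )
                )
            else:
                merged.append(rec)
        out.extend(merged)
    return out


@dataclass
class ConsensusSegmentation:
    """Disjoint intervals with a consensus super state (or None)."""

    intervals: list[GenomicInterval]
    states: list[str | None]
    support: list[float]  # fraction of samples agreeing
    n_samples: int
    min_fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "state": [s if s is not None else "." for s in self.states],
                "support": self.support,
            }
        )


def call_consensus(
    collapsed: Sequence[SegmentationRecord], min_fraction: float = 0.5
) -> ConsensusSegmentation:
    """Consensus super state per atomic interval.

    The genome is partitioned at the union of all samples' breakpoints; an
    atomic interval gets state S when ``ceil(min_fraction * n)`` or more
    samples label it S *and* S strictly out-votes every other state (a tie
    is no consensus).
    """
    if not collapsed:
        raise ValueError("no segmentation records")
    samples = sorted({r.sample_id for r in collapsed})
    n = len(samples)
    if n < 2:
        raise ValueError("consensus needs >= 2 samples")
    need = int(np.ceil(min_fraction * n))

    by_chrom: dict[str, list[SegmentationRecord]] = {}
    for rec in collapsed:
        by_chrom.setdefault(rec.interval.chrom, []).append(rec)

    intervals: list[GenomicInterval] = []
    states: list[str | None] = []
    support: list[float] = []
    for chrom in sorted(by_chrom):
        recs = by_chrom[chrom]
        points = sorted({r.interval.start for r in recs} | {r.interval.end for r in recs})
        starts = np.array(points[:-1])
        ends = np.array(points[1:])
        # vote per atomic interval
        votes: list[dict[str, int]] = [dict() for _ in range(len(starts))]
        for rec in recs:
            lo = np.searchsorted(starts, rec.interval.start)
            hi = np.searchsorted(starts, rec.interval.end)
            for i in range(lo, hi):
                votes[i][rec.state_label] = votes[i].get(rec.state_label, 0) + 1
        for i in range(len(starts)):
            if not votes[i]:
                continue
            best_state, best_count = max(
                votes[i].items(), key=lambda kv: (kv[1], -STATE_PRIORITY.get(kv[0], 99))
            )
            runner_up = max(
                (c for s, c in votes[i].items() if s != best_state), default=0
            )
            intervals.append(GenomicInterval(chrom, int(starts[i]), int(ends[i])))
            if best_count >= need and best_count > runner_up:
                states.append(best_state)
                support.append(best_count / n)
            else:
                states.append(None)
                support.append(best_count / n)
    return ConsensusSegmentation(
        intervals=intervals, states=states, support=support,
        n_samples=n, min_fraction=min_fraction,
    )


def annotate_regions(
    regions: Sequence[GenomicInterval], consensus: ConsensusSegmentation
) -> list[str]:
    """Assign each region the consensus super state with most bp overlap.

    Ties break by the fixed priority order; regions overlapping only
    no-consensus intervals are ``unassigned``.
    """
    out: list[str] = []
    for region in regions:
        bp: dict[str, int] = {}
        for iv, state in zip(consensus.intervals, consensus.states):
            if state is None:
                continue
            o = region.overlap_bp(iv)
            if o > 0:
                bp[state] = bp.get(state, 0) + o
        if not bp:
            out.append("unassigned")
        else:
            best = min(bp.items(), key=lambda kv: (-kv[1], STATE_PRIORITY[kv[0]]))
            out.append(best[0])
    return out


@dataclass
class StateComposition:
    """Counts and percentages per super state for up/down region sets."""

    table: pd.DataFrame  # columns: direction, state, count, percent
    n_unassigned: dict[str, int]


def state_composition(
    up_regions: Sequence[GenomicInterval],
    down_regions: Sequence[GenomicInterval],
    consensus: ConsensusSegmentation,
) -> StateComposition:
    """Donut-style composition of trended region sets by super state.

    Percentages are over assigned regions only; unassigned counts are
    reported separately.
    """
    rows = []
    n_unassigned: dict[str, int] = {}
    for direction, regions in (("up", up_regions), ("down", down_regions)):
        labels = annotate_regions(regions, consensus)
        assigned = [s for s in labels if s != "unassigned"]
        n_unassigned[direction] = len(labels) - len(assigned)
        if not assigned:
            if regions:
                warnings.warn(f"all {direction}-regions are unassigned")
            else:
                warnings.warn(f"empty {direction}-region set")
            continue
        total = len(assigned)
        for state in SUPER_STATES:
            c = assigned.count(state)
            if c:
                rows.append(
                    {"direction": direction, "state": state, "count": c,
                     "percent": 100.0 * c / total}
                )
    return StateComposition(
        table=pd.DataFrame(rows, columns=["direction", "state", "count", "percent"]),
        n_unassigned=n_unassigned,
    )


def simulate_segmentations(
    chrom_lengths: Mapping[str, int],
    n_samples: int,
    labels_18: Sequence[str],
    segment_mean: int = 2_000,
    agreement: float = 0.8,
    seed: int = 0,
) -> list[SegmentationRecord]:
    """Synthetic 18-label segmentations with controllable agreement.

    A hidden "truth" segmentation is drawn per chromosome; each sample
    copies the truth label with probability ``agreement`` and otherwise
    draws a random label, emulating noisy per-patient chromHMM calls.
    """
    rng = np.random.default_rng(seed)
    labels = list(labels_18)
    out: list[SegmentationRecord] = []
    for chrom, length in chrom_lengths.items():
        # truth breakpoints: exponential segment lengths, min 200 bp
        pos = 0
        segments: list[tuple[int, int, str]] = []
        while pos < length:
            seg = int(max(200, rng.exponential(segment_mean)))
            end = min(pos + seg, length)
            segments.append((pos, end, labels[int(rng.integers(len(labels)))]))
            pos = end
        for j in range(n_samples):
            sid = f"patient{j + 1}"
            for s, e, lab in segments:
                use = lab if rng.random() < agreement else labels[int(rng.integers(len(labels)))]
                out.append(SegmentationRecord(GenomicInterval(chrom, s, e), sid, use))
    return out
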