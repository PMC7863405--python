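import itertools

import numpy as np
import pytest

from spikewin.chromatin_states import (
    SUPER_STATES,
    annotate_regions,
    call_consensus,
    collapse_states,
    load_super_state_map,
    simulate_segmentations,
    state_composition,
)
from spikewin.genomic_io import GenomicInterval, SegmentationRecord


def seg(chrom, start, end, sample, label):
    return SegmentationRecord(GenomicInterval(chrom, start, end), sample, label)


@pytest.fixture(scope="module")
def default_map():
    return load_super_state_map()


class TestSuperStateMap:
    def test_default_map_is_total_18_to_6(self, default_map):
        assert len(default_map.mapping) == 18
        assert set(default_map.mapping.values()) == set(SUPER_STATES)

    def test_unmapped_label_raises_with_name(self, default_map):
        with pytest.raises(KeyError, match="Foo"):
            collapse_states([seg("chr1", 0, 100, "a", "Foo")], default_map)


class TestCollapse:
    def test_adjacent_same_superstate_merged(self, default_map):
        recs = [
            seg("chr1", 0, 200, "a", "TssA"),
            seg("chr1", 200, 400, "a", "TssFlnk"),
            seg("chr1", 400, 600, "a", "Quies"),
        ]
        out = collapse_states(recs, default_map)
        assert len(out) == 2
        assert out[0].interval == GenomicInterval("chr1", 0, 400)
        assert out[0].state_label == "Promoter"

    def test_18_labels_collapse_to_6(self, default_map):
        recs = [
            seg("chr1", i * 100, (i + 1) * 100, "a", lab)
            for i, lab in enumerate(default_map.mapping)
        ]
        out = collapse_states(recs, default_map)
        assert set(r.state_label for r in out) == set(SUPER_STATES)


class TestConsensus:
    def _cohort(self, n, n_agree, state="Promoter"):
        # non-agreeing samples scatter their votes over the other states
        others = [s for s in SUPER_STATES if s != state]
        recs = []
        for i in range(n):
            lab = state if i < n_agree else others[i % len(others)]
            recs.append(seg("chr1", 0, 1000, f"p{i}", lab))
        return recs

    def test_19_sample_threshold_arithmetic(self):
        """With 19 samples, ceil(0.5*19)=10 supporters make a consensus and
        9 do not."""
        cons10 = call_consensus(self._cohort(19, 10))
        assert cons10.states == ["Promoter"]
        assert cons10.support == [pytest.approx(10 / 19)]
        cons9 = call_consensus(self._cohort(19, 9))
        assert cons9.states == [None]

    def test_even_split_is_tie_no_consensus(self):
        recs = [
            seg("chr1", 0, 100, "a", "Promoter"),
            seg("chr1", 0, 100, "b", "Enhancer"),
        ]
        assert call_consensus(recs).states == [None]

    def test_breakpoint_partition(self):
        recs = [
            seg("chr1", 0, 300, "a", "Promoter"),
            seg("chr1", 0, 100, "b", "Promoter"),
            seg("chr1", 100, 300, "b", "Quiescent"),
        ]
        cons = call_consensus(recs)
        assert [(iv.start, iv.end) for iv in cons.intervals] == [(0, 100), (100, 300)]
        assert cons.states == ["Promoter", None]

    def test_permutation_invariance(self):
        recs = [
            seg("chr1", 0, 500, "a", "Promoter"),
            seg("chr1", 0, 500, "b", "Promoter"),
            seg("chr1", 0, 500, "c", "Enhancer"),
        ]
        base = call_consensus(recs)
        for perm in itertools.permutations(recs):
            other = call_consensus(list(perm))
            assert other.states == base.states
            assert other.support == base.support

    def test_min_fraction_monotonicity(self):
        recs = self._cohort(10, 6)
        lo = call_consensus(recs, min_fraction=0.5)
        hi = call_consensus(recs, min_fraction=0.8)
        for s_lo, s_hi in zip(lo.states, hi.states):
            if s_hi is not None:  # raising the bar never creates consensus
                assert s_lo is not None

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            call_consensus([])


class TestAnnotation:
    def _consensus(self):
        recs = []
        for sample in ("a", "b"):
            recs.append(seg("chr1", 0, 600, sample, "Promoter"))
            recs.append(seg("chr1", 600, 1000, sample, "Quiescent"))
        return call_consensus(recs)

    def test_majority_bp_rule(self):
        cons = self._consensus()
        # region [0,1000): 600 bp Promoter vs 400 bp Quiescent
        assert annotate_regions([GenomicInterval("chr1", 0, 1000)], cons) == ["Promoter"]

    def test_tie_breaks_by_priority(self):
        recs = []
        for sample in ("a", "b"):
            recs.append(seg("chr1", 0, 500, sample, "Enhancer"))
            recs.append(seg("chr1", 500, 1000, sample, "Promoter"))
        cons = call_consensus(recs)
        # exact 50/50 overlap -> Promoter wins by priority
        assert annotate_regions([GenomicInterval("chr1", 0, 1000)], cons) == ["Promoter"]

    def test_unassigned_over_no_consensus(self):
        recs = [
            seg("chr1", 0, 1000, "a", "Promoter"),
            seg("chr1", 0, 1000, "b", "Enhancer"),
        ]
        cons = call_consensus(recs)
        assert annotate_regions([GenomicInterval("chr1", 100, 200)], cons) == ["unassigned"]


class TestComposition:
    def test_percentage_arithmetic(self):
        recs = []
        for sample in ("a", "b"):
            recs.append(seg("chr1", 0, 3000, sample, "Promoter"))
            recs.append(seg("chr1", 3000, 4000, sample, "Enhancer"))
        cons = call_consensus(recs)
        up = [
            GenomicInterval("chr1", 0, 500),
            GenomicInterval("chr1", 1000, 1500),
            GenomicInterval("chr1", 2000, 2500),
            GenomicInterval("chr1", 3000, 3500),
        ]
        comp = state_composition(up, [], cons)
        table = comp.table.set_index("state")
        assert table.loc["Promoter", "percent"] == pytest.approx(75.0)
        assert table.loc["Enhancer", "percent"] == pytest.approx(25.0)
        assert table["percent"].sum() == pytest.approx(100.0)

    def test_empty_set_warns(self):
        recs = [seg("chr1", 0, 100, s, "Promoter") for s in ("a", "b")]
        cons = call_consensus(recs)
        with pytest.warns(UserWarning):
            comp = state_composition([], [], cons)
        assert comp.table.empty

    def test_collapse_consensus_annotate_hand_example(self, default_map):
        """Three samples, hand-computed consensus end to end."""
        raw = [
            # sample 1: promoter then transcription
            seg("chr1", 0, 400, "s1", "TssA"),
            seg("chr1", 400, 1000, "s1", "Tx"),
            # sample 2 agrees on a shifted grid
            seg("chr1", 0, 500, "s2", "TssFlnk"),
            seg("chr1", 500, 1000, "s2", "TxWk"),
            # sample 3 disagrees everywhere
            seg("chr1", 0, 1000, "s3", "Quies"),
        ]
        cons = call_consensus(collapse_states(raw, default_map))
        lookup = {
            (iv.start, iv.end): s for iv, s in zip(cons.intervals, cons.states)
        }
        # [0,400): Promoter 2/3; [400,500): split 1/1/1 -> none;
        # [500,1000): Transcription 2/3
        assert lookup[(0, 400)] == "Promoter"
        assert lookup[(400, 500)] is None
        assert lookup[(500, 1000)] == "Transcription"


class TestSimulatedSegmentations:
    def test_agreement_drives_consensus_coverage(self, default_map):
        labels = sorted(default_map.mapping)
        high = simulate_segmentations({"chr1": 50_000}, 10, labels, agreement=0.95, seed=0)
        low = simulate_segmentations({"chr1": 50_000}, 10, labels, agreement=0.2, seed=0)
        c_high = call_consensus(collapse_states(high, default_map))
        c_low = call_consensus(collapse_states(low, default_map))
        frac = lambda c: np.mean([s is not None for s in c.states])
        assert frac(c_high) > frac(c_low)
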