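"""Alignment ingest: parsing, event collapsing, depth profiles, contig selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import naive_depth
from pcrbias.ingest import (
    MODE_GE10KB,
    MODE_GE2KB,
    MODE_NOT_ESTIMABLE,
    AlignmentParseError,
    ReadPairAlignment,
    collapse_events,
    depth_profile,
    depth_profile_from_pairs,
    gc_fraction,
    mate_intervals,
    pairs_from_truth,
    parse_alignments,
    parse_sam,
    select_bias_contigs,
)


def make_pair(contig="c1", start=0, insert_len=300, read_len=100):
    return ReadPairAlignment(
        contig_id=contig,
        start=start,
        insert_len=insert_len,
        mate_starts=(start, start + insert_len - read_len),
        read_len=read_len,
    )


SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:c1\tLN:1000\n"


def write_sam(tmp_path, records, name="mini.sam"):
    path = tmp_path / name
    path.write_text(SAM_HEADER + "".join(records))
    return path


def sam_record(qname, flag, pos, tlen, seq="A" * 50, mate_pos=None):
    mate_pos = pos if mate_pos is None else mate_pos
    return (
        f"{qname}\t{flag}\tc1\t{pos}\t60\t{len(seq)}M\t=\t{mate_pos}\t{tlen}\t"
        f"{seq}\t{'I' * len(seq)}\n"
    )


class TestParseSam:
    def test_pos_and_tlen_convention(self, tmp_path):
        # leftmost mate POS=101 (1-based), TLEN=350 -> start=100, insert 350
        path = write_sam(
            tmp_path,
            [
                sam_record("p1", 99, 101, 350, mate_pos=401),
                sam_record("p1", 147, 401, -350, mate_pos=101),
            ],
        )
        pairs, dropped = parse_sam(path, {"c1": 1000})
        assert len(pairs) == 1
        assert pairs[0].start == 100
        assert pairs[0].insert_len == 350
        assert pairs[0].mate_starts == (100, 400)
        assert dropped.total == 0

    def test_secondary_alignment_excluded(self, tmp_path):
        path = write_sam(
            tmp_path,
            [
                sam_record("p1", 99, 101, 350, mate_pos=401),
                sam_record("p1", 147, 401, -350, mate_pos=101),
                sam_record("p2", 99 | 0x100, 201, 300, mate_pos=451),
            ],
        )
        pairs, dropped = parse_sam(path, {"c1": 1000})
        assert len(pairs) == 1
        assert dropped.secondary == 1

    def test_improper_pair_dropped(self, tmp_path):
        path = write_sam(tmp_path, [sam_record("p1", 97, 101, 350, mate_pos=401)])
        pairs, dropped = parse_sam(path, {"c1": 1000})
        assert pairs == []
        assert dropped.not_proper == 1

    def test_unknown_contig_fails(self, tmp_path):
        path = write_sam(tmp_path, [sam_record("p1", 99, 101, 350, mate_pos=401)])
        with pytest.raises(AlignmentParseError):
            parse_sam(path, {"other": 1000})

    def test_simulated_sam_roundtrip(self, tmp_path, small_library):
        from pcrbias.simulate import write_sam as sim_write_sam

        lib = small_library
        path = tmp_path / "sim.sam"
        sim_write_sam(lib.reads, lib.reference, lib.config, path)
        pairs, dropped = parse_alignments(path, lib.reference)
        assert dropped.total == 0
        got = sorted((p.contig_id, p.start, p.insert_len) for p in pairs)
        want = sorted(
            (r.contig_id, r.start, r.insert_len)
            for r in lib.reads.truth.itertuples(index=False)
        )
        assert got == want


class TestTruthIngest:
    def test_truth_tsv_conservation(self, tmp_path, small_library):
        from pcrbias.simulate import write_truth_tsv

        lib = small_library
        path = tmp_path / "truth.tsv"
        write_truth_tsv(lib.reads, path)
        pairs, dropped = parse_alignments(
            path, lib.reference, read_len=lib.config.read_len
        )
        assert len(pairs) == len(lib.reads.truth)
        assert dropped.total == 0

    def test_out_of_bounds_insert_rejected(self):
        import pandas as pd

        truth = pd.DataFrame(
            [("c1", 900, 300, 0)], columns=["contig_id", "start", "insert_len", "copy_id"]
        )
        with pytest.raises(AlignmentParseError):
            pairs_from_truth(truth, {"c1": 1000}, read_len=100)


class TestCollapseEvents:
    def test_grouping_multiplicities(self):
        refs = {"c1": "A" * 1000}
        pairs = [make_pair(start=100, insert_len=350)] * 3 + [
            make_pair(start=100, insert_len=300)
        ]
        events = collapse_events(pairs, refs)
        assert [(e.start, e.insert_len, e.multiplicity) for e in events] == [
            (100, 300, 1),
            (100, 350, 3),
        ]
        assert sum(e.multiplicity for e in events) == len(pairs)

    def test_gc_of_insert_span(self):
        refs = {"c1": "ATGC"}
        pairs = [make_pair(start=0, insert_len=4, read_len=2)]
        events = collapse_events(pairs, refs)
        assert events[0].gc == pytest.approx(0.5)

    def test_empty_pairs_empty_events(self):
        assert collapse_events([], {"c1": "ACGT"}) == []

    def test_collapse_idempotent_on_expanded_events(self):
        refs = {"c1": "ACGT" * 300}
        pairs = [
            make_pair(start=s, insert_len=l)
            for s, l in [(0, 300), (50, 400), (200, 250)]
        ]
        events = collapse_events(pairs, refs)
        expanded = [
            make_pair(start=e.start, insert_len=e.insert_len)
            for e in events
            for _ in range(e.multiplicity)
        ]
        assert collapse_events(expanded, refs) == events

    @given(
        st.lists(
            st.tuples(st.integers(0, 50), st.integers(200, 400)),
            min_size=1,
            max_size=60,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_multiplicity_conservation(self, coords):
        refs = {"c1": "ACGT" * 120}
        pairs = [make_pair(start=s, insert_len=l) for s, l in coords]
        events = collapse_events(pairs, refs)
        assert sum(e.multiplicity for e in events) == len(pairs)
        # gc agrees with direct character counting
        for e in events:
            span = refs["c1"][e.start : e.start + e.insert_len]
            assert e.gc == pytest.approx(
                sum(c in "GC" for c in span) / len(span)
            )


class TestDepthProfile:
    def test_single_read_depth(self):
        prof = depth_profile([(0, 5)], "c1", 10)
        assert prof.depth.tolist() == [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]

    def test_overlapping_reads_sum(self):
        prof = depth_profile([(0, 5), (3, 8)], "c1", 10)
        assert prof.depth[3] == 2 and prof.depth[4] == 2
        assert prof.depth.tolist() == [1, 1, 1, 2, 2, 1, 1, 1, 0, 0]

    def test_windowed_view_edge_exclusion(self):
        # constant depth 2 on a 1,000 bp contig: retained windows are the six
        # tiles in [200, 800), each with mean exactly 2
        intervals = [(s, s + 100) for s in range(0, 1000, 100)] * 2
        prof = depth_profile(intervals, "c1", 1000, window_size=100, edge_exclusion=200)
        win = prof.windowed()
        assert win.start.tolist() == [200, 300, 400, 500, 600, 700]
        assert (win.mean_depth == 2.0).all()

    def test_pair_depth_counts_both_mates(self):
        pairs = [make_pair(start=0, insert_len=300, read_len=100)]
        prof = depth_profile_from_pairs(pairs, "c1", 400)
        assert prof.depth[:100].sum() == 100  # forward mate
        assert prof.depth[200:300].sum() == 100  # reverse mate
        assert prof.depth[100:200].sum() == 0  # insert gap not counted
        ins = depth_profile(mate_intervals(pairs, span="insert"), "c1", 400)
        assert ins.depth[:300].min() == 1  # insert-span option fills the gap

    @given(
        st.lists(
            st.tuples(st.integers(0, 300), st.integers(10, 80)),
            min_size=0,
            max_size=80,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_depth_matches_naive_oracle(self, reads):
        intervals = [(s, s + l) for s, l in reads]
        prof = depth_profile(intervals, "c1", 400)
        assert np.array_equal(prof.depth, naive_depth(intervals, 400))


class TestSelectBiasContigs:
    def test_mode_a_when_big_contigs_total_50kb(self):
        lengths = {"a": 40_000, "b": 12_000, "c": 3_000}
        selected, mode = select_bias_contigs(lengths)
        assert mode == MODE_GE10KB
        assert sorted(selected) == ["a", "b"]

    def test_mode_b_when_big_contigs_below_50kb(self):
        lengths = {"a": 30_000, "b": 12_000, "c": 3_000}
        selected, mode = select_bias_contigs(lengths)
        assert mode == MODE_GE2KB
        assert sorted(selected) == ["a", "b", "c"]

    def test_not_estimable_when_all_below_2kb(self):
        selected, mode = select_bias_contigs({"a": 1500, "b": 900})
        assert selected == []
        assert mode == MODE_NOT_ESTIMABLE


def test_gc_fraction_direct():
    assert gc_fraction("ATGC") == 0.5
    assert gc_fraction("AAAA") == 0.0
    assert gc_fraction("gggg") == 1.0
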