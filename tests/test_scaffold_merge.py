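"""Scaffold end-overlap detection, chain building, and merge round trips."""

import numpy as np
import pytest

from numtkit import scaffold_merge, synthetic
from numtkit.scaffold_merge import build_join_chains, find_end_overlaps, merge_scaffolds
from numtkit.seqio import SeqRecord, reverse_complement


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture()
def overlapping_pair(rng):
    """A = X+O, B = O+Y with |O| = 2000 exact."""
    x, o, y = _random_seq(rng, 30000), _random_seq(rng, 2000), _random_seq(rng, 25000)
    return SeqRecord("A", x + o), SeqRecord("B", o + y)


class TestFindEndOverlaps:
    def test_exact_overlap_detected(self, overlapping_pair):
        a, b = overlapping_pair
        joins = find_end_overlaps([a, b])
        assert len(joins) == 1
        j = joins[0]
        assert (j.left_id, j.right_id, j.left_orient, j.right_orient) == ("A", "B", "+", "+")
        assert j.overlap_len == 2000
        assert j.identity == 1.0

    def test_1499_below_minimum_rejected(self, rng):
        x, o, y = _random_seq(rng, 30000), _random_seq(rng, 1499), _random_seq(rng, 25000)
        joins = find_end_overlaps([SeqRecord("A", x + o), SeqRecord("B", o + y)])
        assert joins == []
        # the same pair is accepted at exactly 1,500
        o2 = o + "A"
        joins = find_end_overlaps([SeqRecord("A", x + o2), SeqRecord("B", o2 + y)])
        assert len(joins) == 1 and joins[0].overlap_len == 1500

    def test_reverse_complemented_right_member(self, overlapping_pair):
        a, b = overlapping_pair
        b_rc = SeqRecord("B", reverse_complement(b.seq))
        (j,) = find_end_overlaps([a, b_rc])
        assert (j.left_orient, j.right_orient) == ("+", "-")
        assert j.overlap_len == 2000

    def test_candidates_restrict_search(self, rng):
        x, o, y = _random_seq(rng, 20000), _random_seq(rng, 2000), _random_seq(rng, 20000)
        recs = [SeqRecord("A", x + o), SeqRecord("B", o + y), SeqRecord("C", _random_seq(rng, 20000))]
        assert find_end_overlaps(recs, candidates=[("A", "C")]) == []
        assert len(find_end_overlaps(recs, candidates=[("A", "B")])) == 1

    def test_end_window_validation(self, overlapping_pair):
        with pytest.raises(ValueError):
            find_end_overlaps(list(overlapping_pair), min_len=1500, end_window=1000)

    def test_order_invariance(self, small_scaffolds):
        scaffolds, _ = small_scaffolds
        fwd = find_end_overlaps(scaffolds)
        rev = find_end_overlaps(scaffolds[::-1])
        key = lambda j: (j.left_id, j.right_id, j.overlap_len)  # noqa: E731
        assert [key(j) for j in fwd] == [key(j) for j in rev]


class TestChains:
    def test_no_joins_gives_singletons(self):
        cs = build_join_chains([], scaffold_ids=["a", "b"])
        assert [c.members for c in cs.chains] == [[("a", "+")], [("b", "+")]]

    def test_four_member_chain(self, rng):
        # chromosome cut into 4 fragments sharing known overlaps
        chrom = _random_seq(rng, 120000)
        cuts = [(30000, 4636), (60000, 2500), (90000, 4009)]
        starts = [0] + [c for c, _ in cuts]
        ends = [c + ov for c, ov in cuts] + [len(chrom)]
        frags = [SeqRecord(f"f{i + 1}", chrom[s:e]) for i, (s, e) in enumerate(zip(starts, ends))]
        joins = find_end_overlaps(frags)
        cs = build_join_chains(joins, [f.id for f in frags])
        assert len(cs.chains) == 1
        assert cs.chains[0].ids == ["f1", "f2", "f3", "f4"]
        merged, _ = merge_scaffolds(frags, cs)
        assert len(merged) == 1
        assert len(merged[0].seq) == sum(len(f.seq) for f in frags) - (4636 + 2500 + 4009)
        assert merged[0].seq == chrom

    def test_cycle_is_broken_at_smallest_overlap(self, rng):
        # three fragments arranged circularly: a-b, b-c, c-a
        seq = _random_seq(rng, 60000)
        ov = 2000
        a = SeqRecord("a", seq[0:22000])
        b = SeqRecord("b", seq[20000:42000])
        c = SeqRecord("c", seq[40000:] + seq[:ov])  # wraps back to a's start
        joins = find_end_overlaps([a, b, c])
        assert len(joins) == 3
        cs = build_join_chains(joins, ["a", "b", "c"])
        assert len(cs.cycles) == 1
        assert len(cs.chains) == 1 and len(cs.chains[0].members) == 3
        merged, _ = merge_scaffolds([a, b, c], cs)
        assert len(merged) == 1

    def test_conflicting_join_reported(self, rng):
        # b's prefix matches both a's suffix (3000) and c's suffix (2000)
        shared = _random_seq(rng, 3000)
        a = SeqRecord("a", _random_seq(rng, 20000) + shared)
        b = SeqRecord("b", shared + _random_seq(rng, 20000))
        c = SeqRecord("c", _random_seq(rng, 20000) + shared[:2000])
        joins = find_end_overlaps([a, b, c])
        cs = build_join_chains(joins, ["a", "b", "c"])
        assert cs.conflicts  # the 2000 bp join lost to the 3000 bp one
        chains = {tuple(ch.ids) for ch in cs.chains}
        assert ("a", "b") in chains


class TestMergeRoundTrip:
    def test_two_scaffold_length_conservation(self, rng):
        x, o, y = _random_seq(rng, 50000 - 2000), _random_seq(rng, 2000), _random_seq(rng, 28000)
        a, b = SeqRecord("a", x + o), SeqRecord("b", o + y)
        joins = find_end_overlaps([a, b])
        merged, report = merge_scaffolds([a, b], build_join_chains(joins, ["a", "b"]))
        assert len(merged[0].seq) == 50000 + 30000 - 2000
        row = report.iloc[0]
        assert row["overlap_len"] == 2000 and row["status"] == "merged"
        assert row["amplicon_start"] == row["junction_start"] - 2500
        assert row["amplicon_end"] == row["junction_end"] + 2500

    def test_synthetic_round_trip_recovers_chromosomes(self, small_truth, small_scaffolds):
        scaffolds, join_truth = small_scaffolds
        joins = find_end_overlaps(scaffolds)
        # detected joins equal the truth joins (same pairs, orientations, lengths)
        detected = set()
        for j in joins:
            detected.add((j.left_id, j.right_id, j.overlap_len, j.left_orient, j.right_orient))
            f = j.flipped()
            detected.add((f.left_id, f.right_id, f.overlap_len, f.left_orient, f.right_orient))
        for t in join_truth:
            assert (t.left_id, t.right_id, t.overlap_len, t.left_orient, t.right_orient) in detected
        merged, _ = merge_scaffolds(scaffolds, build_join_chains(joins, [s.id for s in scaffolds]))
        orig = {r.id: r.seq for r in small_truth.strain_a}
        assert len(merged) == len(orig)
        for m in merged:
            chrom = orig[m.id.split("_")[0]]
            assert m.seq == chrom or m.seq == reverse_complement(chrom)

    def test_low_identity_chain_aborts(self, rng):
        o = _random_seq(rng, 2000)
        o_bad = "".join("T" if c == "A" else "A" for c in o[:100]) + o[100:]
        a = SeqRecord("a", _random_seq(rng, 20000) + o)
        b = SeqRecord("b", o_bad + _random_seq(rng, 20000))
        joins = find_end_overlaps([a, b], min_identity=0.9)
        assert joins
        merged, report = merge_scaffolds([a, b], build_join_chains(joins), min_identity=0.999)
        assert {m.id for m in merged} == {"a", "b"}
        assert (report["status"] == "aborted").any()
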