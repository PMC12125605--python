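"""Read mapper: index contracts, brute-force agreement, coverage conservation."""

import numpy as np
import pytest

from _oracles import brute_force_map
from numtkit import mapcov
from numtkit.seqio import ReadSet, SeqRecord, reverse_complement


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestIndex:
    def test_lookup_positions(self):
        idx = mapcov.build_index([SeqRecord("r", "ACGTACGT")], k=4)
        assert idx.lookup("ACGT") == [("r", 1), ("r", 5)]
        assert idx.lookup("TTTT") == []

    def test_k_larger_than_reference_rejected(self):
        with pytest.raises(ValueError):
            mapcov.build_index([SeqRecord("r", "ACGT")], k=8)

    def test_revcomp_reference_mirrors_positions(self, rng):
        seq = _random_seq(rng, 200)
        k = 21
        fwd = mapcov.build_index([SeqRecord("r", seq)], k=k)
        rev = mapcov.build_index([SeqRecord("r", reverse_complement(seq))], k=k)
        kmer = seq[50 : 50 + k]
        (hit_f,) = fwd.lookup(kmer)
        (hit_r,) = rev.lookup(reverse_complement(kmer))
        assert hit_f[1] - 1 == len(seq) - (hit_r[1] - 1) - k


class TestMapReads:
    def test_unique_read_maps_once(self, rng):
        ref = _random_seq(rng, 5000)
        idx = mapcov.build_index([SeqRecord("r", ref)])
        reads = [SeqRecord("q", ref[1000:1150])]
        aln = mapcov.map_reads(reads, idx)
        assert len(aln) == 1
        a = aln[0]
        assert (a.ref_id, a.pos, a.strand, a.n_mismatch, a.n_best) == ("r", 1001, "+", 0, 1)

    def test_duplicated_region_gives_n_best_two(self, rng):
        core = _random_seq(rng, 1000)
        ref = _random_seq(rng, 2000) + core + _random_seq(rng, 2000) + core + _random_seq(rng, 500)
        idx = mapcov.build_index([SeqRecord("r", ref)])
        aln = mapcov.map_reads([SeqRecord("q", core[200:350])], idx)
        assert len(aln) == 2
        assert all(a.n_best == 2 for a in aln)
        assert {a.pos for a in aln} == {2201, 5201}
        oracle = brute_force_map(core[200:350], {"r": ref}, 2)
        assert {(a.ref_id, a.pos, a.strand, a.n_mismatch) for a in aln} == oracle

    def test_three_substitutions_unmapped(self, rng):
        ref = _random_seq(rng, 3000)
        read = list(ref[500:650])
        for p in (10, 70, 130):
            read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
        idx = mapcov.build_index([SeqRecord("r", ref)])
        aln = mapcov.map_reads([SeqRecord("q", "".join(read))], idx, max_mismatch=2)
        assert len(aln) == 0

    def test_agreement_with_exhaustive_scan(self, rng):
        refs = {
            "r1": _random_seq(rng, 12000),
            "r2": _random_seq(rng, 8000),
        }
        # embed a shared 600 bp segment so some reads multi-map
        refs["r2"] = refs["r2"][:4000] + refs["r1"][2000:2600] + refs["r2"][4600:]
        records = [SeqRecord(k, v) for k, v in refs.items()]
        idx = mapcov.build_index(records)
        reads = []
        for i in range(300):
            src = refs["r1"] if i % 2 == 0 else refs["r2"]
            start = int(rng.integers(0, len(src) - 150))
            s = list(src[start : start + 150])
            for _ in range(int(rng.integers(0, 3))):  # 0-2 substitutions
                p = int(rng.integers(0, 150))
                s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
            seq = "".join(s)
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            reads.append(SeqRecord(f"q{i}", seq))
        aln = mapcov.map_reads(reads, idx, max_mismatch=2)
        got: dict[str, set] = {r.id: set() for r in reads}
        for a in aln:
            got[a.read_id].add((a.ref_id, a.pos, a.strand, a.n_mismatch))
        for r in reads:
            assert got[r.id] == brute_force_map(r.seq, refs, 2), r.id

    def test_error_free_full_recovery(self, clean_truth, clean_reads):
        rs = clean_reads["A"]
        refs = list(clean_truth.strain_a) + [clean_truth.mito]
        idx = mapcov.build_index(refs)
        aln = mapcov.map_reads(rs, idx)
        assert aln.mapped_read_mask().all()
        # uniquely-mapped reads land exactly at their simulated origin
        uniq = aln.unique_only()
        origins = rs.truth["origin"][uniq.read_idx]
        starts = rs.truth["start"][uniq.read_idx]
        ref_names = [r.id for r in refs]
        origin_names = [rs.origins[i].split(":", 1)[1] for i in range(len(rs.origins))]
        expected_ref = np.array([ref_names.index(origin_names[o]) for o in origins])
        assert (uniq.ref_idx == expected_ref).all()
        assert (uniq.pos == starts).all()

    def test_random_one_policy_single_placement(self, rng):
        core = _random_seq(rng, 500)
        ref = core + _random_seq(rng, 1000) + core
        idx = mapcov.build_index([SeqRecord("r", ref)])
        reads = [SeqRecord("q", core[100:280])]
        aln = mapcov.map_reads(reads, idx, policy="random-one", seed=1)
        assert len(aln) == 1 and aln[0].n_best == 1


class TestSplitAndCoverage:
    def test_split_partition(self, rng):
        ref = _random_seq(rng, 4000)
        other = _random_seq(rng, 4000)
        idx = mapcov.build_index([SeqRecord("r", ref)])
        reads = [SeqRecord(f"m{i}", ref[i * 100 : i * 100 + 150]) for i in range(5)]
        reads += [SeqRecord(f"u{i}", other[i * 100 : i * 100 + 150]) for i in range(5)]
        aln = mapcov.map_reads(reads, idx)
        mapped, unmapped = mapcov.split_by_mapping(reads, aln)
        assert len(mapped) + len(unmapped) == 10
        assert {mapped[i].id for i in range(len(mapped))} == {f"m{i}" for i in range(5)}
        assert {unmapped[i].id for i in range(len(unmapped))} == {f"u{i}" for i in range(5)}

    def test_single_read_coverage_span(self, rng):
        ref = _random_seq(rng, 1000)
        idx = mapcov.build_index([SeqRecord("r", ref)])
        aln = mapcov.map_reads([SeqRecord("q", ref[200:350])], idx)
        track = mapcov.coverage(aln)["r"]
        assert track.depth.sum() == 150
        assert (track.depth[200:350] == 1).all()

    def test_depth_mass_conservation(self, small_reads, small_truth):
        rs = small_reads["A"].subset_by_indices(np.arange(0, 3000))
        idx = mapcov.build_index(list(small_truth.strain_a) + [small_truth.mito])
        aln = mapcov.map_reads(rs, idx)
        tracks = mapcov.coverage(aln, multi_policy="count-all")
        total = sum(int(t.depth.sum()) for t in tracks.values())
        assert total == len(aln) * rs.read_length


class TestKmerFilter:
    def test_partial_overlap_is_flagged(self, rng):
        mito = SeqRecord("m", _random_seq(rng, 2000))
        nuclear = _random_seq(rng, 2000)
        # read with a 40 bp mitochondrial suffix: no end-to-end mito placement
        hybrid = nuclear[200:310] + mito.seq[500:540]
        pure = nuclear[400:550]
        rs = ReadSet.from_records([SeqRecord("h", hybrid), SeqRecord("p", pure)])
        mask = mapcov.kmer_filter_reads(rs, mito, k=21)
        assert mask.tolist() == [True, False]

    def test_mito_reads_all_flagged(self, clean_truth, clean_reads):
        rs = clean_reads["A"]
        mask = mapcov.kmer_filter_reads(rs, clean_truth.mito, k=21)
        origin_names = [rs.origins[i] for i in range(len(rs.origins))]
        mito_origin = origin_names.index("A:mito")
        from_mito = rs.truth["origin"] == len(clean_truth.strain_a)  # mito is last replicon
        assert mask[from_mito].all()
        # reads from Numt interiors are flagged too, their flanks are not
        assert mito_origin >= 0
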