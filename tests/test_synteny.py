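"""Homolog pairing, synteny block calling, flattening, dot-plot seeds."""

import numpy as np
import pytest

from _oracles import collinear_runs_oracle
from numtkit import synteny
from numtkit.seqio import SeqRecord, reverse_complement
from numtkit.synteny import SyntenyBlock, call_blocks, dotplot_seeds, merge_flatten, pair_homologs


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _gene_set(rng, n, length=600, prefix="g"):
    return {f"{prefix}{i:03d}": _random_seq(rng, length) for i in range(n)}


class TestPairHomologs:
    def test_identical_sets_pair_one_to_one(self, rng):
        genes_a = _gene_set(rng, 12)
        genes_b = {f"B_{g}": s for g, s in genes_a.items()}
        pairs = pair_homologs(genes_a, genes_b)
        assert len(pairs) == 12
        assert all(p.reciprocal and p.gene_b == f"B_{p.gene_a}" for p in pairs)
        assert all(p.identity == 1.0 for p in pairs)

    def test_low_identity_unpaired(self, rng):
        genes_a = {"x": _random_seq(rng, 600)}
        genes_b = {"y": _random_seq(rng, 600)}  # unrelated, ~25% identity
        assert pair_homologs(genes_a, genes_b, min_identity=0.7) == []

    def test_duplicated_paralog_single_reciprocal_pair(self, rng):
        base = _random_seq(rng, 600)
        mutated = "C" + base[1:]  # 1 substitution away
        genes_a = {"a1": base, "a2": mutated}
        genes_b = {"b1": base}
        pairs = pair_homologs(genes_a, genes_b)
        recip = [p for p in pairs if p.reciprocal]
        assert len(recip) == 1 and recip[0].gene_a == "a1"

    def test_duplicate_gene_ids_rejected(self, rng):
        from numtkit.seqio import SeqRecord
        from numtkit.variants import GeneModel

        asm = [SeqRecord("r", _random_seq(rng, 1000))]
        models = [GeneModel("g1", "r", 1, 300, "+"), GeneModel("g1", "r", 301, 600, "+")]
        with pytest.raises(ValueError, match="duplicate"):
            synteny.extract_gene_sequences(asm, models)


def _pairs_from_partner(partner):
    return [synteny.HomologPair(a, b, 10, 1.0, True) for a, b in partner.items()]


class TestCallBlocks:
    @pytest.mark.parametrize("n,expected_blocks", [(30, 1), (29, 0)])
    def test_thirty_locus_boundary(self, n, expected_blocks):
        order_a = {"sa": [f"g{i}" for i in range(n)]}
        order_b = {"sb": [f"h{i}" for i in range(n)]}
        partner = {f"g{i}": f"h{i}" for i in range(n)}
        blocks = call_blocks(_pairs_from_partner(partner), order_a, order_b, min_run=30)
        assert len(blocks) == expected_blocks
        if blocks:
            assert blocks[0].n_loci == 30 and blocks[0].orientation == "+"

    def test_inverted_run(self):
        n = 35
        order_a = {"sa": [f"g{i}" for i in range(n)]}
        order_b = {"sb": [f"h{i}" for i in reversed(range(n))]}
        partner = {f"g{i}": f"h{i}" for i in range(n)}
        (block,) = call_blocks(_pairs_from_partner(partner), order_a, order_b, min_run=30)
        assert block.orientation == "-" and block.n_loci == 35

    def test_interruption_tolerance(self):
        n = 40
        order_a = {"sa": [f"g{i}" for i in range(n)]}
        order_b = {"sb": [f"h{i}" for i in range(n)]}
        partner = {f"g{i}": f"h{i}" for i in range(n) if i != 20}  # one unpaired gene
        strict = call_blocks(_pairs_from_partner(partner), order_a, order_b, min_run=30)
        assert strict == []  # 0-interrupt reading splits the run into 20 + 19
        tolerant = call_blocks(
            _pairs_from_partner(partner), order_a, order_b, min_run=30, max_interrupt=1
        )
        assert len(tolerant) == 1 and tolerant[0].n_loci == 39

    def test_agreement_with_exhaustive_run_scanner(self, rng):
        for trial in range(10):
            n = 200
            order_a = {"sa": [f"g{i}" for i in range(n)]}
            # order_b: shuffled segments of a, some inverted
            ids = list(range(n))
            segments = []
            i = 0
            while i < n:
                ln = int(rng.integers(5, 60))
                seg = ids[i : i + ln]
                if rng.random() < 0.5:
                    seg = seg[::-1]
                segments.append(seg)
                i += ln
            perm = [j for seg in rng.permutation(len(segments)) for j in segments[seg]]
            order_b = {"sb": [f"h{j}" for j in perm]}
            partner = {f"g{i}": f"h{i}" for i in range(n)}
            min_run = 10
            blocks = call_blocks(
                _pairs_from_partner(partner), order_a, order_b, min_run=min_run
            )
            got = {(b.a_start, b.a_end, b.orientation, b.n_loci) for b in blocks}
            want = collinear_runs_oracle(
                order_a["sa"], partner, order_b["sb"], min_run
            )
            assert got == want, f"trial {trial}"

    def test_self_synteny_covers_everything(self, small_truth):
        genes = synteny.extract_gene_sequences(small_truth.strain_a, small_truth.gene_models)
        order = {}
        for gm in sorted(small_truth.gene_models, key=lambda g: (g.ref_id, g.cds_start)):
            order.setdefault(gm.ref_id, []).append(gm.gene_id)
        partner = {g: g for g in genes}
        blocks = call_blocks(
            _pairs_from_partner(partner),
            order,
            order,
            small_truth.gene_models,
            small_truth.gene_models,
            min_run=10,
        )
        per_scaffold = {b.ref_a: b for b in blocks}
        for scaf, gene_ids in order.items():
            b = per_scaffold[scaf]
            assert b.orientation == "+"
            assert b.n_loci == len(gene_ids)


class TestMergeFlatten:
    def _blocks(self, ivs):
        return [
            SyntenyBlock("ra", s, e, "rb", s, e, "+", 30) for s, e in ivs
        ]

    def test_overlapping_intervals_union(self):
        flat = merge_flatten(self._blocks([(100, 200), (150, 300)]))
        assert flat["a"] == [("ra", 100, 300)]

    def test_disjoint_unchanged(self):
        flat = merge_flatten(self._blocks([(100, 200), (400, 500)]))
        assert flat["a"] == [("ra", 100, 200), ("ra", 400, 500)]

    def test_abutting_with_gap_tol(self):
        assert merge_flatten(self._blocks([(100, 200), (201, 300)]))["a"] == [("ra", 100, 300)]
        assert merge_flatten(self._blocks([(100, 200), (202, 300)]), gap_tol=1)["a"] == [
            ("ra", 100, 300)
        ]

    def test_idempotent_and_bounded(self, rng):
        ivs = sorted(
            (int(s), int(s + rng.integers(1, 500))) for s in rng.integers(1, 10_000, 40)
        )
        blocks = self._blocks(ivs)
        once = merge_flatten(blocks)
        again_blocks = [
            SyntenyBlock("ra", s, e, "rb", s, e, "+", 30) for _, s, e in once["a"]
        ]
        assert merge_flatten(again_blocks)["a"] == once["a"]
        total = sum(e - s + 1 for _, s, e in once["a"])
        assert total <= 10_500


class TestDotplotSeeds:
    def test_identity_gives_main_diagonal(self, rng):
        seq = _random_seq(rng, 5000)
        table = dotplot_seeds(seq, seq, min_seed=100)
        fwd = table[table["strand"] == "+"]
        assert len(fwd) == 1
        row = fwd.iloc[0]
        assert (row["a_start"], row["b_start"], row["length"]) == (1, 1, 5000)

    def test_revcomp_copy_is_antidiagonal(self, rng):
        seq = _random_seq(rng, 5000)
        table = dotplot_seeds(seq, reverse_complement(seq), min_seed=100)
        assert set(table["strand"]) == {"-"}
        row = table.iloc[0]
        assert (row["a_start"], row["b_start"], row["length"]) == (1, 1, 5000)

    def test_unrelated_sequences_share_nothing(self, rng):
        a, b = _random_seq(rng, 5000), _random_seq(rng, 5000)
        assert dotplot_seeds(a, b, min_seed=100).empty

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            dotplot_seeds("", "ACGT")
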