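"""Synteny blocks from runs of consecutive homologous loci, and dot-plot seeds.

Homologous gene pairs are reciprocal best hits under a k-mer-seeded scoring
(shared-seed count to nominate candidates, edit-distance identity to accept).
A synteny block is a maximal run of consecutive genes of one assembly whose
partners are consecutive in the other assembly in a constant direction; runs
of at least ``min_run`` loci (default 30) become blocks. Block projections
can be merged and flattened into non-overlapping interval tables per
assembly, and whole-sequence dot-plot seed tables list maximal exact shared
substrings on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from . import kmers
from .seqio import SeqRecord
from .variants import GeneModel

Interval = tuple[int, int]  # 1-based inclusive


@dataclass(frozen=True)
class HomologPair:
    gene_a: str
    gene_b: str
    score: int  # shared k-mer seed count
    identity: float
    reciprocal: bool


@dataclass(frozen=True)
class SyntenyBlock:
    ref_a: str
    a_start: int  # 1-based inclusive
    a_end: int
    ref_b: str
    b_start: int
    b_end: int
    orientation: str  # '+' collinear, '-' inverted
    n_loci: int


def extract_gene_sequences(
    assembly: list[SeqRecord], gene_models: list[GeneModel]
) -> dict[str, str]:
    """CDS sequences in coding orientation, keyed by gene id."""
    refs = {r.id: r for r in assembly}
    out: dict[str, str] = {}
    for gm in gene_models:
        if gm.gene_id in out:
            raise ValueError(f"duplicate gene id {gm.gene_id!r}")
        seq = refs[gm.ref_id].seq[gm.cds_start - 1 : gm.cds_end]
        if gm.strand == "-":
            seq = SeqRecord("_", seq).reverse_complement().seq
        out[gm.gene_id] = seq
    return out


def _best_hits(
    queries: dict[str, str], targets: dict[str, str], k: int, min_identity: float, min_cov: float
) -> dict[str, tuple[str, int, float]]:
    """query gene -> (best target gene, seed score, identity)."""
    t_ids = list(targets)
    code_arrays = {t: kmers.encode(targets[t]) for t in t_ids}
    all_codes, all_owner = [], []
    for ti, t in enumerate(t_ids):
        vals, valid = kmers.kmer_codes(code_arrays[t], k)
        v = vals[valid]
        all_codes.append(v)
        all_owner.append(np.full(v.size, ti, np.int32))
    if not all_codes:
        return {}
    codes = np.concatenate(all_codes)
    owner = np.concatenate(all_owner)
    order = np.argsort(codes, kind="stable")
    codes, owner = codes[order], owner[order]

    hits: dict[str, tuple[str, int, float]] = {}
    for q, qseq in queries.items():
        qvals, qvalid = kmers.kmer_codes(kmers.encode(qseq), k)
        qi, tj = kmers.match_hits(qvals, qvalid, codes, np.arange(codes.size))
        if qi.size == 0:
            continue
        counts = np.bincount(owner[tj], minlength=len(t_ids))
        # verify the top few seed-count candidates by edit distance
        top = np.argsort(-counts)[:3]
        best = None
        for ti in top:
            if counts[ti] == 0:
                continue
            t = t_ids[ti]
            tseq = targets[t]
            cov = min(len(qseq), len(tseq)) / max(len(qseq), len(tseq))
            if cov < min_cov:
                continue
            dist = edlib.align(qseq, tseq, mode="NW", task="distance")["editDistance"]
            ident = 1.0 - dist / max(len(qseq), len(tseq))
            if ident < min_identity:
                continue
            cand = (ident, int(counts[ti]), t)
            if best is None or cand > best:
                best = cand
        if best is not None:
            hits[q] = (best[2], best[1], best[0])
    return hits


def pair_homologs(
    genes_a: dict[str, str],
    genes_b: dict[str, str],
    min_identity: float = 0.7,
    min_cov: float = 0.5,
    k: int = 21,
) -> list[HomologPair]:
    """Reciprocal-best-hit homolog pairs between two gene sets.

    ``genes_a``/``genes_b`` map gene ids to CDS sequences (see
    :func:`extract_gene_sequences`). Pairs failing identity or coverage are
    discarded; only reciprocal best pairs are flagged ``reciprocal``.
    """
    ab = _best_hits(genes_a, genes_b, k, min_identity, min_cov)
    ba = _best_hits(genes_b, genes_a, k, min_identity, min_cov)
    pairs = []
    for ga, (gb, score, ident) in sorted(ab.items()):
        reciprocal = ba.get(gb, (None,))[0] == ga
        pairs.append(HomologPair(ga, gb, score, ident, reciprocal))
    return pairs


def call_blocks(
    pairs: list[HomologPair],
    order_a: dict[str, list[str]],
    order_b: dict[str, list[str]],
    models_a: list[GeneModel] | None = None,
    models_b: list[GeneModel] | None = None,
    min_run: int = 30,
    max_interrupt: int = 0,
) -> list[SyntenyBlock]:
    """Call synteny blocks from maximal constant-direction collinear runs.

    ``order_a``/``order_b`` give gene ids in genomic order per scaffold. Two
    consecutive paired loci of A are linked in direction d when their B
    partners sit on the same scaffold d steps apart (allowing up to
    ``max_interrupt`` interruptions per junction: unpaired A genes skipped or
    B ranks jumped, whichever is larger). Maximal link chains are computed
    independently for the two directions, so a locus at a direction flip may
    support one block of each orientation. Chains with >= ``min_run`` paired
    loci become blocks; block intervals span the first to last supporting
    locus (gene coordinates when models are provided, otherwise 1-based gene
    ranks).
    """
    partner = {p.gene_a: p.gene_b for p in pairs if p.reciprocal}
    b_pos: dict[str, tuple[str, int]] = {}
    for scaf, genes in order_b.items():
        for i, g in enumerate(genes):
            b_pos[g] = (scaf, i)
    coord_a = {gm.gene_id: gm for gm in models_a} if models_a else None
    coord_b = {gm.gene_id: gm for gm in models_b} if models_b else None

    blocks: list[SyntenyBlock] = []

    def flush(run: list[tuple[int, str, str, int]], scaf_a: str, direction: int):
        if len(run) < min_run:
            return
        scaf_b = b_pos[run[0][2]][0]
        if coord_a and coord_b:
            a_start = coord_a[run[0][1]].cds_start
            a_end = coord_a[run[-1][1]].cds_end
            bs = [coord_b[r[2]].cds_start for r in run]
            be = [coord_b[r[2]].cds_end for r in run]
            b_start, b_end = min(bs), max(be)
        else:
            a_start, a_end = run[0][0] + 1, run[-1][0] + 1
            ib = [r[3] + 1 for r in run]
            b_start, b_end = min(ib), max(ib)
        blocks.append(
            SyntenyBlock(
                ref_a=scaf_a,
                a_start=a_start,
                a_end=a_end,
                ref_b=scaf_b,
                b_start=b_start,
                b_end=b_end,
                orientation="+" if direction > 0 else "-",
                n_loci=len(run),
            )
        )

    for scaf_a, genes in order_a.items():
        # (a_rank, gene_a, gene_b, b_index) for paired loci, in A order
        loci = []
        for rank, g in enumerate(genes):
            gb = partner.get(g)
            if gb is not None and gb in b_pos:
                loci.append((rank, g, gb, b_pos[gb][1]))
        for direction in (1, -1):
            run: list[tuple[int, str, str, int]] = []
            for locus in loci:
                if run:
                    prev = run[-1]
                    a_gap = locus[0] - prev[0] - 1
                    b_step = direction * (locus[3] - prev[3])
                    same_scaf = b_pos[locus[2]][0] == b_pos[prev[2]][0]
                    if same_scaf and b_step >= 1 and max(a_gap, b_step - 1) <= max_interrupt:
                        run.append(locus)
                        continue
                    flush(run, scaf_a, direction)
                run = [locus]
            flush(run, scaf_a, direction)
    # a run qualifying in both directions (possible only when every junction
    # step is 0, which cannot happen) is not deduplicated; drop exact dupes
    seen = set()
    unique = []
    for b in blocks:
        key = (b.ref_a, b.a_start, b.a_end, b.ref_b, b.b_start, b.b_end, b.orientation)
        if key not in seen:
            seen.add(key)
            unique.append(b)
    unique.sort(key=lambda b: (b.ref_a, b.a_start, b.orientation))
    return unique


def merge_flatten(
    blocks: list[SyntenyBlock], gap_tol: int = 0
) -> dict[str, list[tuple[str, int, int]]]:
    """Union block projections per assembly into sorted non-overlapping tables.

    Intervals overlapping or separated by <= ``gap_tol`` are merged. Keys are
    'a' and 'b'; rows are (scaffold, start, end), 1-based inclusive.
    """
    out: dict[str, list[tuple[str, int, int]]] = {}
    for side in ("a", "b"):
        ivs = [
            ((b.ref_a, b.a_start, b.a_end) if side == "a" else (b.ref_b, b.b_start, b.b_end))
            for b in blocks
        ]
        ivs.sort()
        merged: list[list] = []
        for ref, s, e in ivs:
            if merged and merged[-1][0] == ref and s <= merged[-1][2] + gap_tol + 1:
                merged[-1][2] = max(merged[-1][2], e)
            else:
                merged.append([ref, s, e])
        out[side] = [tuple(m) for m in merged]
    return out


def dotplot_seeds(
    seq_a: SeqRecord | str,
    seq_b: SeqRecord | str,
    min_seed: int = 100,
    k: int = 21,
    chain_gap: int = 0,
) -> pd.DataFrame:
    """Maximal exact shared substrings >= min_seed, both strands.

    Returns a table with 1-based columns (a_start, b_start, length, strand);
    a positive ``chain_gap`` additionally chains same-diagonal seeds across
    short mismatch patches.
    """
    sa = seq_a.seq if isinstance(seq_a, SeqRecord) else seq_a
    sb = seq_b.seq if isinstance(seq_b, SeqRecord) else seq_b
    if not sa or not sb:
        raise ValueError("both sequences must be non-empty")
    segs = kmers.shared_segments(
        kmers.encode(sa), kmers.encode(sb), k=k, min_len=min_seed, gap_tol=chain_gap
    )
    rows = [
        {
            "a_start": s.a_start + 1,
            "b_start": s.b_start + 1,
            "length": s.length,
            "strand": s.strand,
            "identity": round(s.identity, 6),
        }
        for s in segs
    ]
    return pd.DataFrame(rows, columns=["a_start", "b_start", "length", "strand", "identity"])


def blocks_to_frame(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrA": b.ref_a,
                "startA": b.a_start,
                "endA": b.a_end,
                "chrB": b.ref_b,
                "startB": b.b_start,
                "endB": b.b_end,
                "orientation": b.orientation,
                "n_loci": b.n_loci,
            }
            for b in blocks
        ]
    )
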