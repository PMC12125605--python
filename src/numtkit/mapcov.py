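"""Seeded, gap-free short-read mapping and per-base coverage.

The mapper is deliberately minimal: exact k-mer seeds anchor candidate
placements, candidates are verified by substitution count (no indels), and
all placements tied at the minimal mismatch count are reported ("all-best").
Counting a multi-mapped read at every best placement is what makes nuclear
copies of mitochondrial DNA accumulate nuclear + mitochondrial depth, the
signature used by the Numt caller.

With seeds at ``max_mismatch + 1`` disjoint offsets, any end-to-end placement
with at most ``max_mismatch`` substitutions is guaranteed to be found provided
``read_length >= (max_mismatch + 1) * k`` (pigeonhole).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kmers
from .seqio import CoverageTrack, ReadSet, SeqRecord, as_readset

_VERIFY_CHUNK = 200_000


@dataclass(frozen=True)
class Alignment:
    """A gap-free placement of one read (pos is 1-based leftmost)."""

    read_id: str
    ref_id: str
    pos: int
    strand: str
    n_mismatch: int
    n_best: int
    read_len: int


class KmerIndex:
    """Exact k-mer -> position index over the forward strand of references."""

    def __init__(self, references: list[SeqRecord], k: int = 31):
        if not references:
            raise ValueError("empty reference collection")
        shortest = min(len(r.seq) for r in references)
        if k > shortest:
            raise ValueError(f"k={k} exceeds shortest reference ({shortest} bp)")
        self.k = k
        self.ref_ids = [r.id for r in references]
        self.ref_lengths = np.array([len(r.seq) for r in references], dtype=np.int64)
        # concatenate with k ambiguous separators so no valid k-mer spans refs
        sep = np.full(k, 4, dtype=np.uint8)
        parts = []
        offsets = []
        pos = 0
        for r in references:
            if parts:
                parts.append(sep)
                pos += k
            offsets.append(pos)
            enc = kmers.encode(r.seq)
            parts.append(enc)
            pos += enc.size
        self.codes = np.concatenate(parts)
        self.ref_offsets = np.array(offsets, dtype=np.int64)
        self.sorted_codes, self.sorted_pos = kmers.sorted_kmer_index(self.codes, k)

    def ref_of_global(self, gpos: np.ndarray) -> np.ndarray:
        """Reference index owning each global position."""
        return np.searchsorted(self.ref_offsets, gpos, "right") - 1

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """Occurrences of an exact k-mer as (ref_id, 1-based position) pairs."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer")
        code, valid = kmers.kmer_codes(kmers.encode(kmer), self.k)
        if not valid[0]:
            return []
        lo = np.searchsorted(self.sorted_codes, code[0], "left")
        hi = np.searchsorted(self.sorted_codes, code[0], "right")
        out = []
        for g in sorted(self.sorted_pos[lo:hi]):
            r = int(self.ref_of_global(np.array([g]))[0])
            out.append((self.ref_ids[r], int(g - self.ref_offsets[r]) + 1))
        return out


def build_index(references: list[SeqRecord], k: int = 31) -> KmerIndex:
    return KmerIndex(references, k)


class AlignmentSet:
    """Struct-of-arrays collection of alignments; iterates as :class:`Alignment`.

    Ordering is deterministic: sorted by (read index, strand, global start).
    """

    def __init__(
        self,
        reads: ReadSet,
        index: KmerIndex,
        read_idx: np.ndarray,
        gstart: np.ndarray,
        strand: np.ndarray,
        n_mismatch: np.ndarray,
        n_best: np.ndarray,
    ):
        self.reads = reads
        self.index = index
        self.read_idx = read_idx
        self.gstart = gstart
        self.strand = strand
        self.n_mismatch = n_mismatch
        self.n_best = n_best
        self.ref_idx = index.ref_of_global(gstart) if gstart.size else np.empty(0, np.int64)
        self.pos = self.gstart - index.ref_offsets[self.ref_idx] if gstart.size else gstart

    def __len__(self) -> int:
        return int(self.read_idx.size)

    def __getitem__(self, i: int) -> Alignment:
        return Alignment(
            read_id=self.reads.read_id(int(self.read_idx[i])),
            ref_id=self.index.ref_ids[int(self.ref_idx[i])],
            pos=int(self.pos[i]) + 1,
            strand="+" if self.strand[i] == 0 else "-",
            n_mismatch=int(self.n_mismatch[i]),
            n_best=int(self.n_best[i]),
            read_len=self.reads.read_length,
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def mapped_read_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.reads), bool)
        mask[self.read_idx] = True
        return mask

    def select(self, mask: np.ndarray) -> "AlignmentSet":
        return AlignmentSet(
            self.reads,
            self.index,
            self.read_idx[mask],
            self.gstart[mask],
            self.strand[mask],
            self.n_mismatch[mask],
            self.n_best[mask],
        )

    def unique_only(self) -> "AlignmentSet":
        return self.select(self.n_best == 1)

    def oriented_read_rows(self, aln_indices: np.ndarray) -> np.ndarray:
        """Read code rows in reference orientation for the given alignments."""
        rows = self.reads.matrix[self.read_idx[aln_indices]]
        rev = self.strand[aln_indices] == 1
        if rev.any():
            rows = rows.copy()
            rows[rev] = kmers._RC_CODE[rows[rev]][:, ::-1]
        return rows

    def mismatch_table(self, unique_only: bool = True) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(ref_idx, 0-based ref position, read base code) for every mismatch."""
        sel = np.flatnonzero(self.n_best == 1) if unique_only else np.arange(len(self))
        L = self.reads.read_length
        refs_out, pos_out, base_out = [], [], []
        for lo in range(0, sel.size, _VERIFY_CHUNK):
            chunk = sel[lo : lo + _VERIFY_CHUNK]
            if chunk.size == 0:
                continue
            rows = self.oriented_read_rows(chunk)
            gs = self.gstart[chunk]
            ref_win = self.index.codes[gs[:, None] + np.arange(L)]
            mm_r, mm_c = np.nonzero(ref_win != rows)
            refs_out.append(self.ref_idx[chunk][mm_r])
            pos_out.append(self.pos[chunk][mm_r] + mm_c)
            base_out.append(rows[mm_r, mm_c])
        if not refs_out:
            return (np.empty(0, np.int64),) * 2 + (np.empty(0, np.uint8),)
        return np.concatenate(refs_out), np.concatenate(pos_out), np.concatenate(base_out)


def _seed_offsets(read_len: int, k: int, max_mismatch: int) -> np.ndarray:
    n_seeds = max_mismatch + 1
    if read_len < k:
        return np.empty(0, np.int64)
    offs = np.unique(np.linspace(0, read_len - k, n_seeds).round().astype(np.int64))
    return offs


def map_reads(
    reads,
    index: KmerIndex,
    max_mismatch: int = 2,
    policy: str = "all-best",
    seed: int = 0,
) -> AlignmentSet:
    """Map reads to the index, reporting all equally-best gap-free placements.

    ``policy`` is "all-best" (every placement tied at the minimal mismatch
    count) or "random-one" (one best placement chosen with a seeded RNG).
    Reads with no placement at <= max_mismatch are unmapped.
    """
    if policy not in ("all-best", "random-one"):
        raise ValueError(f"unknown policy {policy!r}")
    rs = as_readset(reads)
    n_reads = len(rs)
    k = index.k
    L = rs.read_length
    empty = lambda: AlignmentSet(  # noqa: E731
        rs,
        index,
        np.empty(0, np.int64),
        np.empty(0, np.int64),
        np.empty(0, np.uint8),
        np.empty(0, np.uint8),
        np.empty(0, np.int64),
    )
    if n_reads == 0 or L < k:
        return empty()

    offs = _seed_offsets(L, k, max_mismatch)
    fwd = rs.matrix
    rev = kmers._RC_CODE[fwd][:, ::-1]

    cand_read, cand_strand, cand_start = [], [], []
    for strand, mat in ((0, fwd), (1, rev)):
        # packed seed codes at each offset for all reads at once
        for off in offs:
            window = mat[:, off : off + k]
            vals = np.zeros(n_reads, np.uint64)
            two = np.uint64(2)
            for j in range(k):
                vals = (vals << two) | window[:, j].astype(np.uint64)
            valid = (window < 4).all(axis=1)
            ri, gpos = kmers.match_hits(vals, valid, index.sorted_codes, index.sorted_pos)
            if ri.size == 0:
                continue
            start = gpos - off
            cand_read.append(ri)
            cand_strand.append(np.full(ri.size, strand, np.uint8))
            cand_start.append(start)
    if not cand_read:
        return empty()

    read_i = np.concatenate(cand_read)
    strand_i = np.concatenate(cand_strand)
    start_i = np.concatenate(cand_start)

    # bounds: the placement must lie inside a single reference
    ref_i = index.ref_of_global(np.maximum(start_i, 0))
    ok = (
        (start_i >= 0)
        & (start_i >= index.ref_offsets[ref_i])
        & (start_i + L <= index.ref_offsets[ref_i] + index.ref_lengths[ref_i])
    )
    read_i, strand_i, start_i = read_i[ok], strand_i[ok], start_i[ok]
    if read_i.size == 0:
        return empty()

    # dedupe (read, strand, start)
    key = ((read_i.astype(np.uint64) << np.uint64(1)) | strand_i) << np.uint64(40)
    key |= start_i.astype(np.uint64)
    key = np.unique(key)
    start_i = (key & np.uint64((1 << 40) - 1)).astype(np.int64)
    rs_bits = (key >> np.uint64(40)).astype(np.int64)
    strand_i = (rs_bits & 1).astype(np.uint8)
    read_i = rs_bits >> 1

    # verify by substitution count, chunked
    mism = np.empty(read_i.size, np.uint16)
    span = np.arange(L)
    for lo in range(0, read_i.size, _VERIFY_CHUNK):
        sl = slice(lo, lo + _VERIFY_CHUNK)
        ref_win = index.codes[start_i[sl][:, None] + span]
        reads_win = np.empty_like(ref_win)
        f = strand_i[sl] == 0
        reads_win[f] = fwd[read_i[sl][f]]
        reads_win[~f] = rev[read_i[sl][~f]]
        mism[sl] = (ref_win != reads_win).sum(axis=1)
    keep = mism <= max_mismatch
    read_i, strand_i, start_i, mism = read_i[keep], strand_i[keep], start_i[keep], mism[keep]
    if read_i.size == 0:
        return empty()

    best = np.full(n_reads, np.iinfo(np.uint16).max, np.uint16)
    np.minimum.at(best, read_i, mism)
    keep = mism == best[read_i]
    read_i, strand_i, start_i, mism = read_i[keep], strand_i[keep], start_i[keep], mism[keep]

    order = np.lexsort((start_i, strand_i, read_i))
    read_i, strand_i, start_i, mism = read_i[order], strand_i[order], start_i[order], mism[order]

    counts = np.bincount(read_i, minlength=n_reads)
    if policy == "random-one":
        rng = np.random.default_rng(seed)
        first = np.concatenate(([0], np.cumsum(counts)))[:-1]
        present = np.flatnonzero(counts)
        pick = first[present] + rng.integers(0, counts[present])
        read_i, strand_i, start_i, mism = (
            read_i[pick],
            strand_i[pick],
            start_i[pick],
            mism[pick],
        )
        n_best = np.ones(read_i.size, np.int64)
    else:
        n_best = counts[read_i]

    return AlignmentSet(
        rs,
        index,
        read_i.astype(np.int64),
        start_i.astype(np.int64),
        strand_i,
        mism.astype(np.uint8),
        n_best.astype(np.int64),
    )


def split_by_mapping(reads, alignments: AlignmentSet):
    """Partition reads into (mapped, unmapped) according to the alignments."""
    rs = as_readset(reads)
    mask = np.zeros(len(rs), bool)
    mask[alignments.read_idx] = True
    return rs.subset(mask), rs.subset(~mask)


def coverage(alignments: AlignmentSet, multi_policy: str = "count-all") -> dict[str, CoverageTrack]:
    """Per-base depth per reference; every alignment adds 1 over its span.

    Under "count-all" a read with n_best = m contributes at all m placements;
    under "unique" only reads with a single best placement contribute.
    """
    if multi_policy not in ("count-all", "unique"):
        raise ValueError(f"unknown multi_policy {multi_policy!r}")
    aln = alignments if multi_policy == "count-all" else alignments.unique_only()
    L = aln.reads.read_length
    tracks = {}
    for r, (ref_id, ref_len) in enumerate(zip(aln.index.ref_ids, aln.index.ref_lengths)):
        sel = aln.ref_idx == r
        diff = np.zeros(int(ref_len) + 1, np.int64)
        np.add.at(diff, aln.pos[sel], 1)
        np.add.at(diff, aln.pos[sel] + L, -1)
        tracks[ref_id] = CoverageTrack(ref_id, np.cumsum(diff[:-1]))
    return tracks


def genome_median_depth(tracks: dict[str, CoverageTrack]) -> float:
    """Median depth across all positions of all tracks."""
    return float(np.median(np.concatenate([t.depth for t in tracks.values()])))


def kmer_filter_reads(reads, reference: SeqRecord, k: int = 21) -> np.ndarray:
    """Boolean mask of reads sharing >= 1 exact k-mer with the reference.

    This is the sensitive, local-alignment-like criterion used to strip
    mitochondrial reads before the Numt gap scan: any read whose overlap with
    the reference spans at least k error-free bases is flagged, including
    reads that only partially overlap it and therefore have no end-to-end
    placement on it.
    """
    rs = as_readset(reads)
    if len(rs) == 0:
        return np.zeros(0, bool)
    ref_set = kmers.KmerSet.from_sequence(kmers.encode(reference.seq), k, both_strands=True)
    n, L = rs.matrix.shape
    if L < k:
        return np.zeros(n, bool)
    out = np.zeros(n, bool)
    chunk = max(1, 50_000_000 // (8 * max(1, L - k + 1)))
    two = np.uint64(2)
    for lo in range(0, n, chunk):
        mat = rs.matrix[lo : lo + chunk]
        m = mat.shape[0]
        nk = L - k + 1
        vals = np.zeros((m, nk), np.uint64)
        for j in range(k):
            vals = (vals << two) | mat[:, j : j + nk].astype(np.uint64)
        hit = ref_set.contains(vals.ravel()).reshape(m, nk)
        if (mat >= 4).any():
            bad = mat >= 4
            cs = np.concatenate([np.zeros((m, 1), np.int64), np.cumsum(bad, axis=1)], axis=1)
            hit &= (cs[:, k:] - cs[:, :-k]) == 0
        out[lo : lo + chunk] = hit.any(axis=1)
    return out


def write_alignment_tsv(alignments: AlignmentSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tref_id\tpos\tstrand\tn_mismatch\tn_best\n")
        for a in alignments:
            fh.write(f"{a.read_id}\t{a.ref_id}\t{a.pos}\t{a.strand}\t{a.n_mismatch}\t{a.n_best}\n")


def write_sam(alignments: AlignmentSet, path) -> None:
    """Minimal SAM export: mandatory 11 fields, unsorted, no quality."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for ref_id, ref_len in zip(alignments.index.ref_ids, alignments.index.ref_lengths):
            fh.write(f"@SQ\tSN:{ref_id}\tLN:{int(ref_len)}\n")
        L = alignments.reads.read_length
        for i, a in enumerate(alignments):
            flag = 16 if a.strand == "-" else 0
            row = alignments.oriented_read_rows(np.array([i]))[0]
            seq = kmers.decode(row)
            fh.write(
                f"{a.read_id}\t{flag}\t{a.ref_id}\t{a.pos}\t{0 if a.n_best > 1 else 60}\t"
                f"{L}M\t*\t0\t0\t{seq}\t*\n"
            )
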