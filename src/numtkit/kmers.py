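"""2-bit nucleotide encoding and exact k-mer matching primitives.

Everything downstream (the read mapper, overlap detection, homology
delineation, dot-plot seeding) is built on the same representation: A,C,G,T
are the codes 0..3, any ambiguous base is 4, and a k-mer (k <= 31) is packed
into a ``uint64``. Windows containing an ambiguous base are flagged invalid
and excluded from every index and query. Coordinates in this module are
0-based half-open; callers convert to 1-based inclusive at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASE_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    BASE_CODES[_b] = _i
_RC_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
_CODE_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

MAX_K = 31  # 2*31 = 62 bits in a uint64


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string as an array of 2-bit codes (N and friends -> 4)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return BASE_CODES[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _CODE_BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _RC_CODE[codes][::-1].copy()


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed k-mer codes at every start position, plus a validity mask.

    Positions whose window contains an ambiguous base are invalid; their
    packed value is meaningless and must be ignored by the caller.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in 1..{MAX_K}, got {k}")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    vals = np.zeros(n, np.uint64)
    two = np.uint64(2)
    for j in range(k):
        vals = (vals << two) | codes[j : j + n].astype(np.uint64)
    bad = codes >= 4
    if bad.any():
        cs = np.concatenate(([0], np.cumsum(bad)))
        valid = (cs[k:] - cs[:-k]) == 0
    else:
        valid = np.ones(n, bool)
    return vals, valid


class KmerSet:
    """Sorted set of packed k-mer codes supporting vectorised membership tests."""

    def __init__(self, codes: np.ndarray):
        self.codes = np.unique(codes)

    @classmethod
    def from_sequence(cls, seq_codes: np.ndarray, k: int, both_strands: bool = True) -> "KmerSet":
        vals, valid = kmer_codes(seq_codes, k)
        parts = [vals[valid]]
        if both_strands:
            rvals, rvalid = kmer_codes(revcomp_codes(seq_codes), k)
            parts.append(rvals[rvalid])
        return cls(np.concatenate(parts) if parts else np.empty(0, np.uint64))

    def contains(self, queries: np.ndarray) -> np.ndarray:
        if self.codes.size == 0:
            return np.zeros(queries.shape, bool)
        idx = np.minimum(np.searchsorted(self.codes, queries), self.codes.size - 1)
        return self.codes[idx] == queries


def match_hits(
    query_codes: np.ndarray,
    query_valid: np.ndarray,
    sorted_codes: np.ndarray,
    sorted_pos: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """All (query_position, target_position) pairs with equal k-mer codes.

    ``sorted_codes``/``sorted_pos`` describe the target: codes sorted
    ascending with their original positions carried alongside.
    """
    qi = np.flatnonzero(query_valid)
    if qi.size == 0 or sorted_codes.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    q = query_codes[qi]
    lo = np.searchsorted(sorted_codes, q, "left")
    hi = np.searchsorted(sorted_codes, q, "right")
    cnt = hi - lo
    sel = cnt > 0
    if not sel.any():
        return np.empty(0, np.int64), np.empty(0, np.int64)
    qi, lo, cnt = qi[sel], lo[sel], cnt[sel]
    total = int(cnt.sum())
    out_q = np.repeat(qi, cnt).astype(np.int64)
    grp_end = np.cumsum(cnt)
    within = np.arange(total, dtype=np.int64) - np.repeat(grp_end - cnt, cnt)
    out_t = sorted_pos[np.repeat(lo, cnt) + within].astype(np.int64)
    return out_q, out_t


def sorted_kmer_index(seq_codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(sorted codes, positions) for the valid k-mers of one sequence."""
    vals, valid = kmer_codes(seq_codes, k)
    pos = np.flatnonzero(valid)
    vals = vals[pos]
    order = np.argsort(vals, kind="stable")
    return vals[order], pos[order]


@dataclass(frozen=True)
class Segment:
    """A shared segment between two sequences (0-based half-open coordinates).

    ``strand`` is '+' when the match is forward/forward and '-' when the
    a-segment matches the reverse complement of the b-segment.
    """

    a_start: int
    b_start: int
    length: int
    strand: str
    n_mismatch: int

    @property
    def identity(self) -> float:
        return 1.0 - self.n_mismatch / self.length

    @property
    def a_end(self) -> int:
        return self.a_start + self.length

    @property
    def b_end(self) -> int:
        return self.b_start + self.length


def _forward_segments(
    a_codes: np.ndarray,
    b_codes: np.ndarray,
    k: int,
    min_len: int,
    gap_tol: int,
) -> list[tuple[int, int, int, int]]:
    """Maximal same-diagonal segments (a_start, b_start, length, n_mismatch)."""
    ka, va = kmer_codes(a_codes, k)
    skb, spb = sorted_kmer_index(b_codes, k)
    ai, bpos = match_hits(ka, va, skb, spb)
    if ai.size == 0:
        return []
    diag = ai - bpos
    order = np.lexsort((ai, diag))
    ai, bpos, diag = ai[order], bpos[order], diag[order]
    new = np.empty(ai.size, bool)
    new[0] = True
    new[1:] = (diag[1:] != diag[:-1]) | (ai[1:] != ai[:-1] + 1)
    starts = np.flatnonzero(new)
    ends = np.append(starts[1:] - 1, ai.size - 1)
    runs = [
        (int(ai[s]), int(bpos[s]), int(ai[e] - ai[s]) + k, int(diag[s]))
        for s, e in zip(starts, ends)
    ]
    # Chain same-diagonal runs separated by <= gap_tol unseeded bases (a run of
    # m consecutive mismatches hides exactly m bases from exact k-mer seeding).
    runs.sort(key=lambda r: (r[3], r[0]))
    merged: list[list[int]] = []
    for a0, b0, ln, dg in runs:
        if merged and merged[-1][3] == dg and 0 <= a0 - (merged[-1][0] + merged[-1][2]) <= gap_tol:
            merged[-1][2] = a0 + ln - merged[-1][0]
        else:
            merged.append([a0, b0, ln, dg])
    out = []
    for a0, b0, ln, _dg in merged:
        if ln < min_len:
            continue
        nm = int(np.count_nonzero(a_codes[a0 : a0 + ln] != b_codes[b0 : b0 + ln]))
        out.append((a0, b0, ln, nm))
    return out


def shared_segments(
    a_codes: np.ndarray,
    b_codes: np.ndarray,
    k: int = 21,
    min_len: int = 100,
    gap_tol: int = 0,
    both_strands: bool = True,
) -> list[Segment]:
    """Maximal (near-)exact shared segments between two encoded sequences.

    With ``gap_tol`` 0 the segments are maximal exact matches; a positive
    value chains same-diagonal exact seeds across short mismatch patches
    (no indels, no strand change), reporting the mismatch count of the span.
    """
    segs = [
        Segment(a0, b0, ln, "+", nm)
        for a0, b0, ln, nm in _forward_segments(a_codes, b_codes, k, min_len, gap_tol)
    ]
    if both_strands:
        rb = revcomp_codes(b_codes)
        nb = b_codes.size
        for a0, b0, ln, nm in _forward_segments(a_codes, rb, k, min_len, gap_tol):
            segs.append(Segment(a0, nb - b0 - ln, ln, "-", nm))
    segs.sort(key=lambda s: (s.a_start, s.b_start, s.strand))
    return segs
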