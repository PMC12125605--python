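"""Independent brute-force oracles used by the property tests.

Each oracle deliberately takes the naive path (exhaustive scan, full
enumeration) so that it shares no code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np

from numtkit import kmers
from numtkit.seqio import reverse_complement


def n50_l50_oracle(lengths: list[int]) -> tuple[int, int]:
    """N50/L50 by exhaustive definition checks.

    N50: the largest scaffold length L such that scaffolds of length >= L sum
    to at least half the assembly. L50: the smallest k such that the k largest
    scaffolds sum to at least half the assembly.
    """
    total = sum(lengths)
    half = total / 2
    n50 = None
    for L in sorted(set(lengths), reverse=True):
        if sum(x for x in lengths if x >= L) >= half:
            n50 = L
            break
    desc = sorted(lengths, reverse=True)
    l50 = None
    for k in range(1, len(desc) + 1):
        if sum(desc[:k]) >= half:
            l50 = k
            break
    assert n50 is not None and l50 is not None
    return n50, l50


def brute_force_map(read_seq: str, references: dict[str, str], max_mismatch: int):
    """Every best end-to-end placement of a read by exhaustive position scan.

    Returns a set of (ref_id, 1-based pos, strand, n_mismatch) tuples for all
    placements tied at the minimal mismatch count (empty set if unmapped).
    """
    L = len(read_seq)
    fwd = kmers.encode(read_seq)
    rev = kmers.encode(reverse_complement(read_seq))
    placements = []
    for rid, seq in references.items():
        codes = kmers.encode(seq)
        if codes.size < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, L)
        for strand, r in (("+", fwd), ("-", rev)):
            mism = (windows != r).sum(axis=1)
            for pos in np.flatnonzero(mism <= max_mismatch):
                placements.append((rid, int(pos) + 1, strand, int(mism[pos])))
    if not placements:
        return set()
    best = min(p[3] for p in placements)
    return {p for p in placements if p[3] == best}


def collinear_runs_oracle(
    order_a: list[str],
    partner: dict[str, str],
    order_b: list[str],
    min_run: int,
) -> set[tuple[int, int, str, int]]:
    """Maximal strict collinear runs by exhaustive extension from every start.

    Returns (a_start_rank, a_end_rank, orientation, n_loci) for maximal runs
    of consecutive A genes whose partners are consecutive in B in one
    direction, with no unpaired interruptions (1-based ranks).
    """
    b_rank = {g: i for i, g in enumerate(order_b)}

    def b_of(i):
        g = partner.get(order_a[i])
        return b_rank.get(g) if g is not None else None

    runs = []
    n = len(order_a)
    for i in range(n):
        if b_of(i) is None:
            continue
        for direction in (1, -1):
            j = i
            while j + 1 < n:
                cur, nxt = b_of(j), b_of(j + 1)
                if nxt is None or cur is None or nxt - cur != direction:
                    break
                j += 1
            length = j - i + 1
            if length >= min_run:
                runs.append((i, j, "+" if direction > 0 else "-", length))
    # keep maximal runs only (not contained in a longer run of same direction)
    maximal = set()
    for i, j, d, ln in runs:
        if not any(
            (oi <= i and j <= oj and (oi, oj) != (i, j) and od == d) for oi, oj, od, _ in runs
        ):
            maximal.add((i + 1, j + 1, d, ln))
    # a run of length >= 2 is found from every interior start; dedupe by span
    return maximal
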