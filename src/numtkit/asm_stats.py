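"""Assembly summary statistics and telomere-repeat scanning.

N50 follows the standard inclusive convention: scaffolds are sorted by
decreasing length and N50 is the length of the scaffold at which the running
sum first reaches half the total assembly size (L50 is how many scaffolds
that takes). GC content is computed over unambiguous bases only.

Telomere scanning counts non-overlapping occurrences of the telomeric motif
(and its reverse complement) in consecutive fixed-size windows; a scaffold
end is called telomeric when its terminal window holds at least ``threshold``
repeats. The terminal window for the right end is anchored at the right end
of the sequence, so the left/right calls are symmetric under reverse
complement even when the length is not a multiple of the window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .seqio import SeqRecord, reverse_complement

TELOMERE_MOTIF = "TTAGGGC"


@dataclass(frozen=True)
class AssemblyStats:
    n_scaffolds: int
    total_len: int
    largest: int
    n50: int
    l50: int
    gc_percent: float


def _gc_counts(seq: str) -> tuple[int, int]:
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    return gc, gc + at


def gc_content(records) -> float:
    """GC percentage over unambiguous bases (N excluded from the denominator)."""
    if isinstance(records, str):
        records = [SeqRecord("_", records)]
    elif isinstance(records, SeqRecord):
        records = [records]
    gc = unambig = 0
    for rec in records:
        g, u = _gc_counts(rec.seq)
        gc += g
        unambig += u
    if unambig == 0:
        raise ValueError("no unambiguous bases; GC content undefined")
    return 100.0 * gc / unambig


def assembly_stats(records: list[SeqRecord]) -> AssemblyStats:
    if not records:
        raise ValueError("empty scaffold collection")
    lengths = sorted((len(r.seq) for r in records), reverse=True)
    total = sum(lengths)
    half = total / 2
    cum = 0
    for i, length in enumerate(lengths):
        cum += length
        if cum >= half:
            return AssemblyStats(
                n_scaffolds=len(lengths),
                total_len=total,
                largest=lengths[0],
                n50=length,
                l50=i + 1,
                gc_percent=gc_content(records),
            )
    raise AssertionError("unreachable")


@dataclass
class TelomereProfile:
    scaffold_id: str
    window_counts: list[int]
    left_telomeric: bool
    right_telomeric: bool
    window: int = 10000
    motif: str = TELOMERE_MOTIF


def _count_nonoverlapping(seq: str, motif: str) -> list[int]:
    """Start positions of non-overlapping occurrences of one motif."""
    positions = []
    i = seq.find(motif)
    while i != -1:
        positions.append(i)
        i = seq.find(motif, i + len(motif))
    return positions


def telomere_scan(
    record: SeqRecord,
    motif: str = TELOMERE_MOTIF,
    window: int = 10000,
    threshold: int = 7,
) -> TelomereProfile:
    """Count telomeric repeats per window and call telomeric scaffold ends.

    Occurrences of the motif and of its reverse complement are counted
    non-overlapping (per strand) and summed. ``threshold`` repeats in the
    terminal window marks that end telomeric.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if window < len(motif):
        raise ValueError("window smaller than motif")
    seq = record.seq
    motifs = {motif, reverse_complement(motif)}
    starts: list[int] = []
    for m in motifs:
        starts.extend(_count_nonoverlapping(seq, m))
    n_windows = max(1, math.ceil(len(seq) / window))
    counts = [0] * n_windows
    for s in starts:
        counts[min(s // window, n_windows - 1)] += 1
    left = sum(1 for s in starts if s < window)
    right = sum(1 for s in starts if s >= max(0, len(seq) - window))
    return TelomereProfile(
        scaffold_id=record.id,
        window_counts=counts,
        left_telomeric=left >= threshold,
        right_telomeric=right >= threshold,
        window=window,
        motif=motif,
    )
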