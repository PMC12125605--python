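"""Numt discovery: nuclear segments of mitochondrial origin.

A Numt leaves three independent footprints when short reads from a strain
with a high-copy mitochondrial genome are analysed against its nuclear
assembly:

1. **Coverage anomaly** — mapping *all* reads (counting multi-mapped reads at
   every best placement) piles nuclear + mitochondrial depth onto the Numt,
   e.g. ~750x over a 60x genome when the mitochondrion sits at ~690x.
2. **Filtered-coverage gap** — removing every read of (even partial)
   mitochondrial identity before mapping leaves a near-zero-depth hole the
   size of the insertion.
3. **Direct homology** — the nuclear assembly itself contains a segment
   matching the mitochondrial genome.

``call_numts`` emits one call per homology segment annotated with the other
two evidence channels (>= 50% reciprocal interval overlap); anomaly-and-gap
intervals without homology are emitted as candidates. All reported
coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kmers, mapcov
from .seqio import CoverageTrack, SeqRecord

Interval = tuple[int, int]  # 1-based inclusive


@dataclass(frozen=True)
class HomologyHit:
    ref_id: str
    start: int  # 1-based inclusive, nuclear
    end: int
    mito_start: int  # 1-based inclusive, mitochondrial source
    mito_end: int
    strand: str
    identity: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class NumtCall:
    ref_id: str
    start: int  # 1-based inclusive
    end: int
    mito_start: int | None
    mito_end: int | None
    strand: str | None
    anomaly: bool
    gap: bool
    homology: bool
    mean_depth_all: float | None = None
    mean_depth_filtered: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _runs_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as 0-based half-open (start, end)."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    return [(int(changes[i]), int(changes[i + 1])) for i in range(0, changes.size, 2)]


def _background(track: CoverageTrack, background: float | None) -> float:
    bg = float(np.median(track.depth)) if background is None else float(background)
    if bg <= 0:
        raise ValueError(f"track {track.ref_id!r}: zero background depth, cannot scan")
    return bg


def find_coverage_anomalies(
    track: CoverageTrack,
    window: int = 500,
    ratio: float = 5.0,
    min_span: int = 400,
    background: float | None = None,
) -> list[Interval]:
    """Maximal runs of windows with mean depth >= ratio x background.

    ``background`` defaults to the median of this track; pass the genome-wide
    median when scanning per-scaffold tracks. Run boundaries are refined at
    base resolution to the half-threshold crossing (the plateau edges at half
    height), so a short spike inside one window is measured by its own extent,
    not the window's. Refined runs spanning < min_span bases are dropped;
    intervals are 1-based inclusive.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    bg = _background(track, background)
    depth = track.depth
    n = depth.size
    n_win = (n + window - 1) // window
    starts = np.arange(n_win) * window
    sums = np.add.reduceat(depth, starts)
    sizes = np.minimum(starts + window, n) - starts
    means = sums / sizes
    flagged = means >= ratio * bg
    half = ratio * bg / 2
    out: list[Interval] = []
    for w0, w1 in _runs_from_mask(flagged):
        lo = int(starts[w0])
        hi = int(min(n, starts[w1 - 1] + window))
        above = np.flatnonzero(depth[lo:hi] >= half)
        if above.size == 0:
            continue
        lo, hi = lo + int(above[0]), lo + int(above[-1]) + 1
        # the plateau may cross the flagged windows' edges: expand outward
        while lo > 0 and depth[lo - 1] >= half:
            lo -= 1
        while hi < n and depth[hi] >= half:
            hi += 1
        if hi - lo < min_span:
            continue
        if out and lo + 1 <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo + 1, hi))
    return out


def find_gaps(
    track: CoverageTrack,
    max_depth_frac: float = 0.1,
    min_gap: int = 300,
    background: float | None = None,
) -> list[Interval]:
    """Maximal runs with depth <= max_depth_frac x background, length >= min_gap."""
    if len(track) == 0:
        raise ValueError("empty track")
    bg = _background(track, background)
    mask = track.depth <= max_depth_frac * bg
    return [(lo + 1, hi) for lo, hi in _runs_from_mask(mask) if hi - lo >= min_gap]


def homology_delineation(
    nuclear_refs: list[SeqRecord],
    mito_ref: SeqRecord,
    min_len: int = 200,
    min_identity: float = 0.9,
    k: int = 21,
    chain_gap: int = 10,
) -> list[HomologyHit]:
    """Segments of the nuclear assembly matching the mitochondrial genome.

    Exact k-mer seeds are chained along gap-free diagonals (short mismatch
    patches up to ``chain_gap`` bases are tolerated), on both strands;
    overlapping nuclear projections are merged keeping the longer segment.
    """
    mito_codes = kmers.encode(mito_ref.seq)
    hits: list[HomologyHit] = []
    for rec in nuclear_refs:
        segs = kmers.shared_segments(
            kmers.encode(rec.seq),
            mito_codes,
            k=k,
            min_len=min_len,
            gap_tol=chain_gap,
            both_strands=True,
        )
        kept: list[kmers.Segment] = []
        for seg in sorted(segs, key=lambda s: -s.length):
            if seg.identity < min_identity:
                continue
            if any(not (seg.a_end <= other.a_start or seg.a_start >= other.a_end) for other in kept):
                continue
            kept.append(seg)
        for seg in sorted(kept, key=lambda s: s.a_start):
            hits.append(
                HomologyHit(
                    ref_id=rec.id,
                    start=seg.a_start + 1,
                    end=seg.a_end,
                    mito_start=seg.b_start + 1,
                    mito_end=seg.b_end,
                    strand=seg.strand,
                    identity=seg.identity,
                )
            )
    return hits


def _reciprocal_overlap(a: Interval, b: Interval) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0] + 1), inter / (b[1] - b[0] + 1))


def _intersect_lists(xs: list[Interval], ys: list[Interval]) -> list[Interval]:
    out = []
    for x in xs:
        for y in ys:
            lo, hi = max(x[0], y[0]), min(x[1], y[1])
            if lo <= hi:
                out.append((lo, hi))
    return out


def call_numts(
    anomalies: dict[str, list[Interval]],
    gaps: dict[str, list[Interval]],
    homology: list[HomologyHit],
    min_reciprocal: float = 0.5,
) -> list[NumtCall]:
    """Combine the three evidence channels into Numt calls.

    Every homology segment becomes a call, flagged with whether an anomaly
    and/or gap interval overlaps it reciprocally by >= ``min_reciprocal``.
    Anomaly-gap intersections not explained by any homology segment are
    emitted as homology-less candidate calls.
    """
    calls: list[NumtCall] = []
    for hit in homology:
        iv = (hit.start, hit.end)
        an = any(_reciprocal_overlap(iv, a) >= min_reciprocal for a in anomalies.get(hit.ref_id, []))
        gp = any(_reciprocal_overlap(iv, g) >= min_reciprocal for g in gaps.get(hit.ref_id, []))
        calls.append(
            NumtCall(
                ref_id=hit.ref_id,
                start=hit.start,
                end=hit.end,
                mito_start=hit.mito_start,
                mito_end=hit.mito_end,
                strand=hit.strand,
                anomaly=an,
                gap=gp,
                homology=True,
            )
        )
    hom_by_ref: dict[str, list[Interval]] = {}
    for hit in homology:
        hom_by_ref.setdefault(hit.ref_id, []).append((hit.start, hit.end))
    for ref_id in sorted(set(anomalies) | set(gaps)):
        for iv in _intersect_lists(anomalies.get(ref_id, []), gaps.get(ref_id, [])):
            if any(
                _reciprocal_overlap(iv, h) >= min_reciprocal for h in hom_by_ref.get(ref_id, [])
            ):
                continue
            calls.append(
                NumtCall(
                    ref_id=ref_id,
                    start=iv[0],
                    end=iv[1],
                    mito_start=None,
                    mito_end=None,
                    strand=None,
                    anomaly=True,
                    gap=True,
                    homology=False,
                )
            )
    calls.sort(key=lambda c: (c.ref_id, c.start))
    return calls


@dataclass
class NumtResult:
    calls: list[NumtCall]
    coverage_all: dict[str, CoverageTrack]
    coverage_filtered: dict[str, CoverageTrack]
    median_depth_all: float
    median_depth_filtered: float
    anomalies: dict[str, list[Interval]] = field(default_factory=dict)
    gaps: dict[str, list[Interval]] = field(default_factory=dict)
    homology: list[HomologyHit] = field(default_factory=list)


def detect_numts(
    assembly: list[SeqRecord],
    mito: SeqRecord,
    reads,
    *,
    index_k: int = 31,
    filter_k: int = 21,
    max_mismatch: int = 2,
    window: int = 500,
    ratio: float = 5.0,
    min_span: int = 400,
    max_depth_frac: float = 0.1,
    min_gap: int = 300,
    min_homology_len: int = 200,
    min_homology_identity: float = 0.9,
    min_reciprocal: float = 0.5,
) -> NumtResult:
    """Run the full Numt procedure against a nuclear assembly.

    Maps all reads to the assembly (all-best, count-all) for the anomaly
    channel; strips mitochondrial-identity reads by exact k-mer containment
    against the mitochondrial genome and remaps the remainder for the gap
    channel; delineates mito-to-nuclear homology; intersects the evidence.
    """
    index = mapcov.build_index(assembly, k=index_k)
    aln_all = mapcov.map_reads(reads, index, max_mismatch=max_mismatch, policy="all-best")
    cov_all = mapcov.coverage(aln_all, multi_policy="count-all")
    median_all = mapcov.genome_median_depth(cov_all)

    from .seqio import as_readset

    rs = as_readset(reads)
    mito_like = mapcov.kmer_filter_reads(rs, mito, k=filter_k)
    filtered = rs.subset(~mito_like)
    aln_filt = mapcov.map_reads(filtered, index, max_mismatch=max_mismatch, policy="all-best")
    cov_filt = mapcov.coverage(aln_filt, multi_policy="count-all")
    median_filt = mapcov.genome_median_depth(cov_filt)

    anomalies = {
        ref: find_coverage_anomalies(
            trk, window=window, ratio=ratio, min_span=min_span, background=median_all
        )
        for ref, trk in cov_all.items()
    }
    gaps = {
        ref: find_gaps(trk, max_depth_frac=max_depth_frac, min_gap=min_gap, background=median_filt)
        for ref, trk in cov_filt.items()
    }
    homology = homology_delineation(
        assembly, mito, min_len=min_homology_len, min_identity=min_homology_identity
    )
    calls = call_numts(anomalies, gaps, homology, min_reciprocal=min_reciprocal)
    for call in calls:
        call.mean_depth_all = cov_all[call.ref_id].mean(call.start, call.end)
        call.mean_depth_filtered = cov_filt[call.ref_id].mean(call.start, call.end)
    return NumtResult(
        calls=calls,
        coverage_all=cov_all,
        coverage_filtered=cov_filt,
        median_depth_all=median_all,
        median_depth_filtered=median_filt,
        anomalies=anomalies,
        gaps=gaps,
        homology=homology,
    )
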