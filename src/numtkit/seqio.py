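"""Sequence records and file formats used across the pipeline.

Formats: FASTA, 4-line FASTQ (qualities parsed but ignored downstream),
samtools-depth-style 3-column TSV, and BED for interval output. Internal
coordinates everywhere in the package are 0-based half-open; every
user-facing report is 1-based inclusive.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

from . import kmers

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """An input file violates its declared format (message names the line)."""


@dataclass
class SeqRecord:
    """A named nucleotide sequence over the alphabet {A,C,G,T,N}."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SeqRecord":
        return SeqRecord(self.id, reverse_complement(self.seq), self.description)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (raises on illegal characters)."""
    if not set(seq) <= VALID_BASES:
        bad = sorted(set(seq) - VALID_BASES)
        raise ValueError(f"illegal nucleotide character(s): {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file; wrapped lines are concatenated, case folded to upper.

    Record order is preserved. Duplicate ids, headerless sequence, and
    characters outside {A,C,G,T,N} raise :class:`FormatError` naming the line.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    cur_id = None
    cur_desc = ""
    chunks: list[str] = []

    def _flush():
        if cur_id is None:
            return
        records.append(SeqRecord(cur_id, "".join(chunks), cur_desc))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                parts = header.split(None, 1)
                cur_id = parts[0]
                cur_desc = parts[1] if len(parts) > 1 else ""
                if cur_id in seen:
                    raise FormatError(f"{path}:{lineno}: duplicate record id {cur_id!r}")
                seen.add(cur_id)
                chunks = []
            else:
                if cur_id is None:
                    raise FormatError(f"{path}:{lineno}: sequence before any FASTA header")
                seq = line.upper()
                if not set(seq) <= VALID_BASES:
                    bad = sorted(set(seq) - VALID_BASES)
                    raise FormatError(f"{path}:{lineno}: illegal character(s) {bad}")
                chunks.append(seq)
    _flush()
    return records


def write_fasta(records: Iterable[SeqRecord], path, line_width: int = 80) -> None:
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), line_width):
                fh.write(rec.seq[i : i + line_width] + "\n")


def read_fastq(path) -> list[SeqRecord]:
    """Read strict 4-line FASTQ records; quality strings are discarded."""
    records: list[SeqRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) % 4 != 0:
        # trailing blank lines are tolerated
        while lines and not lines[-1]:
            lines.pop()
        if len(lines) % 4 != 0:
            raise FormatError(f"{path}: truncated FASTQ (line count not a multiple of 4)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        lineno = i + 1
        if not head.startswith("@"):
            raise FormatError(f"{path}:{lineno}: FASTQ header must start with '@'")
        if not plus.startswith("+"):
            raise FormatError(f"{path}:{lineno + 2}: FASTQ separator must start with '+'")
        seq = seq.upper()
        if not set(seq) <= VALID_BASES:
            bad = sorted(set(seq) - VALID_BASES)
            raise FormatError(f"{path}:{lineno + 1}: illegal character(s) {bad}")
        if len(qual) != len(seq):
            raise FormatError(f"{path}:{lineno + 3}: quality length != sequence length")
        records.append(SeqRecord(head[1:].split()[0], seq))
    return records


def write_fastq(records: Iterable[SeqRecord], path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{quality_char * len(rec.seq)}\n")


# ---------------------------------------------------------------------------
# Coverage tracks and depth tables
# ---------------------------------------------------------------------------


@dataclass
class CoverageTrack:
    """Per-base read depth over one reference sequence.

    ``depth[i]`` is the depth at 1-based position ``i + 1``.
    """

    ref_id: str
    depth: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth)
        if self.depth.size and self.depth.min() < 0:
            raise ValueError("negative depth")

    def __len__(self) -> int:
        return int(self.depth.size)

    def depth_at(self, pos: int) -> int:
        """Depth at a 1-based position."""
        return int(self.depth[pos - 1])

    def mean(self, start: int | None = None, end: int | None = None) -> float:
        """Mean depth over the 1-based inclusive interval [start, end]."""
        s = 0 if start is None else start - 1
        e = self.depth.size if end is None else end
        return float(self.depth[s:e].mean())

    def median(self) -> float:
        return float(np.median(self.depth))


def read_depth_table(path, ref_lengths: dict[str, int] | None = None) -> list[CoverageTrack]:
    """Read a samtools-depth-style TSV (ref, 1-based pos, depth).

    Positions absent from the file get depth 0. Track length is taken from
    ``ref_lengths`` when given, otherwise from the largest position seen.
    Positions must be strictly increasing within each reference.
    """
    data: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
            ref, pos_s, depth_s = parts
            try:
                pos = int(pos_s)
                depth = int(depth_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric position or depth") from None
            if pos < 1:
                raise FormatError(f"{path}:{lineno}: position must be >= 1")
            if depth < 0:
                raise FormatError(f"{path}:{lineno}: negative depth")
            if ref not in data:
                data[ref] = []
                order.append(ref)
            elif data[ref] and pos <= data[ref][-1][0]:
                raise FormatError(f"{path}:{lineno}: positions not strictly increasing for {ref!r}")
            data[ref].append((pos, depth))
    tracks = []
    for ref in order:
        rows = data[ref]
        n = ref_lengths[ref] if ref_lengths else rows[-1][0]
        arr = np.zeros(n, dtype=np.int64)
        pos = np.array([r[0] for r in rows])
        arr[pos - 1] = [r[1] for r in rows]
        tracks.append(CoverageTrack(ref, arr))
    return tracks


def write_depth_table(tracks: Iterable[CoverageTrack], path, include_zero: bool = False) -> None:
    with open(path, "w") as fh:
        for track in tracks:
            depth = track.depth
            idx = np.arange(depth.size) if include_zero else np.flatnonzero(depth)
            for i in idx:
                fh.write(f"{track.ref_id}\t{i + 1}\t{int(depth[i])}\n")


def write_bed(intervals: Iterable[tuple], path) -> None:
    """Write (ref, start, end[, name...]) rows; start/end are 0-based half-open."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# ReadSet: a compact, sliceable collection of same-length reads
# ---------------------------------------------------------------------------


class ReadSet(Sequence):
    """A collection of equal-length reads stored as a 2-bit code matrix.

    Behaves as a sequence of :class:`SeqRecord` (records are materialised
    lazily); the mapper consumes the matrix directly. ``origins``/``origin_idx``
    and ``serial`` generate stable read ids of the form ``"{origin}:{serial}"``.
    Optional per-read simulation truth (source reference, 0-based start,
    strand) may ride along for tests.
    """

    def __init__(
        self,
        matrix: np.ndarray,
        origins: list[str],
        origin_idx: np.ndarray,
        serial: np.ndarray,
        truth: dict[str, np.ndarray] | None = None,
    ):
        self.matrix = matrix
        self.origins = origins
        self.origin_idx = origin_idx
        self.serial = serial
        self.truth = truth

    @classmethod
    def from_records(cls, records: Sequence[SeqRecord]) -> "ReadSet":
        if not records:
            return cls(np.empty((0, 0), np.uint8), [], np.empty(0, np.int32), np.empty(0, np.int64))
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            raise ValueError("ReadSet requires equal-length reads")
        mat = kmers.encode("".join(r.seq for r in records)).reshape(len(records), -1)
        origins = [r.id for r in records]
        return cls(
            mat,
            origins,
            np.arange(len(records), dtype=np.int32),
            np.full(len(records), -1, np.int64),
        )

    @property
    def read_length(self) -> int:
        return int(self.matrix.shape[1])

    def __len__(self) -> int:
        return int(self.matrix.shape[0])

    def read_id(self, i: int) -> str:
        s = int(self.serial[i])
        base = self.origins[int(self.origin_idx[i])]
        return base if s < 0 else f"{base}:{s}"

    def __getitem__(self, i):
        if isinstance(i, slice):
            idx = np.arange(len(self))[i]
            return self.subset_by_indices(idx)
        return SeqRecord(self.read_id(i), kmers.decode(self.matrix[i]))

    def subset(self, mask: np.ndarray) -> "ReadSet":
        return self.subset_by_indices(np.flatnonzero(mask))

    def subset_by_indices(self, idx: np.ndarray) -> "ReadSet":
        truth = None
        if self.truth is not None:
            truth = {k: v[idx] for k, v in self.truth.items()}
        return ReadSet(self.matrix[idx], self.origins, self.origin_idx[idx], self.serial[idx], truth)

    def to_records(self) -> list[SeqRecord]:
        return [self[i] for i in range(len(self))]


def as_readset(reads) -> ReadSet:
    """Coerce a ReadSet or an iterable of SeqRecord into a ReadSet."""
    if isinstance(reads, ReadSet):
        return reads
    return ReadSet.from_records(list(reads))


def ensure_dir(path) -> None:
    os.makedirs(path, exist_ok=True)
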