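"""Pileup SNV detection between strains and codon-level effect annotation.

Variants are substitutions supported by the stack of uniquely-mapped reads
covering a position: the most frequent non-reference base is emitted when its
frequency (alt reads / reads covering the position) reaches ``min_freq`` and
the position is covered by at least ``min_depth`` reads. Multi-mapped reads
are excluded so that high-copy mitochondrial paralogy (Numts) cannot
contaminate allele frequencies.

Coding effects are computed against single-exon CDS gene models with the
standard genetic code; minus-strand variants are complemented into coding
orientation. ``compare_strains`` reproduces the reciprocal design of a
two-strain comparison: variants are called in both directions and confirmed
when the reverse analysis finds the complementary substitution at the same
position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import kmers, mapcov
from .seqio import SeqRecord

STOP = "*"


@dataclass(frozen=True)
class GeneModel:
    """A single-exon CDS; coordinates 1-based inclusive, frame anchored at the
    CDS start (+) or CDS end (-)."""

    gene_id: str
    ref_id: str
    cds_start: int
    cds_end: int
    strand: str

    def __post_init__(self):
        if self.cds_end < self.cds_start:
            raise ValueError(f"{self.gene_id}: cds_end < cds_start")
        if (self.cds_end - self.cds_start + 1) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.cds_end - self.cds_start + 1


@dataclass(frozen=True)
class Variant:
    ref_id: str
    pos: int  # 1-based
    ref_base: str
    alt_base: str
    depth: int
    alt_count: int

    @property
    def frequency(self) -> float:
        """Alt-supporting reads as a percentage of reads covering the position."""
        return 100.0 * self.alt_count / self.depth


@dataclass(frozen=True)
class CodingEffect:
    gene_id: str
    codon_index: int  # 1-based residue number
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect_class: str  # synonymous | missense | nonsense


def translate_codon(codon: str) -> str:
    """Single-letter amino acid (stop = '*') under the standard genetic code."""
    return str(Seq(codon).translate())


def classify_codon_pair(ref_codon: str, alt_codon: str) -> tuple[str, str, str]:
    """(ref_aa, alt_aa, effect_class) for a codon substitution."""
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if alt_aa == ref_aa:
        klass = "synonymous"
    elif alt_aa == STOP and ref_aa != STOP:
        klass = "nonsense"
    else:
        klass = "missense"
    return ref_aa, alt_aa, klass


def pileup_variants(
    alignments: mapcov.AlignmentSet,
    references: list[SeqRecord] | None = None,
    min_depth: int = 10,
    min_freq: float = 0.5,
    exclude_multimapped: bool = True,
) -> list[Variant]:
    """Call substitution variants from a gap-free alignment pileup.

    ``min_freq`` is a fraction (0.5 = half the covering reads must support
    the alt base); reported :attr:`Variant.frequency` is a percentage.
    """
    depth_tracks = mapcov.coverage(
        alignments, multi_policy="unique" if exclude_multimapped else "count-all"
    )
    ref_i, pos, base = alignments.mismatch_table(unique_only=exclude_multimapped)
    if ref_i.size == 0:
        return []
    # aggregate counts per (ref, pos, base); base gets 3 bits (codes 0..4)
    key = (ref_i.astype(np.uint64) << np.uint64(43)) | (pos.astype(np.uint64) << np.uint64(3))
    key |= base.astype(np.uint64)
    ukey, counts = np.unique(key, return_counts=True)
    u_ref = (ukey >> np.uint64(43)).astype(np.int64)
    u_pos = ((ukey >> np.uint64(3)) & np.uint64((1 << 40) - 1)).astype(np.int64)
    u_base = (ukey & np.uint64(7)).astype(np.int64)

    index = alignments.index
    variants: list[Variant] = []
    # order guarantees: per (ref, pos) ascending, bases ascending
    i = 0
    n = ukey.size
    while i < n:
        j = i
        while j < n and u_ref[j] == u_ref[i] and u_pos[j] == u_pos[i]:
            j += 1
        ref_id = index.ref_ids[u_ref[i]]
        depth = int(depth_tracks[ref_id].depth[u_pos[i]])
        # best alt base: max count, ties to the lexicographically smaller base
        block = sorted(
            (t for t in range(i, j) if u_base[t] < 4),
            key=lambda t: (-counts[t], u_base[t]),
        )
        if not block:
            i = j
            continue
        btop = block[0]
        alt_count = int(counts[btop])
        if depth >= min_depth and alt_count / depth >= min_freq:
            gpos = index.ref_offsets[u_ref[i]] + u_pos[i]
            ref_base = kmers.decode(index.codes[gpos : gpos + 1])
            alt_base = "ACGT"[u_base[btop]]
            if alt_base != ref_base:
                variants.append(
                    Variant(
                        ref_id=ref_id,
                        pos=int(u_pos[i]) + 1,
                        ref_base=ref_base,
                        alt_base=alt_base,
                        depth=depth,
                        alt_count=alt_count,
                    )
                )
        i = j
    return variants


def _reference_map(references) -> dict[str, SeqRecord]:
    if isinstance(references, dict):
        return references
    if isinstance(references, SeqRecord):
        return {references.id: references}
    return {r.id: r for r in references}


def annotate_coding_effect(
    variant: Variant,
    gene_models: list[GeneModel],
    references,
) -> CodingEffect | None:
    """Coding effect of a variant, or None when it falls outside every CDS."""
    refs = _reference_map(references)
    seq = refs[variant.ref_id].seq
    for gm in gene_models:
        if gm.ref_id != variant.ref_id or not (gm.cds_start <= variant.pos <= gm.cds_end):
            continue
        if gm.strand == "+":
            offset = variant.pos - gm.cds_start
        else:
            offset = gm.cds_end - variant.pos
        codon_index = offset // 3  # 0-based
        within = offset % 3
        if gm.strand == "+":
            c0 = gm.cds_start - 1 + 3 * codon_index
            ref_codon = seq[c0 : c0 + 3]
            alt_codon = ref_codon[:within] + variant.alt_base + ref_codon[within + 1 :]
        else:
            c_end = gm.cds_end - 3 * codon_index  # 1-based end of codon on genome
            genome_codon = seq[c_end - 3 : c_end]
            ref_codon = str(Seq(genome_codon).reverse_complement())
            alt = str(Seq(variant.alt_base).complement())
            alt_codon = ref_codon[:within] + alt + ref_codon[within + 1 :]
        ref_aa, alt_aa, klass = classify_codon_pair(ref_codon, alt_codon)
        return CodingEffect(
            gene_id=gm.gene_id,
            codon_index=codon_index + 1,
            ref_codon=ref_codon,
            alt_codon=alt_codon,
            ref_aa=ref_aa,
            alt_aa=alt_aa,
            effect_class=klass,
        )
    return None


def variants_to_frame(
    variants: list[Variant],
    gene_models: list[GeneModel] | None = None,
    references=None,
) -> pd.DataFrame:
    rows = []
    for v in variants:
        row = {
            "ref_id": v.ref_id,
            "pos": v.pos,
            "ref_base": v.ref_base,
            "alt_base": v.alt_base,
            "depth": v.depth,
            "alt_count": v.alt_count,
            "frequency": round(v.frequency, 2),
        }
        if gene_models is not None and references is not None:
            eff = annotate_coding_effect(v, gene_models, references)
            if eff is None:
                row.update(effect_class="noncoding")
            else:
                row.update(
                    gene_id=eff.gene_id,
                    codon_index=eff.codon_index,
                    ref_codon=eff.ref_codon,
                    alt_codon=eff.alt_codon,
                    aa_change=f"{eff.ref_aa}{eff.codon_index}{eff.alt_aa}",
                    effect_class=eff.effect_class,
                )
        rows.append(row)
    return pd.DataFrame(rows)


def compare_strains(
    reads_a,
    assembly_b: list[SeqRecord],
    reads_b,
    assembly_a: list[SeqRecord],
    *,
    gene_models: list[GeneModel] | None = None,
    min_depth: int = 10,
    min_freq: float = 0.5,
    max_mismatch: int = 2,
    index_k: int = 31,
) -> pd.DataFrame:
    """Reciprocal variant calling between two strains.

    Forward direction: strain-B reads against assembly A (variants expressed
    in A coordinates). A forward variant is confirmed when the reverse
    direction (strain-A reads on assembly B) calls the complementary
    substitution at the homologous position (coordinate identity is assumed,
    valid when the assemblies differ only by substitutions). Reverse-only
    calls are appended unconfirmed.
    """
    idx_a = mapcov.build_index(assembly_a, k=index_k)
    idx_b = mapcov.build_index(assembly_b, k=index_k)
    fwd = pileup_variants(
        mapcov.map_reads(reads_b, idx_a, max_mismatch=max_mismatch),
        min_depth=min_depth,
        min_freq=min_freq,
    )
    rev = pileup_variants(
        mapcov.map_reads(reads_a, idx_b, max_mismatch=max_mismatch),
        min_depth=min_depth,
        min_freq=min_freq,
    )
    rev_by_pos = {(v.ref_id, v.pos): v for v in rev}
    frame = variants_to_frame(fwd, gene_models, assembly_a)
    confirmed = []
    for v in fwd:
        r = rev_by_pos.get((v.ref_id, v.pos))
        confirmed.append(
            r is not None and r.ref_base == v.alt_base and r.alt_base == v.ref_base
        )
    if not frame.empty:
        frame["confirmed"] = confirmed
        frame["direction"] = "forward"
    fwd_pos = {(v.ref_id, v.pos) for v in fwd}
    rev_only = [v for v in rev if (v.ref_id, v.pos) not in fwd_pos]
    if rev_only:
        extra = variants_to_frame(rev_only, gene_models, assembly_b)
        extra["confirmed"] = False
        extra["direction"] = "reverse_only"
        frame = pd.concat([frame, extra], ignore_index=True)
    return frame


# ---------------------------------------------------------------------------
# GFF3 gene-model IO (single-exon CDS features)
# ---------------------------------------------------------------------------


def write_gff3(gene_models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in gene_models:
            fh.write(
                f"{gm.ref_id}\tnumtkit\tCDS\t{gm.cds_start}\t{gm.cds_end}\t.\t"
                f"{gm.strand}\t0\tID={gm.gene_id}\n"
            )


def read_gff3(path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if parts[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            models.append(
                GeneModel(
                    gene_id=attrs.get("ID", f"cds{lineno}"),
                    ref_id=parts[0],
                    cds_start=int(parts[3]),
                    cds_end=int(parts[4]),
                    strand=parts[6],
                )
            )
    return models
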