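"""Synthetic two-strain genome, scaffold, and short-read simulator.

The generator emulates the statistical structure the analysis modules assume
for a small filamentous-fungus genome pair:

* a multi-chromosome nuclear genome at ~49% GC with telomeric TTAGGGC arrays
  at every chromosome end;
* a 27 kb mitochondrial replicon present at high copy number (expressed as a
  separate sequencing depth rather than repeated contigs);
* two nuclear insertions of mitochondrial DNA (Numts) of 10 kb and 500 bp,
  exact copies of configured mitochondrial intervals;
* single-exon toy gene models tiling ~40% of each chromosome;
* a second strain differing from the first by a configured substitution
  profile (161 SNVs: 125 non-coding, 36 coding of which 25 amino-acid
  changing including one nonsense), placed away from Numts, telomeres and
  scaffold-overlap windows so that every truth record is unambiguous;
* scaffold fragmentation with known suffix-prefix overlaps (>= 1,500 bp) and
  a configurable fraction of reverse-complemented fragments;
* uniform single-end reads with i.i.d. substitution errors.

Every product is deterministic given ``SimConfig.seed``; complete ground
truth (Numt intervals, SNV table, join table) accompanies the sequences.
The mitochondrial replicon is generated linear and reads are not wrapped
across the origin: circularity is irrelevant to the Numt logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kmers
from .seqio import ReadSet, SeqRecord
from .variants import GeneModel, Variant, annotate_coding_effect

TELOMERE_MOTIF = "TTAGGGC"

# codon rewrite templates: (reference codon, position within codon, alt base),
# all in coding orientation. The missense set mirrors commonly observed
# single-substitution amino-acid changes (Cys>Gly, Val>Ile, Gly>Ser, Pro>His,
# Leu>Pro, Asp>Gly, His>Arg, Thr>Ala, Ser>Pro); the nonsense template is the
# classic CGA>TGA arginine-to-stop.
_NONSENSE_TEMPLATE = ("CGA", 0, "T")
_MISSENSE_TEMPLATES = [
    ("TGC", 0, "G"),
    ("GTC", 0, "A"),
    ("GGT", 0, "A"),
    ("CCT", 1, "A"),
    ("CTG", 1, "C"),
    ("GAT", 1, "G"),
    ("CAC", 1, "G"),
    ("ACT", 0, "G"),
    ("TCC", 0, "C"),
]
_SYNONYMOUS_TEMPLATES = [
    ("CTG", 2, "A"),
    ("GGA", 2, "G"),
    ("CCG", 2, "A"),
    ("GTT", 2, "C"),
]


@dataclass(frozen=True)
class NumtSpec:
    """One implanted Numt: mito[start : start+length) inserted into a chromosome.

    ``target_pos`` is a 0-based offset into the chromosome core (before
    telomeres are appended); None means the midpoint.
    """

    mito_start: int
    length: int
    target_chrom: str
    target_pos: int | None = None
    strand: str = "+"


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 3
    chrom_lengths: tuple[int, ...] = (300_000, 200_000, 150_000)
    gc_target: float = 0.49
    telomere_copies: int = 12
    telomere_motif: str = TELOMERE_MOTIF
    mito_length: int = 27_000
    numt_specs: tuple[NumtSpec, ...] = (
        NumtSpec(1000, 10_000, "chr2", None, "+"),
        NumtSpec(15_000, 500, "chr3", None, "+"),
    )
    snv_total: int = 161
    snv_noncoding: int = 125
    snv_coding: int = 36
    snv_nonsynonymous: int = 25
    read_length: int = 150
    nuclear_depth: float = 60.0
    mito_depth: float = 690.0
    error_rate: float = 0.001
    overlap_lengths: tuple[int, ...] = (4636, 4009, 2000)
    revcomp_fraction: float = 0.25
    gene_length: int = 1200
    gene_spacing: int = 1800

    def __post_init__(self):
        if self.n_chromosomes != len(self.chrom_lengths):
            raise ValueError("n_chromosomes must match chrom_lengths")
        if any(l <= 0 for l in self.chrom_lengths) or self.mito_length <= 0:
            raise ValueError("lengths must be positive")
        if self.snv_noncoding + self.snv_coding != self.snv_total:
            raise ValueError("snv profile inconsistent: noncoding + coding != total")
        if self.snv_nonsynonymous > self.snv_coding:
            raise ValueError("snv profile inconsistent: nonsynonymous > coding")
        if not 0 <= self.gc_target <= 1 or not 0 <= self.revcomp_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        names = self.chrom_names()
        for spec in self.numt_specs:
            if spec.length > self.mito_length:
                raise ValueError("numt length exceeds mitochondrial genome")
            if not 0 <= spec.mito_start <= self.mito_length - spec.length:
                raise ValueError("numt mito interval out of range")
            if spec.target_chrom not in names:
                raise ValueError(f"numt target chromosome {spec.target_chrom!r} unknown")
            ci = names.index(spec.target_chrom)
            if spec.target_pos is not None and not 0 <= spec.target_pos <= self.chrom_lengths[ci]:
                raise ValueError("numt target position out of range")
        if self.gene_length % 3 != 0:
            raise ValueError("gene_length must be divisible by 3")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass(frozen=True)
class NumtTruth:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    mito_start: int  # 1-based inclusive
    mito_end: int
    strand: str


@dataclass(frozen=True)
class SnvTruth:
    chrom: str
    pos: int  # 1-based
    ref_base: str  # strain A base
    alt_base: str  # strain B base
    klass: str  # noncoding | synonymous | nonsynonymous
    effect: str  # noncoding | synonymous | missense | nonsense
    gene_id: str | None = None


@dataclass(frozen=True)
class JoinTruth:
    left_id: str
    right_id: str
    overlap_len: int
    left_orient: str  # '-' when the left fragment was emitted reverse-complemented
    right_orient: str


@dataclass
class GenomeTruth:
    config: SimConfig
    strain_a: list[SeqRecord]
    strain_b: list[SeqRecord]
    mito: SeqRecord
    gene_models: list[GeneModel]
    numt_truth: list[NumtTruth]
    snv_truth: list[SnvTruth]
    cut_plan: dict[str, list[tuple[int, int]]]  # chrom -> [(0-based cut pos, overlap)]
    join_truth: list[JoinTruth] = field(default_factory=list)


def _streams(config: SimConfig) -> list[np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(5)
    return [np.random.default_rng(c) for c in children]


def _sample_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _encode_str(s: str) -> np.ndarray:
    return kmers.encode(s).copy()


def _intersects(pos: int, zones: list[tuple[int, int]]) -> bool:
    return any(lo <= pos < hi for lo, hi in zones)


def _plan_cuts(
    config: SimConfig,
    chrom_lengths: dict[str, int],
    numts_by_chrom: dict[str, list[tuple[int, int]]],
) -> dict[str, list[tuple[int, int]]]:
    """Deterministic cut positions for fragmentation (0-based, cut between
    pos-1 and pos), shifted off any Numt so overlap windows stay unambiguous."""
    names = list(chrom_lengths)
    per_chrom: dict[str, list[int]] = {n: [] for n in names}
    for i, ov in enumerate(config.overlap_lengths):
        per_chrom[names[i % len(names)]].append(ov)
    plan: dict[str, list[tuple[int, int]]] = {}
    for name in names:
        ovs = per_chrom[name]
        L = chrom_lengths[name]
        cuts = []
        for j, ov in enumerate(ovs):
            cut = (L * (j + 1)) // (len(ovs) + 1)
            for ns, ne in numts_by_chrom.get(name, []):
                if ns - ov - 500 <= cut <= ne + 500:
                    cut = ne + ov + 500
            if not (ov + 1000 <= cut <= L - 1000):
                raise ValueError(f"cannot place a {ov} bp overlap cut on {name} (len {L})")
            cuts.append((cut, ov))
        plan[name] = sorted(cuts)
    return plan


def _layout_genes(
    config: SimConfig,
    chrom_lengths: dict[str, int],
    numts_by_chrom: dict[str, list[tuple[int, int]]],
) -> list[GeneModel]:
    models = []
    counter = 0
    tel = len(config.telomere_motif) * config.telomere_copies
    for name, L in chrom_lengths.items():
        zones = [(max(0, s - 150), e + 150) for s, e in numts_by_chrom.get(name, [])]
        pos = tel + 200
        strand = "+"
        while pos + config.gene_length + tel + 200 <= L:
            span = (pos, pos + config.gene_length)
            if not any(span[0] < hi and span[1] > lo for lo, hi in zones):
                counter += 1
                models.append(
                    GeneModel(
                        gene_id=f"{name}_g{counter:04d}",
                        ref_id=name,
                        cds_start=pos + 1,
                        cds_end=pos + config.gene_length,
                        strand=strand,
                    )
                )
                strand = "-" if strand == "+" else "+"
                pos += config.gene_length + config.gene_spacing
            else:
                pos += 300
    return models


_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def _write_codon(
    seq: np.ndarray, gm: GeneModel, codon_index0: int, ref_codon: str, within: int, alt: str
) -> tuple[int, str, str]:
    """Write a codon (coding orientation) into the genome; return the SNV as
    (0-based genome pos, strain-A base, strain-B base)."""
    codon_codes = _encode_str(ref_codon)
    alt_code = int(_encode_str(alt)[0])
    if gm.strand == "+":
        g0 = gm.cds_start - 1 + 3 * codon_index0
        seq[g0 : g0 + 3] = codon_codes
        gpos = g0 + within
        g_alt = alt_code
    else:
        g_end = gm.cds_end - 3 * codon_index0  # 1-based genome end of this codon
        seq[g_end - 3 : g_end] = _COMP_CODE[codon_codes][::-1]
        gpos = g_end - 1 - within
        g_alt = int(_COMP_CODE[alt_code])
    return gpos, "ACGT"[int(seq[gpos])], "ACGT"[g_alt]


def generate_genome(config: SimConfig) -> GenomeTruth:
    """Build the two-strain genome pair with full ground truth.

    Deterministic given ``config.seed``: the same configuration always yields
    byte-identical sequences and truth tables.
    """
    rng_genome, rng_snv = _streams(config)[:2]
    names = config.chrom_names()

    mito_codes = _sample_bases(rng_genome, config.mito_length, config.gc_target)

    left_tel = _encode_str(
        str(SeqRecord("t", config.telomere_motif * config.telomere_copies).reverse_complement().seq)
    )
    right_tel = _encode_str(config.telomere_motif * config.telomere_copies)
    tel = left_tel.size

    chrom_arrays: dict[str, np.ndarray] = {}
    numt_truth: list[NumtTruth] = []
    numts_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for name, L in zip(names, config.chrom_lengths):
        core = _sample_bases(rng_genome, L, config.gc_target)
        specs = sorted(
            (s for s in config.numt_specs if s.target_chrom == name),
            key=lambda s: s.target_pos if s.target_pos is not None else L // 2,
        )
        shift = 0
        parts = []
        prev = 0
        for spec in specs:
            tpos = spec.target_pos if spec.target_pos is not None else L // 2
            insert = mito_codes[spec.mito_start : spec.mito_start + spec.length]
            if spec.strand == "-":
                insert = kmers.revcomp_codes(insert)
            parts.append(core[prev:tpos])
            parts.append(insert)
            start = tel + tpos + shift  # 0-based on the final chromosome
            numt_truth.append(
                NumtTruth(
                    chrom=name,
                    start=start + 1,
                    end=start + spec.length,
                    mito_start=spec.mito_start + 1,
                    mito_end=spec.mito_start + spec.length,
                    strand=spec.strand,
                )
            )
            numts_by_chrom.setdefault(name, []).append((start, start + spec.length))
            shift += spec.length
            prev = tpos
        parts.append(core[prev:])
        chrom_arrays[name] = np.concatenate([left_tel, *parts, right_tel])

    chrom_lengths = {n: int(a.size) for n, a in chrom_arrays.items()}
    cut_plan = _plan_cuts(config, chrom_lengths, numts_by_chrom)
    gene_models = _layout_genes(config, chrom_lengths, numts_by_chrom)

    # exclusion zones: Numts, overlap windows, telomeric margins (all +/- 200)
    zones: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    for n, ivs in numts_by_chrom.items():
        zones[n].extend((s - 200, e + 200) for s, e in ivs)
    for n, cuts in cut_plan.items():
        zones[n].extend((cut - ov - 200, cut + 200) for cut, ov in cuts)
    for n in names:
        zones[n].append((0, tel + 300))
        zones[n].append((chrom_lengths[n] - tel - 300, chrom_lengths[n]))

    # ---- coding SNVs -------------------------------------------------------
    n_missense = config.snv_nonsynonymous - 1 if config.snv_nonsynonymous else 0
    n_syn = config.snv_coding - config.snv_nonsynonymous
    templates: list[tuple[tuple[str, int, str], str]] = []
    if config.snv_nonsynonymous:
        templates.append((_NONSENSE_TEMPLATE, "nonsense"))
    templates += [
        (_MISSENSE_TEMPLATES[i % len(_MISSENSE_TEMPLATES)], "missense") for i in range(n_missense)
    ]
    templates += [
        (_SYNONYMOUS_TEMPLATES[i % len(_SYNONYMOUS_TEMPLATES)], "synonymous")
        for i in range(n_syn)
    ]
    if len(templates) != config.snv_coding:
        raise ValueError("snv profile inconsistent")

    if config.snv_coding and len(gene_models) < config.snv_coding:
        raise ValueError("not enough gene models for the requested coding SNVs")
    snv_truth: list[SnvTruth] = []
    placed: dict[str, list[int]] = {n: [] for n in names}

    def _clear(chrom: str, gpos: int) -> bool:
        if _intersects(gpos, zones[chrom]):
            return False
        return all(abs(gpos - p) >= 200 for p in placed[chrom])

    if config.snv_coding:
        spread = np.unique(
            np.round(np.linspace(0, len(gene_models) - 1, config.snv_coding)).astype(int)
        ).tolist()
        rest = [i for i in range(len(gene_models)) if i not in set(spread)]
        gene_iter = iter(spread + rest)
        for (ref_codon, within, alt), effect in templates:
            placed_one = False
            while not placed_one:
                try:
                    gm = gene_models[next(gene_iter)]
                except StopIteration:
                    raise ValueError("SNV profile infeasible for the gene model layout") from None
                n_codons = gm.length // 3
                candidates = rng_snv.permutation(np.arange(2, n_codons - 2))
                for ci in candidates:
                    ci = int(ci)
                    if gm.strand == "+":
                        gpos_probe = gm.cds_start - 1 + 3 * ci + within
                    else:
                        gpos_probe = gm.cds_end - 3 * ci - 1 - within
                    if not _clear(gm.ref_id, gpos_probe):
                        continue
                    gpos, a_base, b_base = _write_codon(
                        chrom_arrays[gm.ref_id], gm, ci, ref_codon, within, alt
                    )
                    placed[gm.ref_id].append(gpos)
                    klass = "synonymous" if effect == "synonymous" else "nonsynonymous"
                    snv_truth.append(
                        SnvTruth(gm.ref_id, gpos + 1, a_base, b_base, klass, effect, gm.gene_id)
                    )
                    placed_one = True
                    break

    # ---- non-coding SNVs ---------------------------------------------------
    cds_by_chrom: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    for gm in gene_models:
        cds_by_chrom[gm.ref_id].append((gm.cds_start - 11, gm.cds_end + 10))
    total_len = sum(chrom_lengths.values())
    weights = np.array([chrom_lengths[n] for n in names]) / total_len
    attempts = 0
    n_placed = 0
    while n_placed < config.snv_noncoding:
        attempts += 1
        if attempts > 200 * max(1, config.snv_noncoding):
            raise ValueError("SNV profile infeasible: cannot place non-coding variants")
        chrom = names[int(rng_snv.choice(len(names), p=weights))]
        gpos = int(rng_snv.integers(0, chrom_lengths[chrom]))
        if _intersects(gpos, cds_by_chrom[chrom]) or not _clear(chrom, gpos):
            continue
        a_code = int(chrom_arrays[chrom][gpos])
        alt_code = int((a_code + rng_snv.integers(1, 4)) % 4)
        placed[chrom].append(gpos)
        snv_truth.append(
            SnvTruth(chrom, gpos + 1, "ACGT"[a_code], "ACGT"[alt_code], "noncoding", "noncoding")
        )
        n_placed += 1

    snv_truth.sort(key=lambda s: (s.chrom, s.pos))

    # ---- strain B ----------------------------------------------------------
    strain_b_arrays = {n: a.copy() for n, a in chrom_arrays.items()}
    for snv in snv_truth:
        strain_b_arrays[snv.chrom][snv.pos - 1] = _encode_str(snv.alt_base)[0]

    strain_a = [SeqRecord(n, kmers.decode(chrom_arrays[n]), "strain A") for n in names]
    strain_b = [SeqRecord(n, kmers.decode(strain_b_arrays[n]), "strain B") for n in names]
    mito = SeqRecord("mito", kmers.decode(mito_codes), "mitochondrial genome")

    truth = GenomeTruth(
        config=config,
        strain_a=strain_a,
        strain_b=strain_b,
        mito=mito,
        gene_models=gene_models,
        numt_truth=sorted(numt_truth, key=lambda t: (t.chrom, t.start)),
        snv_truth=snv_truth,
        cut_plan=cut_plan,
    )
    _validate_truth(truth)
    return truth


def _validate_truth(truth: GenomeTruth) -> None:
    """Self-consistency: every coding SNV's class agrees with codon annotation."""
    refs = {r.id: r for r in truth.strain_a}
    for snv in truth.snv_truth:
        if snv.klass == "noncoding":
            continue
        v = Variant(snv.chrom, snv.pos, snv.ref_base, snv.alt_base, depth=1, alt_count=1)
        eff = annotate_coding_effect(v, truth.gene_models, refs)
        if eff is None or eff.effect_class != snv.effect:
            raise ValueError(
                f"SNV profile infeasible: {snv} annotates as "
                f"{eff.effect_class if eff else 'noncoding'}"
            )


def fragment_into_scaffolds(
    truth: GenomeTruth, config: SimConfig | None = None
) -> tuple[list[SeqRecord], list[JoinTruth]]:
    """Cut each strain-A chromosome into overlapping fragments.

    Consecutive fragments share exactly the configured overlap (left fragment
    carries the overlap at its 3' end, right fragment repeats it at its 5'
    end); each fragment is independently reverse-complemented with
    probability ``revcomp_fraction``. The join table records fragment pairs,
    overlap lengths and emitted orientations, and is also stored on
    ``truth.join_truth``.
    """
    config = config or truth.config
    for ov in config.overlap_lengths:
        if ov < 1500:
            raise ValueError(f"overlap {ov} below the 1,500 bp curation minimum")
    rng = _streams(config)[2]
    scaffolds: list[SeqRecord] = []
    joins: list[JoinTruth] = []
    for rec in truth.strain_a:
        cuts = truth.cut_plan.get(rec.id, [])
        for _cut, ov in cuts:
            if ov >= len(rec.seq):
                raise ValueError("overlap longer than the fragment")
        starts = [0] + [c for c, _ in cuts]
        ends = [c + ov for c, ov in cuts] + [len(rec.seq)]
        names = [f"{rec.id}_part{i + 1}" for i in range(len(starts))]
        orients = ["-" if rng.random() < config.revcomp_fraction else "+" for _ in starts]
        for i, (s, e) in enumerate(zip(starts, ends)):
            frag = SeqRecord(names[i], rec.seq[s:e])
            if orients[i] == "-":
                frag = SeqRecord(names[i], frag.reverse_complement().seq)
            scaffolds.append(frag)
        for i, (_cut, ov) in enumerate(cuts):
            joins.append(JoinTruth(names[i], names[i + 1], ov, orients[i], orients[i + 1]))
    truth.join_truth = joins
    return scaffolds, joins


def simulate_reads(
    truth: GenomeTruth, config: SimConfig | None = None, strains: tuple[str, ...] = ("A", "B")
) -> dict[str, ReadSet]:
    """Uniform single-end reads per strain (chromosomes + mitochondrion).

    Read count per replicon is round(depth x length / read_length); start
    positions are uniform, strands equiprobable, substitution errors i.i.d.
    at ``error_rate``. Per-read truth (source, 0-based start, strand) rides
    on the returned :class:`ReadSet`.
    """
    config = config or truth.config
    rl = config.read_length
    rng_a, rng_b = _streams(config)[3:5]
    out: dict[str, ReadSet] = {}
    for strain, rng, records in (("A", rng_a, truth.strain_a), ("B", rng_b, truth.strain_b)):
        if strain not in strains:
            continue
        replicons = list(records) + [truth.mito]
        depths = [config.nuclear_depth] * len(records) + [config.mito_depth]
        mats, origin_idx, serials = [], [], []
        t_origin, t_start, t_strand = [], [], []
        origins = []
        for oi, (rec, depth) in enumerate(zip(replicons, depths)):
            L = len(rec.seq)
            if rl > L:
                raise ValueError(f"read_length {rl} exceeds replicon {rec.id} ({L} bp)")
            n = int(round(depth * L / rl))
            codes = kmers.encode(rec.seq)
            windows = np.lib.stride_tricks.sliding_window_view(codes, rl)
            starts = rng.integers(0, L - rl + 1, n)
            block = windows[starts].copy()
            strand = rng.integers(0, 2, n).astype(np.uint8)
            rev = strand == 1
            if rev.any():
                block[rev] = _COMP_CODE[block[rev]][:, ::-1]
            if config.error_rate > 0:
                n_err = rng.binomial(rl, config.error_rate, n)
                tot = int(n_err.sum())
                if tot:
                    rows = np.repeat(np.arange(n), n_err)
                    cols = rng.integers(0, rl, tot)
                    bump = rng.integers(1, 4, tot).astype(np.uint8)
                    block[rows, cols] = (block[rows, cols] + bump) % 4
            origins.append(f"{strain}:{rec.id}")
            mats.append(block)
            origin_idx.append(np.full(n, oi, np.int32))
            serials.append(np.arange(n, dtype=np.int64))
            t_origin.append(np.full(n, oi, np.int32))
            t_start.append(starts.astype(np.int64))
            t_strand.append(strand)
        out[strain] = ReadSet(
            np.concatenate(mats),
            origins,
            np.concatenate(origin_idx),
            np.concatenate(serials),
            truth={
                "origin": np.concatenate(t_origin),
                "start": np.concatenate(t_start),
                "strand": np.concatenate(t_strand),
            },
        )
    return out


def scaled_config(seed: int = 0, **overrides) -> SimConfig:
    """A small configuration for fast exercises of the full pipeline.

    Keeps the qualitative structure (two Numts, telomeres, fragmentation,
    a consistent SNV profile) at roughly 1/8 of the default genome size.
    """
    base = dict(
        seed=seed,
        chrom_lengths=(60_000, 45_000, 35_000),
        mito_length=12_000,
        numt_specs=(
            NumtSpec(1000, 4000, "chr2", None, "+"),
            NumtSpec(8000, 500, "chr3", None, "+"),
        ),
        snv_total=24,
        snv_noncoding=16,
        snv_coding=8,
        snv_nonsynonymous=5,
        nuclear_depth=40.0,
        mito_depth=300.0,
        overlap_lengths=(2400, 2000, 1700),
    )
    base.update(overrides)
    return SimConfig(**base)
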