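# Methods

This note documents the models, parameter choices, and numerical conventions
behind `numtkit`, and what the synthetic benchmark does and does not show.

## Coordinates and formats

All internal coordinates are 0-based half-open; every user-facing report
(Numt calls, junctions, variants, synteny blocks) is 1-based inclusive, the
convention of genome browsers and of the tables such results are compared
against. BED output is 0-based half-open as the format requires. FASTA/FASTQ
readers fold case, reject characters outside {A,C,G,T,N} naming the offending
line, and require unique ids; depth tables follow the samtools-depth dialect
(ref, 1-based position, depth) with absent positions meaning depth 0.

## The synthetic genome pair

The generator emulates a pair of near-identical filamentous-fungus strains at
the scale where the full analysis still runs in seconds:

| parameter | default | rationale |
|---|---|---|
| chromosomes | 3 of 300 / 200 / 150 kb | multi-chromosome structure at desk scale |
| GC target | 0.49 | typical for the clade being emulated |
| telomeres | 12 × TTAGGGC per end | comfortably above the 7-repeat call threshold |
| mitochondrion | 27 kb, linear | the reference mitochondrial replicon size |
| Numts | mito[1000:11000) → chr2 mid; mito[15000:15500) → chr3 mid | one large (10 kb) and one short (500 bp) insertion |
| nuclear / mito depth | 60× / 690× | mitochondrial high copy number expressed as depth; 60 + 690 = 750× over a Numt under all-best counting |
| reads | 150 bp single-end, error 0.001 subs/base | short-read error regime; indels out of scope |
| SNV profile | 161 = 125 non-coding + 36 coding (25 amino-acid-changing, 1 nonsense) | the inter-strain substitution profile under study |
| overlaps | 4,636 / 4,009 / 2,000 bp, 25% fragments reverse-complemented | known scaffold-join ground truth |

Design points worth stating explicitly:

* **Mitochondrial copy number is a depth, not repeated contigs.** The ~750×
  pile-up over a Numt then *emerges* from all-best multi-mapping rather than
  being painted in, which is exactly the signature the caller exploits.
* **The mitochondrion is generated linear** and reads are not wrapped across
  the origin. Circularity affects ~1 read length at the ends and is
  irrelevant to Numt logic; real circular mtDNA differs here.
* **SNVs are placed ≥ 200 bp apart and away from Numts, telomere margins,
  and scaffold-overlap windows**, so every truth record is unambiguous (no
  read carries two variants; no variant sits in duplicated sequence).
  Fragmentation cut points are a deterministic function of the configuration
  (midpoints, shifted off Numts), so the generator can honour the exclusion
  before fragmentation is ever called.
* **Coding SNVs are written as codons.** For each planned coding variant the
  generator overwrites a codon of strain A (in coding orientation, strand
  aware) with a template whose single-base substitution has the desired
  effect, then applies the substituted base to strain B. 24 missense
  templates cycle through common single-substitution changes
  (Cys>Gly, Val>Ile, Gly>Ser, Pro>His, Leu>Pro, Asp>Gly, His>Arg, Thr>Ala,
  Ser>Pro); one nonsense is the CGA→TGA arginine-to-stop; the remaining 11
  are third-position synonymous edits. How many of the coding variants are
  synonymous is a modelling choice of this generator (the 25/11 split with a
  single nonsense), constrained only by the 36/25 profile. Every generated
  genome is self-checked: each coding truth record must re-annotate to its
  intended class via `variants.annotate_coding_effect`, otherwise generation
  aborts.
* **Toy gene models** are single-exon, non-overlapping, strand-alternating
  CDSs of 1,200 bp every 3,000 bp (~40% coding), length divisible by 3.

What passing the benchmark does **not** show about real data: no indels, no
paired-end information, no quality scores, no repeat families beyond
telomeres, flat coverage (no GC bias), and assemblies that are error-free
copies of the truth. The analysis modules accept real FASTA/FASTQ/depth-TSV
inputs, but their published-data behaviour is not certified by these tests.

## Read mapping

Exact k-mer seeds (k = 31) at `max_mismatch + 1` disjoint read offsets
anchor candidate placements; candidates are verified by substitution count
(gap-free). By pigeonhole, every placement with ≤ `max_mismatch` (default 2)
substitutions is found whenever `read_length ≥ (max_mismatch+1)·k` (150 ≥ 93
holds for the default reads). All placements tied at the minimal mismatch
count are reported (`all-best`); a seeded `random-one` policy exists for
workflows that need single placements. Mapping is fully vectorised and
deterministic: candidates are deduplicated and sorted by (read, strand,
position), independent of input order.

Coverage counts each alignment once over its span; under `count-all` a read
with *m* best placements contributes to all *m* (the Numt-inflation channel),
under `unique` only single-placement reads count (the variant-calling
channel).

## Numt detection

Three channels, intersected:

1. **Coverage anomaly.** Windows (500 bp) of the all-reads track with mean
   depth ≥ 5× the genome-wide **median** (median, not mean — the Numt
   plateaus themselves would drag a mean). Run boundaries are refined at base
   resolution to the half-threshold crossing (plateau edges at half height,
   the FWHM convention), then runs shorter than 400 bp are dropped. The
   refinement makes the span test measure the peak itself rather than the
   window grid, which both suppresses sub-window spikes and keeps a 500 bp
   Numt detectable regardless of its alignment to the grid.
2. **Filtered-coverage gaps.** Reads are stripped when they share any exact
   21-mer (either strand) with the mitochondrial genome
   (`mapcov.kmer_filter_reads`), then the remainder is remapped. This
   containment criterion deliberately behaves like a *local* aligner: a read
   that only partially overlaps a Numt junction is still recognised as
   mitochondrial once ≥ 21 error-free bases match. End-to-end mapping against
   the mitochondrion would leave ~135 bp of junction-straddling cover inside
   each Numt and shrink a 500 bp Numt's gap below both the 300 bp minimum
   gap length and the 50% overlap rule; with k-mer containment the measured
   gaps are within ~10 bp of the true insertion. Gaps are maximal runs with
   depth ≤ 0.1× the filtered track's median, length ≥ 300 bp. A 21-mer false
   hit against a 27 kb mitochondrion is expected ~10⁻⁶ per read — removing a
   stray read cannot fabricate a gap at 60×.
3. **Homology.** Exact 21-mer seeds chained along gap-free diagonals (same
   diagonal, mismatch patches ≤ 10 bp, both strands), segments ≥ 200 bp at
   ≥ 0.9 identity, each carrying its source mitochondrial interval. On the
   synthetic data these segments recover the implants exactly, occasionally
   extended 1–3 bp where flanking bases coincide with the next mitochondrial
   base (a ¼-per-side coincidence inherent to exact-match delineation).

Every homology segment becomes a call flagged with anomaly/gap support at
≥ 50% reciprocal interval overlap — a formalisation of what is otherwise done
by eye in a genome browser. Anomaly∩gap intervals with no homology are
emitted as homology-less candidates rather than silently dropped. Reported
call coordinates come from the homology segment, so a call's length is the
insertion length, not the (slightly narrower) gap or (grid-quantised)
anomaly extent.

## Variant calling

Pileups use uniquely-mapped reads only: multi-mapped reads are excluded so
mitochondrial paralogy (the Numts at ~750×) cannot contaminate allele
frequencies. A substitution is emitted when the most frequent non-reference
base reaches frequency ≥ `min_freq` (default 0.5 — deliberately conservative,
the observed retained variants sit at 65–100%) at depth ≥ 10; ties between
alt bases break to the lexicographically smaller base. The reciprocal design
maps strain-B reads onto assembly A and vice versa; a variant is *confirmed*
when the reverse direction calls the complementary substitution at the same
coordinate (coordinate identity across assemblies holds when they differ
only by substitutions, as here; real assemblies would need a liftover via
the synteny module). Codon effects respect strand: minus-strand variants are
complemented into coding orientation before translation with the standard
genetic code.

## Scaffold curation

Overlap detection anchors shared 21-mers in the terminal 20 kb of each
oriented scaffold end and evaluates every implied gap-free diagonal: the
longest suffix–prefix alignment ≥ 1,500 bp with identity ≥ 0.99 wins per end
pair. The identity floor is configurable; 0.99 reflects short-read-polished
scaffolds whose true overlaps are near-exact. Joins are resolved greedily by
(overlap length, identity, ids) — a deterministic stand-in for by-eye
conflict resolution — with union-find cycle rejection, so chains are always
simple paths. Merging takes the left member's copy of each overlap and
counts (never resolves) disagreement bases; each junction is reported with
1-based coordinates plus a ±2,500 bp amplicon interval for PCR-style
validation. Chain direction is canonicalised to start at the
lexicographically smaller endpoint, making output independent of input
order.

## Synteny

Homolog pairing nominates candidates by shared 21-mer counts and accepts by
edit-distance identity (edlib, ≥ 0.7) and length coverage (≥ 0.5); only
reciprocal best hits enter block calling. "At least 30 consecutive
homologous loci" is read strictly: `max_interrupt` defaults to 0, and a
junction between consecutive paired loci tolerates at most `max_interrupt`
interruptions, counted as the larger of skipped A genes and jumped B ranks
(the same missing locus otherwise double-counts). Maximal runs are computed
per direction independently, so a locus at an inversion breakpoint may
support one block of each orientation — this matches an exhaustive run
scanner, which a greedy single-pass scan does not. Dot-plot seeds are
maximal exact matches ≥ 100 bp from the same diagonal-chaining machinery
(optionally mismatch-chained); no E-value model is used anywhere — identity
and length thresholds are deterministic, database-free equivalents at gene
scale.

## Statistics

N50 uses the inclusive convention (the scaffold length at which the sorted
cumulative sum first reaches half the total), which reproduces the published
values for both 13-scaffold inventories the package is tested against. GC
excludes ambiguous bases from the denominator. Telomere counting is
non-overlapping per strand and summed over the motif and its reverse
complement; whether overlapping occurrences should count is genuinely
ambiguous for a 7-mer that cannot overlap itself, so non-overlapping was
chosen and both motif and threshold are parameters. The right-end call uses
a window anchored at the right end, making the left/right calls symmetric
under reverse complement for any sequence length.

## Problem sizes and determinism

The default configuration (≈ 660 kb genome, ≈ 390 k reads per strain) runs
each full Numt analysis in ~20 s and each reciprocal variant comparison in
~10 s; the bundled property tests use a 1/8-scale configuration
(`synthetic.scaled_config`) with a proportionally scaled SNV profile, while
the acceptance tests exercise the full default conditions across ten seeds.
All randomness flows from a single integer seed through named
`numpy.random.SeedSequence` streams (genome, SNVs, fragmentation, reads per
strain), so every artefact — sequences, truth tables, reads, and therefore
every downstream call — is byte-reproducible from the configuration alone.
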