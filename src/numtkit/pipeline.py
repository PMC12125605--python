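"""End-to-end pipeline driver: simulate -> curate -> map -> Numt -> SNV -> synteny.

Configuration is a flat key-value namespace (``PipelineConfig``); a plain
``key = value`` config file can seed it and command-line options override
file values, which override defaults. All stochastic stages consume the
single master seed, so identical configurations produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import asm_stats, mapcov, numt, scaffold_merge, seqio, synteny, synthetic, variants

log = logging.getLogger("numtkit")

EXIT_CONFIG_ERROR = 2
EXIT_FORMAT_ERROR = 3
EXIT_STAGE_ERROR = 4


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    # simulation (defaults mirror SimConfig)
    seed: int = 0
    simulate: bool = True
    scaled: bool = False  # use the small exercise configuration
    assembly_fasta: str = ""  # used when simulate is false
    mito_fasta: str = ""
    reads_fastq: str = ""
    genes_gff3: str = ""
    # curation / mapping / calling parameters
    min_overlap: int = 1500
    min_identity: float = 0.99
    end_window: int = 20000
    index_k: int = 31
    max_mismatch: int = 2
    min_depth: int = 10
    min_freq: float = 0.5
    min_run: int = 30
    dotplot_min_seed: int = 100
    # outputs
    outdir: str = "numtkit_out"
    write_reads: bool = False
    write_depth: bool = False
    log_level: str = "INFO"

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in dataclasses.fields(cls)}


def parse_config_file(path) -> dict:
    """Parse a plain ``key = value`` file; unknown keys are rejected."""
    values: dict = {}
    known = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    defaults = PipelineConfig()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key = value")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in known:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            current = getattr(defaults, key)
            try:
                if isinstance(current, bool):
                    values[key] = val.lower() in ("1", "true", "yes", "on")
                elif isinstance(current, int):
                    values[key] = int(val)
                elif isinstance(current, float):
                    values[key] = float(val)
                else:
                    values[key] = val
            except ValueError:
                raise ConfigError(f"{path}:{lineno}: bad value for {key!r}") from None
    return values


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("[%s] starting", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise StageError(name, exc) from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write outputs under ``config.outdir``; return the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if not config.simulate:
        raise ConfigError(
            "the end-to-end driver runs on simulated data (simulate = true); "
            "analyse real inputs with the individual subcommands"
        )
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "parameters": dataclasses.asdict(config)}

    # ---- simulate ----------------------------------------------------------
    @_stage("simulate")
    def do_simulate():
        cfg = (
            synthetic.scaled_config(seed=config.seed)
            if config.scaled
            else synthetic.SimConfig(seed=config.seed)
        )
        truth = synthetic.generate_genome(cfg)
        scaffolds, joins = synthetic.fragment_into_scaffolds(truth)
        reads = synthetic.simulate_reads(truth)
        seqio.write_fasta(truth.strain_a, out / "strainA.fasta")
        seqio.write_fasta(truth.strain_b, out / "strainB.fasta")
        seqio.write_fasta([truth.mito], out / "mito.fasta")
        seqio.write_fasta(scaffolds, out / "scaffolds.fasta")
        variants.write_gff3(truth.gene_models, out / "genes.gff3")
        with open(out / "numt_truth.tsv", "w") as fh:
            fh.write("chrom\tstart\tend\tmito_start\tmito_end\tstrand\n")
            for t in truth.numt_truth:
                fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.mito_start}\t{t.mito_end}\t{t.strand}\n")
        with open(out / "snv_truth.tsv", "w") as fh:
            fh.write("chrom\tpos\tref\talt\tclass\teffect\tgene_id\n")
            for s in truth.snv_truth:
                fh.write(
                    f"{s.chrom}\t{s.pos}\t{s.ref_base}\t{s.alt_base}\t{s.klass}\t"
                    f"{s.effect}\t{s.gene_id or '.'}\n"
                )
        with open(out / "join_truth.tsv", "w") as fh:
            fh.write("left\tright\toverlap_len\tleft_orient\tright_orient\n")
            for j in joins:
                fh.write(
                    f"{j.left_id}\t{j.right_id}\t{j.overlap_len}\t{j.left_orient}\t{j.right_orient}\n"
                )
        if config.write_reads:
            for strain, rs in reads.items():
                seqio.write_fastq(rs.to_records(), out / f"reads_{strain}.fastq")
        return truth, scaffolds, reads

    truth, scaffolds, reads = do_simulate()

    # ---- merge (scaffold curation) ----------------------------------------
    @_stage("merge")
    def do_merge():
        joins = scaffold_merge.find_end_overlaps(
            scaffolds,
            min_len=config.min_overlap,
            min_identity=config.min_identity,
            end_window=config.end_window,
        )
        chains = scaffold_merge.build_join_chains(joins, [s.id for s in scaffolds])
        merged, report = scaffold_merge.merge_scaffolds(scaffolds, chains)
        seqio.write_fasta(merged, out / "merged.fasta")
        report.to_csv(out / "junctions.tsv", sep="\t", index=False)
        return merged, report

    merged, junction_report = do_merge()
    manifest["n_scaffolds_in"] = len(scaffolds)
    manifest["n_scaffolds_merged"] = len(merged)

    # ---- stats -------------------------------------------------------------
    @_stage("stats")
    def do_stats():
        stats = asm_stats.assembly_stats(merged)
        profiles = [asm_stats.telomere_scan(rec) for rec in merged]
        with open(out / "assembly_stats.tsv", "w") as fh:
            fh.write("n_scaffolds\ttotal_len\tlargest\tn50\tl50\tgc_percent\n")
            fh.write(
                f"{stats.n_scaffolds}\t{stats.total_len}\t{stats.largest}\t{stats.n50}\t"
                f"{stats.l50}\t{stats.gc_percent:.2f}\n"
            )
        with open(out / "telomeres.tsv", "w") as fh:
            fh.write("scaffold\twindow\tcount\tleft_telomeric\tright_telomeric\n")
            for p in profiles:
                for w, c in enumerate(p.window_counts):
                    fh.write(
                        f"{p.scaffold_id}\t{w + 1}\t{c}\t{p.left_telomeric}\t{p.right_telomeric}\n"
                    )
        return stats

    stats = do_stats()
    manifest["assembly"] = dataclasses.asdict(stats)

    # ---- numt --------------------------------------------------------------
    @_stage("numt")
    def do_numt():
        result = numt.detect_numts(
            truth.strain_a,
            truth.mito,
            reads["A"],
            index_k=config.index_k,
            max_mismatch=config.max_mismatch,
        )
        seqio.write_bed(
            [
                (
                    c.ref_id,
                    c.start - 1,
                    c.end,
                    f"numt_{i + 1}",
                    f"{'A' if c.anomaly else '.'}{'G' if c.gap else '.'}{'H' if c.homology else '.'}",
                )
                for i, c in enumerate(result.calls)
            ],
            out / "numt_calls.bed",
        )
        with open(out / "numt_evidence.tsv", "w") as fh:
            fh.write(
                "ref_id\tstart\tend\tlength\tmito_start\tmito_end\tstrand\tanomaly\tgap\t"
                "homology\tmean_depth_all\tmean_depth_filtered\n"
            )
            for c in result.calls:
                fh.write(
                    f"{c.ref_id}\t{c.start}\t{c.end}\t{c.length}\t{c.mito_start}\t{c.mito_end}\t"
                    f"{c.strand}\t{c.anomaly}\t{c.gap}\t{c.homology}\t"
                    f"{c.mean_depth_all:.1f}\t{c.mean_depth_filtered:.1f}\n"
                )
        if config.write_depth:
            seqio.write_depth_table(result.coverage_all.values(), out / "depth_all.tsv")
            seqio.write_depth_table(result.coverage_filtered.values(), out / "depth_filtered.tsv")
        return result

    numt_result = do_numt()
    manifest["n_numt_calls"] = len(numt_result.calls)
    manifest["median_depth"] = numt_result.median_depth_all

    # ---- variants ----------------------------------------------------------
    @_stage("variants")
    def do_variants():
        frame = variants.compare_strains(
            reads["A"],
            truth.strain_b,
            reads["B"],
            truth.strain_a,
            gene_models=truth.gene_models,
            min_depth=config.min_depth,
            min_freq=config.min_freq,
            max_mismatch=config.max_mismatch,
        )
        frame.to_csv(out / "variants.tsv", sep="\t", index=False)
        return frame

    variant_frame = do_variants()
    if variant_frame.empty:
        manifest["n_variants_confirmed"] = 0
        manifest["n_amino_acid_changing"] = 0
    else:
        confirmed = variant_frame[variant_frame["confirmed"]]
        manifest["n_variants_confirmed"] = int(len(confirmed))
        manifest["n_amino_acid_changing"] = int(
            confirmed["effect_class"].isin(["missense", "nonsense"]).sum()
        )

    # ---- synteny -----------------------------------------------------------
    @_stage("synteny")
    def do_synteny():
        genes_a = synteny.extract_gene_sequences(truth.strain_a, truth.gene_models)
        genes_b = synteny.extract_gene_sequences(truth.strain_b, truth.gene_models)
        # distinct id namespaces for the two assemblies
        genes_b = {f"B_{g}": s for g, s in genes_b.items()}
        pairs = synteny.pair_homologs(genes_a, genes_b)
        order_a: dict[str, list[str]] = {}
        order_b: dict[str, list[str]] = {}
        for gm in sorted(truth.gene_models, key=lambda g: (g.ref_id, g.cds_start)):
            order_a.setdefault(gm.ref_id, []).append(gm.gene_id)
            order_b.setdefault(gm.ref_id, []).append(f"B_{gm.gene_id}")
        models_b = [
            variants.GeneModel(f"B_{g.gene_id}", g.ref_id, g.cds_start, g.cds_end, g.strand)
            for g in truth.gene_models
        ]
        blocks = synteny.call_blocks(
            pairs, order_a, order_b, truth.gene_models, models_b, min_run=config.min_run
        )
        synteny.blocks_to_frame(blocks).to_csv(out / "synteny_blocks.tsv", sep="\t", index=False)
        flat = synteny.merge_flatten(blocks)
        for side in ("a", "b"):
            seqio.write_bed(
                [(ref, s - 1, e) for ref, s, e in flat[side]], out / f"synteny_flat_{side}.bed"
            )
        seeds = synteny.dotplot_seeds(
            truth.strain_a[0], truth.strain_b[0], min_seed=config.dotplot_min_seed
        )
        seeds.to_csv(out / "dotplot_chr1.tsv", sep="\t", index=False)
        return blocks

    blocks = do_synteny()
    manifest["n_synteny_blocks"] = len(blocks)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("pipeline complete: %s", out / "manifest.json")
    return manifest
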