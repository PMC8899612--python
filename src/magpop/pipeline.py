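"""Pipeline orchestration: skew -> SSV -> insertions -> junctions -> regions.

``run_pipeline`` composes the library stages over a set of input files and
writes a report bundle (skew.tsv, ssv.vcf, insertions.vcf, junctions.tsv,
table3.tsv, regions.bed, enrichment.json, summary.json).  Every output is
written atomically (temp file + rename) and the whole bundle is a pure
function of the config and inputs: identical config -> byte-identical
summary.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from magpop import insertions as ins_mod
from magpop import scrapyard as sy_mod
from magpop import ssv as ssv_mod
from magpop.core_io import (
    AlignmentStats,
    Region,
    read_alignments,
    read_fasta,
    read_features,
    write_regions,
)
from magpop.stats import gc_skew_profile, genome_scatter_background, skew_scatter

log = logging.getLogger("magpop.pipeline")


@dataclass
class SkewParams:
    window: int = 10_000
    step: int = 2_000


@dataclass
class InsertionParams:
    min_len: int = 10
    min_clip: int = 100
    min_read_length: int = 1000
    cluster_window: int = 100
    margin: int = 50
    min_support: int = 2
    min_identity: float = 0.8
    min_cov: float = 0.5


@dataclass
class JunctionParams:
    flank: int = 50
    min_overlap: int = 20
    search_window: int = 1000


@dataclass
class PipelineConfig:
    """Input paths plus per-stage parameter blocks.

    ``short_sam`` feeds both the SSV caller and junction genotyping;
    ``ssv_vcf`` optionally replaces the internal caller with externally
    called variants.  Anchor names, when set, delimit the region for the
    content table; de novo detection always runs as well.
    """

    genome_fasta: str
    genes_gff3: str
    long_sam: str
    short_sam: str
    elements_fasta: str
    outdir: str
    ssv_vcf: str | None = None
    left_anchor: str | None = None
    right_anchor: str | None = None
    seed: int = 0
    skew: SkewParams = field(default_factory=SkewParams)
    ssv_thresholds: ssv_mod.CallerThresholds = field(default_factory=ssv_mod.CallerThresholds)
    insertion: InsertionParams = field(default_factory=InsertionParams)
    junction: JunctionParams = field(default_factory=JunctionParams)
    detection: sy_mod.DetectionParams = field(default_factory=sy_mod.DetectionParams)

    def validate(self) -> None:
        missing = [
            p
            for p in (
                self.genome_fasta,
                self.genes_gff3,
                self.long_sam,
                self.short_sam,
                self.elements_fasta,
                self.ssv_vcf,
            )
            if p is not None and not Path(p).is_file()
        ]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {', '.join(map(str, missing))}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the summary dict.

    Stage order: GC skew profile; SSV calling (or VCF ingest); insertion
    signal collection, clustering, classification and disruption
    assignment; junction genotyping; region content statistics and de
    novo scrapyard detection.  Any stage failure aborts with the stage
    name; partially written outputs are removed.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {"parameters": _parameters_echo(config), "counts": {}}
    t_start = time.time()

    def emit(name: str, text: str) -> None:
        path = outdir / name
        _atomic_write(path, text)
        written.append(path)

    stage = "load-inputs"
    try:
        contigs = read_fasta(config.genome_fasta)
        contig = contigs[0]
        features = read_features(config.genes_gff3)
        library = {c.id: c.sequence for c in read_fasta(config.elements_fasta)}
        L = len(contig)
        log.info("loaded genome %s (%d bp), %d features", contig.id, L, len(features))

        # --- GC skew
        stage = "skew"
        profile = gc_skew_profile(
            contig.sequence, config.skew.window, config.skew.step, contig.circular
        )
        skew_lines = ["start\tskew\tsign"]
        skew_lines += [
            f"{int(s)}\t{v:.6f}\t{int(g)}"
            for s, v, g in zip(profile.starts, profile.values, profile.signs)
        ]
        emit("skew.tsv", "\n".join(skew_lines) + "\n")

        # --- SSV
        stage = "ssv"
        if config.ssv_vcf:
            variants = ssv_mod.read_vcf(config.ssv_vcf)
            log.info("ingested %d variants from %s", len(variants), config.ssv_vcf)
        else:
            stats = AlignmentStats()
            variants = ssv_mod.call_ssv(
                read_alignments(config.short_sam, stats),
                contig.sequence,
                contig.id,
                config.ssv_thresholds,
            )
            log.info(
                "called %d SSVs from %d short-read alignments (%d skipped)",
                len(variants),
                stats.parsed,
                stats.skipped_unmapped + stats.skipped_secondary,
            )
        vcf_path = outdir / "ssv.vcf"
        ssv_mod.write_vcf(variants, str(vcf_path), contig.id, L)
        written.append(vcf_path)
        summary["counts"]["ssv_total"] = len(variants)
        if variants:
            summary["counts"]["ssv_orf_fraction"] = round(
                ssv_mod.ssv_orf_fraction(variants, features), 4
            )

        # --- insertions
        stage = "insertions"
        long_stats = AlignmentStats()
        signals, long_alns = ins_mod.collect_insertion_signals(
            read_alignments(config.long_sam, long_stats),
            min_len=config.insertion.min_len,
            min_clip=config.insertion.min_clip,
            min_read_length=config.insertion.min_read_length,
        )
        calls = ins_mod.cluster_and_call(
            signals,
            long_alns,
            cluster_window=config.insertion.cluster_window,
            margin=config.insertion.margin,
            min_support=config.insertion.min_support,
        )
        ins_mod.annotate_calls(
            calls,
            library,
            features,
            min_identity=config.insertion.min_identity,
            min_cov=config.insertion.min_cov,
        )
        vcf_path = outdir / "insertions.vcf"
        ins_mod.write_insertion_vcf(calls, str(vcf_path), L)
        written.append(vcf_path)
        variable = [c for c in calls if c.is_variable]
        by_class: dict[str, int] = {}
        for c in variable:
            by_class[c.disruption_class] = by_class.get(c.disruption_class, 0) + 1
        summary["counts"]["insertion_calls"] = len(calls)
        summary["counts"]["variable_me"] = len(variable)
        summary["counts"]["variable_by_class"] = {
            k: by_class.get(k, 0)
            for k in (
                ins_mod.DISRUPT_FUNCTIONAL,
                ins_mod.DISRUPT_HP,
                ins_mod.DISRUPT_SELFISH,
                ins_mod.DISRUPT_INTERGENIC,
            )
        }
        # headline total: functional-gene disruptions; HP reported separately
        summary["counts"]["variable_gene_disruptions"] = by_class.get(
            ins_mod.DISRUPT_FUNCTIONAL, 0
        )
        log.info("%d insertion calls, %d variable", len(calls), len(variable))

        # --- junction genotyping
        stage = "junctions"
        short_stats = AlignmentStats()
        short_alns = list(read_alignments(config.short_sam, short_stats))
        jlines = [
            "breakpoint\telement\tdisrupted_feature\tdisruption_class\t"
            "y\tn\tratio\tformatted"
        ]
        for call in calls:
            reads = ins_mod.reads_near(
                short_alns, call.breakpoint, config.junction.search_window
            )
            try:
                assay = ins_mod.genotype_junctions(
                    call,
                    reads,
                    contig.sequence,
                    flank=config.junction.flank,
                    min_overlap=config.junction.min_overlap,
                )
            except ValueError as exc:
                log.warning("junction assay skipped at %d: %s", call.breakpoint, exc)
                continue
            ratio = "" if assay.ratio is None else f"{assay.ratio:.4f}"
            jlines.append(
                f"{call.breakpoint}\t{call.classification}\t"
                f"{call.disrupted_feature or '.'}\t{call.disruption_class}\t"
                f"{assay.disrupted}\t{assay.intact}\t{ratio}\t{assay.formatted()}"
            )
        emit("junctions.tsv", "\n".join(jlines) + "\n")

        # --- region statistics
        stage = "regions"
        rows = []
        enrichment: dict = {}
        anchored: Region | None = None
        if config.left_anchor and config.right_anchor:
            anchored = sy_mod.delimit_by_anchors(
                features, config.left_anchor, config.right_anchor
            )
            inside, outside = sy_mod.region_content_stats(features, variants, anchored, L)
            rows += [inside, outside]
            report = sy_mod.enrichment_ratios(inside, outside)
            enrichment["anchored"] = {
                name: asdict(m) for name, m in report.metrics.items()
            }
            try:
                enrichment["anchored_skew"] = {
                    "scatter_inside": skew_scatter(profile, anchored),
                    "scatter_background": genome_scatter_background(profile),
                }
            except ValueError:
                pass
            summary["counts"]["anchored_region"] = [anchored.start, anchored.end]

        islands = sy_mod.detect_scrapyards(
            L, features, variants, profile, config.detection, contig.id
        )
        for island in islands:
            inside, outside = sy_mod.region_content_stats(features, variants, island, L)
            rows += [inside, outside]
        bed_path = outdir / "regions.bed"
        write_regions(([anchored] if anchored else []) + islands, str(bed_path))
        written.append(bed_path)
        emit("table3.tsv", sy_mod.format_table(rows))
        emit("enrichment.json", json.dumps(enrichment, indent=2, sort_keys=True) + "\n")
        summary["counts"]["islands"] = [[r.start, r.end] for r in islands]

        stage = "summary"
        summary["runtime_seconds"] = None  # filled below, excluded from determinism
        summary_text = json.dumps(
            {k: v for k, v in summary.items() if k != "runtime_seconds"},
            indent=2,
            sort_keys=True,
        )
        emit("summary.json", summary_text + "\n")
        summary["runtime_seconds"] = round(time.time() - t_start, 2)
        log.info("pipeline finished in %.1f s", summary["runtime_seconds"])
        return summary
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc


def _parameters_echo(config: PipelineConfig) -> dict:
    echo = {}
    for block in ("skew", "ssv_thresholds", "insertion", "junction", "detection"):
        echo[block] = asdict(getattr(config, block))
    echo["seed"] = config.seed
    echo["left_anchor"] = config.left_anchor
    echo["right_anchor"] = config.right_anchor
    return echo


__all__ = [
    "InsertionParams",
    "JunctionParams",
    "PipelineConfig",
    "SkewParams",
    "StageError",
    "run_pipeline",
]
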