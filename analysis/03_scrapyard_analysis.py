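#!/usr/bin/env python
"""Regional content statistics, enrichment and island detection.

Part A recomputes the published per-region statistics of the five natural
populations from their printed counts (percents, per-10-kbp densities,
inside/outside fold ratios and the three rank-test p-values).  Part B,
when scratch/sim/ exists, delimits the simulated scrapyard by its tRNA
anchors and detects islands de novo from gene content plus the SSV calls
of 02_call_variants.py.

    python analysis/03_scrapyard_analysis.py
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from magpop.datasets import CONTENT_TABLE, PUBLISHED_SSV_FOLDS, printed_column
from magpop.scrapyard import (
    delimit_by_anchors,
    detect_scrapyards,
    enrichment_ratios,
    format_table,
    jaccard,
    region_content_stats,
    stats_row_from_counts,
)
from magpop.stats import mann_whitney_exact

SIM = Path("scratch/sim")
RESULTS = Path("results")


def build_row(strain, region):
    r = CONTENT_TABLE[strain][region]
    return stats_row_from_counts(
        f"{strain}:{region}", r["counts"], r["length"],
        ssv_count=r["ssv"], orf_total=r["orf_total"],
        start=r.get("start", 1) - 1, end=r.get("end"),
    )


def main():
    RESULTS.mkdir(exist_ok=True)

    rows = [build_row(s, r) for s in CONTENT_TABLE for r in CONTENT_TABLE[s]]
    (RESULTS / "table_content.tsv").write_text(format_table(rows))
    print("recomputed content table -> results/table_content.tsv")

    enrichment = {}
    for strain, published in PUBLISHED_SSV_FOLDS.items():
        rep = enrichment_ratios(build_row(strain, "scrapyard"), build_row(strain, "outside"))
        m = rep.metrics["SSV"]
        enrichment[strain] = {
            "ssv_fold": round(m.fold, 2),
            "direction": m.direction,
            "published": published,
        }
        print(f"  {strain}: SSV {m.fold:.1f}x {m.direction} (published {published}x)")

    p_values = {}
    for name, (cat, kind) in {
        "functional_percent": ("FUNCTIONAL", "percent"),
        "hp_percent": ("HP", "percent"),
        "me_density": ("ME", "density"),
    }.items():
        res = mann_whitney_exact(
            printed_column("scrapyard", cat, kind), printed_column("outside", cat, kind)
        )
        p_values[name] = {"p": round(res.p_value, 5), "method": res.method}
        print(f"  rank test {name}: p = {res.p_value:.4f} ({res.method})")
    (RESULTS / "enrichment.json").write_text(
        json.dumps({"ssv_folds": enrichment, "rank_tests": p_values}, indent=2) + "\n"
    )
    print("wrote results/enrichment.json")

    if not (SIM / "genes.gff3").is_file():
        print("no scratch/sim data; skipping simulated-island detection")
        return
    from magpop.core_io import read_fasta, read_features, read_regions
    from magpop.ssv import read_vcf

    contig = read_fasta(SIM / "genome.fasta")[0]
    features = read_features(SIM / "genes.gff3")
    anchored = delimit_by_anchors(features, "tRNA-Ser-CGA", "tRNA-Val-CAC")
    variants = read_vcf(str(SIM / "ssv_calls.vcf")) if (SIM / "ssv_calls.vcf").is_file() else None
    islands = detect_scrapyards(len(contig), features, variants, contig=contig.id)
    (truth_region,) = read_regions(SIM / "truth_regions.bed")
    print(f"anchored region: [{anchored.start}, {anchored.end}) "
          f"(Jaccard vs truth {jaccard(anchored, truth_region):.3f})")
    for isl in islands:
        print(f"de novo island: [{isl.start}, {isl.end}) "
              f"(Jaccard vs truth {jaccard(isl, truth_region):.3f})")
    inside, outside = region_content_stats(features, variants, anchored, len(contig))
    (RESULTS / "sim_table_content.tsv").write_text(format_table([inside, outside]))
    with open(RESULTS / "sim_islands.bed", "w") as fh:
        for isl in islands:
            fh.write(f"{isl.contig}\t{isl.start}\t{isl.end}\t{isl.label}\n")
    print("wrote results/sim_table_content.tsv, results/sim_islands.bed")


if __name__ == "__main__":
    main()
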