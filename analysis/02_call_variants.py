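#!/usr/bin/env python
"""Call SSVs and IS insertions on the simulated reads and score them.

Runs the pileup SSV caller on the short-read truth alignments and the
long-read insertion caller (signal extraction, clustering, library
classification, disruption assignment), then scores both against the
planted truth.  Expects scratch/sim/ from 01_simulate_population.py.

    python analysis/02_call_variants.py
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from magpop.core_io import read_alignments, read_fasta, read_features
from magpop.insertions import annotate_calls, cluster_and_call, collect_insertion_signals, write_insertion_vcf
from magpop.ssv import call_ssv, ssv_orf_fraction, write_vcf

SIM = Path("scratch/sim")


def load_truth_insertions():
    rows = []
    with open(SIM / "truth_insertions.tsv") as fh:
        header = fh.readline().strip().split("\t")
        for line in fh:
            rows.append(dict(zip(header, line.strip().split("\t"))))
    return rows


def main():
    contig = read_fasta(SIM / "genome.fasta")[0]
    features = read_features(SIM / "genes.gff3")
    library = {c.id: c.sequence for c in read_fasta(SIM / "elements.fasta")}

    print("SSV calling (pileup, default thresholds) ...")
    calls = call_ssv(read_alignments(str(SIM / "truth_short.sam")), contig.sequence, contig.id)
    write_vcf(calls, str(SIM / "ssv_calls.vcf"), contig.id, len(contig))
    truth = {}
    for line in open(SIM / "truth_ssv.vcf"):
        if line.startswith("#"):
            continue
        c = line.split("\t")
        truth[(int(c[1]) - 1, c[3], c[4])] = float(c[7].split("AF=")[1])
    call_keys = {(v.position, v.ref, v.alt) for v in calls}
    target = {k for k, f in truth.items() if f >= 0.1}
    recall = len(call_keys & target) / len(target)
    precision = len(call_keys & set(truth)) / len(call_keys)
    orf_frac = ssv_orf_fraction(calls, features)
    print(f"  {len(calls)} calls; recall {recall:.3f} (truth AF>=0.1), "
          f"precision {precision:.3f}, {orf_frac:.0%} inside ORFs")

    print("insertion calling (long-read signals, >=2 supporting reads) ...")
    signals, retained = collect_insertion_signals(read_alignments(str(SIM / "truth_long.sam")))
    ins_calls = cluster_and_call(signals, retained)
    annotate_calls(ins_calls, library, features)
    write_insertion_vcf(ins_calls, str(SIM / "insertion_calls.vcf"), len(contig))
    truth_ins = load_truth_insertions()
    hits = 0
    for row in truth_ins:
        bp = int(row["breakpoint"])
        if any(abs(c.breakpoint - bp) <= 20 for c in ins_calls):
            hits += 1
    variable = [c for c in ins_calls if c.is_variable]
    print(f"  {len(ins_calls)} calls ({len(variable)} variable) for "
          f"{len(truth_ins)} planted; breakpoint hits (+-20 bp): {hits}")
    for c in ins_calls:
        print(f"    {c.breakpoint}  {c.classification:10s} {c.disruption_class:15s} "
              f"{c.variability}  support {c.supporting}/{c.spanning}")

    results = Path("results")
    results.mkdir(exist_ok=True)
    metrics = {
        "ssv_calls": len(calls),
        "ssv_recall_af_ge_0.1": round(recall, 4),
        "ssv_precision": round(precision, 4),
        "ssv_orf_fraction": round(orf_frac, 4),
        "insertion_calls": len(ins_calls),
        "insertion_breakpoint_hits": hits,
        "variable_insertions": len(variable),
        "variable_by_class": {
            cls: sum(1 for c in variable if c.disruption_class == cls)
            for cls in ("FUNCTIONAL-GENE", "HP", "ME/PHAGE", "INTERGENIC")
        },
    }
    (results / "calling_metrics.json").write_text(json.dumps(metrics, indent=2) + "\n")
    print("wrote results/calling_metrics.json")


if __name__ == "__main__":
    main()
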