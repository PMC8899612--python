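#!/usr/bin/env python
"""Short-read junction genotyping of the called IS insertions.

For every insertion call of 02_call_variants.py, builds the junction
diagnostic sequences and counts short reads supporting the disrupted (y)
versus intact (n) allele; y/n estimates f/(1-f) for an insertion at
population frequency f.  Compares the estimates with the planted truth.

    python analysis/04_junction_ratios.py
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from magpop.core_io import read_alignments, read_fasta
from magpop.insertions import InsertionCall, genotype_junctions, reads_near

SIM = Path("scratch/sim")
RESULTS = Path("results")


def main():
    contig = read_fasta(SIM / "genome.fasta")[0]
    truth = []
    with open(SIM / "truth_insertions.tsv") as fh:
        header = fh.readline().strip().split("\t")
        for line in fh:
            truth.append(dict(zip(header, line.strip().split("\t"))))

    print("loading short-read alignments ...")
    short_alns = list(read_alignments(str(SIM / "truth_short.sam")))

    lines = ["breakpoint\ttruth_frequency\ty\tn\tratio\texpected_ratio\tformatted"]
    print(f"{'breakpoint':>10} {'f':>5} {'y':>4} {'n':>4} {'y/n':>6} {'f/(1-f)':>8}  report")
    for row in truth:
        bp = int(row["breakpoint"])
        f = float(row["frequency"])
        call = InsertionCall("chr", bp, row_sequence(row), 2, 2)
        reads = reads_near(short_alns, bp)
        try:
            assay = genotype_junctions(call, reads, contig.sequence)
        except ValueError as exc:
            print(f"{bp:>10} {f:>5.2f}  skipped: {exc}")
            continue
        expected = f / (1 - f) if f < 1 else float("inf")
        ratio = "" if assay.ratio is None else f"{assay.ratio:.2f}"
        print(f"{bp:>10} {f:>5.2f} {assay.disrupted:>4} {assay.intact:>4} "
              f"{ratio:>6} {expected:>8.2f}  {assay.formatted()}")
        lines.append(
            f"{bp}\t{f:.2f}\t{assay.disrupted}\t{assay.intact}\t{ratio}\t"
            f"{expected:.3f}\t{assay.formatted()}"
        )
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "junction_ratios.tsv").write_text("\n".join(lines) + "\n")
    print("wrote results/junction_ratios.tsv")


def row_sequence(row):
    # truth consensus: the element plus its target-site duplication is not
    # stored in the TSV; rebuild it from the element library and reference
    from magpop.core_io import read_fasta

    library = {c.id: c.sequence for c in read_fasta(SIM / "elements.fasta")}
    contig = read_fasta(SIM / "genome.fasta")[0]
    element = library[row["element_id"]]
    bp = int(row["breakpoint"])
    tsd = int(row["tsd_length"])
    return element + contig.sequence[bp - tsd : bp]


if __name__ == "__main__":
    main()
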