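# Methods

This note documents the models, parameter choices and numerical conventions
behind `magpop`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Coordinate and counting conventions

All in-memory intervals are 0-based half-open; GFF3 and VCF are read and
written 1-based. Genes are counted "in" a region by their **start**
position, and tRNA/rRNA genes are excluded from ORF totals. Anchored
regions are exclusive of both anchors: from the end of the left tRNA to the
start of the right one; the region length printed in content tables is
`end − start` under this convention. A multi-base variant counts once, at
its left VCF anchor, toward all densities.

Published content-table rows can be rebuilt from their printed counts with
`stats_row_from_counts`; one published row (S2.4, outside) carries an ORF
total larger than the sum of its four category counts, so the function
accepts an explicit total — percentages then divide by the printed total,
exactly as published. Pipeline-computed rows always satisfy
counts-sum-to-total.

## Synthetic population model

`magpop.simulate` generates the study conditions end to end. Defaults are
the conditions the analysis models:

| parameter | default | rationale |
|---|---|---|
| genome length | 2,749,106 bp, circular | matches the modeled chromosome |
| GC | 0.541 | observed genome GC |
| skew amplitude | 0.15 | gives an unambiguous two-replichore sign pattern |
| scrapyard | [32,353, 226,192) | the anchored island; length 193,839 bp |
| ORF proportions inside | HP .717 / phage .037 / ME .090 / functional .156 | island content row |
| ORF proportions outside | .374 / .005 / .042 / .579 | outside content row |
| gene lengths | lognormal, median 800 bp, σ=0.45, gap ~Exp(100 bp) | ~1 kb per gene incl. gap, matching observed ORF density |
| SSV rate | 11.9 / 1.77 per 10 kbp (inside/outside), Poisson | SSV density rows |
| SSV spectrum | 80% SNV, 10% ins, 10% del; indel length ~ min(Geom(0.4), 139) | "mostly 1 bp, sporadically up to ~139 bp" |
| allele frequencies | Uniform(0.05, 0.95), realized as k/20 carriers | no published spectrum; a modeling choice |
| haplotypes | 20 equally abundant lineages | linked variants co-occur as in a clonal population |
| IS elements | 3 elements (1.0–1.45 kb) with 15–25 bp terminal inverted repeats; insertion adds a 4–8 bp target-site duplication | IS biology; junction assays face realistic micro-homology |
| long reads | 20×, lognormal mean 9 kb, sub/ins/del 2%/3%/4% | nanopore-like error mix |
| short reads | 50×, 2×250 bp, insert N(700, 70), 0.3% substitutions | paired-end short-read model |

The two replichores are G-rich on the leading strand with the origin at 0
and terminus at L/2; inside the scrapyard, per-kilobase skew signs are
randomized — this is the generator's operationalization of "scattered"
skew. Scrapyard anchors (tRNA-Ser-CGA / tRNA-Val-CAC) are placed flush
with the island so anchor delimitation recovers it exactly.

Reads are sampled per haplotype through an alignment-column representation
(per-column CIGAR op, query base and reference position), so the truth SAM
CIGARs expose planted insertions as I ops, or soft clips for reads ending
inside an element, with injected sequencing errors spliced into the same
column arrays. Insertion/intergenic target sites keep ≥ min(10 kb, L/10)
from the linearized ends, where long-read coverage ramps up from zero.

**What the generator does not emulate:** genes are annotation-only
intervals (the underlying sequence has no codon structure); no homopolymer-
specific or signal-level nanopore errors; no contaminating species; no
mapper — the truth SAM stands in for one, though the callers accept any SAM.
Passing tests therefore demonstrate the callers' logic under the stated
error models, not robustness to mapper artifacts or cross-species read
recruitment.

## SSV caller

Per-position allele counts over M/=/X columns (bases under quality 10
ignored when qualities are present); indels keyed by left-anchored
position; a call needs depth ≥ 10, alt support ≥ 2, alt fraction ≥ 0.1;
indels are capped at 200 bp. Raising any threshold can only shrink the
call set. The caller is deliberately a pileup, not a local reassembler:
the downstream statistics consume positions and counts, and a transparent
counting model makes the truth comparison exact. VCF ingest
(`ssv.read_vcf`) provides parity with external callers.

## Insertion caller

Signals: CIGAR I ops ≥ 10 bp anchored at their reference offset, soft
clips ≥ 100 bp anchored at the aligned end, from reads ≥ 1000 bp (the
long-read length filter). Signals within 100 bp single-link into one
cluster; the breakpoint is the median signal position. Supporting = number
of distinct signal-bearing reads; spanning = distinct reads covering
breakpoint ± 50 bp without a signal there. A call requires support ≥ 2 and
is *variable* iff min(supporting, spanning) ≥ 2 — both alleles seen at
least twice. The consensus insert is the medoid by edit distance of the
cluster's signal sequences (capped at the 12 longest); breakpoint accuracy
rather than a polished consensus is what classification needs.
Classification is best local alignment (match 2, mismatch −3, gap −5/−2)
against the element library on both strands, accepting ≥ 80% identity over
≥ 50% of the consensus.

Disruption classes: a breakpoint inside a functional gene (or structural
RNA) counts toward the headline disruption totals; HP hits are tallied
separately (published practice on whether HP disruptions belong in headline
counts is ambiguous, so both totals are reported); ME/phage hits and
intergenic insertions are excluded from totals but still reported.

## Junction genotyping

For a call at breakpoint b with consensus insert E, three diagnostic
sequences are built with flank 50 bp: left junction (ref[b−50:b] + E
start), right junction (E end + ref[b:b+50]) and the intact
flank-through-flank. A read supports an allele when it contains, in either
orientation, the 2k-mer core centered on the junction point (k =
min_overlap = 20 on each side), exactly or within 10% edits (edlib), which
tolerates read errors and an imperfect consensus.

The ratio y/n is taken at a **single** junction (left by default, right
when the left flank is unavailable; the other junction's count is reported
separately). Counting reads at *either* junction would give the disrupted
allele twice the detection opportunity of the intact allele and bias y/n
toward 2f/(1−f); the single-junction assay makes y/n an unbiased estimate
of f/(1−f), which is the interpretation the disruption-ratio table rests
on. Formatting follows that table: `y/n = 0.32`, `n (0/114)` when no
disrupted reads are found, and a `fixed` flag when no intact reads are.

## Scrapyard detection

Sliding windows (10 kbp, step 2 kbp) are scored on three criteria: HP
proportion ≥ 0.55, ME+phage density ≥ 1.0 per 10 kbp, and SSV density ≥ 3×
the genome-median window density (plus optional skew-scatter corroboration
at ≥ 2× the genome background flip fraction). A window is island-like when
it passes the HP criterion plus at least one other. Because a 10-kbp
window holds only ~10 ORFs, isolated windows pass by composition noise
alone; only runs of ≥ 3 consecutive passing windows count, runs merge
across gaps ≤ 20 kbp, and islands < 50 kbp are dropped.

Window grids quantize boundaries to half a window and edge windows fail
stochastically, so coarse edges are refined by a changepoint scan: 1-kbp
bins within ±20 kbp of each edge are scored by the log-likelihood ratio of
the island versus background model — binomial for ORF HP labels plus
Poisson for SSV positions, with both models estimated from the coarse
segmentation — and the boundary moves to the score-maximizing cut. On
planted full-scale simulations this lifts boundary Jaccard overlap from
0.88–0.98 to ≈ 0.99. Detection is monotone: relaxing any threshold never
shrinks reported island coverage.

All thresholds live in `DetectionParams`; the criteria themselves are this
package's operationalization of the island phenotype (content depletion,
mobilome accumulation, SSV concentration, scattered skew) — chosen to
separate the published inside/outside values by a wide margin, not fitted
to any dataset.

## Statistics kernels

**Mann–Whitney U.** Exact two-sided p by full enumeration of the U
distribution (rank-subset dynamic program) when there are no ties and
m+n ≤ 20; otherwise the normal approximation with tie-corrected variance
and continuity correction. This reproduces the reference statistical
environment's `wilcox.test` switching behavior, including the published
p = 0.012 case where a printed-value tie forces the approximation.

**NG86 dN/dS.** Per-codon synonymous site fractions (changes to stops
count as nonsynonymous), averaged over both sequences; multi-substitution
codons average differences over all minimal mutational pathways, excluding
pathways through stop codons unless all pass through one; Jukes–Cantor
correction d = −(3/4)·ln(1 − 4p/3) applied to pN and pS; the ratio is
flagged undefined when dS = 0 or a correction saturates. A trailing stop
codon pair is dropped from the accounting.

**GC skew.** (G−C)/(G+C) per window; windows without G or C get value 0
and sign 0; circular mode wraps. The "scatter" statistic is the fraction
of adjacent nonzero-sign window pairs that flip — 0 for clean replichores,
~0.5 for random signs.

## Problem sizes

Unit and property tests simulate 150–750 kb genomes (the session fixture:
300 kb with a 60 kb island at full coverage conditions); the acceptance
script runs the full 2,749,106 bp population at 20× long + 50× short
coverage, which completes in about a minute. Junction-ratio convergence is
measured at 200× short coverage, pooling ten replicate loci so the
estimator's binomial noise is well below the quantity compared.

## Known limitations

* The callers are exercised against truth alignments; with a real mapper,
  reference-allele bias and multi-mapping around repeated IS copies would
  add error modes the tests do not measure.
* The pileup SSV caller reports one alternative per allele and position; it
  does not phase nearby SSVs or realign indels, so homopolymer-adjacent
  indel representation may differ from reassembly-based callers.
* De novo detection assumes one dominant HP-enrichment scale (10 kbp
  windows); islands much shorter than 50 kbp are deliberately out of scope.
* The exact Mann–Whitney branch is limited to m+n ≤ 20 (beyond that the
  normal approximation is used, as in the reference environment).
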