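"""Polymorphic mobile-element insertion calling from long reads.

Signal extraction mirrors long-read SV callers run at high sensitivity
(minimum 2 supporting reads, minimum event length 10 bp, minimum read
length 1000 bp): every sufficiently long CIGAR insertion op and every long
soft clip is a candidate signal.  Signals are clustered by breakpoint
proximity; each cluster is genotyped against the reads that span the
breakpoint cleanly, classified against a user-supplied IS element library,
assigned a gene-disruption class, and finally genotyped from short reads
via junction sequences (the disruption ratio y/n of reads supporting the
disrupted versus the intact allele).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np
from Bio import Align

from magpop.core_io import (
    AlignmentRecord,
    GeneFeature,
    Category,
    reverse_complement,
)

VARIABLE = "variable"
POSSIBLY_NON_VARIABLE = "possibly-non-variable"

DISRUPT_FUNCTIONAL = "FUNCTIONAL-GENE"
DISRUPT_HP = "HP"
DISRUPT_SELFISH = "ME/PHAGE"
DISRUPT_INTERGENIC = "INTERGENIC"


@dataclass
class InsertionSignal:
    read_id: str
    contig: str
    breakpoint: int
    kind: str  # cigar-insertion | left-clip | right-clip
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class InsertionCall:
    contig: str
    breakpoint: int
    consensus: str
    supporting: int
    spanning: int
    classification: str = "UNKNOWN"  # "ME:<element>" or "UNKNOWN"
    disrupted_feature: str | None = None
    disruption_class: str = DISRUPT_INTERGENIC
    variability: str = POSSIBLY_NON_VARIABLE
    signals: list[InsertionSignal] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.consensus)

    @property
    def is_variable(self) -> bool:
        return self.variability == VARIABLE


def collect_insertion_signals(
    alignments: Iterable[AlignmentRecord],
    min_len: int = 10,
    min_clip: int = 100,
    min_read_length: int = 1000,
) -> tuple[list[InsertionSignal], list[AlignmentRecord]]:
    """Extract insertion signals from long-read alignments.

    Every CIGAR I op of at least ``min_len`` bases yields a signal at its
    reference anchor; soft clips of at least ``min_clip`` bases yield clip
    signals at the aligned end they hang off.  Reads shorter than
    ``min_read_length`` are ignored entirely.  Returns the signals plus
    the retained alignments (needed downstream for spanning-read counts).
    """
    signals: list[InsertionSignal] = []
    retained: list[AlignmentRecord] = []
    for rec in alignments:
        if rec.query_length() < min_read_length:
            continue
        retained.append(rec)
        rpos = rec.ref_start
        qpos = 0
        n_ops = len(rec.cigar)
        for k, (op, ln) in enumerate(rec.cigar):
            if op in "M=X":
                rpos += ln
                qpos += ln
            elif op == "I":
                if ln >= min_len:
                    signals.append(
                        InsertionSignal(
                            rec.read_id,
                            rec.contig,
                            rpos,
                            "cigar-insertion",
                            rec.seq[qpos : qpos + ln],
                        )
                    )
                qpos += ln
            elif op == "D" or op == "N":
                rpos += ln
            elif op == "S":
                if ln >= min_clip:
                    kind = "left-clip" if k == 0 else "right-clip"
                    anchor = rec.ref_start if k == 0 else rpos
                    signals.append(
                        InsertionSignal(
                            rec.read_id, rec.contig, anchor, kind, rec.seq[qpos : qpos + ln]
                        )
                    )
                qpos += ln
            # H/P consume nothing we track
    return signals, retained


def _medoid(sequences: list[str]) -> str:
    """Sequence minimizing total edit distance to the others."""
    if len(sequences) == 1:
        return sequences[0]
    # cap the pool for O(n^2) distance work; longest signals carry the
    # most complete element copy
    pool = sorted(sequences, key=len, reverse=True)[:12]
    best, best_total = pool[0], float("inf")
    for cand in pool:
        total = 0
        for other in pool:
            if other is cand:
                continue
            total += edlib.align(cand, other)["editDistance"]
        if total < best_total:
            best, best_total = cand, total
    return best


def cluster_and_call(
    signals: Sequence[InsertionSignal],
    alignments: Sequence[AlignmentRecord],
    cluster_window: int = 100,
    margin: int = 50,
    min_support: int = 2,
) -> list[InsertionCall]:
    """Cluster signals by breakpoint proximity and emit insertion calls.

    Per cluster: ``supporting`` counts distinct signal-bearing reads,
    ``spanning`` counts distinct reads covering breakpoint +/- ``margin``
    with no signal there, the consensus inserted sequence is the medoid
    (by edit distance) of the cluster's signal sequences, and the
    variability flag applies the >= 2 minor-variant-read rule: a call is
    ``variable`` only when both the insertion-bearing and the intact
    allele are seen in at least two reads.
    """
    if not signals:
        return []
    ordered = sorted(signals, key=lambda s: (s.contig, s.breakpoint))
    clusters: list[list[InsertionSignal]] = [[ordered[0]]]
    for sig in ordered[1:]:
        prev = clusters[-1][-1]
        if sig.contig == prev.contig and sig.breakpoint - prev.breakpoint <= cluster_window:
            clusters[-1].append(sig)
        else:
            clusters.append([sig])

    # alignment extents for spanning-read queries
    by_contig: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for contig in {s.contig for s in ordered}:
        recs = [r for r in alignments if r.contig == contig]
        starts = np.array([r.ref_start for r in recs], dtype=np.int64)
        ends = np.array([r.ref_end for r in recs], dtype=np.int64)
        by_contig[contig] = (starts, ends, [r.read_id for r in recs])

    calls: list[InsertionCall] = []
    for cluster in clusters:
        contig = cluster[0].contig
        bps = sorted(s.breakpoint for s in cluster)
        breakpoint = int(bps[len(bps) // 2])
        support_reads = {s.read_id for s in cluster}
        if len(support_reads) < min_support:
            continue
        starts, ends, read_ids = by_contig[contig]
        covering = (starts <= breakpoint - margin) & (ends >= breakpoint + margin)
        spanning_reads = {
            read_ids[i] for i in np.flatnonzero(covering)
        } - support_reads
        consensus = _medoid([s.sequence for s in cluster])
        supporting = len(support_reads)
        spanning = len(spanning_reads)
        variability = (
            VARIABLE if min(supporting, spanning) >= min_support else POSSIBLY_NON_VARIABLE
        )
        calls.append(
            InsertionCall(
                contig=contig,
                breakpoint=breakpoint,
                consensus=consensus,
                supporting=supporting,
                spanning=spanning,
                variability=variability,
                signals=list(cluster),
            )
        )
    calls.sort(key=lambda c: (c.contig, c.breakpoint))
    return calls


# ---------------------------------------------------------------------------
# Classification against an element library


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def _local_identity(aligner: Align.PairwiseAligner, query: str, target: str):
    """(identity over aligned columns, fraction of query aligned, score)."""
    if not query or not target:
        return 0.0, 0.0, 0.0
    aln = aligner.align(query, target)
    if len(aln) == 0:
        return 0.0, 0.0, 0.0
    best = aln[0]
    qblocks, tblocks = best.aligned
    matches = 0
    aligned_cols = 0
    qspan = 0
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        aligned_cols += qe - qs
        qspan += qe - qs
        matches += sum(1 for a, b in zip(query[qs:qe], target[ts:te]) if a == b)
    if aligned_cols == 0:
        return 0.0, 0.0, 0.0
    return matches / aligned_cols, qspan / len(query), best.score


def classify_insertion(
    call: InsertionCall,
    library: dict[str, str],
    min_identity: float = 0.8,
    min_cov: float = 0.5,
) -> str:
    """Classify the consensus inserted sequence against an ME library.

    Best local alignment over both strands of each element; returns
    ``"ME:<element>"`` when identity >= ``min_identity`` over at least
    ``min_cov`` of the consensus length, else ``"UNKNOWN"``.
    """
    if not library:
        raise ValueError("empty element library")
    if not call.consensus:
        warnings.warn(f"call at {call.breakpoint}: empty consensus; classified UNKNOWN")
        return "UNKNOWN"
    aligner = _make_aligner()
    best_name, best_score = None, 0.0
    for name, element in library.items():
        for target in (element, reverse_complement(element)):
            identity, cov, score = _local_identity(aligner, call.consensus, target)
            if identity >= min_identity and cov >= min_cov and score > best_score:
                best_name, best_score = name, score
    return f"ME:{best_name}" if best_name else "UNKNOWN"


# ---------------------------------------------------------------------------
# Disruption assignment


def assign_disruption(
    call: InsertionCall, features: Sequence[GeneFeature]
) -> tuple[str, str | None]:
    """(disruption class, disrupted feature id) for an insertion call.

    Breakpoint inside a FUNCTIONAL gene (or a structural RNA) counts
    toward the headline disruption totals; HP hits are reported
    separately; hits inside ME/phage features and intergenic insertions
    are excluded from the totals.
    """
    for f in features:
        if f.contig == call.contig and f.start <= call.breakpoint < f.end:
            if f.category in (Category.ME, Category.PHAGE):
                return DISRUPT_SELFISH, f.id
            if f.category is Category.HP:
                return DISRUPT_HP, f.id
            return DISRUPT_FUNCTIONAL, f.id
    return DISRUPT_INTERGENIC, None


def annotate_calls(
    calls: Sequence[InsertionCall],
    library: dict[str, str],
    features: Sequence[GeneFeature],
    min_identity: float = 0.8,
    min_cov: float = 0.5,
) -> None:
    """Classify and assign disruption status for every call, in place."""
    ordered = sorted(features, key=lambda f: f.start)
    for call in calls:
        call.classification = classify_insertion(call, library, min_identity, min_cov)
        call.disruption_class, call.disrupted_feature = assign_disruption(call, ordered)


# ---------------------------------------------------------------------------
# Junction genotyping from short reads


@dataclass
class JunctionAssay:
    """Disruption-ratio genotyping of one insertion from short reads.

    ``disrupted`` (y) counts distinct reads spanning the assayed element
    junction; ``intact`` (n) counts reads spanning the same anchor on the
    uninterrupted allele.  Because both alleles are assayed at one and
    the same junction point, ``ratio`` y/n is an unbiased estimate of
    f/(1-f) for an insertion at population frequency f.  The counts at
    the non-assayed junction are kept in ``disrupted_other``.
    """

    breakpoint: int
    disrupted: int
    intact: int
    junction: str = "left"
    disrupted_other: int = 0

    @property
    def ratio(self) -> float | None:
        return self.disrupted / self.intact if self.intact > 0 else None

    @property
    def frequency_estimate(self) -> float | None:
        total = self.disrupted + self.intact
        return self.disrupted / total if total else None

    def formatted(self) -> str:
        if self.disrupted == 0:
            return f"n (0/{self.intact})"
        if self.intact == 0:
            return f"fixed ({self.disrupted}/0)"
        return f"y/n = {self.ratio:.2f}"


def _matches(core: str, read: str, max_edits: int) -> bool:
    if core in read:
        return True
    if max_edits <= 0:
        return False
    return edlib.align(core, read, mode="HW", k=max_edits)["editDistance"] >= 0


def genotype_junctions(
    call: InsertionCall,
    short_reads: Iterable[str],
    reference: str,
    flank: int = 50,
    min_overlap: int = 20,
    max_edit_fraction: float = 0.1,
) -> JunctionAssay:
    """Count short reads supporting the disrupted versus intact allele.

    Builds three diagnostic sequences around the breakpoint — left flank +
    element start, element end + right flank, and the intact
    flank-through-flank — and scores reads containing (in either
    orientation) a junction-spanning core with ``min_overlap`` bases on
    both sides of the junction point; up to ``max_edit_fraction`` of the
    core may mismatch, tolerating sequencing errors and an imperfect
    consensus.  The ratio is taken at a single junction (left by default;
    right when the left flank is unavailable) so that y/n estimates
    f/(1-f) without the double counting a two-junction tally would add.
    """
    if not call.consensus:
        raise ValueError("call has no consensus sequence")
    bp = call.breakpoint
    cons = call.consensus
    k = min_overlap
    if len(cons) < k:
        raise ValueError(f"consensus shorter than min_overlap ({len(cons)} < {k})")
    junction = "left" if bp >= k else "right"
    left_core = reference[max(0, bp - k) : bp] + cons[:k]
    right_core = cons[-k:] + reference[bp : bp + k]
    intact_core = reference[max(0, bp - k) : bp + k]
    primary = left_core if junction == "left" else right_core
    secondary = right_core if junction == "left" else left_core
    max_edits = max(1, int(max_edit_fraction * 2 * k))

    y = n = other = 0
    for read in short_reads:
        rc = reverse_complement(read)
        if _matches(primary, read, max_edits) or _matches(primary, rc, max_edits):
            y += 1
        elif _matches(intact_core, read, max_edits) or _matches(intact_core, rc, max_edits):
            n += 1
        elif _matches(secondary, read, max_edits) or _matches(secondary, rc, max_edits):
            other += 1
    if y == 0 and n == 0:
        raise ValueError(f"no short-read coverage at breakpoint {bp}")
    return JunctionAssay(bp, y, n, junction, other)


def reads_near(
    alignments: Iterable[AlignmentRecord], breakpoint: int, window: int = 1000
) -> list[str]:
    """Read sequences whose alignment touches breakpoint +/- window
    (convenience filter so junction genotyping need not scan every read)."""
    lo, hi = breakpoint - window, breakpoint + window
    return [
        rec.seq for rec in alignments if rec.ref_start <= hi and rec.ref_end >= lo
    ]


# ---------------------------------------------------------------------------
# VCF output


def write_insertion_vcf(
    calls: Sequence[InsertionCall], path: str, contig_length: int = 0
) -> None:
    """SVTYPE=INS records with INFO SUPPORT/SPANNING/CLASS/DISRUPT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if calls and contig_length:
            fh.write(f"##contig=<ID={calls[0].contig},length={contig_length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Insertion length">\n')
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Insertion-bearing reads">\n')
        fh.write('##INFO=<ID=SPANNING,Number=1,Type=Integer,Description="Clean spanning reads">\n')
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="Element classification">\n')
        fh.write('##INFO=<ID=DISRUPT,Number=1,Type=String,Description="Disruption class">\n')
        fh.write('##INFO=<ID=VARIABLE,Number=1,Type=String,Description="Variability flag">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(calls, 1):
            fh.write(
                f"{c.contig}\t{c.breakpoint + 1}\tins{i}\tN\t<INS>\t.\tPASS\t"
                f"SVTYPE=INS;SVLEN={c.length};SUPPORT={c.supporting};"
                f"SPANNING={c.spanning};CLASS={c.classification};"
                f"DISRUPT={c.disruption_class};VARIABLE={c.variability}\n"
            )


__all__ = [
    "DISRUPT_FUNCTIONAL",
    "DISRUPT_HP",
    "DISRUPT_INTERGENIC",
    "DISRUPT_SELFISH",
    "InsertionCall",
    "InsertionSignal",
    "JunctionAssay",
    "POSSIBLY_NON_VARIABLE",
    "VARIABLE",
    "annotate_calls",
    "assign_disruption",
    "classify_insertion",
    "cluster_and_call",
    "collect_insertion_signals",
    "genotype_junctions",
    "reads_near",
    "write_insertion_vcf",
]
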