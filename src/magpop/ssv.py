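"""Short sequence variant (SSV) calling and regional distribution.

A transparent pileup caller over short-read alignments: per-column allele
counting for substitutions, left-anchored counting for indels taken from
CIGAR I/D ops.  Variants are population polymorphisms of a clonal
metagenome — there is no diploid genotype model; the alt read fraction is
the allele-frequency estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from magpop.core_io import AlignmentRecord, GeneFeature, Region

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASE_CODES):
    _CODE_OF[_b] = _i


@dataclass
class CallerThresholds:
    """Pileup caller cutoffs; all config-exposed.

    ``max_indel_length`` caps reportable indels (default 200, covering
    the longest short variants seen in real populations of this kind,
    ~139 bp)."""

    min_depth: int = 10
    min_alt_support: int = 2
    min_alt_fraction: float = 0.1
    min_base_quality: int = 10
    max_indel_length: int = 200


@dataclass
class ShortVariant:
    """An intrapopulation substitution or short indel.

    ``position`` is the 0-based VCF-style anchor; ``ref``/``alt`` follow
    VCF conventions (anchor base included for indels)."""

    contig: str
    position: int
    ref: str
    alt: str
    variant_class: str  # SNV | insertion | deletion | MNV
    depth: int
    alt_support: int

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("alt equals ref")
        if not 1 <= self.alt_support <= max(self.depth, 1):
            raise ValueError("alt support must be in [1, depth]")

    @property
    def alt_fraction(self) -> float:
        return self.alt_support / self.depth if self.depth else 0.0


def _variant_class(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNV"
    if len(ref) < len(alt) and alt.startswith(ref):
        return "insertion"
    if len(ref) > len(alt) and ref.startswith(alt):
        return "deletion"
    return "MNV"


def call_ssv(
    alignments: Iterable[AlignmentRecord],
    reference: str,
    contig: str = "chr",
    thresholds: CallerThresholds | None = None,
) -> list[ShortVariant]:
    """Call SSVs from short-read alignments against ``reference``.

    Substitutions come from per-position base counting over M/=/X ops
    (bases below ``min_base_quality`` are ignored when qualities are
    present); insertions and deletions are keyed by their left-anchored
    reference position.  One variant is emitted per alternative allele
    passing the depth/support/fraction thresholds.  Deterministic for a
    fixed input stream.
    """
    th = thresholds or CallerThresholds()
    L = len(reference)
    counts = np.zeros((4, L), dtype=np.int32)
    indels: dict[tuple[int, str, str], int] = {}
    n_records = 0

    for rec in alignments:
        if rec.contig != contig:
            raise ValueError(f"alignment contig {rec.contig!r} != reference contig {contig!r}")
        n_records += 1
        seq_codes = _CODE_OF[np.frombuffer(rec.seq.encode(), dtype=np.uint8)]
        quals = np.asarray(rec.quals) if rec.quals is not None else None
        rpos = rec.ref_start
        qpos = 0
        for op, ln in rec.cigar:
            if op in "M=X":
                codes = seq_codes[qpos : qpos + ln]
                positions = np.arange(rpos, rpos + ln)
                ok = codes >= 0
                if quals is not None:
                    ok &= quals[qpos : qpos + ln] >= th.min_base_quality
                if ok.all():
                    np.add.at(counts, (codes, positions), 1)
                else:
                    np.add.at(counts, (codes[ok], positions[ok]), 1)
                rpos += ln
                qpos += ln
            elif op == "I":
                if 1 <= ln <= th.max_indel_length and 0 < rpos <= L:
                    anchor = rpos - 1
                    ins = rec.seq[qpos : qpos + ln]
                    key = (anchor, reference[anchor], reference[anchor] + ins)
                    indels[key] = indels.get(key, 0) + 1
                qpos += ln
            elif op == "D":
                if 1 <= ln <= th.max_indel_length and rpos > 0 and rpos + ln <= L:
                    anchor = rpos - 1
                    key = (anchor, reference[anchor : anchor + ln + 1], reference[anchor])
                    indels[key] = indels.get(key, 0) + 1
                rpos += ln
            elif op == "S":
                qpos += ln
            elif op in "HNP":
                if op == "N":
                    rpos += ln
            else:
                raise ValueError(f"unsupported CIGAR op {op!r}")

    if n_records == 0:
        warnings.warn("no aligned reads; returning empty call set")
        return []

    depth = counts.sum(axis=0)
    ref_codes = _CODE_OF[np.frombuffer(reference.encode(), dtype=np.uint8)]
    variants: list[ShortVariant] = []

    # substitutions: positions where some non-reference base has support
    alt_counts = counts.copy()
    valid_ref = ref_codes >= 0
    cols = np.flatnonzero(valid_ref)
    alt_counts[ref_codes[cols], cols] = 0
    candidate = np.flatnonzero((alt_counts >= th.min_alt_support).any(axis=0) & valid_ref)
    for pos in candidate:
        d = int(depth[pos])
        if d < th.min_depth:
            continue
        for code in range(4):
            if code == ref_codes[pos]:
                continue
            support = int(counts[code, pos])
            if support >= th.min_alt_support and support / d >= th.min_alt_fraction:
                variants.append(
                    ShortVariant(
                        contig,
                        int(pos),
                        reference[pos],
                        "ACGT"[code],
                        "SNV",
                        d,
                        support,
                    )
                )

    for (anchor, ref_allele, alt_allele), support in indels.items():
        d = int(depth[anchor])
        if d < th.min_depth or support < th.min_alt_support:
            continue
        if support / d < th.min_alt_fraction:
            continue
        variants.append(
            ShortVariant(
                contig,
                anchor,
                ref_allele,
                alt_allele,
                _variant_class(ref_allele, alt_allele),
                d,
                min(support, d),
            )
        )

    variants.sort(key=lambda v: (v.position, v.ref, v.alt))
    return variants


# ---------------------------------------------------------------------------
# Regional statistics


def ssv_region_density(variants: Sequence[ShortVariant], region: Region) -> float:
    """Variant count per 10 kbp inside ``region`` (anchor-position rule;
    a multi-base variant counts once).  Unrounded; round at reporting."""
    if len(region) <= 0:
        raise ValueError("zero-length region")
    count = sum(1 for v in variants if region.contains(v.position))
    return count * 10_000 / len(region)


def ssv_orf_fraction(
    variants: Sequence[ShortVariant], features: Sequence[GeneFeature]
) -> float:
    """Fraction of variants whose anchor lies inside a protein-coding
    feature interval."""
    if not variants:
        raise ValueError("empty variant list")
    orfs = [f for f in features if f.feature_type == "CDS"]
    if not orfs:
        return 0.0
    starts = np.array([f.start for f in sorted(orfs, key=lambda f: f.start)])
    ends = np.array([f.end for f in sorted(orfs, key=lambda f: f.start)])
    # ORFs are non-overlapping in this pipeline; binary search per variant
    inside = 0
    for v in variants:
        i = np.searchsorted(starts, v.position, side="right") - 1
        if i >= 0 and v.position < ends[i]:
            inside += 1
    return inside / len(variants)


# ---------------------------------------------------------------------------
# VCF in/out


def write_vcf(
    variants: Sequence[ShortVariant], path: str, contig: str = "chr", contig_length: int = 0
) -> None:
    """Write calls as VCF v4.2 (INFO: DP, AO, AF)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_length:
            fh.write(f"##contig=<ID={contig},length={contig_length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=AO,Number=1,Type=Integer,Description="Alt allele support">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Alt allele fraction">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(
                f"{v.contig}\t{v.position + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                f"DP={v.depth};AO={v.alt_support};AF={v.alt_fraction:.4f}\n"
            )


def read_vcf(path: str) -> list[ShortVariant]:
    """Ingest externally-called variants from a VCF (SNV/indel records).

    DP/AO are taken from INFO when present; records without them get
    depth = support = 1 so that downstream density statistics (which only
    use positions) are unaffected.
    """
    import pysam

    variants: list[ShortVariant] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                depth = int(rec.info.get("DP", 1))
                support = int(rec.info.get("AO", depth))
                variants.append(
                    ShortVariant(
                        rec.chrom,
                        rec.start,
                        rec.ref,
                        str(alt),
                        _variant_class(rec.ref, str(alt)),
                        max(depth, 1),
                        max(min(support, max(depth, 1)), 1),
                    )
                )
    return variants


__all__ = [
    "CallerThresholds",
    "ShortVariant",
    "call_ssv",
    "read_vcf",
    "ssv_orf_fraction",
    "ssv_region_density",
    "write_vcf",
]
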