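"""Domain types, coordinate conventions, and readers/writers.

All in-memory coordinates are 0-based half-open; GFF3 and VCF are read and
written in their standard 1-based inclusive dialects.  Circular contigs are
linearized at position 0 for analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

import pysam


class Category(str, Enum):
    """Functional category of a gene feature.

    ``HP`` hypothetical protein, ``ME`` mobile element (transposases,
    integrases, ...), ``PHAGE`` phage protein, ``FUNCTIONAL`` everything
    else ("rest of ORF"), ``TRNA``/``RRNA`` structural RNA genes.
    """

    HP = "HP"
    ME = "ME"
    PHAGE = "PHAGE"
    FUNCTIONAL = "FUNCTIONAL"
    TRNA = "TRNA"
    RRNA = "RRNA"


#: Case-insensitive substring lexicon mapping product strings to categories.
#: Applied in priority order ME > PHAGE > HP; anything else is FUNCTIONAL.
#: Override by passing a custom mapping to :func:`classify_gene_category`.
DEFAULT_LEXICON: Mapping[str, tuple[str, ...]] = {
    "ME": (
        "transposase",
        "insertion sequence",
        "is element",
        " family transposase",
        "integrase",
        "resolvase",
        "mobile element",
        "recombinase",
    ),
    "PHAGE": ("phage", "capsid", "tail", "terminase", "portal"),
    "HP": ("hypothetical protein",),
}


def classify_gene_category(
    product: str,
    feature_type: str = "CDS",
    lexicon: Mapping[str, tuple[str, ...]] = DEFAULT_LEXICON,
) -> Category:
    """Assign a functional category from an annotation product string.

    Deterministic, case-insensitive substring rules in priority order
    ME > PHAGE > HP; unmatched products fall through to FUNCTIONAL.
    tRNA/rRNA are recognized from ``feature_type``, never from the product.
    """
    ft = feature_type.lower()
    if ft == "trna":
        return Category.TRNA
    if ft == "rrna":
        return Category.RRNA
    text = product.lower()
    for cat in ("ME", "PHAGE", "HP"):
        if any(kw in text for kw in lexicon.get(cat, ())):
            return Category[cat]
    return Category.FUNCTIONAL


@dataclass(frozen=True)
class Region:
    """Half-open interval [start, end) on a contig."""

    contig: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(
                f"region {self.label!r}: end ({self.end}) must exceed start ({self.start})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class GeneFeature:
    """One annotated gene: 0-based half-open interval plus product string."""

    id: str
    contig: str
    start: int
    end: int
    strand: str
    product: str
    category: Category
    feature_type: str = "CDS"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"feature {self.id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.id}: strand must be '+' or '-'")


@dataclass
class Contig:
    id: str
    sequence: str
    circular: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AnnotatedGenome:
    """Reference sequence(s) plus categorized gene features."""

    contigs: list[Contig]
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {c.id: len(c) for c in self.contigs}
        seen: set[str] = set()
        for f in self.features:
            if f.id in seen:
                raise ValueError(f"duplicate feature id {f.id!r}")
            seen.add(f.id)
            if f.contig not in lengths:
                raise ValueError(f"feature {f.id}: unknown contig {f.contig!r}")
            if f.end > lengths[f.contig]:
                raise ValueError(
                    f"feature {f.id}: end {f.end} beyond contig length {lengths[f.contig]}"
                )

    @property
    def length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)

    def gc_content(self) -> float:
        gc = sum(c.sequence.count("G") + c.sequence.count("C") for c in self.contigs)
        return gc / max(self.length, 1)

    def orfs(self) -> list[GeneFeature]:
        """Protein-coding features only (tRNA/rRNA excluded)."""
        return [f for f in self.features if f.category not in (Category.TRNA, Category.RRNA)]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str) -> list[Contig]:
    from Bio import SeqIO

    contigs = []
    for rec in SeqIO.parse(path, "fasta"):
        circular = "circular=true" in rec.description.lower()
        contigs.append(Contig(rec.id, str(rec.seq).upper(), circular))
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            topo = " circular=true" if c.circular else ""
            fh.write(f">{c.id}{topo}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

class GffParseError(ValueError):
    pass


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"malformed attribute {item!r}")
        key, value = item.split("=", 1)
        attrs[key] = value
    return attrs


def read_features(
    path: str, lexicon: Mapping[str, tuple[str, ...]] = DEFAULT_LEXICON
) -> list[GeneFeature]:
    """Read gene features from GFF3 (1-based inclusive on disk).

    Coordinates are converted to 0-based half-open; categories are assigned
    with :func:`classify_gene_category`.  Raises :class:`GffParseError`
    naming the offending line for malformed rows.
    """
    features: list[GeneFeature] = []
    counter = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GffParseError(f"{path} line {lineno}: expected 9 columns, got {len(cols)}")
            contig, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
                attrs = _parse_attributes(attr_s)
            except ValueError as exc:
                raise GffParseError(f"{path} line {lineno}: {exc}") from exc
            if end1 < start1:
                raise GffParseError(f"{path} line {lineno}: end {end1} < start {start1}")
            counter += 1
            product = attrs.get("product", "")
            features.append(
                GeneFeature(
                    id=attrs.get("ID", f"feature_{counter}"),
                    contig=contig,
                    start=start1 - 1,
                    end=end1,
                    strand=strand if strand in "+-" else "+",
                    product=product,
                    category=classify_gene_category(product, ftype, lexicon),
                    feature_type=ftype,
                )
            )
    return features


def write_features(features: Sequence[GeneFeature], path: str, source: str = "magpop") -> None:
    """Write features as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.id};product={f.product}"
            fh.write(
                "\t".join(
                    (
                        f.contig,
                        source,
                        f.feature_type,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED regions

def read_regions(path: str) -> list[Region]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            cols = line.rstrip("\n").split("\t")
            label = cols[3] if len(cols) > 3 else ""
            regions.append(Region(cols[0], int(cols[1]), int(cols[2]), label))
    return regions


def write_regions(regions: Iterable[Region], path: str) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.label}\n")


# ---------------------------------------------------------------------------
# SAM alignments

_CIGAR_OPS = "MIDNSHP=X"
_QUERY_CONSUMING = frozenset("MIS=X")
_REF_CONSUMING = frozenset("MDN=X")


@dataclass
class AlignmentRecord:
    """A mapped read: reference anchor plus parsed CIGAR and sequence."""

    read_id: str
    contig: str
    ref_start: int
    strand: str
    cigar: list[tuple[str, int]]
    seq: str
    quals: list[int] | None = None
    mapped: bool = True

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.cigar if op in _REF_CONSUMING)

    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in "MIS=X")


@dataclass
class AlignmentStats:
    """Counters for records skipped or rejected while streaming a SAM file."""

    parsed: int = 0
    skipped_unmapped: int = 0
    skipped_secondary: int = 0
    rejected: int = 0


def read_alignments(path: str, stats: AlignmentStats | None = None) -> Iterator[AlignmentRecord]:
    """Stream mapped primary alignments from a SAM file.

    Unmapped, secondary and supplementary records are skipped and counted;
    records whose CIGAR query length disagrees with the stored sequence are
    rejected with a warning.
    """
    stats = stats if stats is not None else AlignmentStats()
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        iterator = iter(sam)
        while True:
            try:
                rec = next(iterator)
            except StopIteration:
                break
            except OSError as exc:  # htslib aborts the stream on malformed records
                raise ValueError(f"SAM parse error in {path}: {exc}") from exc
            if rec.is_unmapped:
                stats.skipped_unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                stats.skipped_secondary += 1
                continue
            cigar = [(_CIGAR_OPS[op], n) for op, n in rec.cigartuples or []]
            seq = rec.query_sequence or ""
            qlen = sum(n for op, n in cigar if op in _QUERY_CONSUMING)
            if seq and qlen != len(seq):
                stats.rejected += 1
                warnings.warn(
                    f"read {rec.query_name}: CIGAR query length {qlen} != sequence length {len(seq)}"
                )
                continue
            stats.parsed += 1
            quals = list(rec.query_qualities) if rec.query_qualities is not None else None
            yield AlignmentRecord(
                read_id=rec.query_name,
                contig=rec.reference_name,
                ref_start=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                cigar=cigar,
                seq=seq,
                quals=quals,
            )


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


__all__ = [
    "AlignmentRecord",
    "AlignmentStats",
    "AnnotatedGenome",
    "Category",
    "Contig",
    "DEFAULT_LEXICON",
    "GeneFeature",
    "GffParseError",
    "Region",
    "classify_gene_category",
    "read_alignments",
    "read_fasta",
    "read_features",
    "read_regions",
    "reverse_complement",
    "write_fasta",
    "write_features",
    "write_regions",
]
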