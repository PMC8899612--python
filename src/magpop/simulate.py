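"""Synthetic population generator with full ground truth.

Emulates a single-species-dominated metagenome at desk scale: a circular
~2.7 Mbp chromosome (GC ~= 54%) with a two-replichore GC skew, a planted
"scrapyard" island with elevated hypothetical-protein / mobile-element /
phage gene content, randomized window skew and concentrated short-variant
density; a finite pool of population haplotypes carrying SSVs and IS-element
insertions at set allele frequencies; and long + short sequencing reads with
configurable error models, accompanied by a truth SAM that exposes every
planted insertion as CIGAR I ops (or soft clips at element boundaries).

Every stage draws from its own seeded RNG stream, so outputs are
deterministic per seed and reproducible stage by stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from magpop.core_io import (
    AnnotatedGenome,
    Category,
    Contig,
    GeneFeature,
    Region,
    classify_gene_category,
    reverse_complement,
    write_fasta,
    write_features,
    write_regions,
)

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (int(b) for b in _BASE_CODES)
_CODE_OF = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(_BASE_CODES):
    _CODE_OF[_b] = _i

# RNG stream tags (mixed with the user seed)
_STAGE_GENOME = 1
_STAGE_POPULATION = 2
_STAGE_READS = 3
_STAGE_ELEMENTS = 4


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class LongReadSpec:
    """Nanopore-like reads: lognormal lengths, sub/ins/del errors."""

    coverage: float = 20.0
    mean_length: int = 9000
    sigma_log: float = 0.35
    min_length: int = 500
    sub_rate: float = 0.02
    ins_rate: float = 0.03
    del_rate: float = 0.04


@dataclass
class ShortReadSpec:
    """Illumina-like 2 x 250 bp pairs with substitution errors."""

    coverage: float = 50.0
    read_length: int = 250
    insert_mean: int = 700
    insert_sd: int = 70
    error_rate: float = 0.003


@dataclass
class InsertionSpec:
    """One planted IS insertion.

    ``target`` is a gene category name ("FUNCTIONAL", "HP", "ME", "PHAGE"),
    "INTERGENIC", a ("gene", gene_id) pair, or a ("locus", position) pair.
    ``region`` restricts category/intergenic targets to "scrapyard" or
    "background" when set.
    """

    element_id: str
    target: object = "FUNCTIONAL"
    frequency: float = 0.5
    region: str | None = None


def _default_insertions() -> list[InsertionSpec]:
    return [
        InsertionSpec("ISFm1", "FUNCTIONAL", 0.30, "background"),
        InsertionSpec("ISFm2", "FUNCTIONAL", 0.50, "background"),
        InsertionSpec("ISFm3", "FUNCTIONAL", 0.20, "background"),
        InsertionSpec("ISFm1", "FUNCTIONAL", 0.70, "background"),
        InsertionSpec("ISFm2", "HP", 0.40, "background"),
        InsertionSpec("ISFm3", "HP", 0.60, "scrapyard"),
        InsertionSpec("ISFm1", "ME", 0.50, "scrapyard"),
        InsertionSpec("ISFm2", "INTERGENIC", 0.30, "background"),
        InsertionSpec("ISFm3", "INTERGENIC", 0.50, "background"),
        InsertionSpec("ISFm1", "FUNCTIONAL", 0.95, "background"),
    ]


@dataclass
class SimConfig:
    """Study conditions for one synthetic population.

    Defaults follow the genome and regional statistics of the natural
    populations the package models: a 2,749,106 bp circular chromosome at
    GC 54.1%, a ~194 kbp scrapyard at [32353, 226193) with HP/phage/ME/
    functional ORF proportions 71.7/3.7/9.0/15.6 % inside versus
    37.4/0.5/4.2/57.9 % outside, SSV densities 11.9 versus 1.77 per
    10 kbp, 20 population haplotypes with Uniform(0.05, 0.95) allele
    frequencies, and 20x long-read plus 50x short-read (2 x 250 bp)
    coverage.
    """

    seed: int = 0
    contig_id: str = "chr"
    genome_length: int = 2_749_106
    gc: float = 0.541
    circular: bool = True
    skew_amplitude: float = 0.15
    skew_block: int = 1000
    scrapyard_start: int = 32_353
    scrapyard_end: int = 226_192
    proportions_scrapyard: dict = field(
        default_factory=lambda: {"HP": 0.717, "PHAGE": 0.037, "ME": 0.090, "FUNCTIONAL": 0.156}
    )
    proportions_background: dict = field(
        default_factory=lambda: {"HP": 0.374, "PHAGE": 0.005, "ME": 0.042, "FUNCTIONAL": 0.579}
    )
    gene_length_median: int = 800
    gene_length_sigma: float = 0.45
    intergenic_mean: int = 100
    ssv_rate_scrapyard: float = 11.9 / 10_000
    ssv_rate_background: float = 1.77 / 10_000
    freq_min: float = 0.05
    freq_max: float = 0.95
    n_haplotypes: int = 20
    insertions: list[InsertionSpec] = field(default_factory=_default_insertions)
    long_reads: LongReadSpec = field(default_factory=LongReadSpec)
    short_reads: ShortReadSpec = field(default_factory=ShortReadSpec)

    @property
    def scrapyard(self) -> Region:
        return Region(self.contig_id, self.scrapyard_start, self.scrapyard_end, "scrapyard")

    def validate(self) -> None:
        if not 0 < self.scrapyard_start < self.scrapyard_end <= self.genome_length:
            raise ValueError(
                f"scrapyard [{self.scrapyard_start}, {self.scrapyard_end}) "
                f"outside genome of length {self.genome_length}"
            )
        for name, props in (
            ("scrapyard", self.proportions_scrapyard),
            ("background", self.proportions_background),
        ):
            if abs(sum(props.values()) - 1.0) > 0.01:
                raise ValueError(f"{name} category proportions must sum to 1")
        for spec in self.insertions:
            if not 0 <= spec.frequency <= 1:
                raise ValueError(f"insertion frequency {spec.frequency} outside [0, 1]")
        if self.ssv_rate_scrapyard < 0 or self.ssv_rate_background < 0:
            raise ValueError("SSV rates must be >= 0")
        if self.long_reads.coverage <= 0 or self.short_reads.coverage <= 0:
            raise ValueError("coverage must be > 0")

    def scaled(self, genome_length: int, scrapyard_start: int, scrapyard_end: int) -> "SimConfig":
        """Copy with a smaller genome/scrapyard, same per-bp conditions."""
        return replace(
            self,
            genome_length=genome_length,
            scrapyard_start=scrapyard_start,
            scrapyard_end=scrapyard_end,
        )


# ---------------------------------------------------------------------------
# Truth tables


@dataclass
class TruthSSV:
    position: int  # 0-based VCF-style anchor
    ref: str
    alt: str
    frequency: float  # realized: carriers / haplotypes
    carriers: tuple[int, ...]


@dataclass
class TruthInsertion:
    breakpoint: int  # 0-based reference position where reads show the I op
    element_id: str
    length: int  # inserted bases (element + target-site duplication)
    sequence: str
    frequency: float
    carriers: tuple[int, ...]
    disrupted_gene: str | None
    tsd_length: int


@dataclass
class TruthTables:
    scrapyard: Region
    ssvs: list[TruthSSV] = field(default_factory=list)
    insertions: list[TruthInsertion] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Stage 1: genome

_PRODUCTS = {
    "HP": ["hypothetical protein"],
    "ME": [
        "IS5 family transposase",
        "IS110 family transposase",
        "IS3 family transposase",
        "tyrosine-type recombinase/integrase",
        "transposase",
        "site-specific DNA recombinase",
    ],
    "PHAGE": [
        "phage major capsid protein",
        "phage tail tape measure protein",
        "phage terminase large subunit",
        "phage portal protein",
        "phage baseplate assembly protein",
    ],
    "FUNCTIONAL": [
        "diguanylate cyclase (GGDEF domain protein)",
        "diguanylate cyclase/phosphodiesterase",
        "acetate kinase",
        "aerotaxis sensor receptor protein",
        "cellulose biosynthesis regulation protein BcsB",
        "type II/IV secretion system secretin RcpA/CpaC",
        "uptake [NiFe] hydrogenase small subunit",
        "ribulose bisphosphate carboxylase large chain",
        "assimilatory nitrate reductase large subunit",
        "5-methyltetrahydrofolate--homocysteine methyltransferase",
        "circadian clock protein KaiC",
        "heavy metal efflux pump CusA",
        "DNA helicase RecQ",
        "ATP synthase F1 subunit alpha",
        "elongation factor Tu",
        "DNA-directed RNA polymerase beta subunit",
        "chaperonin GroEL",
        "citrate synthase",
        "NADH-quinone oxidoreductase subunit D",
        "30S ribosomal protein S12",
    ],
}

LEFT_ANCHOR = "tRNA-Ser-CGA"
RIGHT_ANCHOR = "tRNA-Val-CAC"
_OTHER_TRNAS = [
    "tRNA-Ala-GGC",
    "tRNA-Gly-GCC",
    "tRNA-Leu-TAA",
    "tRNA-Met-CAT",
    "tRNA-Thr-TGT",
    "tRNA-Phe-GAA",
    "tRNA-Lys-TTT",
    "tRNA-Asp-GTC",
]


def _simulate_sequence(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Base array with target GC and two-replichore skew.

    The leading strand of each replichore is G-rich (origin at 0,
    terminus at L/2); inside the scrapyard the per-block skew sign is
    randomized, which is what makes the island's skew "scattered".
    """
    L = config.genome_length
    block = config.skew_block
    n_blocks = math.ceil(L / block)
    starts = np.arange(n_blocks) * block
    sign = np.where(starts < L / 2, 1.0, -1.0)
    in_sy = (starts >= config.scrapyard_start) & (starts < config.scrapyard_end)
    sign[in_sy] = rng.choice([-1.0, 1.0], size=int(in_sy.sum()))
    p_g = 0.5 + config.skew_amplitude * sign / 2
    p_g_per_base = np.repeat(p_g, block)[:L]

    is_gc = rng.random(L) < config.gc
    u = rng.random(L)
    bases = np.where(
        is_gc,
        np.where(u < p_g_per_base, _G, _C),
        np.where(u < 0.5, _A, _T),
    ).astype(np.uint8)
    return bases


def _reserved_intervals(config: SimConfig, rng: np.random.Generator):
    """tRNA/rRNA intervals: scrapyard anchors at fixed positions, the rest
    scattered outside the island without overlaps."""
    sy = config.scrapyard
    L = config.genome_length
    trna_len = 85
    reserved = [
        (sy.start - trna_len, sy.start, LEFT_ANCHOR, "tRNA"),
        (sy.end, sy.end + trna_len, RIGHT_ANCHOR, "tRNA"),
    ]
    lo, hi = sy.end + trna_len + 2000, L - 6000
    n_extra = len(_OTHER_TRNAS) + 2
    if hi - lo > n_extra * 12_000:
        pos = np.sort(rng.integers(lo, hi, size=n_extra))
        # push apart so no two reserved intervals overlap
        for i in range(1, n_extra):
            pos[i] = max(pos[i], pos[i - 1] + 6000)
        if pos[-1] < L - 6000:
            for i, name in enumerate(_OTHER_TRNAS):
                p = int(pos[i])
                reserved.append((p, p + trna_len, name, "tRNA"))
            for j in range(2):
                p = int(pos[len(_OTHER_TRNAS) + j])
                reserved.append((p, p + 5000, f"rRNA-array-{j + 1}", "rRNA"))
    reserved.sort()
    return reserved


def simulate_genome(config: SimConfig) -> tuple[AnnotatedGenome, TruthTables]:
    """Generate the annotated reference genome and seed the truth tables.

    Genes are non-overlapping, lognormal-length ORFs whose category
    proportions differ between the planted scrapyard and the background;
    the scrapyard is delimited by tRNA anchor genes (the left anchor ends
    at its start, the right anchor starts at its end), mirroring how such
    islands are delimited on real assemblies.  Gene intervals are
    annotation-only: the underlying simulated sequence has no codon
    structure.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STAGE_GENOME])
    L = config.genome_length
    bases = _simulate_sequence(config, rng)
    sequence = bases.tobytes().decode()

    sy = config.scrapyard
    reserved = _reserved_intervals(config, rng)
    features: list[GeneFeature] = []
    for start, end, name, ftype in reserved:
        features.append(
            GeneFeature(
                id=name,
                contig=config.contig_id,
                start=start,
                end=end,
                strand="+",
                product=name,
                category=Category.RRNA if ftype == "rRNA" else Category.TRNA,
                feature_type=ftype,
            )
        )

    mu = math.log(config.gene_length_median)
    cats_sy = list(config.proportions_scrapyard)
    p_sy = np.array([config.proportions_scrapyard[c] for c in cats_sy], dtype=float)
    p_sy /= p_sy.sum()
    cats_bg = list(config.proportions_background)
    p_bg = np.array([config.proportions_background[c] for c in cats_bg], dtype=float)
    p_bg /= p_bg.sum()

    cursor = 0
    gene_no = 0
    res_idx = 0
    while cursor < L - 200:
        gap = int(rng.exponential(config.intergenic_mean)) + 1
        length = int(rng.lognormal(mu, config.gene_length_sigma))
        length = max(150, length - length % 3)
        start = cursor + gap
        end = start + length
        while res_idx < len(reserved) and reserved[res_idx][1] <= start:
            res_idx += 1
        if res_idx < len(reserved) and end > reserved[res_idx][0]:
            cursor = reserved[res_idx][1]
            res_idx += 1
            continue
        if end > L:
            break
        in_scrapyard = sy.contains(start)
        cats, probs = (cats_sy, p_sy) if in_scrapyard else (cats_bg, p_bg)
        category = cats[int(rng.choice(len(cats), p=probs))]
        vocab = _PRODUCTS[category]
        product = vocab[int(rng.integers(len(vocab)))]
        gene_no += 1
        features.append(
            GeneFeature(
                id=f"gene_{gene_no:05d}",
                contig=config.contig_id,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                product=product,
                category=classify_gene_category(product),
            )
        )
        cursor = end

    features.sort(key=lambda f: f.start)
    genome = AnnotatedGenome([Contig(config.contig_id, sequence, config.circular)], features)
    return genome, TruthTables(scrapyard=sy)


# ---------------------------------------------------------------------------
# Element library


def make_element_library(config: SimConfig) -> dict[str, str]:
    """IS-like elements with 15-25 bp terminal inverted repeats.

    Deterministic per seed; the same library is used for planting and for
    classification.
    """
    rng = np.random.default_rng([config.seed, _STAGE_ELEMENTS])
    lengths = {"ISFm1": 1200, "ISFm2": 1000, "ISFm3": 1450}
    library: dict[str, str] = {}
    for name, length in lengths.items():
        tir_len = int(rng.integers(15, 26))
        core = rng.choice(_BASE_CODES, size=length - 2 * tir_len).tobytes().decode()
        tir = rng.choice(_BASE_CODES, size=tir_len).tobytes().decode()
        library[name] = tir + core + reverse_complement(tir)
    return library


# ---------------------------------------------------------------------------
# Stage 2: population haplotypes


@dataclass
class Haplotype:
    """One population lineage: the reference plus its sorted edit list.

    Each edit is (ref_pos, ref_len, alt_seq): substitution (1, base),
    insertion (0, seq) or deletion (n, "")."""

    index: int
    edits: list[tuple[int, int, str]]

    def materialize(self, reference: str) -> str:
        pieces = []
        prev = 0
        for pos, ref_len, alt in self.edits:
            pieces.append(reference[prev:pos])
            pieces.append(alt)
            prev = pos + ref_len
        pieces.append(reference[prev:])
        return "".join(pieces)


@dataclass
class Population:
    haplotypes: list[Haplotype]
    truth: TruthTables
    library: dict[str, str]


def _draw_spaced_positions(
    rng: np.random.Generator,
    count: int,
    low: int,
    high: int,
    spacing: int,
    forbidden: np.ndarray,
    forbid_margin: int,
) -> np.ndarray:
    """Uniform positions in [low, high) with pairwise spacing and a margin
    around forbidden sites, by iterative resampling (keeps the count)."""
    if count == 0:
        return np.empty(0, dtype=np.int64)
    pos = rng.integers(low, high, size=count)
    for _ in range(500):
        pos = np.sort(pos)
        bad = np.zeros(count, dtype=bool)
        bad[1:] |= np.diff(pos) < spacing
        if len(forbidden):
            near = np.min(np.abs(pos[:, None] - forbidden[None, :]), axis=1)
            bad |= near < forbid_margin
        if not bad.any():
            return pos
        pos[bad] = rng.integers(low, high, size=int(bad.sum()))
    raise RuntimeError("could not place variant positions with required spacing")


def _carriers(
    rng: np.random.Generator, frequency: float, n_haplotypes: int
) -> tuple[tuple[int, ...], float]:
    if frequency <= 0:
        return (), 0.0
    k = int(round(frequency * n_haplotypes))
    k = min(max(k, 1), n_haplotypes)
    chosen = tuple(sorted(int(i) for i in rng.choice(n_haplotypes, size=k, replace=False)))
    return chosen, k / n_haplotypes


def _plan_insertion_sites(
    genome: AnnotatedGenome, config: SimConfig, rng: np.random.Generator
) -> list[tuple[InsertionSpec, int, str | None]]:
    """Pick a breakpoint (and disrupted gene, if any) for every insertion
    spec, keeping breakpoints >= 1 kbp apart."""
    sy = config.scrapyard
    L = config.genome_length
    # keep planted sites away from the linear ends: long-read coverage
    # ramps up from zero there, starving the caller of spanning reads
    edge = min(10_000, L // 10)
    by_id = {f.id: f for f in genome.features}
    orfs = genome.orfs()
    starts = np.array([f.start for f in genome.features])
    ends = np.array([f.end for f in genome.features])

    def intergenic_ok(p: int, margin: int = 60) -> bool:
        i = np.searchsorted(starts, p, side="right")
        if i > 0 and ends[i - 1] + margin > p:
            return False
        if i < len(starts) and starts[i] - margin < p:
            return False
        return True

    used_genes: set[str] = set()
    accepted: list[int] = []
    planned: list[tuple[InsertionSpec, int, str | None]] = []

    def far_enough(p: int) -> bool:
        return all(abs(p - q) >= 1000 for q in accepted)

    for spec in config.insertions:
        target = spec.target
        bp0: int | None = None
        gene: str | None = None
        if isinstance(target, tuple) and target[0] == "locus":
            bp0 = int(target[1])
            gene = next((f.id for f in orfs if f.start <= bp0 < f.end), None)
            if not far_enough(bp0):
                raise ValueError(f"locus {bp0} too close to another planted insertion")
        elif isinstance(target, tuple) and target[0] == "gene":
            if target[1] not in by_id:
                raise ValueError(f"insertion target gene {target[1]!r} not in annotation")
            f = by_id[target[1]]
            for _ in range(200):
                cand = int(rng.integers(f.start + 50, f.end - 50))
                if far_enough(cand):
                    bp0, gene = cand, f.id
                    break
            else:
                raise ValueError(f"no breakpoint found in gene {target[1]}")
        elif target == "INTERGENIC":
            for _ in range(5000):
                cand = int(rng.integers(edge, L - edge))
                if spec.region == "scrapyard" and not sy.contains(cand):
                    continue
                if spec.region == "background" and sy.contains(cand):
                    continue
                if intergenic_ok(cand) and far_enough(cand):
                    bp0 = cand
                    break
            else:
                raise ValueError("no intergenic insertion site found")
        else:
            cat = Category[str(target)]

            def pool(respect_region: bool) -> list:
                return [
                    f
                    for f in orfs
                    if f.category is cat
                    and f.id not in used_genes
                    and (f.end - f.start) >= 400
                    and f.start >= edge
                    and f.end <= L - edge
                    and (
                        not respect_region
                        or spec.region is None
                        or (spec.region == "scrapyard") == sy.contains(f.start)
                    )
                ]

            # small scaled-down genomes may lack the category inside the
            # requested region; fall back to the whole genome before failing
            candidates = pool(True) or pool(False)
            rng.shuffle(candidates)
            for f in candidates:
                cand = int(rng.integers(f.start + 100, f.end - 100))
                if far_enough(cand):
                    bp0, gene = cand, f.id
                    used_genes.add(f.id)
                    break
            if bp0 is None:
                raise ValueError(
                    f"no candidate gene of category {target} in region {spec.region!r}"
                )
        accepted.append(bp0)
        planned.append((spec, bp0, gene))
    return planned


def simulate_population(genome: AnnotatedGenome, config: SimConfig) -> Population:
    """Plant SSVs and IS insertions on a finite haplotype pool.

    SSV loci are Poisson with region-specific per-bp rates; each variant
    gets a Uniform(freq_min, freq_max) population frequency realized as
    the nearest carrier count among ``n_haplotypes`` lineages, so linked
    variants co-occur as in a clonal population.  Insertions copy a
    library element into the breakpoint with a 4-8 bp target-site
    duplication.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STAGE_POPULATION])
    contig = genome.contigs[0]
    reference = contig.sequence
    L = len(reference)
    sy = config.scrapyard
    truth = TruthTables(scrapyard=sy)
    library = make_element_library(config)
    for spec in config.insertions:
        if spec.element_id not in library:
            raise ValueError(f"unknown element {spec.element_id!r}")

    edits_per_hap: list[list[tuple[int, int, str]]] = [[] for _ in range(config.n_haplotypes)]

    for spec, bp0, gene in _plan_insertion_sites(genome, config, rng):
        element = library[spec.element_id]
        tsd_len = int(rng.integers(4, 9))
        inserted = element + reference[bp0 : bp0 + tsd_len]
        anchor = bp0 + tsd_len  # reads show the I op here
        carriers, freq = _carriers(rng, spec.frequency, config.n_haplotypes)
        truth.insertions.append(
            TruthInsertion(
                breakpoint=anchor,
                element_id=spec.element_id,
                length=len(inserted),
                sequence=inserted,
                frequency=freq,
                carriers=carriers,
                disrupted_gene=gene,
                tsd_length=tsd_len,
            )
        )
        for h in carriers:
            edits_per_hap[h].append((anchor, 0, inserted))

    forbidden = np.array([t.breakpoint for t in truth.insertions], dtype=np.int64)
    regions = [
        (sy.start, sy.end, config.ssv_rate_scrapyard),
        (0, sy.start, config.ssv_rate_background),
        (sy.end, L, config.ssv_rate_background),
    ]
    snv_p, ins_p, del_p = 0.8, 0.1, 0.1
    for low, high, rate in regions:
        span = high - low
        if span <= 400 or rate <= 0:
            continue
        count = int(rng.poisson(rate * span))
        positions = _draw_spaced_positions(
            rng,
            count,
            max(low, 200),
            high - 200,
            spacing=150,
            forbidden=forbidden,
            forbid_margin=300,
        )
        kinds = rng.choice(3, size=len(positions), p=[snv_p, ins_p, del_p])
        for pos, kind in zip(positions, kinds):
            pos = int(pos)
            carriers, freq = _carriers(
                rng, float(rng.uniform(config.freq_min, config.freq_max)), config.n_haplotypes
            )
            if kind == 0:  # SNV
                ref = reference[pos]
                alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
                edit = (pos, 1, alt)
            else:
                ln = min(139, int(rng.geometric(0.4)))
                anchor_base = reference[pos]
                if kind == 1:  # insertion after the anchor base
                    ins_seq = rng.choice(_BASE_CODES, size=ln).tobytes().decode()
                    ref, alt = anchor_base, anchor_base + ins_seq
                    edit = (pos + 1, 0, ins_seq)
                else:  # deletion of ln bases after the anchor base
                    ref = reference[pos : pos + ln + 1]
                    alt = anchor_base
                    edit = (pos + 1, ln, "")
            truth.ssvs.append(TruthSSV(pos, ref, alt, freq, carriers))
            for h in carriers:
                edits_per_hap[h].append(edit)

    truth.ssvs.sort(key=lambda v: v.position)
    truth.insertions.sort(key=lambda v: v.breakpoint)
    haplotypes = [Haplotype(h, sorted(edits)) for h, edits in enumerate(edits_per_hap)]
    return Population(haplotypes, truth, library)


# ---------------------------------------------------------------------------
# Stage 3: reads

_OP_M, _OP_I, _OP_D = 0, 1, 2
_OP_CHARS = "MID"


@dataclass
class ReadProvenance:
    read_id: str
    haplotype: int
    hap_start: int
    length: int
    strand: str


@dataclass
class ReadSet:
    """Paths of the emitted read files plus per-read provenance."""

    long_fastq: Path
    short_r1: Path
    short_r2: Path
    truth_long_sam: Path
    truth_short_sam: Path
    long_provenance: list[ReadProvenance]
    short_provenance: list[ReadProvenance]
    long_bases: int
    short_bases: int


def _hap_columns(reference: str, hap: Haplotype):
    """Alignment-column arrays of a haplotype against the reference.

    Returns (ops, bases, refpos, colindex): per-column CIGAR op code and
    query base, per-column reference position, and for every haplotype
    position the index of its column (for slicing reads out by haplotype
    coordinate).
    """
    ref_arr = np.frombuffer(reference.encode(), dtype=np.uint8)
    ops_parts, base_parts, ref_parts = [], [], []
    prev = 0
    for pos, ref_len, alt in hap.edits:
        if pos > prev:
            ops_parts.append(np.zeros(pos - prev, dtype=np.int8))
            base_parts.append(ref_arr[prev:pos])
            ref_parts.append(np.arange(prev, pos, dtype=np.int64))
        if ref_len == 1 and len(alt) == 1:  # substitution
            ops_parts.append(np.zeros(1, dtype=np.int8))
            base_parts.append(np.frombuffer(alt.encode(), dtype=np.uint8))
            ref_parts.append(np.array([pos], dtype=np.int64))
        else:
            if alt:  # insertion
                ops_parts.append(np.full(len(alt), _OP_I, dtype=np.int8))
                base_parts.append(np.frombuffer(alt.encode(), dtype=np.uint8))
                ref_parts.append(np.full(len(alt), pos, dtype=np.int64))
            if ref_len:  # deletion
                ops_parts.append(np.full(ref_len, _OP_D, dtype=np.int8))
                base_parts.append(np.zeros(ref_len, dtype=np.uint8))
                ref_parts.append(np.arange(pos, pos + ref_len, dtype=np.int64))
        prev = pos + ref_len
    if prev < len(ref_arr):
        ops_parts.append(np.zeros(len(ref_arr) - prev, dtype=np.int8))
        base_parts.append(ref_arr[prev:])
        ref_parts.append(np.arange(prev, len(ref_arr), dtype=np.int64))
    ops = np.concatenate(ops_parts)
    bases = np.concatenate(base_parts)
    refpos = np.concatenate(ref_parts)
    colindex = np.flatnonzero(ops != _OP_D)
    return ops, bases, refpos, colindex


def _substitute(bases: np.ndarray, idx: np.ndarray, rng: np.random.Generator) -> None:
    shift = rng.integers(1, 4, size=len(idx))
    bases[idx] = _BASE_CODES[(_CODE_OF[bases[idx]] + shift) % 4]


def _inject_long_errors(
    ops: np.ndarray,
    bases: np.ndarray,
    refpos: np.ndarray,
    rng: np.random.Generator,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
):
    """Sub/ins/del sequencing errors applied to alignment columns; all
    three arrays stay aligned."""
    qlen = int((ops != _OP_D).sum())
    n_sub = rng.binomial(qlen, sub_rate) if sub_rate > 0 else 0
    n_del = rng.binomial(qlen, del_rate) if del_rate > 0 else 0
    n_ins = rng.binomial(qlen, ins_rate) if ins_rate > 0 else 0
    if n_sub:
        qcols = np.flatnonzero(ops != _OP_D)
        idx = rng.choice(qcols, size=min(n_sub, len(qcols)), replace=False)
        _substitute(bases, idx, rng)
    if n_del:
        mcols = np.flatnonzero(ops == _OP_M)
        if len(mcols):
            idx = rng.choice(mcols, size=min(n_del, len(mcols)), replace=False)
            ops[idx] = _OP_D
    if n_ins:
        at = np.sort(rng.integers(0, len(ops) + 1, size=n_ins))
        ins_bases = rng.choice(_BASE_CODES, size=n_ins)
        ops = np.insert(ops, at, _OP_I)
        bases = np.insert(bases, at, ins_bases)
        refpos = np.insert(refpos, at, refpos[np.minimum(at, len(refpos) - 1)])
    return ops, bases, refpos


def _cigar_and_seq(ops: np.ndarray, bases: np.ndarray, refpos: np.ndarray):
    """(cigar string, seq, ref_start) for an alignment-column slice.

    Leading/trailing I runs become soft clips; edge D runs are dropped.
    Returns None if no M column remains."""
    m_idx = np.flatnonzero(ops == _OP_M)
    if len(m_idx) == 0:
        return None
    first, last = int(m_idx[0]), int(m_idx[-1]) + 1
    seq = bases[ops != _OP_D].tobytes().decode()
    lead_clip = int((ops[:first] != _OP_D).sum())
    tail_clip = int((ops[last:] != _OP_D).sum())
    core_ops = ops[first:last]
    change = np.flatnonzero(np.diff(core_ops)) + 1
    bounds = np.concatenate([[0], change, [len(core_ops)]])
    parts = []
    if lead_clip:
        parts.append(f"{lead_clip}S")
    for a, b in zip(bounds[:-1], bounds[1:]):
        parts.append(f"{b - a}{_OP_CHARS[core_ops[a]]}")
    if tail_clip:
        parts.append(f"{tail_clip}S")
    return "".join(parts), seq, int(refpos[first])


_QUAL_CACHE: dict[int, str] = {}


def _qual(n: int) -> str:
    if n not in _QUAL_CACHE:
        _QUAL_CACHE[n] = "I" * n
    return _QUAL_CACHE[n]


def simulate_reads(
    genome: AnnotatedGenome,
    population: Population,
    config: SimConfig,
    outdir: str | Path,
) -> ReadSet:
    """Sample long and short reads from the haplotype pool and write
    FASTQ plus a truth SAM (reads aligned back to the reference, with
    planted insertions exposed as I ops or boundary soft clips).

    Reads are drawn uniformly across haplotypes (lineages are equally
    abundant), so a variant's read support tracks its haplotype
    frequency.  Deterministic per seed.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, _STAGE_READS])
    contig = genome.contigs[0]
    reference = contig.sequence
    L = len(reference)
    H = config.n_haplotypes

    header = f"@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:{contig.id}\tLN:{L}\n"

    lr = config.long_reads
    n_long = max(1, int(round(lr.coverage * L / lr.mean_length)))
    mu = math.log(lr.mean_length) - lr.sigma_log**2 / 2
    lengths = np.maximum(lr.min_length, rng.lognormal(mu, lr.sigma_log, n_long).astype(np.int64))
    long_hap = rng.integers(0, H, size=n_long)
    long_strand = rng.random(n_long) < 0.5
    long_u = rng.random(n_long)

    sr = config.short_reads
    n_pairs = max(1, int(round(sr.coverage * L / (2 * sr.read_length))))
    inserts = np.clip(
        rng.normal(sr.insert_mean, sr.insert_sd, n_pairs).astype(np.int64),
        2 * sr.read_length + 10,
        None,
    )
    short_hap = rng.integers(0, H, size=n_pairs)
    short_u = rng.random(n_pairs)

    long_fastq = outdir / "long.fastq"
    r1_fastq = outdir / "short_R1.fastq"
    r2_fastq = outdir / "short_R2.fastq"
    long_sam = outdir / "truth_long.sam"
    short_sam = outdir / "truth_short.sam"

    long_prov: list[ReadProvenance] = []
    short_prov: list[ReadProvenance] = []
    long_bases = 0
    short_bases = 0

    with open(long_fastq, "w") as lfq, open(long_sam, "w") as lsam, open(
        r1_fastq, "w"
    ) as f1, open(r2_fastq, "w") as f2, open(short_sam, "w") as ssam:
        lsam.write(header)
        ssam.write(header)
        for h in range(H):
            hap = population.haplotypes[h]
            ops_all, bases_all, refpos_all, colindex = _hap_columns(reference, hap)
            hap_len = len(colindex)

            for i in np.flatnonzero(long_hap == h):
                ln = int(min(lengths[i], hap_len))
                start = int(long_u[i] * (hap_len - ln))
                c0, c1 = colindex[start], colindex[start + ln - 1] + 1
                ops = ops_all[c0:c1].copy()
                bases = bases_all[c0:c1].copy()
                refpos = refpos_all[c0:c1]
                ops, bases, refpos = _inject_long_errors(
                    ops, bases, refpos, rng, lr.sub_rate, lr.ins_rate, lr.del_rate
                )
                res = _cigar_and_seq(ops, bases, refpos)
                if res is None:
                    continue
                cigar, seq, ref_start = res
                name = f"long_{i:07d}"
                strand = "-" if long_strand[i] else "+"
                flag = 16 if strand == "-" else 0
                fq_seq = reverse_complement(seq) if strand == "-" else seq
                lfq.write(f"@{name}\n{fq_seq}\n+\n{_qual(len(seq))}\n")
                lsam.write(
                    f"{name}\t{flag}\t{contig.id}\t{ref_start + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\n"
                )
                long_bases += len(seq)
                long_prov.append(ReadProvenance(name, h, start, ln, strand))

            for i in np.flatnonzero(short_hap == h):
                ins = int(min(inserts[i], hap_len))
                fstart = int(short_u[i] * (hap_len - ins))
                rl = sr.read_length
                name = f"short_{i:07d}"
                for mate, (s, e, strand) in enumerate(
                    ((fstart, fstart + rl, "+"), (fstart + ins - rl, fstart + ins, "-"))
                ):
                    c0, c1 = colindex[s], colindex[e - 1] + 1
                    ops = ops_all[c0:c1]
                    bases = bases_all[c0:c1]
                    refpos = refpos_all[c0:c1]
                    n_err = rng.binomial(rl, sr.error_rate) if sr.error_rate > 0 else 0
                    if n_err:
                        bases = bases.copy()
                        qcols = np.flatnonzero(ops != _OP_D)
                        idx = rng.choice(qcols, size=min(n_err, len(qcols)), replace=False)
                        _substitute(bases, idx, rng)
                    if (ops != _OP_M).any():
                        res = _cigar_and_seq(ops, bases, refpos)
                        if res is None:
                            continue
                        cigar, seq, ref_start = res
                    else:
                        seq = bases.tobytes().decode()
                        cigar = f"{len(seq)}M"
                        ref_start = int(refpos[0])
                    flag = 0 if mate == 0 else 16
                    fh = f1 if mate == 0 else f2
                    fq_seq = reverse_complement(seq) if strand == "-" else seq
                    fh.write(f"@{name}/{mate + 1}\n{fq_seq}\n+\n{_qual(len(seq))}\n")
                    ssam.write(
                        f"{name}/{mate + 1}\t{flag}\t{contig.id}\t{ref_start + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\n"
                    )
                    short_bases += len(seq)
                    short_prov.append(ReadProvenance(f"{name}/{mate + 1}", h, s, e - s, strand))

    long_prov.sort(key=lambda p: p.read_id)
    short_prov.sort(key=lambda p: p.read_id)
    return ReadSet(
        long_fastq,
        r1_fastq,
        r2_fastq,
        long_sam,
        short_sam,
        long_prov,
        short_prov,
        long_bases,
        short_bases,
    )


# ---------------------------------------------------------------------------
# Dataset writer


def write_truth(
    genome: AnnotatedGenome, population: Population, outdir: str | Path
) -> dict[str, Path]:
    """Write genome.fasta, genes.gff3, elements.fasta, haplotypes.fasta,
    truth_ssv.vcf, truth_insertions.tsv and truth_regions.bed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = population.truth
    contig = genome.contigs[0]
    paths = {
        "genome": outdir / "genome.fasta",
        "genes": outdir / "genes.gff3",
        "elements": outdir / "elements.fasta",
        "haplotypes": outdir / "haplotypes.fasta",
        "ssv": outdir / "truth_ssv.vcf",
        "insertions": outdir / "truth_insertions.tsv",
        "regions": outdir / "truth_regions.bed",
    }
    write_fasta(genome.contigs, paths["genome"])
    write_features(genome.features, paths["genes"])
    write_fasta(
        [Contig(name, seq) for name, seq in population.library.items()], paths["elements"]
    )
    write_fasta(
        [
            Contig(f"hap_{h.index:02d}", h.materialize(contig.sequence))
            for h in population.haplotypes
        ],
        paths["haplotypes"],
    )
    with open(paths["ssv"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig.id},length={len(contig)}>\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in truth.ssvs:
            fh.write(
                f"{contig.id}\t{v.position + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\tAF={v.frequency:.4f}\n"
            )
    with open(paths["insertions"], "w") as fh:
        fh.write(
            "breakpoint\telement_id\tlength\tfrequency\tcarriers\tdisrupted_gene\ttsd_length\n"
        )
        for t in truth.insertions:
            fh.write(
                f"{t.breakpoint}\t{t.element_id}\t{t.length}\t{t.frequency:.4f}\t"
                f"{','.join(map(str, t.carriers))}\t{t.disrupted_gene or '.'}\t{t.tsd_length}\n"
            )
    write_regions([truth.scrapyard], paths["regions"])
    return paths


__all__ = [
    "Haplotype",
    "InsertionSpec",
    "LongReadSpec",
    "Population",
    "ReadProvenance",
    "ReadSet",
    "ShortReadSpec",
    "SimConfig",
    "TruthInsertion",
    "TruthSSV",
    "TruthTables",
    "make_element_library",
    "simulate_genome",
    "simulate_population",
    "simulate_reads",
    "write_truth",
]
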