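"""Genome scrapyard statistics and detection.

A "scrapyard" is a genome island with depleted functional-gene content,
accumulated hypothetical proteins (HP), mobile elements (ME) and phage
genes, concentrated short-variant density, and scattered GC skew.  This
module computes per-region content statistics (counts, percents of ORFs,
densities per 10 kbp), inside/outside enrichment ratios, tRNA-anchor
delimitation, and sliding-window de novo island detection.

Features are counted "in" a region by their start position; tRNA/rRNA
genes are excluded from ORF totals.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from magpop.core_io import Category, GeneFeature, Region
from magpop.ssv import ShortVariant
from magpop.stats import SkewProfile, genome_scatter_background, skew_scatter

_CONTENT_CATS = (Category.HP, Category.PHAGE, Category.ME, Category.FUNCTIONAL)


@dataclass
class CategoryStats:
    count: int
    percent: float  # of ORF total
    density: float  # per 10 kbp


@dataclass
class RegionStats:
    """One content-table row: per-category ORF statistics plus SSVs."""

    label: str
    categories: dict[Category, CategoryStats]
    ssv_count: int | None
    ssv_density: float | None
    orf_total: int
    length: int
    start: int
    end: int

    def category(self, cat: Category) -> CategoryStats:
        return self.categories[cat]


def _stats_for(
    label: str,
    features: Sequence[GeneFeature],
    variants: Sequence[ShortVariant] | None,
    start: int,
    end: int,
    length: int,
    orf_total: int | None = None,
) -> RegionStats:
    orfs = [f for f in features if f.category in _CONTENT_CATS]
    # orf_total normally equals len(orfs); published rows may carry a
    # larger printed total (ORFs outside the four content classes)
    total = orf_total if orf_total is not None else len(orfs)
    categories = {}
    for cat in _CONTENT_CATS:
        count = sum(1 for f in orfs if f.category is cat)
        percent = 100.0 * count / total if total else 0.0
        density = count * 10_000 / length
        categories[cat] = CategoryStats(count, percent, density)
    if variants is None:
        ssv_count = ssv_density = None
    else:
        ssv_count = len(variants)
        ssv_density = ssv_count * 10_000 / length
    return RegionStats(label, categories, ssv_count, ssv_density, total, length, start, end)


def region_content_stats(
    features: Sequence[GeneFeature],
    variants: Sequence[ShortVariant] | None,
    region: Region,
    genome_length: int,
) -> tuple[RegionStats, RegionStats]:
    """(inside, outside) content statistics for a region.

    ORFs are assigned by start position; SSVs by anchor position; the
    outside row covers the genome minus the region.  Percentages use the
    region's ORF total; densities use the region length.  Values are
    unrounded — round only at reporting time.
    """
    if len(region) <= 0:
        raise ValueError("zero-length region")
    if region.end > genome_length:
        raise ValueError("region extends beyond genome")
    f_in = [f for f in features if region.contains(f.start)]
    f_out = [f for f in features if not region.contains(f.start)]
    if variants is None:
        v_in = v_out = None
    else:
        v_in = [v for v in variants if region.contains(v.position)]
        v_out = [v for v in variants if not region.contains(v.position)]
    inside = _stats_for(region.label or "inside", f_in, v_in, region.start, region.end, len(region))
    out_len = genome_length - len(region)
    outside = _stats_for("outside", f_out, v_out, 0, genome_length, out_len)
    return inside, outside


def stats_row_from_counts(
    label: str,
    counts: dict[str, int],
    length: int,
    ssv_count: int | None = None,
    start: int = 0,
    end: int | None = None,
    orf_total: int | None = None,
) -> RegionStats:
    """RegionStats from category counts alone, through the same
    percent/density arithmetic as :func:`region_content_stats` — used to
    recompute published content-table rows from their printed counts."""
    features = []
    idx = 0
    products = {
        "HP": "hypothetical protein",
        "PHAGE": "phage major capsid protein",
        "ME": "transposase",
        "FUNCTIONAL": "acetate kinase",
    }
    for cat_name, count in counts.items():
        for _ in range(count):
            idx += 1
            features.append(
                GeneFeature(
                    id=f"{label}_{idx}",
                    contig="chr",
                    start=start + idx,
                    end=start + idx + 1,
                    strand="+",
                    product=products[cat_name],
                    category=Category[cat_name],
                )
            )
    variants = (
        None
        if ssv_count is None
        else [
            ShortVariant("chr", start + i, "A", "C", "SNV", 100, 50)
            for i in range(ssv_count)
        ]
    )
    return _stats_for(
        label,
        features,
        variants,
        start,
        end if end is not None else start + length,
        length,
        orf_total=orf_total,
    )


# ---------------------------------------------------------------------------
# Enrichment


@dataclass
class MetricEnrichment:
    inside: float
    outside: float
    fold: float  # max/min, >= 1; infinite flagged with math.inf
    direction: str  # "higher-inside" | "higher-outside" | "none"


@dataclass
class EnrichmentReport:
    """Inside/outside fold ratios.

    Gene categories are compared on percent of ORFs; SSVs on density per
    10 kbp — the combination under which published inside/outside
    contrasts of both kinds are reproduced simultaneously.
    """

    metrics: dict[str, MetricEnrichment] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)


def _fold(inside: float, outside: float) -> MetricEnrichment:
    if inside == outside:
        return MetricEnrichment(inside, outside, 1.0, "none")
    lo, hi = sorted((inside, outside))
    fold = float("inf") if lo == 0 else hi / lo
    direction = "higher-inside" if inside > outside else "higher-outside"
    return MetricEnrichment(inside, outside, fold, direction)


def enrichment_ratios(stats_in: RegionStats, stats_out: RegionStats) -> EnrichmentReport:
    if stats_in.orf_total == 0 or stats_out.orf_total == 0:
        raise ValueError("degenerate region statistics (no ORFs)")
    report = EnrichmentReport()
    for cat in _CONTENT_CATS:
        report.metrics[cat.value] = _fold(
            stats_in.category(cat).percent, stats_out.category(cat).percent
        )
    if stats_in.ssv_density is not None and stats_out.ssv_density is not None:
        report.metrics["SSV"] = _fold(stats_in.ssv_density, stats_out.ssv_density)
    return report


# ---------------------------------------------------------------------------
# Anchor delimitation


def delimit_by_anchors(
    features: Sequence[GeneFeature], left_anchor: str, right_anchor: str
) -> Region:
    """Region between two named anchor genes (typically conserved tRNAs),
    exclusive of both: from the end of the left anchor to the start of
    the right one."""

    def find(name: str) -> GeneFeature:
        hits = [f for f in features if f.id == name or f.product == name]
        if not hits:
            raise ValueError(f"anchor {name!r} not found in annotation")
        if len(hits) > 1:
            locs = ", ".join(f"{f.id}@{f.start}" for f in hits)
            raise ValueError(f"anchor {name!r} is multi-copy ({locs}); cannot delimit uniquely")
        return hits[0]

    left = find(left_anchor)
    right = find(right_anchor)
    if right.start <= left.end:
        raise ValueError(
            f"right anchor {right_anchor!r} ({right.start}) does not lie after "
            f"left anchor {left_anchor!r} (ends {left.end})"
        )
    return Region(left.contig, left.end, right.start, f"{left_anchor}..{right_anchor}")


# ---------------------------------------------------------------------------
# De novo detection


@dataclass
class DetectionParams:
    """Sliding-window scrapyard criteria.

    A window is scrapyard-like when it passes the HP-proportion criterion
    plus at least one of: mobilome(+phage) gene density, SSV enrichment
    over the genome-median window density, or (optionally) GC-skew
    scatter above twice the genome background.  Runs of at least
    ``min_run`` consecutive passing windows (a ~10-kbp window holds only
    ~10 ORFs, so isolated windows pass by composition noise alone) are
    merged across gaps and short islands dropped.
    """

    window: int = 10_000
    step: int = 2_000
    hp_proportion: float = 0.55
    mobilome_density: float = 1.0  # ME+PHAGE ORFs per 10 kbp
    ssv_enrichment: float = 3.0  # x genome median window density
    use_skew_scatter: bool = False
    scatter_factor: float = 2.0
    min_run: int = 3  # consecutive passing windows
    merge_gap: int = 20_000
    min_length: int = 50_000
    refine_boundaries: bool = True
    refine_span: int = 20_000  # changepoint search radius around coarse edges


def detect_scrapyards(
    genome_length: int,
    features: Sequence[GeneFeature],
    variants: Sequence[ShortVariant] | None = None,
    skew: SkewProfile | None = None,
    params: DetectionParams | None = None,
    contig: str = "chr",
) -> list[Region]:
    """Scan the genome for scrapyard-like islands.

    Relaxing any threshold never shrinks the reported island coverage
    (detection is monotone in the parameters).
    """
    p = params or DetectionParams()
    if p.window > genome_length:
        raise ValueError("window exceeds genome length")
    starts = np.arange(0, genome_length - p.window + 1, p.step)

    orfs = sorted(
        (f for f in features if f.category in _CONTENT_CATS), key=lambda f: f.start
    )
    orf_starts = np.array([f.start for f in orfs], dtype=np.int64)
    is_hp = np.array([f.category is Category.HP for f in orfs])
    is_mob = np.array([f.category in (Category.ME, Category.PHAGE) for f in orfs])
    hp_cum = np.concatenate([[0], np.cumsum(is_hp)])
    mob_cum = np.concatenate([[0], np.cumsum(is_mob)])

    lo = np.searchsorted(orf_starts, starts)
    hi = np.searchsorted(orf_starts, starts + p.window)
    n_orf = hi - lo
    n_hp = hp_cum[hi] - hp_cum[lo]
    n_mob = mob_cum[hi] - mob_cum[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        hp_frac = np.where(n_orf > 0, n_hp / np.maximum(n_orf, 1), 0.0)
    mob_density = n_mob * 10_000 / p.window

    crit_hp = hp_frac >= p.hp_proportion
    crit_mob = mob_density >= p.mobilome_density

    crit_ssv = np.zeros(len(starts), dtype=bool)
    if variants is not None and len(variants):
        vpos = np.sort(np.array([v.position for v in variants], dtype=np.int64))
        vlo = np.searchsorted(vpos, starts)
        vhi = np.searchsorted(vpos, starts + p.window)
        ssv_density = (vhi - vlo) * 10_000 / p.window
        baseline = float(np.median(ssv_density))
        if baseline > 0:
            crit_ssv = ssv_density >= p.ssv_enrichment * baseline
        else:
            crit_ssv = ssv_density > 0

    crit_scatter = np.zeros(len(starts), dtype=bool)
    if p.use_skew_scatter and skew is not None:
        background = genome_scatter_background(skew)
        for i, s in enumerate(starts):
            region = Region(contig, int(s), int(s) + p.window)
            try:
                crit_scatter[i] = (
                    skew_scatter(skew, region) >= p.scatter_factor * background
                )
            except ValueError:
                crit_scatter[i] = False

    passing = crit_hp & (crit_mob | crit_ssv | crit_scatter)

    # Island bounds come from passing-window CENTERS (+/- half a step): a
    # boundary window only passes once most of it lies inside the island,
    # so its center tracks the true edge to within about one step, while
    # its outer end would overshoot by half a window.
    islands: list[Region] = []
    idx = np.flatnonzero(passing)
    if len(idx) == 0:
        return islands
    # keep only runs of >= min_run consecutive passing windows
    keep = []
    run: list[int] = []
    for i in idx:
        if run and i == run[-1] + 1:
            run.append(int(i))
        else:
            if len(run) >= p.min_run:
                keep.extend(run)
            run = [int(i)]
    if len(run) >= p.min_run:
        keep.extend(run)
    if not keep:
        return islands
    idx = np.array(keep)
    centers = starts[idx] + p.window // 2
    half = p.step // 2
    run_start = int(centers[0]) - half
    run_end = int(centers[0]) + half
    for c in centers[1:]:
        c = int(c)
        if c - half - run_end <= p.merge_gap:
            run_end = max(run_end, c + half)
        else:
            if run_end - run_start >= p.min_length:
                islands.append(
                    Region(contig, run_start, run_end, f"scrapyard_{len(islands) + 1}")
                )
            run_start, run_end = c - half, c + half
    if run_end - run_start >= p.min_length:
        islands.append(Region(contig, run_start, run_end, f"scrapyard_{len(islands) + 1}"))
    if p.refine_boundaries and islands:
        vpos = (
            np.sort(np.array([v.position for v in variants], dtype=np.int64))
            if variants
            else None
        )
        islands = _refine_island_boundaries(
            islands, orf_starts, is_hp, vpos, p, contig, genome_length
        )
    return islands


def _refine_island_boundaries(
    islands: list[Region],
    orf_starts: np.ndarray,
    is_hp: np.ndarray,
    vpos: np.ndarray | None,
    p: DetectionParams,
    contig: str,
    genome_length: int,
) -> list[Region]:
    """Sharpen coarse window-grid edges by a changepoint scan.

    Window-level criteria locate islands to within half a window at best,
    and boundary windows fail stochastically — a 10-kbp window holds only
    ~10 ORFs.  Around each coarse edge, 1-kbp bins are scored by the
    log-likelihood ratio of the island model versus the background model:
    binomial for the ORF HP labels plus Poisson for the SSV rate (both
    estimated from the coarse segmentation).  The boundary moves to the
    cut maximizing the island-side score.
    """
    inside = np.zeros(len(orf_starts), dtype=bool)
    for r in islands:
        inside |= (orf_starts >= r.start) & (orf_starts < r.end)
    if inside.sum() < 5 or (~inside).sum() < 5:
        return islands
    p_in = float(np.clip(is_hp[inside].mean(), 0.05, 0.95))
    p_out = float(np.clip(is_hp[~inside].mean(), 0.05, 0.95))
    if p_in <= p_out:
        return islands
    w_hp = math.log(p_in / p_out)
    w_fn = math.log((1 - p_in) / (1 - p_out))

    w_ssv = 0.0
    rate_diff = 0.0
    if vpos is not None and len(vpos):
        island_len = sum(len(r) for r in islands)
        out_len = max(genome_length - island_len, 1)
        v_inside = np.zeros(len(vpos), dtype=bool)
        for r in islands:
            v_inside |= (vpos >= r.start) & (vpos < r.end)
        lam_in = max(v_inside.sum() / island_len, 1e-9)
        lam_out = max((~v_inside).sum() / out_len, 1e-9)
        if lam_in > lam_out:
            w_ssv = math.log(lam_in / lam_out)
            rate_diff = lam_in - lam_out

    bin_size = 1000

    def bin_scores(lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
        edges = np.arange(lo, hi + bin_size, bin_size)
        score = np.full(len(edges) - 1, -rate_diff * bin_size)
        o = orf_starts[(orf_starts >= lo) & (orf_starts < hi)]
        h = is_hp[(orf_starts >= lo) & (orf_starts < hi)]
        idx = (o - lo) // bin_size
        np.add.at(score, idx, np.where(h, w_hp, w_fn))
        if w_ssv > 0 and vpos is not None:
            v = vpos[(vpos >= lo) & (vpos < hi)]
            np.add.at(score, (v - lo) // bin_size, w_ssv)
        return edges, score

    def refine(edge: int, side: str) -> int:
        lo = max(0, edge - p.refine_span)
        hi = min(genome_length, edge + p.refine_span)
        edges, score = bin_scores(lo, hi)
        if side == "left":  # island to the right: maximize suffix sum
            suffix = np.concatenate([np.cumsum(score[::-1])[::-1], [0.0]])
            return int(edges[int(np.argmax(suffix))])
        prefix = np.concatenate([[0.0], np.cumsum(score)])
        return int(edges[int(np.argmax(prefix))])

    refined = []
    for r in islands:
        start = max(0, refine(r.start, "left"))
        end = min(genome_length, refine(r.end, "right"))
        if end - start >= p.min_length:
            refined.append(Region(contig, start, end, r.label))
        else:
            refined.append(r)
    return refined


def jaccard(a: Region, b: Region) -> float:
    """Interval Jaccard overlap of two regions on the same contig."""
    if a.contig != b.contig:
        return 0.0
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    union = (a.end - a.start) + (b.end - b.start) - inter
    return inter / union if union else 0.0


# ---------------------------------------------------------------------------
# Reporting


def format_table(rows: Sequence[RegionStats]) -> str:
    """TSV content table, column-compatible with the published layout;
    percents/densities rounded to 3 significant digits at print time."""

    def sig3(x: float | None) -> str:
        if x is None:
            return "N/A"
        if x == 0:
            return "0"
        return f"{x:.3g}"

    header = ["label"]
    for cat in _CONTENT_CATS:
        header += [f"{cat.value}_count", f"{cat.value}_pct", f"{cat.value}_per10kbp"]
    header += ["SSV_count", "SSV_per10kbp", "ORF_total", "length_bp", "from_bp", "to_bp"]
    lines = ["\t".join(header)]
    for r in rows:
        cells = [r.label]
        for cat in _CONTENT_CATS:
            c = r.category(cat)
            cells += [str(c.count), sig3(c.percent), sig3(c.density)]
        cells += [
            "N/A" if r.ssv_count is None else str(r.ssv_count),
            sig3(r.ssv_density),
            str(r.orf_total),
            str(r.length),
            str(r.start + 1),
            str(r.end),
        ]
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


__all__ = [
    "CategoryStats",
    "DetectionParams",
    "EnrichmentReport",
    "MetricEnrichment",
    "RegionStats",
    "delimit_by_anchors",
    "detect_scrapyards",
    "enrichment_ratios",
    "format_table",
    "jaccard",
    "region_content_stats",
    "stats_row_from_counts",
]
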