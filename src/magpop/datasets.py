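"""Published regional content statistics of five natural populations.

Per-region gene-content and short-variant counts observed in five complete
genomes of a chemolithotrophic bacterium assembled from single-species-
dominated biostalactite metagenomes: the scrapyard island of each genome
(delimited by conserved tRNA anchors) versus the rest of the chromosome,
plus the alternative scrapyard of strain S2.4.  These counts are the
package's worked example: feeding them through
:func:`magpop.scrapyard.stats_row_from_counts` and
:func:`magpop.scrapyard.enrichment_ratios` recomputes every published
percent, density and fold ratio, and the printed percent/density columns
drive the published rank tests.

``printed`` holds the values as published (percents to ~3 significant
digits, densities to 2 decimals) for comparison against the recomputed
ones.  The S2.4 outside row's printed ORF total (2497) exceeds the sum of
its four category counts (2436); the published percents divide by the
printed total, so it is carried explicitly.
"""

from __future__ import annotations

#: strain -> region ("scrapyard" | "outside") -> row dict with keys
#: counts (HP/PHAGE/ME/FUNCTIONAL), ssv (count or None), length (bp),
#: start/end (1-based "From bp"/"To bp", scrapyard rows only),
#: orf_total, printed {category: (percent, density), "SSV": density}.
CONTENT_TABLE: dict[str, dict[str, dict]] = {
    "MI1A": {
        "scrapyard": {
            "counts": {"HP": 175, "PHAGE": 9, "ME": 22, "FUNCTIONAL": 38},
            "ssv": 231,
            "length": 193839,
            "start": 32354,
            "end": 226193,
            "orf_total": 244,
            "printed": {
                "HP": (71.7, 9.03),
                "PHAGE": (3.69, 0.46),
                "ME": (9.02, 1.13),
                "FUNCTIONAL": (15.6, 1.96),
                "SSV": 11.9,
            },
        },
        "outside": {
            "counts": {"HP": 1026, "PHAGE": 13, "ME": 116, "FUNCTIONAL": 1592},
            "ssv": 452,
            "length": 2555267,
            "orf_total": 2747,
            "printed": {
                "HP": (37.4, 4.02),
                "PHAGE": (0.47, 0.05),
                "ME": (4.22, 0.45),
                "FUNCTIONAL": (58.0, 6.23),
                "SSV": 1.77,
            },
        },
    },
    "MI1I": {
        "scrapyard": {
            "counts": {"HP": 175, "PHAGE": 10, "ME": 21, "FUNCTIONAL": 43},
            "ssv": 162,
            "length": 193534,
            "start": 32354,
            "end": 225888,
            "orf_total": 249,
            "printed": {
                "HP": (70.3, 9.04),
                "PHAGE": (4.02, 0.52),
                "ME": (8.43, 1.09),
                "FUNCTIONAL": (17.3, 2.22),
                "SSV": 8.37,
            },
        },
        "outside": {
            "counts": {"HP": 1040, "PHAGE": 12, "ME": 127, "FUNCTIONAL": 1588},
            "ssv": 413,
            "length": 2560898,
            "orf_total": 2767,
            "printed": {
                "HP": (37.6, 4.06),
                "PHAGE": (0.43, 0.05),
                "ME": (4.59, 0.50),
                "FUNCTIONAL": (57.4, 6.20),
                "SSV": 1.61,
            },
        },
    },
    "MI1III": {
        "scrapyard": {
            "counts": {"HP": 162, "PHAGE": 9, "ME": 16, "FUNCTIONAL": 41},
            "ssv": None,
            "length": 184321,
            "start": 32348,
            "end": 216669,
            "orf_total": 228,
            "printed": {
                "HP": (71.1, 8.79),
                "PHAGE": (3.95, 0.49),
                "ME": (7.02, 0.87),
                "FUNCTIONAL": (18.0, 2.22),
                "SSV": None,
            },
        },
        "outside": {
            "counts": {"HP": 1027, "PHAGE": 12, "ME": 118, "FUNCTIONAL": 1590},
            "ssv": None,
            "length": 2564129,
            "orf_total": 2747,
            "printed": {
                "HP": (37.4, 4.01),
                "PHAGE": (0.44, 0.05),
                "ME": (4.30, 0.46),
                "FUNCTIONAL": (57.9, 6.20),
                "SSV": None,
            },
        },
    },
    "S2.4": {
        "scrapyard": {
            "counts": {"HP": 95, "PHAGE": 1, "ME": 7, "FUNCTIONAL": 51},
            "ssv": 3,
            "length": 134793,
            "start": 31234,
            "end": 166027,
            "orf_total": 154,
            "printed": {
                "HP": (61.7, 7.05),
                "PHAGE": (0.65, 0.07),
                "ME": (4.55, 0.52),
                "FUNCTIONAL": (33.1, 3.78),
                "SSV": 0.22,
            },
        },
        "outside": {
            "counts": {"HP": 853, "PHAGE": 12, "ME": 49, "FUNCTIONAL": 1522},
            "ssv": 317,
            "length": 2350931,
            "orf_total": 2497,  # exceeds the category sum (2436) as published
            "printed": {
                "HP": (34.2, 3.63),
                "PHAGE": (0.48, 0.05),
                "ME": (1.96, 0.21),
                "FUNCTIONAL": (61.0, 6.47),
                "SSV": 1.35,
            },
        },
    },
    "OL2a6": {
        "scrapyard": {
            "counts": {"HP": 142, "PHAGE": 0, "ME": 32, "FUNCTIONAL": 41},
            "ssv": 61,
            "length": 156636,
            "start": 293058,
            "end": 449694,
            "orf_total": 215,
            "printed": {
                "HP": (66.1, 9.07),
                "PHAGE": (0.0, 0.0),
                "ME": (14.9, 2.04),
                "FUNCTIONAL": (19.1, 2.62),
                "SSV": 3.89,
            },
        },
        "outside": {
            "counts": {"HP": 1030, "PHAGE": 8, "ME": 169, "FUNCTIONAL": 1576},
            "ssv": 355,
            "length": 2538403,
            "orf_total": 2783,
            "printed": {
                "HP": (37.0, 4.06),
                "PHAGE": (0.29, 0.03),
                "ME": (6.07, 0.67),
                "FUNCTIONAL": (56.6, 6.21),
                "SSV": 1.40,
            },
        },
    },
    "S2.4 alt.": {
        "scrapyard": {
            "counts": {"HP": 150, "PHAGE": 18, "ME": 12, "FUNCTIONAL": 61},
            "ssv": 278,
            "length": 188208,
            "start": 456809,
            "end": 645017,
            "orf_total": 241,
            "printed": {
                "HP": (62.2, 7.97),
                "PHAGE": (7.47, 0.96),
                "ME": (4.98, 0.64),
                "FUNCTIONAL": (25.3, 3.24),
                "SSV": 14.8,
            },
        },
    },
}

#: The five strains with both rows (the alternative scrapyard has no
#: published outside row of its own).
STRAINS = ("MI1A", "MI1I", "MI1III", "S2.4", "OL2a6")

#: Published fold contrasts between scrapyards and the rest of the
#: genomes: SSV density ratios per strain (direction: higher inside
#: except S2.4) and category percent-ratio ranges across strains.
PUBLISHED_SSV_FOLDS = {"MI1A": 6.7, "MI1I": 5.2, "OL2a6": 2.8, "S2.4": 6.1}
PUBLISHED_PERCENT_RANGES = {
    "HP": (1.7, 1.9),  # lower outside
    "ME": (1.6, 2.5),  # lower outside
    "FUNCTIONAL": (1.8, 3.7),  # higher outside
}

#: Published rank-test p-values with the table columns they compare
#: (scrapyard versus outside across the five strains): functional-gene
#: percents, HP percents (a tie forces the approximation branch), and
#: ME per-10-kbp densities.
PUBLISHED_P_VALUES = {"FUNCTIONAL_percent": 0.008, "HP_percent": 0.012, "ME_density": 0.016}

#: Published fractions of SSVs lying inside ORFs (MI1A, MI1I, S2.4, OL2a6).
PUBLISHED_SSV_ORF_PERCENT = {"MI1A": 86, "MI1I": 81, "S2.4": 87, "OL2a6": 85}


def printed_column(region: str, category: str, kind: str) -> list[float]:
    """Published column across :data:`STRAINS` (skipping N/A entries).

    ``kind`` is "percent" or "density"; ``category`` one of HP/PHAGE/ME/
    FUNCTIONAL/SSV.
    """
    out = []
    for strain in STRAINS:
        row = CONTENT_TABLE[strain][region]
        printed = row["printed"][category]
        if category == "SSV":
            value = printed
        else:
            value = printed[0] if kind == "percent" else printed[1]
        if value is None:
            continue
        out.append(value)
    return out


__all__ = [
    "CONTENT_TABLE",
    "PUBLISHED_P_VALUES",
    "PUBLISHED_PERCENT_RANGES",
    "PUBLISHED_SSV_FOLDS",
    "PUBLISHED_SSV_ORF_PERCENT",
    "STRAINS",
    "printed_column",
]
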