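"""Self-contained statistics kernels.

GC skew profiling and the adjacent-sign "scatter" statistic used to
corroborate scrapyard islands; an exact Mann-Whitney U test matching R's
``wilcox.test`` switching behavior; and Nei-Gojobori (1986) dN/dS with
Jukes-Cantor correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from magpop.core_io import Region, reverse_complement

# ---------------------------------------------------------------------------
# GC skew


@dataclass
class SkewProfile:
    """Per-window (G-C)/(G+C) values over a sequence.

    ``starts[i]`` is the 0-based window start; windows wrap in circular
    mode.  ``signs`` holds +1/-1/0 (0 where the window has no G or C).
    """

    window: int
    step: int
    starts: np.ndarray
    values: np.ndarray
    signs: np.ndarray
    circular: bool = False

    def __len__(self) -> int:
        return len(self.values)

    def windows_in(self, region: Region) -> np.ndarray:
        """Boolean mask of windows whose start lies inside ``region``."""
        return (self.starts >= region.start) & (self.starts < region.end)


def gc_skew_profile(sequence: str, window: int, step: int, circular: bool = False) -> SkewProfile:
    """Sliding-window GC skew (G-C)/(G+C).

    Linear mode yields ``floor((L - window)/step) + 1`` windows; circular
    mode yields ``ceil(L/step)`` windows that wrap past the origin.
    Windows with G+C = 0 get value 0 and sign 0.
    """
    L = len(sequence)
    if L == 0:
        raise ValueError("empty sequence")
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if window > L:
        raise ValueError(f"window ({window}) exceeds sequence length ({L})")

    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    is_g = (arr == ord("G")).astype(np.int64)
    is_c = (arr == ord("C")).astype(np.int64)
    if circular:
        starts = np.arange(0, L, step)
        is_g = np.concatenate([is_g, is_g[: window - 1]]) if window > 1 else is_g
        is_c = np.concatenate([is_c, is_c[: window - 1]]) if window > 1 else is_c
    else:
        starts = np.arange(0, L - window + 1, step)
    cg = np.concatenate([[0], np.cumsum(is_g)])
    cc = np.concatenate([[0], np.cumsum(is_c)])
    g = cg[starts + window] - cg[starts]
    c = cc[starts + window] - cc[starts]
    tot = g + c
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(tot > 0, (g - c) / np.maximum(tot, 1), 0.0)
    signs = np.sign(values).astype(np.int8)
    signs[tot == 0] = 0
    return SkewProfile(window, step, starts, values, signs, circular)


def skew_sign_changes(profile: SkewProfile) -> int:
    """Number of sign flips between successive nonzero-sign windows
    (wrapping in circular mode).  A correctly assembled circular
    chromosome with two replichores shows exactly two."""
    s = profile.signs[profile.signs != 0]
    if len(s) < 2:
        return 0
    pairs = zip(s, np.roll(s, -1)) if profile.circular else zip(s[:-1], s[1:])
    return sum(1 for a, b in pairs if a != b)


def skew_scatter(profile: SkewProfile, region: Region) -> float:
    """Fraction of adjacent window pairs inside ``region`` whose nonzero
    skew signs differ.  0 for a constant-sign region, ~0.5 for i.i.d.
    random signs, 1 for strictly alternating signs."""
    mask = profile.windows_in(region)
    if mask.sum() < 3:
        raise ValueError(
            f"region {region.label!r} covers {int(mask.sum())} windows; need >= 3"
        )
    signs = profile.signs[mask]
    signs = signs[signs != 0]
    if len(signs) < 2:
        return 0.0
    return float(np.mean(signs[:-1] != signs[1:]))


def genome_scatter_background(profile: SkewProfile) -> float:
    """Genome-wide adjacent-sign flip fraction, for comparison with
    per-region :func:`skew_scatter` values."""
    signs = profile.signs[profile.signs != 0]
    if len(signs) < 2:
        return 0.0
    return float(np.mean(signs[:-1] != signs[1:]))


# ---------------------------------------------------------------------------
# Mann-Whitney U


@dataclass
class MannWhitneyResult:
    u: float
    p_value: float
    method: str  # "exact" or "normal-approximation"


def _rank(values: np.ndarray) -> np.ndarray:
    """Midranks (1-based, ties averaged)."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    sorted_v = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def _exact_u_distribution(m: int, n: int) -> list[int]:
    """Counts of labelings per U value of the size-``m`` group, over all
    C(m+n, m) ways of assigning ranks 1..m+n without ties.

    Rank-subset DP: ``f[k][s]`` = number of k-subsets of the ranks seen so
    far with rank-sum s; U = s - m(m+1)/2.
    """
    N = m + n
    max_sum = sum(range(N - m + 1, N + 1))
    f = [[0] * (max_sum + 1) for _ in range(m + 1)]
    f[0][0] = 1
    for r in range(1, N + 1):
        for k in range(min(m, r), 0, -1):
            row, prev = f[k], f[k - 1]
            for s in range(max_sum, r - 1, -1):
                if prev[s - r]:
                    row[s] += prev[s - r]
    offset = m * (m + 1) // 2
    return [f[m][u + offset] for u in range(m * n + 1)]


def mann_whitney_exact(group_a, group_b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Without ties and with m+n <= 20 the p-value is exact, from the full
    distribution of U over all C(m+n, n) labelings.  With ties or larger
    samples it falls back to the normal approximation with tie-corrected
    variance and continuity correction — the same switching rule as R's
    ``wilcox.test`` default.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    m, n = len(a), len(b)
    if m == 0 or n == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = _rank(pooled)
    ra = ranks[:m].sum()
    u_a = ra - m * (m + 1) / 2  # number of (a, b) pairs with a > b
    has_ties = len(np.unique(pooled)) < m + n

    if not has_ties and m + n <= 20:
        dist = _exact_u_distribution(m, n)  # distribution of U_A
        total = sum(dist)
        u = int(round(u_a))
        p_le = sum(dist[: u + 1]) / total
        p_ge = sum(dist[u:]) / total
        p = min(1.0, 2 * min(p_le, p_ge))
        return MannWhitneyResult(u_a, p, "exact")

    N = m + n
    mu = m * n / 2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    sigma2 = m * n / 12 * ((N + 1) - tie_term / (N * (N - 1)))
    if sigma2 <= 0:
        return MannWhitneyResult(u_a, 1.0, "normal-approximation")
    diff = u_a - mu
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(sigma2)
    p = min(1.0, math.erfc(abs(z) / math.sqrt(2)))
    return MannWhitneyResult(u_a, p, "normal-approximation")


# ---------------------------------------------------------------------------
# NG86 dN/dS

_BASES = "TCAG"
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE = dict(zip(_CODONS, _AA))
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")


@dataclass
class DnDsResult:
    """Nei-Gojobori site/difference counts and corrected rates.

    ``ratio`` is ``None`` when dS = 0 or a Jukes-Cantor correction
    saturates (p >= 3/4).
    """

    n_sites: float
    s_sites: float
    n_diffs: float
    s_diffs: float
    pn: float
    ps: float
    dn: float | None
    ds: float | None
    ratio: float | None


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts for one codon.

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes to stop codons count as nonsynonymous.
    """
    syn = 0.0
    aa = GENETIC_CODE[codon]
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa and mutant not in STOP_CODONS:
                syn += 1 / 3
    return 3.0 - syn, syn


def _codon_diff_counts(c1: str, c2: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) differences between two codons,
    averaged over all minimal mutational pathways; pathways passing
    through a stop codon are excluded (unless all do)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        current = c1
        nd = sd = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if GENETIC_CODE[nxt] == "*" and nxt != c2:
                through_stop = True
            if GENETIC_CODE[current] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        pathways.append((nd, sd, through_stop))
    valid = [(nd, sd) for nd, sd, ts in pathways if not ts]
    if not valid:
        valid = [(nd, sd) for nd, sd, _ in pathways]
    nd = sum(v[0] for v in valid) / len(valid)
    sd = sum(v[1] for v in valid) / len(valid)
    return nd, sd


def _jukes_cantor(p: float) -> float | None:
    arg = 1 - 4 * p / 3
    if arg <= 0:
        return None
    return -0.75 * math.log(arg)


def dnds_ng86(coding_seq_a: str, coding_seq_b: str) -> DnDsResult:
    """Nei-Gojobori (NG86) dN/dS for an in-frame, gap-free sequence pair.

    Site counts are averaged over both sequences; multi-substitution
    codons average their differences over all minimal mutational
    pathways; pN and pS are Jukes-Cantor corrected.
    """
    a, b = coding_seq_a.upper(), coding_seq_b.upper()
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    if len(a) % 3 != 0:
        raise ValueError(f"length {len(a)} not divisible by 3")
    if set(a + b) - set("ACGT"):
        raise ValueError("sequences must be gap-free A/C/G/T")
    codons_a = [a[i : i + 3] for i in range(0, len(a), 3)]
    codons_b = [b[i : i + 3] for i in range(0, len(b), 3)]
    for i, (ca, cb) in enumerate(zip(codons_a, codons_b)):
        internal = i < len(codons_a) - 1
        if internal and (ca in STOP_CODONS or cb in STOP_CODONS):
            raise ValueError(f"internal stop codon at codon {i}")
    # drop a trailing stop pair from the site/difference accounting
    if codons_a and (codons_a[-1] in STOP_CODONS or codons_b[-1] in STOP_CODONS):
        codons_a, codons_b = codons_a[:-1], codons_b[:-1]

    n_sites = s_sites = 0.0
    n_diffs = s_diffs = 0.0
    for ca, cb in zip(codons_a, codons_b):
        na, sa = _codon_site_counts(ca)
        nb, sb = _codon_site_counts(cb)
        n_sites += (na + nb) / 2
        s_sites += (sa + sb) / 2
        nd, sd = _codon_diff_counts(ca, cb)
        n_diffs += nd
        s_diffs += sd

    pn = n_diffs / n_sites if n_sites else 0.0
    ps = s_diffs / s_sites if s_sites else 0.0
    dn = _jukes_cantor(pn)
    ds = _jukes_cantor(ps)
    ratio = None
    if dn is not None and ds is not None and ds > 0:
        ratio = dn / ds
    return DnDsResult(n_sites, s_sites, n_diffs, s_diffs, pn, ps, dn, ds, ratio)


__all__ = [
    "DnDsResult",
    "GENETIC_CODE",
    "MannWhitneyResult",
    "SkewProfile",
    "dnds_ng86",
    "gc_skew_profile",
    "genome_scatter_background",
    "mann_whitney_exact",
    "skew_scatter",
    "skew_sign_changes",
]
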