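"""Statistics kernels: GC skew, scatter, Mann-Whitney U, NG86 dN/dS."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from magpop.core_io import Region, reverse_complement
from magpop.stats import (
    SkewProfile,
    dnds_ng86,
    gc_skew_profile,
    genome_scatter_background,
    mann_whitney_exact,
    skew_scatter,
    skew_sign_changes,
)

# ---------------------------------------------------------------------------
# GC skew


class TestSkew:
    def test_direct_count(self):
        p = gc_skew_profile("GGGGCC", 6, 6)
        assert p.values[0] == pytest.approx((4 - 2) / (4 + 2))
        assert p.signs[0] == 1

    def test_no_gc_window_gets_zero_sign(self):
        p = gc_skew_profile("ATATAT", 6, 6)
        assert p.values[0] == 0.0
        assert p.signs[0] == 0

    def test_two_replichore_genome_has_two_sign_changes(self):
        # G-biased first half, C-biased second half, circular
        seq = "G" * 500 + "C" * 500
        p = gc_skew_profile(seq, 100, 100, circular=True)
        assert skew_sign_changes(p) == 2

    def test_reverse_complement_negates_skew(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 1200))
        fwd = gc_skew_profile(seq, 100, 100, circular=True)
        rev = gc_skew_profile(reverse_complement(seq), 100, 100, circular=True)
        assert np.allclose(sorted(fwd.values), sorted(-rev.values))

    def test_window_count_invariants(self):
        seq = "ACGT" * 250
        linear = gc_skew_profile(seq, 100, 30)
        assert len(linear) == (1000 - 100) // 30 + 1
        circular = gc_skew_profile(seq, 100, 30, circular=True)
        assert len(circular) == math.ceil(1000 / 30)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            gc_skew_profile("", 10, 10)


def _profile_from_signs(signs, step=100):
    signs = np.asarray(signs, dtype=np.int8)
    starts = np.arange(len(signs)) * step
    return SkewProfile(step, step, starts, signs.astype(float) * 0.1, signs)


class TestScatter:
    def test_constant_sign_region_is_zero(self):
        p = _profile_from_signs([1] * 10)
        assert skew_scatter(p, Region("chr", 0, 1000)) == 0.0

    def test_alternating_signs_give_one(self):
        p = _profile_from_signs([1, -1] * 5)
        assert skew_scatter(p, Region("chr", 0, 1000)) == 1.0

    def test_random_signs_near_half(self):
        rng = np.random.default_rng(1)
        p = _profile_from_signs(rng.choice([-1, 1], 1000))
        frac = skew_scatter(p, Region("chr", 0, 100_000))
        sigma = 0.5 / math.sqrt(999)
        assert abs(frac - 0.5) < 3 * sigma

    def test_region_too_narrow_rejected(self):
        p = _profile_from_signs([1] * 10)
        with pytest.raises(ValueError, match="windows"):
            skew_scatter(p, Region("chr", 0, 150))

    def test_background_matches_whole_genome_scatter(self):
        p = _profile_from_signs([1, 1, -1, 1, -1, -1])
        assert genome_scatter_background(p) == pytest.approx(3 / 5)


# ---------------------------------------------------------------------------
# Mann-Whitney


def _enumeration_oracle(a, b):
    """Two-sided exact p by brute force over all labelings (no ties)."""
    pooled = list(a) + list(b)
    m = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    mn = m * len(b)

    def u_of(subset):
        rest = [pooled[i] for i in range(len(pooled)) if i not in subset]
        chosen = [pooled[i] for i in subset]
        return sum(1 for x in chosen for y in rest if x > y)

    us = [u_of(s) for s in itertools.combinations(range(len(pooled)), m)]
    p_le = sum(1 for u in us if u <= u_obs) / len(us)
    p_ge = sum(1 for u in us if u >= u_obs) / len(us)
    return min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    def test_complete_separation_small(self):
        res = mann_whitney_exact([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups(self):
        res = mann_whitney_exact([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=5), rng.normal(size=7)
        assert mann_whitney_exact(a, b).p_value == pytest.approx(
            mann_whitney_exact(b, a).p_value
        )

    def test_complete_separation_minimizes_p(self):
        rng = np.random.default_rng(3)
        a = sorted(rng.normal(size=4))
        b = sorted(rng.normal(size=4))
        sep_p = mann_whitney_exact([1, 2, 3, 4], [5, 6, 7, 8]).p_value
        assert mann_whitney_exact(a, b).p_value >= sep_p

    @pytest.mark.parametrize("m,n", [(m, n) for m in range(1, 7) for n in range(m, 7)])
    def test_exact_branch_equals_enumeration(self, m, n):
        rng = np.random.default_rng(m * 10 + n)
        a = list(rng.permutation(np.arange(1.0, m + n + 1))[:m])
        b = [x for x in np.arange(1.0, m + n + 1) if x not in a]
        res = mann_whitney_exact(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(_enumeration_oracle(a, b), abs=1e-12)

    def test_tied_data_matches_reference_environment(self):
        # tie-corrected normal approximation with continuity correction
        a = [71.7, 70.3, 71.1, 61.7, 66.1]
        b = [37.4, 37.6, 37.4, 34.2, 37.0]
        res = mann_whitney_exact(a, b)
        assert res.method == "normal-approximation"
        ref = sps.mannwhitneyu(a, b, method="asymptotic").pvalue
        assert res.p_value == pytest.approx(ref, abs=1e-9)


# ---------------------------------------------------------------------------
# NG86 dN/dS


def _oracle_ng86(a, b):
    """Independent brute-force NG86: codon tables from biopython, explicit
    pathway enumeration; stop changes nonsynonymous, stop pathways skipped."""
    from Bio.Data.CodonTable import standard_dna_table

    code = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        code[stop] = "*"

    def sites(codon):
        syn = 0.0
        for i in range(3):
            for base in "ACGT":
                if base == codon[i]:
                    continue
                mut = codon[:i] + base + codon[i + 1 :]
                if code[mut] == code[codon] and code[mut] != "*":
                    syn += 1 / 3
        return 3 - syn, syn

    n_sites = s_sites = nd = sd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        na, sa = sites(ca)
        nb, sb = sites(cb)
        n_sites += (na + nb) / 2
        s_sites += (sa + sb) / 2
        pos = [j for j in range(3) if ca[j] != cb[j]]
        if not pos:
            continue
        paths = []
        for order in itertools.permutations(pos):
            cur, pn, ps, bad = ca, 0, 0, False
            for j in order:
                nxt = cur[:j] + cb[j] + cur[j + 1 :]
                if code[nxt] == "*" and nxt != cb:
                    bad = True
                if code[nxt] == code[cur]:
                    ps += 1
                else:
                    pn += 1
                cur = nxt
            paths.append((pn, ps, bad))
        ok = [(x, y) for x, y, bad in paths if not bad] or [(x, y) for x, y, _ in paths]
        nd += sum(p[0] for p in ok) / len(ok)
        sd += sum(p[1] for p in ok) / len(ok)
    pn_, ps_ = nd / n_sites, sd / s_sites
    jc = lambda p: None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
    return n_sites, s_sites, nd, sd, pn_, ps_, jc(pn_), jc(ps_)


def _planted_gene_pair(seed=4, codons=200, syn=6, nonsyn=4):
    """Random stop-free coding pair differing by exactly ``syn``
    synonymous and ``nonsyn`` nonsynonymous single-codon changes."""
    from Bio.Data.CodonTable import standard_dna_table

    code = dict(standard_dna_table.forward_table)
    rng = np.random.default_rng(seed)
    all_codons = [c for c in code]  # sense codons only
    seq_a = [all_codons[i] for i in rng.integers(0, len(all_codons), codons)]
    seq_b = list(seq_a)
    order = list(rng.permutation(codons))
    placed_syn = placed_non = 0
    for idx in order:
        codon = seq_a[idx]
        subs = []
        for i in range(3):
            for base in "ACGT":
                if base == codon[i]:
                    continue
                mut = codon[:i] + base + codon[i + 1 :]
                if mut in code:
                    subs.append((mut, code[mut] == code[codon]))
        rng.shuffle(subs)
        if placed_syn < syn:
            pick = next((m for m, is_syn in subs if is_syn), None)
            if pick:
                seq_b[idx] = pick
                placed_syn += 1
                continue
        if placed_non < nonsyn:
            pick = next((m for m, is_syn in subs if not is_syn), None)
            if pick:
                seq_b[idx] = pick
                placed_non += 1
        if placed_syn == syn and placed_non == nonsyn:
            break
    assert (placed_syn, placed_non) == (syn, nonsyn)
    return "".join(seq_a), "".join(seq_b)


class TestDnDs:
    def test_identical_sequences_undefined_ratio(self):
        r = dnds_ng86("ATGAAACCC", "ATGAAACCC")
        assert r.pn == r.ps == 0.0
        assert r.ratio is None

    def test_nonsynonymous_only_flags_undefined(self):
        r = dnds_ng86("ATGAAA", "ATGATA")  # Lys -> Ile
        assert r.s_diffs == 0.0
        assert r.ds == 0.0 or r.ds == -0.0
        assert r.ratio is None

    def test_site_conservation(self):
        a, b = _planted_gene_pair()
        r = dnds_ng86(a, b)
        assert r.n_sites + r.s_sites == pytest.approx(len(a), abs=1e-9)

    def test_matches_brute_force_oracle(self):
        a, b = _planted_gene_pair(seed=4, codons=200, syn=6, nonsyn=4)
        r = dnds_ng86(a, b)
        n_sites, s_sites, nd, sd, pn, ps, dn, ds = _oracle_ng86(a, b)
        assert r.n_sites == pytest.approx(n_sites, abs=1e-9)
        assert r.s_sites == pytest.approx(s_sites, abs=1e-9)
        assert r.n_diffs == pytest.approx(nd, abs=1e-9)
        assert r.s_diffs == pytest.approx(sd, abs=1e-9)
        assert r.pn == pytest.approx(pn, abs=1e-9)
        assert r.ps == pytest.approx(ps, abs=1e-9)
        assert r.dn == pytest.approx(dn, abs=1e-9)
        assert r.ds == pytest.approx(ds, abs=1e-9)
        assert r.ratio == pytest.approx(dn / ds, rel=1e-9)

    def test_multi_substitution_codons_match_oracle(self):
        rng = np.random.default_rng(7)
        bases = "ACGT"
        for _ in range(20):
            a = "".join(rng.choice(list(bases), 30))
            b = "".join(rng.choice(list(bases), 30))
            stops = {"TAA", "TAG", "TGA"}
            if any(s[i : i + 3] in stops for s in (a, b) for i in range(0, 30, 3)):
                continue  # oracle does not model stop-codon trimming
            r = dnds_ng86(a, b)
            n_sites, s_sites, nd, sd, *_ = _oracle_ng86(a, b)
            assert r.n_diffs == pytest.approx(nd, abs=1e-9)
            assert r.s_diffs == pytest.approx(sd, abs=1e-9)

    def test_codon_permutation_invariance(self):
        a, b = _planted_gene_pair(seed=9, codons=50)
        rng = np.random.default_rng(10)
        perm = rng.permutation(50)
        pa = "".join(a[3 * i : 3 * i + 3] for i in perm)
        pb = "".join(b[3 * i : 3 * i + 3] for i in perm)
        r1, r2 = dnds_ng86(a, b), dnds_ng86(pa, pb)
        assert (r1.pn, r1.ps) == pytest.approx((r2.pn, r2.ps))

    def test_input_contract(self):
        with pytest.raises(ValueError, match="length"):
            dnds_ng86("ATG", "ATGAAA")
        with pytest.raises(ValueError, match="divisible"):
            dnds_ng86("ATGA", "ATGA")
        with pytest.raises(ValueError, match="stop"):
            dnds_ng86("TAAAAA", "TAAAAA")
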