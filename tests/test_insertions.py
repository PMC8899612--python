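"""Insertion signal extraction, clustering, classification, junctions."""

import numpy as np
import pytest

from magpop.core_io import (
    AlignmentRecord,
    Category,
    GeneFeature,
    read_alignments,
    reverse_complement,
)
from magpop.insertions import (
    DISRUPT_FUNCTIONAL,
    DISRUPT_HP,
    DISRUPT_INTERGENIC,
    DISRUPT_SELFISH,
    InsertionCall,
    POSSIBLY_NON_VARIABLE,
    VARIABLE,
    assign_disruption,
    classify_insertion,
    cluster_and_call,
    collect_insertion_signals,
    genotype_junctions,
)

RNG = np.random.default_rng(42)


def rand_seq(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), n))


def _aln(read_id, pos, cigar, seq):
    return AlignmentRecord(read_id, "chr", pos, "+", cigar, seq)


def long_read(read_id, pos, length=2000, insertion=None, clip=None):
    """An alignment record with an optional I op (at read offset) or clip."""
    if insertion is not None:
        offset, ins_seq = insertion
        cigar = [("M", offset), ("I", len(ins_seq)), ("M", length - offset)]
        seq = rand_seq(offset) + ins_seq + rand_seq(length - offset)
    elif clip is not None:
        side, clip_seq = clip
        if side == "left":
            cigar = [("S", len(clip_seq)), ("M", length)]
            seq = clip_seq + rand_seq(length)
        else:
            cigar = [("M", length), ("S", len(clip_seq))]
            seq = rand_seq(length) + clip_seq
    else:
        cigar = [("M", length)]
        seq = rand_seq(length)
    return _aln(read_id, pos, cigar, seq)


class TestSignals:
    def test_cigar_insertion_anchor_and_length(self):
        rec = _aln("r", 500, [("M", 100), ("I", 900), ("M", 100)], rand_seq(1100))
        signals, _ = collect_insertion_signals([rec], min_read_length=100)
        (s,) = signals
        assert (s.breakpoint, s.length, s.kind) == (600, 900, "cigar-insertion")

    def test_short_insertion_below_min_len_ignored(self):
        rec = _aln("r", 500, [("M", 600), ("I", 8), ("M", 600)], rand_seq(1208))
        signals, _ = collect_insertion_signals([rec], min_read_length=100)
        assert signals == []

    def test_left_clip_signal_at_alignment_start(self):
        rec = _aln("r", 1000, [("S", 400), ("M", 1060)], rand_seq(1460))
        signals, _ = collect_insertion_signals([rec], min_clip=100, min_read_length=100)
        (s,) = signals
        assert (s.breakpoint, s.kind, s.length) == (1000, "left-clip", 400)

    def test_right_clip_signal_at_alignment_end(self):
        rec = _aln("r", 1000, [("M", 1100), ("S", 300)], rand_seq(1400))
        signals, _ = collect_insertion_signals([rec], min_clip=100, min_read_length=100)
        (s,) = signals
        assert (s.breakpoint, s.kind) == (2100, "right-clip")

    def test_short_reads_filtered_by_min_read_length(self):
        rec = _aln("r", 0, [("M", 400), ("I", 50), ("M", 400)], rand_seq(850))
        signals, retained = collect_insertion_signals([rec], min_read_length=1000)
        assert signals == [] and retained == []


class TestClusterAndCall:
    def _locus(self, n_carrier, n_clean, bp=5000, ins_len=600):
        ins_seq = rand_seq(ins_len)
        alns = []
        for i in range(n_carrier):
            alns.append(long_read(f"c{i}", bp - 1000, 2000, insertion=(1000, ins_seq)))
        for i in range(n_clean):
            alns.append(long_read(f"s{i}", bp - 1000, 2000))
        signals, retained = collect_insertion_signals(alns, min_read_length=100)
        return cluster_and_call(signals, retained)

    def test_variable_call_with_both_alleles_supported(self):
        (call,) = self._locus(4, 6)
        assert (call.supporting, call.spanning) == (4, 6)
        assert call.variability == VARIABLE
        assert call.breakpoint == 5000

    def test_single_minor_read_not_called(self):
        assert self._locus(1, 9) == []

    def test_majority_insertion_flagged_possibly_non_variable(self):
        (call,) = self._locus(10, 1)
        assert call.variability == POSSIBLY_NON_VARIABLE
        assert call.supporting == 10 and call.spanning == 1

    def test_nearby_signals_cluster_once(self):
        ins_seq = rand_seq(300)
        alns = [
            long_read(f"a{d}", 4000, 2000, insertion=(1000 + d, ins_seq))
            for d in (-30, 0, 25)
        ] + [long_read(f"s{i}", 4000, 2000) for i in range(4)]
        signals, retained = collect_insertion_signals(alns, min_read_length=100)
        calls = cluster_and_call(signals, retained)
        assert len(calls) == 1
        assert calls[0].supporting == 3

    def test_distant_loci_give_separate_sorted_calls(self):
        ins_seq = rand_seq(300)
        alns = []
        for bp in (9000, 3000):
            for i in range(3):
                alns.append(long_read(f"{bp}_{i}", bp - 1000, 2000, insertion=(1000, ins_seq)))
        alns += [long_read(f"s{i}", 2000, 9000) for i in range(5)]
        signals, retained = collect_insertion_signals(alns, min_read_length=100)
        calls = cluster_and_call(signals, retained)
        assert [c.breakpoint for c in calls] == [3000, 9000]

    def test_variability_flag_matches_two_read_rule(self, small_dataset):
        sam = str(small_dataset["reads"].truth_long_sam)
        signals, retained = collect_insertion_signals(read_alignments(sam))
        for call in cluster_and_call(signals, retained):
            expected = VARIABLE if min(call.supporting, call.spanning) >= 2 else POSSIBLY_NON_VARIABLE
            assert call.variability == expected


class TestClassification:
    LIBRARY = {"ISx": rand_seq(800), "ISy": rand_seq(1200)}

    def _call(self, consensus):
        return InsertionCall("chr", 100, consensus, 4, 4)

    def test_exact_element_match(self):
        assert classify_insertion(self._call(self.LIBRARY["ISx"]), self.LIBRARY) == "ME:ISx"

    def test_reverse_complement_match(self):
        rc = reverse_complement(self.LIBRARY["ISy"])
        assert classify_insertion(self._call(rc), self.LIBRARY) == "ME:ISy"

    def test_unrelated_sequence_unknown(self):
        assert classify_insertion(self._call(rand_seq(700)), self.LIBRARY) == "UNKNOWN"

    def test_partial_identity_passes_thresholds(self):
        # ~85% identity over 60% of the consensus length -> ME (0.8/0.5)
        rng = np.random.default_rng(3)
        element = self.LIBRARY["ISx"]
        segment = list(element[:480])
        for i in rng.choice(480, size=72, replace=False):
            segment[i] = "ACGT"[("ACGT".index(segment[i]) + 1) % 4]
        consensus = "".join(segment) + rand_seq(320)
        assert classify_insertion(self._call(consensus), self.LIBRARY) == "ME:ISx"

    def test_empty_consensus_unknown_with_warning(self):
        with pytest.warns(UserWarning, match="empty consensus"):
            assert classify_insertion(self._call(""), self.LIBRARY) == "UNKNOWN"

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            classify_insertion(self._call("ACGT"), {})

    def test_alignment_score_matches_quadratic_oracle(self):
        # Smith-Waterman DP oracle (match 2 / mismatch -3 / open -5 / extend -2)
        from magpop.insertions import _make_aligner

        def sw(a, b):
            neg = float("-inf")
            m, n = len(a), len(b)
            H = [[0.0] * (n + 1) for _ in range(m + 1)]
            E = [[neg] * (n + 1) for _ in range(m + 1)]
            F = [[neg] * (n + 1) for _ in range(m + 1)]
            best = 0.0
            for i in range(1, m + 1):
                for j in range(1, n + 1):
                    E[i][j] = max(E[i][j - 1] - 2, H[i][j - 1] - 5)
                    F[i][j] = max(F[i - 1][j] - 2, H[i - 1][j] - 5)
                    diag = H[i - 1][j - 1] + (2 if a[i - 1] == b[j - 1] else -3)
                    H[i][j] = max(0.0, diag, E[i][j], F[i][j])
                    best = max(best, H[i][j])
            return best

        aligner = _make_aligner()
        rng = np.random.default_rng(5)
        for _ in range(5):
            a = "".join(rng.choice(list("ACGT"), 60))
            b = "".join(rng.choice(list("ACGT"), 80))
            assert aligner.align(a, b).score == pytest.approx(sw(a, b))


class TestDisruption:
    FEATURES = [
        GeneFeature("dgc", "chr", 1000, 3000, "+", "diguanylate cyclase", Category.FUNCTIONAL),
        GeneFeature("hp", "chr", 4000, 5000, "+", "hypothetical protein", Category.HP),
        GeneFeature("tn", "chr", 6000, 7000, "+", "IS5 family transposase", Category.ME),
    ]

    @pytest.mark.parametrize(
        "bp,expected_class,expected_id",
        [
            (2000, DISRUPT_FUNCTIONAL, "dgc"),
            (4500, DISRUPT_HP, "hp"),
            (6500, DISRUPT_SELFISH, "tn"),
            (3500, DISRUPT_INTERGENIC, None),
        ],
    )
    def test_classes(self, bp, expected_class, expected_id):
        call = InsertionCall("chr", bp, "ACGT", 4, 4)
        assert assign_disruption(call, self.FEATURES) == (expected_class, expected_id)


class TestJunctions:
    REF = rand_seq(4000, np.random.default_rng(8))
    ELEMENT = rand_seq(1200, np.random.default_rng(9))
    BP = 2000

    def _hap(self, disrupted):
        if disrupted:
            return self.REF[: self.BP] + self.ELEMENT + self.REF[self.BP :]
        return self.REF

    def _reads(self, f, coverage, rng, read_len=250):
        reads = []
        for disrupted, weight in ((True, f), (False, 1 - f)):
            hap = self._hap(disrupted)
            n = int(coverage * weight * len(hap) / read_len)
            starts = rng.integers(0, len(hap) - read_len, size=n)
            for s in starts:
                r = hap[s : s + read_len]
                reads.append(reverse_complement(r) if rng.random() < 0.5 else r)
        return reads

    def _call(self):
        return InsertionCall("chr", self.BP, self.ELEMENT, 4, 4)

    def test_zero_disrupted_formats_published_style(self):
        rng = np.random.default_rng(10)
        reads = self._reads(0.0, 200, rng)
        assay = genotype_junctions(self._call(), reads, self.REF)
        assert assay.disrupted == 0
        assert assay.formatted() == f"n (0/{assay.intact})"

    def test_ratio_definition_and_format(self):
        assay_cls = type(genotype_junctions(self._call(), [self.REF[self.BP - 125 : self.BP + 125]], self.REF))
        assay = assay_cls(breakpoint=0, disrupted=32, intact=100)
        assert assay.ratio == pytest.approx(0.32)
        assert assay.formatted() == "y/n = 0.32"

    def test_fixed_allele_flag_when_no_intact_reads(self):
        rng = np.random.default_rng(11)
        reads = self._reads(1.0, 100, rng)
        assay = genotype_junctions(self._call(), reads, self.REF)
        assert assay.intact == 0 and assay.disrupted > 0
        assert assay.formatted().startswith("fixed")

    def test_no_coverage_is_an_error(self):
        with pytest.raises(ValueError, match="no short-read coverage"):
            genotype_junctions(self._call(), ["ACGT" * 60], self.REF)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(12)
        reads = self._reads(0.4, 100, rng)
        a = genotype_junctions(self._call(), reads, self.REF)
        b = genotype_junctions(self._call(), [reverse_complement(r) for r in reads], self.REF)
        assert (a.disrupted, a.intact) == (b.disrupted, b.intact)

    def test_ratio_converges_to_odds(self):
        f = 0.3
        rng = np.random.default_rng(13)
        reads = self._reads(f, 200, rng)
        assay = genotype_junctions(self._call(), reads, self.REF)
        est = assay.frequency_estimate
        sigma = (f * (1 - f) / (assay.disrupted + assay.intact)) ** 0.5
        assert abs(est - f) <= 3 * sigma
        assert assay.ratio == pytest.approx(est / (1 - est))


class TestPlantedRecovery:
    def test_all_mid_frequency_insertions_recovered(self, small_dataset):
        population = small_dataset["population"]
        library = population.library
        sam = str(small_dataset["reads"].truth_long_sam)
        signals, retained = collect_insertion_signals(read_alignments(sam))
        calls = cluster_and_call(signals, retained)
        for truth in population.truth.insertions:
            if not 0.1 <= truth.frequency <= 0.9:
                continue
            near = [c for c in calls if abs(c.breakpoint - truth.breakpoint) <= 20]
            assert near, f"planted insertion at {truth.breakpoint} missed"
            assert (
                classify_insertion(near[0], library) == f"ME:{truth.element_id}"
            )

    def test_no_calls_on_insertion_free_simulation(self, tmp_path):
        from magpop.simulate import SimConfig, simulate_genome, simulate_population, simulate_reads

        cfg = SimConfig(seed=31, insertions=[]).scaled(150_000, 30_000, 70_000)
        genome, _ = simulate_genome(cfg)
        population = simulate_population(genome, cfg)
        reads = simulate_reads(genome, population, cfg, tmp_path)
        signals, retained = collect_insertion_signals(
            read_alignments(str(reads.truth_long_sam))
        )
        assert cluster_and_call(signals, retained) == []
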