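"""Promoter, terminator, ORF and RBS scanners against hand counts, brute
force and strand-mirror symmetry."""

import numpy as np
import pytest

from talocus.feature_scanners import (
    find_rbs,
    gravy,
    scan_orfs,
    scan_promoters,
    scan_terminators,
)
from talocus.sequence_core import AnnotatedSequence, revcomp, translate


def _random_seq(seed, n, alphabet="ACGT"):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(alphabet), size=n))


# -- promoters --------------------------------------------------------------


class TestScanPromoters:
    def test_consensus_self_match(self):
        s = _random_seq(0, 60) + "TTGACA" + _random_seq(1, 17) + "TATAAT" + _random_seq(2, 60)
        seq = AnnotatedSequence("p", s)
        hits = scan_promoters(seq, "+")
        top = hits[0]
        assert top.minus35_start == 60
        assert top.m35 == 6 and top.m10 == 6
        assert top.spacer_len == 17
        assert top.score == 12.0

    @pytest.mark.parametrize(
        "hexamer,matches",
        [("TATACT", 5), ("TAAAAT", 5), ("TGTCCC", 2), ("TGACAC", 2), ("TATAAT", 6)],
    )
    def test_minus10_match_counts(self, hexamer, matches):
        # consensus-identity count against TATAAT, as used in scoring
        from talocus.feature_scanners import MINUS10_CONSENSUS, _matches

        assert _matches(hexamer, MINUS10_CONSENSUS) == matches

    @pytest.mark.parametrize("mutant", ["TGTCCC", "TGACAC"])
    def test_inactivating_triple_mutations_rejected(self, mutant):
        """The documented −10 triple mutations fall below the default −10
        threshold, abolishing the promoter call."""
        background = _random_seq(3, 40, "C")  # featureless background
        s = background + "TTGACA" + _random_seq(4, 17, "C") + mutant + background
        hits = scan_promoters(AnnotatedSequence("p", s), "+")
        assert hits == []

    def test_tss_seven_nt_downstream_of_minus10(self):
        s = "C" * 40 + "TTGACA" + "C" * 17 + "TATAAT" + "C" * 40
        top = scan_promoters(AnnotatedSequence("p", s), "+")[0]
        minus10_end = top.minus10_start + 6
        assert top.tss == minus10_end + 6  # 7th nt downstream of the 3' base

    def test_score_monotone_in_mismatches_and_spacer(self):
        def best_score(spacer, hexamer):
            s = "C" * 30 + "TTGACA" + "C" * spacer + hexamer + "C" * 30
            hits = scan_promoters(AnnotatedSequence("p", s), "+", min_score=0)
            return max(h.score for h in hits)

        assert best_score(17, "TATAAT") >= best_score(17, "TATACT") >= best_score(17, "TACACT")
        assert best_score(17, "TATAAT") >= best_score(19, "TATAAT") >= best_score(21, "TATAAT")

    def test_short_sequence_returns_empty(self):
        assert scan_promoters(AnnotatedSequence("p", "ACGT" * 5), "+") == []

    def test_strand_mirror_symmetry(self):
        s = _random_seq(5, 300)
        seq = AnnotatedSequence("p", s)
        mirror = AnnotatedSequence("m", revcomp(s))
        fwd = scan_promoters(seq, "+")
        rev = scan_promoters(mirror, "-")
        n = len(s)
        assert [(h.score, h.m35, h.m10, h.spacer_len) for h in fwd] == [
            (h.score, h.m35, h.m10, h.spacer_len) for h in rev
        ]
        assert [n - h.minus10_start - 6 for h in fwd] == [h.minus10_start for h in rev]


# -- terminators -------------------------------------------------------------


class TestScanTerminators:
    def test_planted_gc_hairpin(self):
        s = "C" * 20 + "GCCGCC" + "TTCG" + "GGCGGC" + "TTTTTTT" + "ACA" + "C" * 20
        hits = scan_terminators(AnnotatedSequence("t", s), "+")
        top = hits[0]
        assert top.stem_len == 6
        assert top.loop_len == 4
        assert top.u_tract_len == 7  # capped by the 8-nt window
        assert top.score == 2 * 6 + 7

    def test_poly_a_has_no_hits(self):
        assert scan_terminators(AnnotatedSequence("t", "A" * 60), "+") == []

    def test_two_stem_mismatches_rejected_at_budget_one(self):
        # left stem GCCGCC pairs GGAGAC at only 4 of 6 positions (two
        # interior mismatches)
        s = "C" * 20 + "GCCGCC" + "TTCG" + "GGAGAC" + "TTTTTTT" + "C" * 20
        hits = scan_terminators(
            AnnotatedSequence("t", s), "+", min_stem=6, max_mismatch_stem=1
        )
        assert hits == []
        # the same hairpin with a two-mismatch budget is accepted
        hits2 = scan_terminators(
            AnnotatedSequence("t", s), "+", min_stem=6, max_mismatch_stem=2
        )
        assert hits2 and hits2[0].stem_len == 6

    def test_u_tract_must_follow_hairpin(self):
        s = "A" * 20 + "GCCGCC" + "TTCG" + "GGCGGC" + "CAGCAG" + "A" * 20
        assert scan_terminators(AnnotatedSequence("t", s), "+") == []

    def test_strand_mirror_symmetry(self):
        s = _random_seq(6, 400)
        n = len(s)
        fwd = scan_terminators(AnnotatedSequence("t", s), "+")
        rev = scan_terminators(AnnotatedSequence("m", revcomp(s)), "-")
        assert [(h.score, h.stem_len, h.loop_len, h.u_tract_len) for h in fwd] == [
            (h.score, h.stem_len, h.loop_len, h.u_tract_len) for h in rev
        ]
        assert [(n - h.hairpin_end, n - h.hairpin_start) for h in fwd] == [
            (h.hairpin_start, h.hairpin_end) for h in rev
        ]


# -- ORFs --------------------------------------------------------------------


def orf_oracle(seq: str, min_aa: int, max_aa: int, starts=("ATG", "GTG")):
    """Independent six-frame enumeration: per stop-to-stop segment, the
    5'-most start defines the ORF.  Returns top-strand (start, end, strand)."""
    stops = {"TAA", "TAG", "TGA"}
    out = set()
    n = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            codon_starts = list(range(frame, n - 2, 3))
            codons = [s[i : i + 3] for i in codon_starts]
            stop_idx = [k for k, c in enumerate(codons) if c in stops]
            seg_begin = 0
            for k in stop_idx:
                seg = [
                    codon_starts[m]
                    for m in range(seg_begin, k)
                    if codons[m] in starts
                ]
                if seg:
                    start, end = min(seg), codon_starts[k] + 3
                    aa = (end - start) // 3 - 1
                    if min_aa <= aa <= max_aa:
                        if strand == "+":
                            out.add((start, end, "+"))
                        else:
                            out.add((n - end, n - start, "-"))
                seg_begin = k + 1
    return out


class TestScanOrfs:
    def test_minimal_orf(self):
        hits = scan_orfs(AnnotatedSequence("o", "ATGAAATAA"), min_aa=2, max_aa=10)
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        assert plus[0].peptide == "MK"
        assert plus[0].length_aa == 2
        assert plus[0].end - plus[0].start == 9  # includes the stop codon

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_2kb(self, seed):
        s = _random_seq(seed, 2000)
        hits = scan_orfs(AnnotatedSequence("o", s), min_aa=20, max_aa=40)
        assert {(h.start, h.end, h.strand) for h in hits} == orf_oracle(s, 20, 40)

    def test_strand_symmetry(self):
        s = _random_seq(11, 1000)
        n = len(s)
        fwd = scan_orfs(AnnotatedSequence("o", s), min_aa=10, max_aa=60)
        rev = scan_orfs(AnnotatedSequence("o", revcomp(s)), min_aa=10, max_aa=60)
        mirrored = {(n - h.end, n - h.start, "+-"[h.strand == "+"]) for h in rev}
        assert {(h.start, h.end, h.strand) for h in fwd} == mirrored

    def test_peptides_come_from_translate(self):
        s = _random_seq(12, 1500)
        for h in scan_orfs(AnnotatedSequence("o", s), min_aa=15, max_aa=50):
            cds = s[h.start : h.end] if h.strand == "+" else revcomp(s[h.start : h.end])
            assert h.peptide == translate(cds)
            assert "*" not in h.peptide


# -- GRAVY and RBS -----------------------------------------------------------


class TestGravy:
    @pytest.mark.parametrize(
        "pep,value", [("III", 4.5), ("RRR", -4.5), ("AIV", 3.5)]
    )
    def test_kyte_doolittle_means(self, pep, value):
        assert gravy(pep) == pytest.approx(value)

    def test_unknown_residue_is_error(self):
        with pytest.raises(ValueError):
            gravy("AXZ")


class TestFindRbs:
    def _orf_at(self, seq_str, start):
        seq = AnnotatedSequence("r", seq_str)
        hits = [h for h in scan_orfs(seq, min_aa=2, max_aa=50) if h.start == start]
        assert hits
        return seq, hits[0]

    def test_perfect_sd_at_offset_8(self):
        s = "C" * 20 + "AGGAGG" + "C" * 8 + "ATG" + "AAA" * 4 + "TAA" + "C" * 10
        seq, orf = self._orf_at(s, 34)
        hit = find_rbs(seq, orf)
        assert hit.sd_score == 6
        assert hit.offset == 8

    def test_single_mismatch_sd(self):
        s = "C" * 20 + "AGGCGG" + "C" * 8 + "ATG" + "AAA" * 4 + "TAA" + "C" * 10
        seq, orf = self._orf_at(s, 34)
        assert find_rbs(seq, orf).sd_score == 5

    def test_no_sd_in_all_c_upstream(self):
        s = "C" * 34 + "ATG" + "AAA" * 4 + "TAA" + "C" * 10
        seq, orf = self._orf_at(s, 34)
        assert find_rbs(seq, orf) is None
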