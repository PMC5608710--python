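"""Nussinov folding against exhaustive enumeration; duplex scan against a
quadratic brute-force oracle; structural invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from talocus.rna_duplex import annotate_dr, duplex_scan, nussinov_fold

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def can_pair(a, b, allow_gu=True):
    return (a, b) in _PAIRS or (allow_gu and (a, b) in _GU)


def max_pairs_exhaustive(s, min_loop=3, allow_gu=True):
    """Plain recursion over all nested structures (no memoization)."""

    def go(i, j):
        if j - i <= min_loop:
            return 0
        best = go(i, j - 1)  # j unpaired
        for k in range(i, j - min_loop):
            if can_pair(s[k], s[j], allow_gu):
                best = max(best, go(i, k - 1) + 1 + go(k + 1, j - 1))
        return best

    return go(0, len(s) - 1)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestNussinov:
    @pytest.mark.parametrize(
        "rna,n_pairs",
        [("GGGAAACCC", 3), ("AAAA", 0), ("GCGC", 0)],
    )
    def test_known_structures(self, rna, n_pairs):
        assert nussinov_fold(rna).n_pairs == n_pairs

    def test_equals_exhaustive_enumeration_up_to_12(self):
        rng = np.random.default_rng(0)
        for n in range(1, 13):
            for _ in range(8):
                s = random_rna(rng, n)
                assert nussinov_fold(s).n_pairs == max_pairs_exhaustive(s)

    def test_pairs_nested_and_loop_respected(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            s = random_rna(rng, 60)
            fold = nussinov_fold(s)
            seen = set()
            for i, j in fold.pairs:
                assert j - i > 3
                assert i not in seen and j not in seen
                seen.update((i, j))
            for (i1, j1) in fold.pairs:
                for (i2, j2) in fold.pairs:
                    if i1 < i2:
                        assert j2 < j1 or i2 > j1  # nested or disjoint

    def test_t_mapped_to_u(self):
        assert nussinov_fold("GGGTTTCCC").rna == "GGGUUUCCC"

    def test_deterministic_traceback(self):
        s = "GGGAAACCCUUUGGGAAACCC"
        assert nussinov_fold(s).pairs == nussinov_fold(s).pairs

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            nussinov_fold("")

    def test_dot_bracket_is_balanced(self):
        db = nussinov_fold("GGGAAACCCAUUGCGCAAAGCGC").dot_bracket()
        assert db.count("(") == db.count(")")

    def test_engineered_utr_annotations(self, default_locus):
        """The planted 5' UTR folds an upstream helix within the first 10 nt
        and a downstream stem-loop overlapping the SD sequence."""
        seq, truth = default_locus
        rna = truth.toxin_transcript["rna"][:46]
        fold = nussinov_fold(rna)
        ann = fold.annotations
        assert ann["UH"] is not None and ann["UH"][0] < 10
        assert ann["SL"] is not None and ann["SL"][0] >= ann["UH"][1]
        sd_start, sd_end = 46 - 8 - 6, 46 - 8  # SD occupies the SL 3' stem
        assert ann["SL"][0] < sd_end and ann["SL"][1] > sd_start


def duplex_oracle(a, b, min_len=15, frac=0.1):
    """All containment-maximal antiparallel complementary runs, by direct
    enumeration of every (a-window, b-window) pairing."""
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    a = a.upper().replace("T", "U")
    b = b.upper().replace("T", "U")
    valid = []
    for a_s in range(len(a)):
        for L in range(min_len, len(a) - a_s + 1):
            for b_e in range(L, len(b) + 1):
                b_s = b_e - L
                flags = [comp.get(a[a_s + t]) == b[b_e - 1 - t] for t in range(L)]
                if not (flags[0] and flags[-1]):
                    continue
                mm = L - sum(flags)
                if mm <= int(frac * L):
                    valid.append((a_s, a_s + L, b_s, b_e, mm))
    maximal = set()
    for w in valid:
        contained = any(
            v != w and v[0] <= w[0] and w[1] <= v[1] and v[2] <= w[2] and w[3] <= v[3]
            and (v[1] - v[0]) > (w[1] - w[0])
            for v in valid
        )
        if not contained:
            maximal.add(w)
    return maximal


class TestDuplexScan:
    def test_planted_perfect_duplex(self):
        rng = np.random.default_rng(2)
        core = random_rna(rng, 20)
        comp = core.translate(str.maketrans("ACGU", "UGCA"))[::-1]
        a = "AAAA" + core + "AAAA"
        b = "CCC" + comp + "CCC"
        matches = duplex_scan(a, b, min_len=15)
        assert matches
        best = matches[0]
        assert best.length >= 20 and best.mismatches == 0
        assert best.a_start <= 4 and best.a_end >= 24

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(6):
            n = int(rng.integers(40, 120))
            a, b = random_rna(rng, n), random_rna(rng, n)
            # plant a duplex so matches exist
            core = random_rna(rng, 18)
            comp = core.translate(str.maketrans("ACGU", "UGCA"))[::-1]
            a = a[:10] + core + a[10:]
            b = b[:5] + comp + b[5:]
            got = {
                (m.a_start, m.a_end, m.b_start, m.b_end, m.mismatches)
                for m in duplex_scan(a, b, min_len=12)
            }
            assert got == duplex_oracle(a, b, min_len=12)

    def test_mismatch_budget_splits_runs(self):
        rng = np.random.default_rng(4)
        core = list(random_rna(rng, 24))
        # two interior substitutions that break complementarity
        comp = core[:]
        for idx in (8, 15):
            comp[idx] = {"A": "C", "C": "A", "G": "U", "U": "G"}[comp[idx]]
        comp_rna = "".join(comp).translate(str.maketrans("ACGU", "UGCA"))[::-1]
        # A/A flanks cannot pair with each other, so the planted diagonal
        # cannot extend past the core
        a = "AAAA" + "".join(core) + "AAAA"
        b = "AAAA" + comp_rna + "AAAA"
        with_budget = duplex_scan(a, b, min_len=5, max_mismatch_frac=0.1)
        assert with_budget[0].length == 24 and with_budget[0].mismatches == 2
        tight = duplex_scan(a, b, min_len=5, max_mismatch_frac=0.05)
        assert all(m.length < 24 for m in tight)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_ab_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_rna(rng, 50), random_rna(rng, 50)
        ab = {(m.a_start, m.a_end, m.b_start, m.b_end) for m in duplex_scan(a, b, min_len=6)}
        ba = {(m.b_start, m.b_end, m.a_start, m.a_end) for m in duplex_scan(b, a, min_len=6)}
        assert ab == ba


class TestAnnotateDr:
    def test_planted_dr_spans_start_codon(self, default_locus):
        seq, truth = default_locus
        tox = truth.toxin_transcript["rna"]
        anti = truth.antitoxin_transcript["rna"]
        atg = truth.orf[0] - truth.toxin_transcript["tss"]
        m = annotate_dr(tox, anti, atg)
        assert m is not None and m.spans_start_codon
        assert m.length == 24 and m.mismatches == 0

    def test_duplex_away_from_start_codon_is_rejected(self):
        rng = np.random.default_rng(5)
        core = random_rna(rng, 20)
        comp = core.translate(str.maketrans("ACGU", "UGCA"))[::-1]
        tox = random_rna(rng, 30) + core + random_rna(rng, 30)
        anti = "CCC" + comp + "CCC"
        # start codon placed well before the planted duplex
        assert annotate_dr(tox, anti, start_codon_pos=2) is None
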