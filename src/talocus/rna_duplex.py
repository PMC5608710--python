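"""RNA-level computations: nested secondary structure by base-pair
maximization (Nussinov dynamic programming) with hairpin/UH/SL annotation,
and intermolecular complementarity (direct-repeat) scanning between two RNAs.

Base-pair maximization stands in for free-energy folding: the testable claims
about type I antitoxin/toxin RNA architecture are hairpin-level (an upstream
helix near the 5' end, a stem-loop sequestering the RBS), not exact MFE
structures.  G·U wobble pairs are allowed when folding a single RNA and off
by default for the intermolecular duplex scan, which models DNA-templated
direct-repeat complementarity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "StructureFold",
    "DirectRepeatMatch",
    "nussinov_fold",
    "duplex_scan",
    "annotate_dr",
]

_RNA_COMP = str.maketrans("ACGUN", "UGCAN")


def _to_rna(s: str) -> str:
    s = s.upper().replace("T", "U")
    bad = set(s) - set("ACGUN")
    if bad:
        raise ValueError(f"illegal RNA characters {sorted(bad)}")
    return s


def _can_pair(a: str, b: str, allow_gu: bool) -> bool:
    if (a, b) in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}:
        return True
    return allow_gu and (a, b) in {("G", "U"), ("U", "G")}


@dataclass
class StructureFold:
    """A nested secondary structure: pair list, derived hairpins, annotations.

    ``hairpins`` lists maximal stacked-pair runs whose innermost pair encloses
    an unpaired loop, as (stem_len, loop_start, loop_end) with loop_end
    exclusive.  ``annotations`` maps "UH" to the interval of the 5'-most
    hairpin whose stem starts within the first 10 nt (upstream helix) and
    "SL" to the first distinct hairpin downstream of it, when present.
    """

    rna: str
    pairs: list[tuple[int, int]]
    n_pairs: int
    hairpins: list[tuple[int, int, int]]
    annotations: dict[str, tuple[int, int] | None]

    def dot_bracket(self) -> str:
        out = ["."] * len(self.rna)
        for i, j in self.pairs:
            out[i], out[j] = "(", ")"
        return "".join(out)


@dataclass(frozen=True)
class DirectRepeatMatch:
    """An antiparallel complementary run between RNA A and RNA B.

    Intervals are 0-based half-open on each RNA 5'→3'; position a_start + t
    of A pairs with position b_end - 1 - t of B.
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    length: int
    mismatches: int
    spans_start_codon: bool = False

    def swapped(self) -> "DirectRepeatMatch":
        return DirectRepeatMatch(
            a_start=self.b_start,
            a_end=self.b_end,
            b_start=self.a_start,
            b_end=self.a_end,
            length=self.length,
            mismatches=self.mismatches,
            spans_start_codon=self.spans_start_codon,
        )


def _traceback(
    M: np.ndarray, s: str, i: int, j: int, min_loop: int, allow_gu: bool, pairs: list
) -> None:
    while i < j:
        if M[i, j] == 0:
            return
        if (
            j - i > min_loop
            and _can_pair(s[i], s[j], allow_gu)
            and M[i, j] == M[i + 1, j - 1] + 1
        ):
            pairs.append((i, j))
            i, j = i + 1, j - 1
            continue
        # smallest split point first for deterministic output
        for k in range(i, j):
            if M[i, k] + M[k + 1, j] == M[i, j]:
                _traceback(M, s, i, k, min_loop, allow_gu, pairs)
                i = k + 1
                break
        else:  # pragma: no cover - DP consistency guard
            raise AssertionError("traceback failed")


def _hairpins_from_pairs(pairs: list[tuple[int, int]]) -> list[tuple[int, int, int]]:
    """Maximal strictly stacked runs whose innermost loop is unpaired."""
    pair_set = set(pairs)
    paired = {i for p in pairs for i in p}
    hairpins = []
    for i, j in sorted(pairs):
        if (i - 1, j + 1) in pair_set:
            continue  # not outermost of its stack
        stem = 0
        a, b = i, j
        while (a, b) in pair_set:
            stem += 1
            a, b = a + 1, b - 1
        # hairpin only if the enclosed loop contains no paired base
        if a > b or any(k in paired for k in range(a, b + 1)):
            continue
        hairpins.append((stem, a, b + 1))
    hairpins.sort(key=lambda h: h[1])
    return hairpins


def _annotate(hairpins: list[tuple[int, int, int]]) -> dict[str, tuple[int, int] | None]:
    ann: dict[str, tuple[int, int] | None] = {"UH": None, "SL": None}
    for stem, loop_start, loop_end in hairpins:
        outer = (loop_start - stem, loop_end + stem)
        if ann["UH"] is None and outer[0] < 10:
            ann["UH"] = outer
        elif ann["UH"] is not None and outer[0] >= ann["UH"][1]:
            ann["SL"] = outer
            break
    return ann


def nussinov_fold(rna: str, min_loop: int = 3, allow_gu: bool = True) -> StructureFold:
    """Maximum-cardinality nested base pairing by dynamic programming.

    A pair (i, j) requires j − i > ``min_loop``.  Traceback is deterministic:
    pairing (i, j) is preferred over bifurcation on ties, and the smallest
    split point is taken first.
    """
    if not rna:
        raise ValueError("empty RNA")
    s = _to_rna(rna)
    n = len(s)
    if n > 10_000:
        raise ValueError("sequence too long for folding (limit 10,000 nt)")
    M = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1, j - 1] + 1 if _can_pair(s[i], s[j], allow_gu) else 0
            ks = np.arange(i, j)
            split = int((M[i, ks] + M[ks + 1, j]).max())
            M[i, j] = max(best, split)
    pairs: list[tuple[int, int]] = []
    if n > 1:
        _traceback(M, s, 0, n - 1, min_loop, allow_gu, pairs)
    pairs.sort()
    hairpins = _hairpins_from_pairs(pairs)
    return StructureFold(
        rna=s,
        pairs=pairs,
        n_pairs=len(pairs),
        hairpins=hairpins,
        annotations=_annotate(hairpins),
    )


def duplex_scan(
    rna_a: str,
    rna_b: str,
    min_len: int = 15,
    max_mismatch_frac: float = 0.1,
    allow_gu: bool = False,
) -> list[DirectRepeatMatch]:
    """Exhaustive antiparallel complementarity scan between two RNAs.

    Reports containment-maximal runs: windows beginning and ending on a
    paired position, with at most floor(max_mismatch_frac · length)
    mismatches and length ≥ min_len, not contained in any longer qualifying
    window.  Sorted by length desc, then fewest mismatches.
    """
    if not rna_a or not rna_b:
        raise ValueError("empty RNA input")
    a = _to_rna(rna_a)
    b = _to_rna(rna_b)
    # antiparallel pairing of a[i] with b[j] == string identity between a and
    # the reverse-complement image of b
    c = b.translate(_RNA_COMP)[::-1]
    na, nc = len(a), len(c)
    candidates: list[tuple[int, int, int, int]] = []  # (a_start, c_start, length, mism)
    for d in range(-(nc - 1), na):
        i0 = max(0, d)
        j0 = i0 - d
        K = min(na - i0, nc - j0)
        if K < min_len:
            continue
        match = [a[i0 + t] == c[j0 + t] and a[i0 + t] != "N" for t in range(K)]
        if allow_gu:
            for t in range(K):
                if not match[t]:
                    # pairing partner in b read antiparallel
                    x, y = a[i0 + t], c[j0 + t].translate(_RNA_COMP)
                    match[t] = _can_pair(x, y, True)
        pref = [0] * (K + 1)
        for t in range(K):
            pref[t + 1] = pref[t] + (0 if match[t] else 1)
        diag_runs = []
        for x in range(K - min_len + 1):
            if not match[x]:
                continue
            for y in range(x + min_len, K + 1):
                if not match[y - 1]:
                    continue
                L = y - x
                mism = pref[y] - pref[x]
                if mism <= int(max_mismatch_frac * L):
                    diag_runs.append((x, y, mism))
        # containment-maximal filter within the diagonal
        for x, y, mism in diag_runs:
            if any((u <= x and y <= v) and (v - u > y - x) for u, v, _ in diag_runs):
                continue
            candidates.append((i0 + x, j0 + x, y - x, mism))
    matches = []
    for a_start, c_start, L, mism in candidates:
        b_end = len(b) - c_start
        matches.append(
            DirectRepeatMatch(
                a_start=a_start,
                a_end=a_start + L,
                b_start=b_end - L,
                b_end=b_end,
                length=L,
                mismatches=mism,
            )
        )
    matches.sort(key=lambda m: (-m.length, m.mismatches, m.a_start, m.b_start))
    return matches


def annotate_dr(
    toxin_rna: str,
    antitoxin_rna: str,
    start_codon_pos: int,
    min_len: int = 15,
    max_mismatch_frac: float = 0.1,
) -> DirectRepeatMatch | None:
    """Best toxin/antitoxin complementary run spanning the toxin start codon.

    ``start_codon_pos`` is the 0-based position of the first start-codon base
    on the toxin RNA.  Returns the longest duplex-scan match overlapping
    [start_codon_pos, start_codon_pos + 3), flagged spans_start_codon, or
    None when no match covers the start codon.
    """
    for m in duplex_scan(toxin_rna, antitoxin_rna, min_len, max_mismatch_frac):
        if m.a_start < start_codon_pos + 3 and m.a_end > start_codon_pos:
            return replace(m, spans_start_codon=True)
    return None
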