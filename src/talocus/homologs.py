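"""Cross-plasmid comparison of toxin-antitoxin loci: toxin peptide
extraction from locus regions, pairwise global alignment identity, and
peptide grouping.

Identity is computed over all alignment columns, counting gap columns as
non-matches; this definition is documented because database percent-identity
columns rarely state theirs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .config import RunConfig
from .sequence_core import AnnotatedSequence, extract_region
from .ta_finder import find_ta_loci

__all__ = [
    "PairwiseAlignment",
    "PeptideGroup",
    "nw_align",
    "extract_toxin_peptides",
    "group_peptides",
    "identity_matrix",
]

log = logging.getLogger(__name__)

_DNA = set("ACGTN")
_PROTEIN = set("ACDEFGHIKLMNPQRSTVWYX*")


@dataclass(frozen=True)
class PairwiseAlignment:
    a_id: str
    b_id: str
    aligned_a: str
    aligned_b: str
    matches: int
    columns: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.columns


@dataclass
class PeptideGroup:
    group_id: int
    members: list[tuple[str, str]] = field(default_factory=list)
    representative: str = ""


def _alphabet(s: str) -> str:
    up = set(s.upper())
    if up <= _DNA:
        return "dna"
    if up <= _PROTEIN:
        return "protein"
    raise ValueError(f"unrecognized alphabet in sequence: {sorted(up - _PROTEIN)}")


def nw_align(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    a_id: str = "a",
    b_id: str = "b",
) -> PairwiseAlignment:
    """Needleman-Wunsch global alignment with a linear gap penalty.

    Among score-optimal alignments the one maximizing matches and then
    minimizing columns is chosen (a lexicographic objective, which keeps the
    reported identity canonical and symmetric under argument swap); remaining
    ties in the traceback prefer diagonal > up (gap in b) > left (gap in a).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if _alphabet(a) != _alphabet(b):
        raise ValueError("mixed alphabets: one DNA, one peptide")
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    # cell value: (score, matches, -columns), compared lexicographically;
    # per-step vectors are additive so the DP recursion remains valid
    cell = [[(0.0, 0, 0)] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        cell[i][0] = (i * gap, 0, -i)
    for j in range(1, m + 1):
        cell[0][j] = (j * gap, 0, -j)
    for i in range(1, n + 1):
        ai = a[i - 1]
        row, prev = cell[i], cell[i - 1]
        for j in range(1, m + 1):
            hit = ai == b[j - 1]
            d = prev[j - 1]
            diag = (d[0] + (match if hit else mismatch), d[1] + hit, d[2] - 1)
            u = prev[j]
            up = (u[0] + gap, u[1], u[2] - 1)
            l = row[j - 1]
            left = (l[0] + gap, l[1], l[2] - 1)
            row[j] = max(diag, up, left)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        here = cell[i][j]
        if i > 0 and j > 0:
            hit = a[i - 1] == b[j - 1]
            d = cell[i - 1][j - 1]
            if here == (d[0] + (match if hit else mismatch), d[1] + hit, d[2] - 1):
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i, j = i - 1, j - 1
                continue
        if i > 0 and here == (
            cell[i - 1][j][0] + gap, cell[i - 1][j][1], cell[i - 1][j][2] - 1
        ):
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    matches = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    return PairwiseAlignment(
        a_id=a_id,
        b_id=b_id,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        matches=matches,
        columns=len(aligned_a),
    )


def extract_toxin_peptides(
    regions: Iterable[tuple[AnnotatedSequence, tuple[int, int]]],
    pad: int = 100,
    config: RunConfig | None = None,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Run locus detection on each (sequence, GenBank-style range) region.

    Ranges are 1-based inclusive; a descending pair denotes the minus strand.
    Each range is widened by ``pad`` bp on both sides to form the search
    window.  Returns (hits, misses): the top candidate's toxin peptide per
    region id, and the ids of regions where no candidate qualified.
    """
    hits: list[tuple[str, str]] = []
    misses: list[str] = []
    for seq, (a, b) in regions:
        lo, hi = (a, b) if a < b else (b, a)
        start = max(0, lo - 1 - pad)
        end = min(len(seq), hi + pad)
        window = extract_region(seq, start, end, "+")
        sub = AnnotatedSequence(id=seq.id, residues=window)
        found = find_ta_loci(sub, config, fold=False)
        if not found:
            misses.append(seq.id)
            log.info("region %s (%d-%d): no locus candidate", seq.id, a, b)
            continue
        hits.append((seq.id, found[0].orf.peptide))
    return hits, misses


def group_peptides(
    peptides: Sequence[tuple[str, str]],
    criterion: str = "identical",
    identity_ge: float = 100.0,
) -> list[PeptideGroup]:
    """Group (id, peptide) pairs by sequence identity.

    ``identical`` forms equivalence classes of exact equality;
    ``identity_ge`` performs single-linkage clustering at the given percent
    identity (from nw_align).  Groups are numbered by first appearance.
    """
    if not peptides:
        raise ValueError("no peptides to group")
    if criterion == "identical":
        groups: list[PeptideGroup] = []
        index: dict[str, PeptideGroup] = {}
        for pid, pep in peptides:
            if pep not in index:
                g = PeptideGroup(group_id=len(groups) + 1, representative=pep)
                groups.append(g)
                index[pep] = g
            index[pep].members.append((pid, pep))
        return groups
    if criterion != "identity_ge":
        raise ValueError(f"unknown grouping criterion {criterion!r}")
    n = len(peptides)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            aln = nw_align(peptides[i][1], peptides[j][1])
            if aln.identity_pct >= identity_ge:
                parent[find(i)] = find(j)
    roots: dict[int, PeptideGroup] = {}
    groups = []
    for i, (pid, pep) in enumerate(peptides):
        r = find(i)
        if r not in roots:
            g = PeptideGroup(group_id=len(groups) + 1, representative=pep)
            groups.append(g)
            roots[r] = g
        roots[r].members.append((pid, pep))
    return groups


def identity_matrix(items: Sequence[tuple[str, str]]) -> list[list[float]]:
    """Symmetric percent-identity matrix over (id, sequence) pairs."""
    n = len(items)
    mat = [[100.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            pct = nw_align(
                items[i][1], items[j][1], a_id=items[i][0], b_id=items[j][0]
            ).identity_pct
            mat[i][j] = mat[j][i] = pct
    return mat
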