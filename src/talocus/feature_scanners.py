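"""First-principles detectors for σ70 promoters, rho-independent terminators,
small hydrophobic ORFs and Shine–Dalgarno ribosome binding sites.

The promoter model is transparent consensus-mismatch scoring against the
canonical −35 (TTGACA) and −10 (TATAAT) hexamers with a spacer-length
penalty; the terminator model is inverted-repeat (hairpin) search followed by
a T-tract requirement on the coding strand.  Both were calibrated so that the
near-consensus promoter/terminator architecture of Fst-family toxin–antitoxin
loci is detected while the documented −10 triple mutations fall below
threshold.

All hit coordinates are reported on the top strand (0-based, half-open);
motif strings are reported 5'→3' on the hit's own strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .sequence_core import AnnotatedSequence, revcomp, translate

__all__ = [
    "PromoterHit",
    "TerminatorHit",
    "OrfHit",
    "RbsHit",
    "MINUS35_CONSENSUS",
    "MINUS10_CONSENSUS",
    "SD_CONSENSUS",
    "DEFAULT_TSS_OFFSET",
    "scan_promoters",
    "scan_terminators",
    "scan_orfs",
    "gravy",
    "find_rbs",
]

log = logging.getLogger(__name__)

MINUS35_CONSENSUS = "TTGACA"
MINUS10_CONSENSUS = "TATAAT"
SD_CONSENSUS = "AGGAGG"

# +1 placed this many nt downstream of the last base of the −10 hexamer;
# calibrated so the predicted antitoxin transcript length on the reference
# locus architecture is 74 nt.
DEFAULT_TSS_OFFSET = 7

SPACER_RANGE = (15, 21)

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}

# Kyte-Doolittle standard residue set
_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _matches(word: str, consensus: str) -> int:
    """Number of identities to the consensus; N never matches."""
    return sum(1 for a, b in zip(word, consensus) if a == b and a != "N")


def _to_top(start: int, end: int, strand: str, n: int) -> tuple[int, int]:
    """Map a scanning-strand interval to top-strand coordinates."""
    if strand == "+":
        return start, end
    return n - end, n - start


@dataclass(frozen=True)
class PromoterHit:
    strand: str
    minus35_start: int  # top-strand start of the −35 hexamer interval
    minus35_seq: str
    spacer_len: int
    minus10_start: int
    minus10_seq: str
    m35: int
    m10: int
    score: float
    tss: int  # 0-based +1 position on the top strand


@dataclass(frozen=True)
class TerminatorHit:
    strand: str
    stem_len: int
    loop_len: int
    hairpin_start: int  # top-strand interval of the full hairpin
    hairpin_end: int
    u_tract_len: int
    score: float


@dataclass(frozen=True)
class OrfHit:
    strand: str
    start: int  # top-strand interval; includes the stop codon
    end: int
    start_codon: str
    peptide: str
    length_aa: int
    gravy: float


@dataclass(frozen=True)
class RbsHit:
    orf_start: int
    sd_seq: str
    sd_score: int
    offset: int  # nt between SD 3' end and the start codon


def scan_promoters(
    seq: AnnotatedSequence,
    strand: str,
    min_m10: int = 4,
    min_score: float = 8.0,
    lambda_spacer: float = 0.5,
    tss_offset: int = DEFAULT_TSS_OFFSET,
) -> list[PromoterHit]:
    """Scan one strand for σ70 −35/−10 promoter arrangements.

    Every (−35, spacer, −10) arrangement with spacer length 15–21 is scored
    as ``m35 + m10 − lambda_spacer·|spacer − 17|``; hits require at least
    ``min_m10`` identities in the −10 hexamer and total score ≥ ``min_score``.
    Overlapping hits (−10 centres within 10 bp on the same strand) are merged
    keeping the best.  The predicted +1 is placed ``tss_offset`` nt downstream
    of the −10 hexamer 3' end, strand-aware.
    """
    n = len(seq)
    if n < 40:
        log.warning("sequence %s too short for promoter scan (%d nt)", seq.id, n)
        return []
    s = seq.residues if strand == "+" else revcomp(seq.residues)
    raw: list[tuple] = []
    lo, hi = SPACER_RANGE
    for i in range(n - 6 - lo - 6 + 1):
        w35 = s[i : i + 6]
        m35 = _matches(w35, MINUS35_CONSENSUS)
        for spacer in range(lo, hi + 1):
            j = i + 6 + spacer
            if j + 6 > n:
                break
            w10 = s[j : j + 6]
            m10 = _matches(w10, MINUS10_CONSENSUS)
            if m10 < min_m10:
                continue
            score = m35 + m10 - lambda_spacer * abs(spacer - 17)
            if score < min_score:
                continue
            raw.append((score, abs(spacer - 17), i, spacer, j, w35, w10, m35, m10))
    # sort: score desc, closer-to-17 spacer, 5'-most position on the strand
    raw.sort(key=lambda t: (-t[0], t[1], t[2]))
    kept: list[tuple] = []
    for cand in raw:
        c10 = cand[4] + 3  # −10 hexamer centre (scanning coords)
        if any(abs(c10 - (k[4] + 3)) <= 10 for k in kept):
            continue
        kept.append(cand)
    hits = []
    for score, _, i, spacer, j, w35, w10, m35, m10 in kept:
        tss_local = j + 5 + tss_offset
        if tss_local >= n:
            continue
        m35_top = _to_top(i, i + 6, strand, n)
        m10_top = _to_top(j, j + 6, strand, n)
        tss_top = tss_local if strand == "+" else n - 1 - tss_local
        hits.append(
            PromoterHit(
                strand=strand,
                minus35_start=m35_top[0],
                minus35_seq=w35,
                spacer_len=spacer,
                minus10_start=m10_top[0],
                minus10_seq=w10,
                m35=m35,
                m10=m10,
                score=score,
                tss=tss_top,
            )
        )
    return hits


def _hairpins_at(
    s: str,
    loop_start: int,
    loop_len: int,
    min_stem: int,
    max_mismatch: int,
) -> list[tuple]:
    """All stems for a fixed loop placement, extending outward.

    Stems may contain up to ``max_mismatch`` non-Watson–Crick positions but
    must begin and end on a paired base; every qualifying stem length is a
    candidate (a shorter stem immediately followed by a T-tract can beat a
    longer one that swallows it).  Stem score counts 2 per G·C pair and 1
    per A·T pair.
    """
    n = len(s)
    left = loop_start - 1
    right = loop_start + loop_len
    pair_flags: list[bool] = []
    mismatches = 0
    while left - len(pair_flags) >= 0 and right + len(pair_flags) < n:
        a, b = s[left - len(pair_flags)], s[right + len(pair_flags)]
        if (a, b) in _WC:
            pair_flags.append(True)
        elif mismatches < max_mismatch:
            mismatches += 1
            pair_flags.append(False)
        else:
            break
    if not pair_flags or not pair_flags[0]:
        return []
    out = []
    score = 0
    for k, paired in enumerate(pair_flags):
        if paired:
            score += 2 if s[left - k] in "GC" else 1
        stem = k + 1
        if paired and stem >= min_stem:
            out.append((left - stem + 1, right + stem, stem, score))
    return out


def scan_terminators(
    seq: AnnotatedSequence,
    strand: str,
    min_stem: int = 5,
    loop_range: tuple[int, int] = (3, 9),
    min_u: int = 4,
    max_mismatch_stem: int = 1,
    u_window: int = 8,
) -> list[TerminatorHit]:
    """Scan one strand for rho-independent terminators.

    A terminator is an inverted repeat (hairpin) followed by a T-tract on the
    coding strand: a contiguous run of at least ``min_u`` T residues starting
    immediately after the hairpin, counted within the first ``u_window`` nt.
    Score = stem pairing score (2·GC + 1·AT) plus the T-tract length.
    Overlapping hits are merged keeping the best.
    """
    n = len(seq)
    if n < 20:
        log.warning("sequence %s too short for terminator scan (%d nt)", seq.id, n)
        return []
    s = seq.residues if strand == "+" else revcomp(seq.residues)
    raw = []
    for loop_len in range(loop_range[0], loop_range[1] + 1):
        for loop_start in range(min_stem, n - loop_len - min_stem + 1):
            for h_start, h_end, stem, stem_score in _hairpins_at(
                s, loop_start, loop_len, min_stem, max_mismatch_stem
            ):
                window = s[h_end : h_end + u_window]
                u_len = len(window) - len(window.lstrip("T"))  # contiguous T run
                if u_len < min_u:
                    continue
                raw.append((stem_score + u_len, h_start, h_end, stem, loop_len, u_len))
    # ties prefer the longer T-tract (the more canonical terminator), then
    # the leftmost hairpin
    raw.sort(key=lambda t: (-t[0], -t[5], t[1]))
    kept: list[tuple] = []
    for cand in raw:
        if any(cand[1] < k[2] and k[1] < cand[2] for k in kept):
            continue
        kept.append(cand)
    hits = []
    for score, h_start, h_end, stem, loop_len, u_len in kept:
        top = _to_top(h_start, h_end, strand, n)
        hits.append(
            TerminatorHit(
                strand=strand,
                stem_len=stem,
                loop_len=loop_len,
                hairpin_start=top[0],
                hairpin_end=top[1],
                u_tract_len=u_len,
                score=float(score),
            )
        )
    hits.sort(key=lambda h: (-h.score, h.hairpin_start))
    return hits


def gravy(peptide: str) -> float:
    """Grand average of hydropathy (mean Kyte–Doolittle index)."""
    if not peptide:
        raise ValueError("empty peptide")
    bad = set(peptide.upper()) - _STANDARD_AA
    if bad:
        raise ValueError(f"unknown residues {sorted(bad)}")
    return ProteinAnalysis(peptide.upper()).gravy()


def scan_orfs(
    seq: AnnotatedSequence,
    min_aa: int = 20,
    max_aa: int = 40,
    start_policy: str = "ATG_GTG",
) -> list[OrfHit]:
    """Exhaustive small-ORF scan over all six frames.

    Within each stop-to-stop frame segment the 5'-most qualifying start codon
    (ATG, or GTG under the ``ATG_GTG`` policy) defines the ORF, which must end
    at an in-frame stop; ORFs with peptide length outside [min_aa, max_aa] are
    discarded.  Coordinates include the stop codon.
    """
    starts = ("ATG", "GTG") if start_policy == "ATG_GTG" else ("ATG",)
    stops = ("TAA", "TAG", "TGA")
    n = len(seq)
    hits = []
    for strand in ("+", "-"):
        s = seq.residues if strand == "+" else revcomp(seq.residues)
        for frame in range(3):
            seg_start_codon = None  # local index of 5'-most start in open segment
            i = frame
            while i + 3 <= n:
                codon = s[i : i + 3]
                if codon in stops:
                    if seg_start_codon is not None:
                        aa = (i + 3 - seg_start_codon) // 3 - 1
                        if min_aa <= aa <= max_aa:
                            cds = s[seg_start_codon : i + 3]
                            pep = translate(cds, start_policy)
                            top = _to_top(seg_start_codon, i + 3, strand, n)
                            hits.append(
                                OrfHit(
                                    strand=strand,
                                    start=top[0],
                                    end=top[1],
                                    start_codon=cds[:3],
                                    peptide=pep,
                                    length_aa=aa,
                                    gravy=gravy(pep),
                                )
                            )
                    seg_start_codon = None
                elif seg_start_codon is None and codon in starts:
                    seg_start_codon = i
                i += 3
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def find_rbs(
    seq: AnnotatedSequence,
    orf: OrfHit,
    window: tuple[int, int] = (4, 14),
    min_sd: int = 3,
) -> RbsHit | None:
    """Best Shine–Dalgarno match upstream of an ORF start.

    Scores every 6-mer whose 3' end lies ``window`` nt upstream of the start
    codon (strand-aware) by contiguous identity to AGGAGG; ties prefer the
    offset closest to 8.  Returns None below ``min_sd``.
    """
    n = len(seq)
    s = seq.residues if orf.strand == "+" else revcomp(seq.residues)
    start_local = orf.start if orf.strand == "+" else n - orf.end
    best: tuple | None = None
    for offset in range(window[0], window[1] + 1):
        sd_end = start_local - offset
        sd_start = sd_end - 6
        if sd_start < 0:
            continue
        word = s[sd_start:sd_end]
        score = _matches(word, SD_CONSENSUS)
        key = (-score, abs(offset - 8), offset)
        if best is None or key < best[0]:
            best = (key, word, score, offset)
    if best is None or best[2] < min_sd:
        return None
    return RbsHit(orf_start=orf.start, sd_seq=best[1], sd_score=best[2], offset=best[3])
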