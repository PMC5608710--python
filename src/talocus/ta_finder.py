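"""Assembly of scanner outputs into transcript models and ranking of
convergent toxin/antitoxin locus candidates.

A type I toxin-antitoxin locus of the Fst/Lpt family is recognized as a pair
of small convergently transcribed RNAs: a toxin mRNA carrying a 20-40 codon
hydrophobic ORF with a Shine-Dalgarno site, and an ORF-free antitoxin
non-coding RNA whose sequence is antiparallel-complementary to a direct
repeat spanning the toxin start codon.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from dataclasses import replace as _replace
from typing import Sequence

from . import __version__
from .config import RunConfig
from .feature_scanners import (
    OrfHit,
    PromoterHit,
    RbsHit,
    TerminatorHit,
    find_rbs,
    scan_orfs,
    scan_promoters,
    scan_terminators,
)
from .rna_duplex import DirectRepeatMatch, StructureFold, duplex_scan, nussinov_fold
from .sequence_core import AnnotatedSequence, extract_region

__all__ = [
    "TranscriptModel",
    "TALocusCandidate",
    "assemble_transcripts",
    "find_ta_loci",
    "locus_report",
]

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class TranscriptModel:
    """A predicted RNA from a promoter paired with its nearest terminator.

    ``tss`` is the top-strand position of the +1 base; ``end3`` is the
    top-strand half-open boundary of the 3' end (just past the U-tract for a
    plus-strand transcript, the leftmost transcribed position for a
    minus-strand one).
    """

    strand: str
    tss: int
    end3: int
    length: int
    promoter: PromoterHit
    terminator: TerminatorHit
    rna: str
    category: str = "unclassified"

    @property
    def interval(self) -> tuple[int, int]:
        """Top-strand footprint as a half-open interval."""
        if self.strand == "+":
            return self.tss, self.end3
        return self.end3, self.tss + 1


@dataclass
class TALocusCandidate:
    toxin: TranscriptModel
    antitoxin: TranscriptModel
    orf: OrfHit
    rbs: RbsHit
    dr: DirectRepeatMatch
    toxin_fold: StructureFold | None
    composite_score: float
    rank: int = 0
    extra_drs: tuple[DirectRepeatMatch, ...] = ()

    @property
    def interval(self) -> tuple[int, int]:
        a, b = self.toxin.interval, self.antitoxin.interval
        return min(a[0], b[0]), max(a[1], b[1])


def assemble_transcripts(
    seq: AnnotatedSequence,
    promoters: Sequence[PromoterHit],
    terminators: Sequence[TerminatorHit],
    max_transcript: int = 400,
    min_transcript: int = 30,
) -> list[TranscriptModel]:
    """Pair each promoter with its nearest same-strand downstream terminator.

    The transcript runs from the predicted +1 through the end of the
    terminator T-tract; promoters whose nearest terminator would give a
    transcript longer than ``max_transcript`` (or shorter than
    ``min_transcript``) yield nothing.
    """
    n = len(seq)
    out = []
    for p in promoters:
        tss_local = p.tss if p.strand == "+" else n - 1 - p.tss
        best = None
        for t in terminators:
            if t.strand != p.strand:
                continue
            if t.strand == "+":
                h_start_local, h_end_local = t.hairpin_start, t.hairpin_end
            else:
                h_start_local, h_end_local = n - t.hairpin_end, n - t.hairpin_start
            if h_start_local < tss_local:
                continue
            end_local = min(h_end_local + t.u_tract_len, n)
            length = end_local - tss_local
            if length > max_transcript or length < min_transcript:
                continue
            if best is None or h_start_local < best[0]:
                best = (h_start_local, end_local, t)
        if best is None:
            continue
        _, end_local, term = best
        if p.strand == "+":
            tss, end3 = tss_local, end_local
            rna = extract_region(seq, tss, end3, "+").replace("T", "U")
        else:
            tss, end3 = n - 1 - tss_local, n - end_local
            rna = extract_region(seq, end3, tss + 1, "-").replace("T", "U")
        out.append(
            TranscriptModel(
                strand=p.strand,
                tss=tss,
                end3=end3,
                length=end_local - tss_local,
                promoter=p,
                terminator=term,
                rna=rna,
            )
        )
    return out


def _orfs_within(transcript: TranscriptModel, orfs: Sequence[OrfHit]) -> list[OrfHit]:
    lo, hi = transcript.interval
    return [
        o
        for o in orfs
        if o.strand == transcript.strand and o.start >= lo and o.end <= hi
    ]


def _orf_start_on_rna(transcript: TranscriptModel, orf: OrfHit) -> int:
    if transcript.strand == "+":
        return orf.start - transcript.tss
    return transcript.tss - (orf.end - 1)


def find_ta_loci(
    seq: AnnotatedSequence,
    config: RunConfig | None = None,
    fold: bool = True,
) -> list[TALocusCandidate]:
    """Detect and rank convergent toxin/antitoxin locus candidates.

    Runs all scanners, assembles transcripts on both strands, enumerates
    convergent opposite-strand pairs, and keeps pairs where exactly one
    transcript carries a qualifying hydrophobic ORF with an RBS and a direct
    repeat spanning its start codon while the other is a short ORF-free RNA.
    Returns candidates sorted by composite score (stable tie-break by
    leftmost coordinate); an empty list when nothing qualifies.
    """
    cfg = config or RunConfig()
    promoters = [
        h
        for strand in ("+", "-")
        for h in scan_promoters(
            seq,
            strand,
            min_m10=cfg.promoter.min_m10,
            min_score=cfg.promoter.min_score,
            lambda_spacer=cfg.promoter.lambda_spacer,
            tss_offset=cfg.promoter.tss_offset,
        )
    ]
    terminators = [
        h
        for strand in ("+", "-")
        for h in scan_terminators(
            seq,
            strand,
            min_stem=cfg.terminator.min_stem,
            loop_range=(cfg.terminator.loop_min, cfg.terminator.loop_max),
            min_u=cfg.terminator.min_u,
            max_mismatch_stem=cfg.terminator.max_mismatch_stem,
        )
    ]
    transcripts = assemble_transcripts(
        seq, promoters, terminators, cfg.finder.max_transcript, cfg.finder.min_transcript
    )
    orfs = scan_orfs(seq, cfg.orf.min_aa, cfg.orf.max_aa, cfg.orf.start_policy)

    candidates = []
    plus = [t for t in transcripts if t.strand == "+"]
    minus = [t for t in transcripts if t.strand == "-"]
    for tp in plus:
        for tm in minus:
            if tp.tss >= tm.tss:
                continue  # not transcribed toward each other
            gap = tm.end3 - tp.end3  # negative when the 3' ends overlap
            if gap > cfg.finder.convergence_gap:
                continue
            for toxin, anti in ((tp, tm), (tm, tp)):
                cand = _evaluate_pair(seq, toxin, anti, orfs, cfg, fold)
                if cand is not None:
                    candidates.append(cand)
    candidates.sort(key=lambda c: (-c.composite_score, c.interval[0]))
    # candidates sharing the same ORF and antitoxin transcript are alternative
    # models of one locus; keep the best-scoring representative
    deduped: list[TALocusCandidate] = []
    seen: set[tuple] = set()
    for c in candidates:
        key = (c.orf.start, c.orf.end, c.orf.strand, c.antitoxin.interval)
        if key in seen:
            continue
        seen.add(key)
        deduped.append(c)
    for i, c in enumerate(deduped, start=1):
        c.rank = i
    return deduped


def _evaluate_pair(
    seq: AnnotatedSequence,
    toxin: TranscriptModel,
    anti: TranscriptModel,
    orfs: Sequence[OrfHit],
    cfg: RunConfig,
    fold: bool,
) -> TALocusCandidate | None:
    f = cfg.finder
    if not (f.antitoxin_min_len <= anti.length <= f.antitoxin_max_len):
        return None
    if _orfs_within(anti, orfs):
        return None  # an ORF-bearing second transcript disqualifies the pair
    toxin_orfs = sorted(_orfs_within(toxin, orfs), key=lambda o: -o.gravy)
    for orf in toxin_orfs:
        if orf.gravy < f.gravy_min:
            continue
        rbs = find_rbs(
            seq, orf, (cfg.rbs.window_min, cfg.rbs.window_max), cfg.rbs.min_sd
        )
        if rbs is None:
            continue
        start_on_rna = _orf_start_on_rna(toxin, orf)
        spanning = [
            m
            for m in duplex_scan(
                toxin.rna, anti.rna, cfg.dr.min_len, cfg.dr.max_mismatch_frac
            )
            if m.a_start < start_on_rna + 3 and m.a_end > start_on_rna
        ]
        if not spanning:
            continue
        dr = _replace(spanning[0], spans_start_codon=True)
        extra = tuple(_replace(m, spans_start_codon=True) for m in spanning[1:])
        score = (
            f.w_promoter * (toxin.promoter.score + anti.promoter.score)
            + f.w_terminator * (toxin.terminator.score + anti.terminator.score)
            + f.w_dr * dr.length * (1 - dr.mismatches / dr.length)
            + f.w_gravy * max(orf.gravy, 0.0)
            + f.w_sd * rbs.sd_score
        )
        toxin_fold = nussinov_fold(toxin.rna) if fold else None
        toxin = _categorize(toxin, "toxin_mRNA")
        anti = _categorize(anti, "antitoxin_ncRNA")
        return TALocusCandidate(
            toxin=toxin,
            antitoxin=anti,
            orf=orf,
            rbs=rbs,
            dr=dr,
            toxin_fold=toxin_fold,
            composite_score=score,
            extra_drs=extra,
        )
    return None


def _categorize(t: TranscriptModel, category: str) -> TranscriptModel:
    from dataclasses import replace

    return replace(t, category=category)


def locus_report(
    candidate: TALocusCandidate,
    seq: AnnotatedSequence,
    config: RunConfig | None = None,
) -> dict:
    """Machine-readable report of a locus candidate.

    Contains every model field, the thresholds in force, the software
    version and a digest of the input sequence; schema versioned.  Two runs
    on identical input produce byte-identical JSON.
    """
    cfg = config or RunConfig()

    def transcript_dict(t: TranscriptModel) -> dict:
        d = asdict(t)
        return d

    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "software_version": __version__,
        "input": {
            "id": seq.id,
            "length": len(seq),
            "sha256": hashlib.sha256(seq.residues.encode()).hexdigest(),
        },
        "config": cfg.to_dict(),
        "rank": candidate.rank,
        "composite_score": candidate.composite_score,
        "toxin": transcript_dict(candidate.toxin),
        "antitoxin": transcript_dict(candidate.antitoxin),
        "orf": asdict(candidate.orf),
        "rbs": asdict(candidate.rbs),
        "dr": asdict(candidate.dr),
        "extra_drs": [asdict(d) for d in candidate.extra_drs],
        "toxin_fold": None
        if candidate.toxin_fold is None
        else {
            "n_pairs": candidate.toxin_fold.n_pairs,
            "dot_bracket": candidate.toxin_fold.dot_bracket(),
            "hairpins": list(candidate.toxin_fold.hairpins),
            "annotations": candidate.toxin_fold.annotations,
        },
    }
    # round-trip through JSON for canonical types
    return json.loads(json.dumps(doc, sort_keys=True))
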