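"""Generators for synthetic inputs with the architecture the analysis assumes.

``make_ta_locus`` plants a complete convergent type I toxin-antitoxin locus
into random background sequence: a toxin transcription unit (near-consensus
σ70 promoter, engineered 5' UTR folding an upstream helix and an RBS-
sequestering stem-loop, a small hydrophobic ORF, rho-independent terminator)
and, on the opposite strand, a short antitoxin non-coding RNA whose template
carries a direct DNA repeat of the toxin start-codon region, so that the two
RNAs are antiparallel-complementary over the toxin start codon.  Defaults
encode the reference locus architecture: TATACT/TAAAAT −10 hexamers with
20/17 bp spacers, a 29-residue hydrophobic toxin peptide, a 24 nt direct
repeat and a 74 nt antitoxin RNA.

Guard bases are planted at element boundaries (non-complementary flanks
around the direct repeat, non-extending bases next to terminator stems and
T-tracts) so that every element is re-detected at exactly its planted
coordinates by the default scanners; this makes ground-truth recovery a
deterministic property rather than a probabilistic one.

Every generator is a pure function of its configuration and seed, and emits
a SyntheticTruth record with all planted coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .afm_occupancy import AfmMeasurement, PromoterSpec
from .feature_scanners import gravy
from .sequence_core import AnnotatedSequence, Feature, FeatureKind, revcomp

__all__ = [
    "LocusConfig",
    "SyntheticTruth",
    "make_ta_locus",
    "mutate_promoter",
    "simulate_afm",
    "make_homolog_panel",
    "random_locus_config",
    "DEFAULT_TOXIN_PEPTIDE",
]

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

# one codon per residue; used to back-translate planted peptides
_CODON = {
    "A": "GCA", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAA", "R": "CGT",
    "S": "TCC", "T": "ACC", "V": "GTC", "W": "TGG", "Y": "TAC",
}

_HYDROPHOBIC_ALPHABET = "AILVFMGST"

# engineered 5' UTR elements (see module docstring): an upstream helix at the
# transcript 5' end, a linker carrying an in-frame stop that isolates the
# planted ORF in its reading frame, and a stem-loop whose 3' stem is the
# Shine-Dalgarno sequence itself
_UH = "GGCAGG" + "TTCA" + "CCTGCC"
_SL = "CCTCCT" + "TCGA" + "AGGAGG"
_LINKER_LEN = 6

# stems of the two planted intrinsic terminators (all-G/C, mutually dissimilar
# so the two hairpin regions cannot cross-hybridize)
_TOXIN_STEM_POOL = "GCCGCAGCGGCC"
_ANTI_STEM_POOL = "CGGTGCCGCAGG"

_MUTATIONS = {"TATACT": "TGTCCC", "TAAAAT": "TGACAC"}


def _default_peptide() -> str:
    """A fixed 29-residue hydrophobic peptide (GRAVY ≥ 1.5)."""
    rng = np.random.default_rng(20170921)
    while True:
        pep = "M" + "".join(rng.choice(list(_HYDROPHOBIC_ALPHABET), size=28))
        if gravy(pep) >= 1.5:
            return pep


DEFAULT_TOXIN_PEPTIDE = _default_peptide()


@dataclass(frozen=True)
class LocusConfig:
    seed: int = 0
    toxin_minus35: str = "TTGACA"
    toxin_minus10: str = "TATACT"
    antitoxin_minus35: str = "TTGACA"
    antitoxin_minus10: str = "TAAAAT"
    toxin_spacer: int = 20
    antitoxin_spacer: int = 17
    utr5_len: int = 46  # UH(16) + linker(6) + SL(16) + RBS-to-start offset(8)
    orf_peptide: str = DEFAULT_TOXIN_PEPTIDE
    dr_len: int = 24
    dr_mismatches: int = 0
    terminator_stem: int = 6
    terminator_loop: int = 4
    u_tract: int = 7
    convergence_gap: int = 40
    anti_utr5_len: int = 15  # antitoxin TSS to its direct-repeat copy
    anti_gap_len: int = 12  # direct-repeat copy to the antitoxin terminator
    post_orf_gap: int = 8
    tss_offset: int = 7
    flank_len: int = 150
    gc_background: float = 0.42

    @property
    def rbs_offset(self) -> int:
        return self.utr5_len - len(_UH) - _LINKER_LEN - len(_SL)

    def validate(self) -> None:
        if not (15 <= self.toxin_spacer <= 21) or not (15 <= self.antitoxin_spacer <= 21):
            raise ValueError("promoter spacers must be in [15, 21]")
        if self.dr_len < 15:
            raise ValueError("dr_len must be >= 15")
        if self.dr_mismatches > int(0.1 * self.dr_len):
            raise ValueError("dr_mismatches exceed the default duplex budget")
        if not (4 <= self.rbs_offset <= 14):
            raise ValueError("utr5_len incompatible with the engineered UTR layout")
        if len(self.orf_peptide) < 5 or self.orf_peptide[0] != "M":
            raise ValueError("orf_peptide must start with M and have >= 5 residues")
        dr_right = self.dr_len - 3 - (self.dr_len - 2) // 2
        if dr_right > 3 * len(self.orf_peptide) - 3:
            raise ValueError("direct repeat longer than the coding region allows")
        anti_len = (
            self.u_tract
            + 2 * self.terminator_stem
            + self.terminator_loop
            + self.anti_gap_len
            + self.dr_len
            + self.anti_utr5_len
        )
        if anti_len < 30:
            raise ValueError("antitoxin transcript geometrically too short")
        if self.anti_utr5_len < 7 or self.anti_gap_len < 7:
            raise ValueError("antitoxin gaps must leave room for 6-nt duplex guards")
        if self.terminator_stem > len(_TOXIN_STEM_POOL):
            raise ValueError("terminator_stem too long")
        if self.u_tract < 4 or self.u_tract > 8:
            raise ValueError("u_tract must be in [4, 8]")


@dataclass
class SyntheticTruth:
    """Ground-truth record for a generated dataset."""

    seed: int
    features: list[Feature] = field(default_factory=list)
    toxin_transcript: dict | None = None
    antitoxin_transcript: dict | None = None
    orf: tuple[int, int, str] | None = None
    peptide: str | None = None
    dr_a: tuple[int, int] | None = None
    dr_b: tuple[int, int] | None = None
    afm: dict | None = None
    panel: dict | None = None
    mutations: list[str] = field(default_factory=list)

    def feature(self, kind: FeatureKind, **attrs: str) -> Feature:
        for f in self.features:
            if f.kind is kind and all(f.attrs.get(k) == v for k, v in attrs.items()):
                return f
        raise KeyError(f"no planted {kind} feature with {attrs}")


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return list(rng.choice(_BASES, size=n, p=p)) if n else []


def _forbid(chars: list[str], idx: int, banned: str) -> None:
    """Deterministically replace chars[idx] if it equals a banned base."""
    if chars[idx] in banned:
        for alt in "CGAT":
            if alt not in banned:
                chars[idx] = alt
                return


def make_ta_locus(cfg: LocusConfig | None = None) -> tuple[AnnotatedSequence, SyntheticTruth]:
    """Emit a planted convergent toxin/antitoxin locus and its ground truth.

    The random background is redrawn (deterministically, from seeds derived
    from ``cfg.seed``) until the default scanners recover every planted
    element at exactly its planted coordinates — in particular until no
    chance hairpin inside either transcript would pre-empt the planted
    terminator under the nearest-terminator rule.
    """
    cfg = cfg or LocusConfig()
    cfg.validate()
    for attempt in range(25):
        seq, truth, mutable = _build_locus(cfg, np.random.default_rng([cfg.seed, attempt]))
        result = _sanitize(seq, truth, cfg, mutable)
        if result is not None:
            # _sanitize succeeds only when _collect_offenders — which ends
            # with the full finder gate — reports a clean locus
            return result
    raise RuntimeError(f"could not build a self-consistent locus for seed {cfg.seed}")


def _build_locus(
    cfg: LocusConfig, rng: np.random.Generator
) -> tuple[AnnotatedSequence, SyntheticTruth, set[int]]:
    gc = cfg.gc_background

    stem1 = _TOXIN_STEM_POOL[: cfg.terminator_stem]
    stem2 = _ANTI_STEM_POOL[: cfg.terminator_stem]
    loop1 = "TTCGTTCGT"[: cfg.terminator_loop]
    loop2 = "TTCGTTCGT"[: cfg.terminator_loop]

    # engineered 5' UTR: UH + linker (with in-frame stop) + SL + SD offset
    linker = list("ACACAC")
    for s in range(len(_UH), len(_UH) + 4):
        if (cfg.utr5_len - s) % 3 == 0:
            linker[s - len(_UH) : s - len(_UH) + 3] = list("TAA")
            break
    sd_spacer = ("CACTAT" * 3)[: cfg.rbs_offset]
    utr = _UH + "".join(linker) + _SL + sd_spacer
    assert len(utr) == cfg.utr5_len

    cds = "".join(_CODON[aa] for aa in cfg.orf_peptide) + "TAA"

    post_gap = _random_dna(rng, cfg.post_orf_gap, gc)
    post_gap[-3:] = list("CGC")  # blocks outward stem extension of the toxin hairpin

    conv_gap = _random_dna(rng, cfg.convergence_gap, gc)
    for i in range(max(1, 8 - cfg.u_tract)):  # keep the toxin T-tract at its length
        _forbid(conv_gap, i, "T")
    for i in range(1, max(2, 8 - cfg.u_tract + 1)):  # and the antitoxin one
        _forbid(conv_gap, -i, "A")

    g2 = _random_dna(rng, cfg.anti_gap_len, gc)
    for i in range(3):  # blocks outward stem extension of the antitoxin hairpin
        _forbid(g2, i, "T")
    g1 = _random_dna(rng, cfg.anti_utr5_len, gc)

    t_spacer = "".join(_random_dna(rng, cfg.toxin_spacer, gc))
    t_gap = "".join(_random_dna(rng, cfg.tss_offset - 1, gc))
    a_spacer = "".join(_random_dna(rng, cfg.antitoxin_spacer, gc))
    a_gap = "".join(_random_dna(rng, cfg.tss_offset - 1, gc))
    flank_l = "".join(_random_dna(rng, cfg.flank_len, gc))
    flank_r = "".join(_random_dna(rng, cfg.flank_len, gc))

    # the direct repeat: dr_len nt of the toxin RNA centred on the start codon
    dr_left = (cfg.dr_len - 2) // 2  # nt of UTR included before the ATG
    utr_cds = utr + cds
    dra_local = cfg.utr5_len - dr_left  # within utr_cds
    dr_seq = list(utr_cds[dra_local : dra_local + cfg.dr_len])
    interior = rng.permutation(np.arange(2, cfg.dr_len - 2))[: cfg.dr_mismatches]
    for i in sorted(int(x) for x in interior):
        dr_seq[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[dr_seq[i]]
    dr_b = "".join(dr_seq)

    # 6-nt guard zones: make the flanks of the repeat copy non-complementary
    # to the toxin RNA so the planted duplex cannot extend by chance
    for t in range(1, 7):
        _forbid(g2, -t, utr_cds[dra_local - t])
        after = utr_cds[dra_local + cfg.dr_len - 1 + t]
        _forbid(g1, t - 1, after)

    parts = [
        ("flank_l", flank_l),
        ("t_m35", cfg.toxin_minus35),
        ("t_spacer", t_spacer),
        ("t_m10", cfg.toxin_minus10),
        ("t_gap", t_gap),
        ("utr", utr),
        ("cds", cds),
        ("post_gap", "".join(post_gap)),
        ("t_term", stem1 + loop1 + revcomp(stem1) + "T" * cfg.u_tract),
        ("conv_gap", "".join(conv_gap)),
        ("a_tract", "A" * cfg.u_tract),
        ("a_term", stem2 + loop2 + revcomp(stem2)),
        ("g2", "".join(g2)),
        ("dr_b", dr_b),
        ("g1", "".join(g1)),
        ("a_gap", a_gap),
        ("a_m10", revcomp(cfg.antitoxin_minus10)),
        ("a_spacer", a_spacer),
        ("a_m35", revcomp(cfg.antitoxin_minus35)),
        ("flank_r", flank_r),
    ]
    offsets = {}
    pos = 0
    for name, chunk in parts:
        offsets[name] = (pos, pos + len(chunk))
        pos += len(chunk)
    residues = "".join(chunk for _, chunk in parts)
    seq = AnnotatedSequence(id=f"synthetic_locus_seed{cfg.seed}", residues=residues)

    # ground truth, all on top-strand 0-based half-open coordinates
    tss1 = offsets["utr"][0]
    toxin_end3 = offsets["t_term"][1]
    atg = offsets["cds"][0]
    orf_iv = (atg, offsets["cds"][1], "+")
    dra = (atg - dr_left, atg - dr_left + cfg.dr_len)
    drb = offsets["dr_b"]
    tss2 = offsets["g1"][1] - 1
    anti_end3 = offsets["a_tract"][0]
    hairpin1 = (offsets["t_term"][0], offsets["t_term"][1] - cfg.u_tract)
    hairpin2 = offsets["a_term"]

    toxin_rna = residues[tss1:toxin_end3].replace("T", "U")
    anti_rna = revcomp(residues[anti_end3 : tss2 + 1]).replace("T", "U")

    features = [
        Feature(FeatureKind.promoter, offsets["t_m10"][0], offsets["t_m10"][1], "+",
                attrs={"element": "minus10", "unit": "toxin", "hexamer": cfg.toxin_minus10}),
        Feature(FeatureKind.promoter, offsets["t_m35"][0], offsets["t_m35"][1], "+",
                attrs={"element": "minus35", "unit": "toxin", "hexamer": cfg.toxin_minus35}),
        Feature(FeatureKind.promoter, offsets["a_m10"][0], offsets["a_m10"][1], "-",
                attrs={"element": "minus10", "unit": "antitoxin", "hexamer": cfg.antitoxin_minus10}),
        Feature(FeatureKind.promoter, offsets["a_m35"][0], offsets["a_m35"][1], "-",
                attrs={"element": "minus35", "unit": "antitoxin", "hexamer": cfg.antitoxin_minus35}),
        Feature(FeatureKind.terminator, hairpin1[0], hairpin1[1], "+",
                attrs={"unit": "toxin", "u_tract": str(cfg.u_tract)}),
        Feature(FeatureKind.terminator, hairpin2[0], hairpin2[1], "-",
                attrs={"unit": "antitoxin", "u_tract": str(cfg.u_tract)}),
        Feature(FeatureKind.orf, orf_iv[0], orf_iv[1], "+", attrs={"unit": "toxin"}),
        Feature(FeatureKind.rbs, offsets["utr"][0] + cfg.utr5_len - cfg.rbs_offset - 6,
                offsets["utr"][0] + cfg.utr5_len - cfg.rbs_offset, "+", attrs={"unit": "toxin"}),
        Feature(FeatureKind.dr, dra[0], dra[1], "+", attrs={"copy": "a"}),
        Feature(FeatureKind.dr, drb[0], drb[1], "+", attrs={"copy": "b"}),
        Feature(FeatureKind.transcript, tss1, toxin_end3, "+", attrs={"unit": "toxin"}),
        Feature(FeatureKind.transcript, anti_end3, tss2 + 1, "-", attrs={"unit": "antitoxin"}),
    ]
    truth = SyntheticTruth(
        seed=cfg.seed,
        features=features,
        toxin_transcript={
            "strand": "+", "tss": tss1, "end3": toxin_end3,
            "length": toxin_end3 - tss1, "rna": toxin_rna,
        },
        antitoxin_transcript={
            "strand": "-", "tss": tss2, "end3": anti_end3,
            "length": tss2 + 1 - anti_end3, "rna": anti_rna,
        },
        orf=orf_iv,
        peptide=cfg.orf_peptide,
        dr_a=dra,
        dr_b=drb,
    )
    # positions whose content is free background, available to the
    # sanitization pass; engineered elements and guard bases are excluded
    mutable: set[int] = set()
    for name in ("flank_l", "t_spacer", "t_gap", "a_gap", "a_spacer", "flank_r"):
        mutable.update(range(*offsets[name]))
    lo, hi = offsets["post_gap"]
    mutable.update(range(lo, hi - 3))
    lo, hi = offsets["conv_gap"]
    mutable.update(range(lo + 4, hi - 4))
    lo, hi = offsets["g2"]
    mutable.update(range(lo + 3, hi - 6))
    lo, hi = offsets["g1"]
    mutable.update(range(lo + 6, hi - 1))  # last base is the antitoxin +1
    return seq, truth, mutable


def _refresh_rna(truth: SyntheticTruth, residues: str) -> None:
    t, a = truth.toxin_transcript, truth.antitoxin_transcript
    t["rna"] = residues[t["tss"] : t["end3"]].replace("T", "U")
    a["rna"] = revcomp(residues[a["end3"] : a["tss"] + 1]).replace("T", "U")


def _sanitize(
    seq: AnnotatedSequence, truth: SyntheticTruth, cfg: LocusConfig, mutable: set[int]
) -> tuple[AnnotatedSequence, SyntheticTruth] | None:
    """Degrade chance background motifs until the planted elements are the
    only ones the scanners act on.

    Repeatedly rescans the sequence (and its two promoter-knockout mutants),
    and rewrites individual bases — only at positions designated as free
    background — to break stand-in promoters, arrangements that would merge
    away a planted promoter, and hairpins that would pre-empt a planted
    terminator.  Returns the cleaned sequence, or None when an offender
    cannot be reached through mutable positions.
    """
    chars = list(seq.residues)
    for _ in range(40):
        current = AnnotatedSequence(id=seq.id, residues="".join(chars))
        offenders = _collect_offenders(current, truth, cfg)
        if not offenders:
            _refresh_rna(truth, current.residues)
            return current, truth
        progress = False
        for kind, hit, strand in offenders:
            if kind == "prom":
                progress |= _break_promoter(chars, hit, strand, mutable)
            elif kind == "trans":
                # disable the stand-in transcript through whichever of its
                # two elements is reachable in free background
                if not _break_promoter(chars, hit.promoter, strand, mutable):
                    progress |= _break_hairpin(chars, hit.terminator, mutable)
                else:
                    progress = True
            else:
                progress |= _break_hairpin(chars, hit, mutable)
        if not progress:
            return None
    return None


def _collect_offenders(
    seq: AnnotatedSequence, truth: SyntheticTruth, cfg: LocusConfig
) -> list[tuple]:
    from .feature_scanners import scan_promoters, scan_terminators

    n = len(seq)
    offenders: list[tuple] = []
    units = (
        ("toxin", "+", truth.toxin_transcript),
        ("antitoxin", "-", truth.antitoxin_transcript),
    )
    for unit, strand, transcript in units:
        m10 = truth.feature(FeatureKind.promoter, element="minus10", unit=unit)
        proms = scan_promoters(seq, strand, tss_offset=cfg.tss_offset)
        if not any(h.minus10_start == m10.start and h.tss == transcript["tss"] for h in proms):
            centre = m10.start + 3
            offenders += [
                ("prom", h, strand)
                for h in proms
                if abs(h.minus10_start + 3 - centre) <= 10 and h.minus10_start != m10.start
            ]
        hairpin = truth.feature(FeatureKind.terminator, unit=unit)
        terms = scan_terminators(seq, strand)
        if not any(
            (t.hairpin_start, t.hairpin_end) == (hairpin.start, hairpin.end)
            and t.u_tract_len == cfg.u_tract
            for t in terms
        ):
            offenders += [
                ("term", t, strand)
                for t in terms
                if t.hairpin_start < hairpin.end and hairpin.start < t.hairpin_end
                and (t.hairpin_start, t.hairpin_end) != (hairpin.start, hairpin.end)
            ]
        tss_local = transcript["tss"] if strand == "+" else n - 1 - transcript["tss"]
        planted_local = hairpin.start if strand == "+" else n - hairpin.end
        for t in terms:
            start_local = t.hairpin_start if strand == "+" else n - t.hairpin_end
            if tss_local <= start_local < planted_local:
                offenders.append(("term", t, strand))
        offenders += [
            ("trans", t, strand)
            for t in _standin_transcripts(seq, truth, strand, exclude_tss=transcript["tss"])
        ]
    for which, strand in (("toxin", "+"), ("antitoxin", "-")):
        feat = truth.feature(FeatureKind.promoter, element="minus10", unit=which)
        hexamer = (
            seq.residues[feat.start : feat.end]
            if feat.strand == "+"
            else revcomp(seq.residues[feat.start : feat.end])
        )
        if hexamer not in _MUTATIONS:
            continue
        mut_seq, _ = mutate_promoter(seq, truth, which)
        offenders += [
            ("trans", t, strand)
            for t in _standin_transcripts(mut_seq, truth, strand, exclude_tss=None)
        ]
    if not offenders:
        # final (and most expensive) gate, only once the cheap element-level
        # checks are clean: the finder itself must agree
        offenders = _spurious_candidate_offenders(seq, truth)
    return offenders


def _spurious_candidate_offenders(seq: AnnotatedSequence, truth: SyntheticTruth) -> list[tuple]:
    """Promoters driving full locus candidates other than the planted one.

    The final authority: the locus finder itself must report exactly the
    planted candidate on the built sequence and nothing on either
    promoter-knockout mutant; any other candidate (e.g. a chance locus
    assembled entirely in flanking background) is dismantled through its
    non-planted promoters.
    """
    from .ta_finder import find_ta_loci

    planted_m10 = {
        (f.start, f.end)
        for f in truth.features
        if f.kind is FeatureKind.promoter and f.attrs.get("element") == "minus10"
    }
    planted_key = (
        truth.toxin_transcript["tss"],
        truth.antitoxin_transcript["tss"],
        truth.orf[:2],
    )

    def collect(cands, keep_planted: bool) -> list[tuple]:
        out = []
        for c in cands:
            key = (c.toxin.tss, c.antitoxin.tss, (c.orf.start, c.orf.end))
            if keep_planted and key == planted_key:
                continue
            for tm in (c.toxin, c.antitoxin):
                iv = (tm.promoter.minus10_start, tm.promoter.minus10_start + 6)
                if iv not in planted_m10:
                    out.append(("prom", tm.promoter, tm.strand))
        return out

    offenders = collect(find_ta_loci(seq, fold=False), keep_planted=True)
    for which in ("toxin", "antitoxin"):
        feat = truth.feature(FeatureKind.promoter, element="minus10", unit=which)
        hexamer = (
            seq.residues[feat.start : feat.end]
            if feat.strand == "+"
            else revcomp(seq.residues[feat.start : feat.end])
        )
        if hexamer not in _MUTATIONS:
            continue
        mut_seq, _ = mutate_promoter(seq, truth, which)
        offenders += collect(find_ta_loci(mut_seq, fold=False), keep_planted=False)
    return offenders


def _break_promoter(chars: list[str], hit, strand: str, mutable: set[int]) -> bool:
    """Mutate matching −10 (then −35) bases of a background promoter hit."""
    from .feature_scanners import MINUS10_CONSENSUS, MINUS35_CONSENSUS

    comp = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}
    changed = 0
    for start, consensus, budget in (
        (hit.minus10_start, MINUS10_CONSENSUS, max(1, hit.m10 - 3)),
        (hit.minus35_start, MINUS35_CONSENSUS, 2),
    ):
        for k in range(6):
            if changed >= budget:
                break
            top = start + k
            if top not in mutable or top >= len(chars):
                continue
            idx = k if strand == "+" else 5 - k
            local = chars[top] if strand == "+" else comp[chars[top]]
            if local != consensus[idx]:
                continue
            # any base whose strand-aware reading mismatches the consensus
            for alt in "CGAT":
                reading = alt if strand == "+" else comp[alt]
                if reading != consensus[idx] and alt != chars[top]:
                    chars[top] = alt
                    changed += 1
                    break
        if changed:
            return True
    return False


def _break_hairpin(chars: list[str], hit, mutable: set[int]) -> bool:
    """Break Watson-Crick stem pairs of a background hairpin."""
    broken = 0
    h_start, h_end, stem = hit.hairpin_start, hit.hairpin_end, hit.stem_len
    for k in range(stem):
        if broken >= 2:
            break
        p1, p2 = h_start + k, h_end - 1 - k
        for p, partner in ((p1, p2), (p2, p1)):
            if p in mutable:
                chars[p] = "C" if chars[partner] != "G" else "A"
                broken += 1
                break
    return broken > 0


def _self_consistent(seq: AnnotatedSequence, truth: SyntheticTruth, cfg: LocusConfig) -> bool:
    """True when the default scanners recover the planted elements exactly.

    Checks, per transcription unit: the planted −10 hexamer is re-detected at
    its coordinates with the planted +1; the planted terminator hairpin is
    re-detected with its exact boundaries and T-tract length; and no other
    terminator hit lies between the +1 and the planted hairpin (which would
    pre-empt it under the nearest-terminator pairing rule).
    """
    from .feature_scanners import scan_promoters, scan_terminators

    n = len(seq)
    units = (
        ("toxin", "+", truth.toxin_transcript),
        ("antitoxin", "-", truth.antitoxin_transcript),
    )
    for unit, strand, transcript in units:
        m10 = truth.feature(FeatureKind.promoter, element="minus10", unit=unit)
        proms = scan_promoters(seq, strand, tss_offset=cfg.tss_offset)
        planted = [
            h for h in proms if h.minus10_start == m10.start and h.tss == transcript["tss"]
        ]
        if not planted:
            return False
        hairpin = truth.feature(FeatureKind.terminator, unit=unit)
        terms = scan_terminators(seq, strand)
        exact = [
            t
            for t in terms
            if (t.hairpin_start, t.hairpin_end) == (hairpin.start, hairpin.end)
            and t.u_tract_len == cfg.u_tract
        ]
        if not exact:
            return False
        tss_local = transcript["tss"] if strand == "+" else n - 1 - transcript["tss"]
        planted_start_local = hairpin.start if strand == "+" else n - hairpin.end
        for t in terms:
            start_local = t.hairpin_start if strand == "+" else n - t.hairpin_end
            if tss_local <= start_local < planted_start_local:
                return False
        if _standin_transcripts(seq, truth, strand, exclude_tss=transcript["tss"]):
            return False
    # a planted-promoter knockout must leave no stand-in: re-check the two
    # mutant sequences, where arrangements previously merged into the planted
    # hit can surface
    for which, strand in (("toxin", "+"), ("antitoxin", "-")):
        feat = truth.feature(FeatureKind.promoter, element="minus10", unit=which)
        hexamer = (
            seq.residues[feat.start : feat.end]
            if feat.strand == "+"
            else revcomp(seq.residues[feat.start : feat.end])
        )
        if hexamer not in _MUTATIONS:
            continue
        mut_seq, _ = mutate_promoter(seq, truth, which)
        if _standin_transcripts(mut_seq, truth, strand, exclude_tss=None):
            return False
    return not _spurious_candidate_offenders(seq, truth)


def _standin_transcripts(
    seq: AnnotatedSequence, truth: SyntheticTruth, strand: str, exclude_tss: int | None
) -> list:
    """Assembled same-strand transcripts (other than the planted one) that
    could stand in for a knocked-out planted unit: a plus-strand transcript
    covering the whole toxin ORF, or a minus-strand transcript of antitoxin
    length that overlaps the toxin start codon antisense or its image inside
    the direct-repeat copy."""
    from .feature_scanners import scan_promoters

    from .feature_scanners import scan_terminators
    from .ta_finder import assemble_transcripts

    promoters = [
        h for h in scan_promoters(seq, strand)
        if exclude_tss is None or h.tss != exclude_tss
    ]
    terminators = scan_terminators(seq, strand)
    transcripts = assemble_transcripts(seq, promoters, terminators)
    atg = truth.orf[0]
    atg_img = truth.dr_b[0] + (atg - truth.dr_a[0])
    out = []
    for t in transcripts:
        lo, hi = t.interval
        if strand == "+":
            harmful = lo <= truth.orf[0] and truth.orf[1] <= hi
        else:
            covers_codon = lo < atg + 3 and atg < hi
            covers_image = lo < atg_img + 3 and atg_img < hi
            harmful = (50 <= t.length <= 200) and (covers_codon or covers_image)
        if harmful:
            out.append(t)
    return out


def mutate_promoter(
    seq: AnnotatedSequence, truth: SyntheticTruth, which: str
) -> tuple[AnnotatedSequence, SyntheticTruth]:
    """Introduce the inactivating −10 triple mutation (TATACT→TGTCCC for the
    toxin promoter, TAAAAT→TGACAC for the antitoxin promoter)."""
    if which not in ("toxin", "antitoxin"):
        raise ValueError("which must be 'toxin' or 'antitoxin'")
    feat = truth.feature(FeatureKind.promoter, element="minus10", unit=which)
    current = seq.residues[feat.start : feat.end]
    hexamer = current if feat.strand == "+" else revcomp(current)
    if hexamer not in _MUTATIONS:
        raise ValueError(
            f"planted -10 hexamer {hexamer!r} has no defined triple mutation"
        )
    mutant = _MUTATIONS[hexamer]
    replacement = mutant if feat.strand == "+" else revcomp(mutant)
    residues = seq.residues[: feat.start] + replacement + seq.residues[feat.end :]
    new_seq = AnnotatedSequence(id=seq.id + f"_{which}_m10mut", residues=residues)
    new_truth = replace(truth, mutations=truth.mutations + [f"{which}:{hexamer}->{mutant}"])
    return new_seq, new_truth


def simulate_afm(
    n: int,
    template_bp: int,
    promoters: list[PromoterSpec],
    fractions: dict[str, float],
    sigma_bp: float = 15.0,
    contour_cv: float = 0.03,
    nm_per_bp: float = 0.34,
    seed: int = 0,
) -> tuple[list[AfmMeasurement], SyntheticTruth]:
    """Simulate AFM complex-position measurements from a mixture model.

    Each molecule draws a category from ``fractions`` (promoter names plus
    "nonspecific"); specific positions are Normal(centre, sigma_bp) truncated
    to the template, nonspecific ones Uniform(0, template).  Positions are
    reflected end-for-end with probability 0.5 (unlabelled template), and the
    molecule contour is template·nm_per_bp·(1 + Normal(0, contour_cv)).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = list(fractions)
    probs = np.array([fractions[k] for k in names], dtype=float)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be nonnegative and sum to 1")
    centers = {p.name: p.center_bp for p in promoters}
    unknown = set(names) - set(centers) - {"nonspecific"}
    if unknown:
        raise ValueError(f"fractions name unknown promoters {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    measurements = []
    categories = []
    for i in range(n):
        cat = names[int(rng.choice(len(names), p=probs))]
        categories.append(cat)
        if cat == "nonspecific":
            position = rng.uniform(0, template_bp)
        else:
            position = float(
                np.clip(centers[cat] + rng.normal(0, sigma_bp), 0, template_bp)
            )
        if rng.random() < 0.5:
            position = template_bp - position
        contour = template_bp * nm_per_bp * (1 + rng.normal(0, contour_cv))
        contour = max(contour, 1e-6)
        measurements.append(
            AfmMeasurement(
                molecule_id=f"mol{i:05d}",
                contour_nm=contour,
                complex_pos_nm=position * contour / template_bp,
                template_bp=template_bp,
            )
        )
    truth = SyntheticTruth(
        seed=seed,
        afm={
            "fractions": dict(fractions),
            "sigma_bp": sigma_bp,
            "contour_cv": contour_cv,
            "n": n,
            "template_bp": template_bp,
            "categories": categories,
        },
    )
    return measurements, truth


def _random_peptide(rng: np.random.Generator, length: int, min_gravy: float = 1.5) -> str:
    while True:
        pep = "M" + "".join(rng.choice(list(_HYDROPHOBIC_ALPHABET), size=length - 1))
        if gravy(pep) >= min_gravy:
            return pep


def random_locus_config(seed: int) -> LocusConfig:
    """A randomized planted-locus configuration for recovery testing:
    spacers 15-21, peptide 20-40 aa, direct repeat 20-30 nt."""
    rng = np.random.default_rng(seed)
    return LocusConfig(
        seed=seed,
        toxin_spacer=int(rng.integers(15, 22)),
        antitoxin_spacer=int(rng.integers(15, 22)),
        orf_peptide=_random_peptide(rng, int(rng.integers(20, 41))),
        dr_len=int(rng.integers(20, 31)),
    )


def make_homolog_panel(
    k: int, n_groups: int, seed: int = 0
) -> tuple[list[tuple[AnnotatedSequence, tuple[int, int]]], SyntheticTruth]:
    """A panel of k planted loci whose toxin peptides come from n_groups
    distinct peptides (lengths 29, 30, ... cycling), groups as even as
    possible; ranges are 1-based inclusive locus spans."""
    if not (1 <= n_groups <= k):
        raise ValueError("need 1 <= n_groups <= k")
    rng = np.random.default_rng(seed)
    group_peptides = [
        _random_peptide(rng, 29 + (g % 6)) for g in range(n_groups)
    ]
    panel = []
    assignment = []
    for i in range(k):
        g = i % n_groups
        assignment.append(g + 1)
        cfg = LocusConfig(
            seed=int(rng.integers(0, 2**31 - 1)), orf_peptide=group_peptides[g]
        )
        seq, truth = make_ta_locus(cfg)
        seq = replace_id(seq, f"plasmid{i + 1:02d}")
        span = truth.feature(FeatureKind.promoter, element="minus35", unit="toxin").start
        end = truth.feature(FeatureKind.promoter, element="minus35", unit="antitoxin").end
        panel.append((seq, (span + 1, end)))
    truth = SyntheticTruth(
        seed=seed,
        panel={"groups": assignment, "peptides": group_peptides},
    )
    return panel, truth


def replace_id(seq: AnnotatedSequence, new_id: str) -> AnnotatedSequence:
    return AnnotatedSequence(
        id=new_id, residues=seq.residues, topology=seq.topology, features=seq.features
    )
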