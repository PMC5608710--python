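"""Sequence data model, coordinate conventions and I/O.

All internal coordinates are 0-based, half-open intervals on the top strand.
External formats (GFF3, GenBank-style 1-based inclusive ranges) are converted
at the I/O boundary and nowhere else.  A descending GenBank-style range
``(a, b)`` with ``a > b`` denotes the minus strand and is normalized on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "Topology",
    "FeatureKind",
    "Feature",
    "AnnotatedSequence",
    "read_fasta",
    "extract_region",
    "revcomp",
    "translate",
    "write_gff3",
    "read_gff3",
]

log = logging.getLogger(__name__)

_VALID = set("ACGTN")
# IUPAC ambiguity codes other than N are degraded to N: scanners treat N as a
# universal mismatch, so an ambiguous call can never create a spurious motif.
_AMBIGUOUS = set("RYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_BACTERIAL_TABLE = CodonTable.unambiguous_dna_by_id[11]


class Topology(str, Enum):
    linear = "linear"
    circular = "circular"


class FeatureKind(str, Enum):
    promoter = "promoter"
    terminator = "terminator"
    orf = "orf"
    rbs = "rbs"
    dr = "dr"
    transcript = "transcript"
    other = "other"


@dataclass(frozen=True)
class Feature:
    """A stranded interval on a sequence, 0-based half-open."""

    kind: FeatureKind
    start: int
    end: int
    strand: str
    score: float = 0.0
    attrs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedSequence:
    """A DNA sequence with identifier, topology and feature annotations."""

    id: str
    residues: str
    topology: Topology = Topology.linear
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues empty")
        normalized = self.residues.upper()
        bad = set(normalized) - _VALID
        if bad:
            degraded = bad & _AMBIGUOUS
            if degraded:
                log.warning(
                    "sequence %s: ambiguity codes %s degraded to N",
                    self.id,
                    "".join(sorted(degraded)),
                )
                normalized = normalized.translate(
                    str.maketrans({c: "N" for c in degraded})
                )
                bad -= degraded
            if bad:
                raise ValueError(
                    f"sequence {self.id!r}: illegal characters {sorted(bad)}"
                )
        self.residues = normalized
        for f in self.features:
            if f.end > len(self) and self.topology is Topology.linear:
                raise ValueError(
                    f"sequence {self.id!r}: feature {f} outside [0, {len(self)})"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def add_feature(self, feature: Feature) -> None:
        if self.topology is Topology.linear and feature.end > len(self):
            raise ValueError(f"feature {feature} outside sequence bounds")
        self.features.append(feature)

    def with_features(self, features: Iterable[Feature]) -> "AnnotatedSequence":
        return replace(self, features=list(features))


def revcomp(s: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N} (case-insensitive)."""
    s = s.upper()
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"illegal characters for revcomp: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[AnnotatedSequence]:
    """Read a (possibly multi-record) FASTA file.

    Whitespace inside sequence lines is ignored and lowercase input is
    normalized to upper; the header token before the first whitespace becomes
    the record id.  Topology defaults to linear.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).replace(" ", "").replace("\t", "")
        try:
            records.append(AnnotatedSequence(id=rec.id, residues=residues))
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no records")
    return records


def write_fasta(seqs: Iterable[AnnotatedSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def extract_region(
    seq: AnnotatedSequence,
    start: int,
    end: int,
    strand: str = "+",
    *,
    genbank_style: bool = False,
) -> str:
    """Extract a strand-correct subsequence.

    Internal convention: ``start``/``end`` are 0-based half-open on the top
    strand; ``strand '-'`` returns the reverse complement of that interval.
    With ``genbank_style=True`` the coordinates are 1-based inclusive and a
    descending pair (a, b) with a > b denotes the reverse complement of
    [b-1, a) — the convention used for minus-strand ranges in GenBank records.
    On circular sequences start > end (internal convention) wraps through the
    origin.
    """
    n = len(seq)
    if genbank_style:
        a, b = start, end
        if a == b:
            raise ValueError("zero-length request")
        if a < b:
            start, end, strand = a - 1, b, "+"
        else:
            start, end, strand = b - 1, a, "-"
    if start == end:
        raise ValueError("zero-length request")
    if start < 0 or end < 0:
        raise ValueError(f"negative coordinate in [{start}, {end})")
    if start > end or end > n:
        if seq.topology is Topology.circular:
            if start >= n or end > n:
                raise ValueError(f"coordinates [{start}, {end}) out of range 0..{n}")
            sub = seq.residues[start:] + seq.residues[:end]
            return revcomp(sub) if strand == "-" else sub
        raise ValueError(
            f"coordinates [{start}, {end}) out of range for linear sequence of length {n}"
        )
    sub = seq.residues[start:end]
    return revcomp(sub) if strand == "-" else sub


def translate(s: str, start_codon_policy: str = "ATG_GTG") -> str:
    """Translate a DNA coding sequence with bacterial start-codon handling.

    The first codon is rendered as M when it is ATG, or GTG under the
    ``ATG_GTG`` policy (alternative initiator, standard in the bacterial
    code).  Internal codons use the standard code; translation stops at and
    excludes the first stop codon.
    """
    if start_codon_policy not in ("ATG_only", "ATG_GTG"):
        raise ValueError(f"unknown start codon policy {start_codon_policy!r}")
    s = s.upper()
    if len(s) == 0:
        raise ValueError("empty coding sequence")
    if len(s) % 3 != 0:
        raise ValueError(f"length {len(s)} not divisible by 3")
    peptide = []
    for i in range(0, len(s), 3):
        codon = s[i : i + 3]
        if "N" in codon:
            raise ValueError(f"ambiguous codon {codon!r} at position {i}")
        if codon in _BACTERIAL_TABLE.stop_codons:
            break
        if i == 0:
            if codon == "ATG" or (codon == "GTG" and start_codon_policy == "ATG_GTG"):
                peptide.append("M")
                continue
        peptide.append(_BACTERIAL_TABLE.forward_table[codon])
    return "".join(peptide)


# -- GFF3 ------------------------------------------------------------------

_GFF_VERSION = "##gff-version 3"


def write_gff3(seq: AnnotatedSequence, path, source: str = "talocus", header: bool = True) -> None:
    """Serialize features as GFF3 (1-based inclusive coordinates).

    ``path`` may be a filesystem path or an open text handle (for writing
    several sequences into one file; pass header=False after the first).
    """
    fh = open(path, "w") if isinstance(path, (str, Path)) else path
    close = isinstance(path, (str, Path))
    try:
        if header:
            fh.write(_GFF_VERSION + "\n")
        fh.write(f"##sequence-region {seq.id} 1 {len(seq)}\n")
        for f in seq.features:
            attrs = ";".join(f"{k}={v}" for k, v in sorted(f.attrs.items())) or "."
            fh.write(
                "\t".join(
                    [
                        seq.id,
                        source,
                        f.kind.value,
                        str(f.start + 1),
                        str(f.end),
                        f"{f.score:g}",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            fh.close()


def read_gff3(path: str | Path) -> dict[str, list[Feature]]:
    """Parse a GFF3 file back into features keyed by sequence id."""
    out: dict[str, list[Feature]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _source, kind, start, end, score, strand, _phase, attrs = cols
            attr_map = {}
            if attrs != ".":
                for part in attrs.split(";"):
                    if part:
                        k, _, v = part.partition("=")
                        attr_map[k] = v
            out.setdefault(seqid, []).append(
                Feature(
                    kind=FeatureKind(kind),
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    score=float(score) if score != "." else 0.0,
                    attrs=attr_map,
                )
            )
    return out
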