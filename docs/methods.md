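# Methods

This note documents the models behind `talocus`, the defaults and why they
are what they are, what the synthetic generators do and do not emulate, and
the numerical conventions that make every output deterministic.

## Coordinate conventions

All internal coordinates are 0-based, half-open, on the top strand; GFF3
(1-based inclusive) and GenBank-style ranges (1-based inclusive, descending
pair = minus strand) are converted only at the I/O boundary. Motif strings
are always reported 5′→3′ on the hit's own strand. IUPAC ambiguity codes
other than N are degraded to N with a warning; N never matches any motif
position and never pairs.

## Promoter model

A transparent consensus-mismatch scorer rather than a trained model: every
(−35, spacer, −10) arrangement with spacer ∈ [15, 21] is scored

    score = m35 + m10 − λ·|spacer − 17|

where m35/m10 count identities to TTGACA/TATAAT and λ = 0.5/bp. Defaults
`min_m10 = 4`, `min_score = 8` were calibrated so that the near-consensus
promoters characteristic of Fst-family TA loci (e.g. −10 `TATACT` or
`TAAAAT`, both m10 = 5) are called, while the classical inactivating −10
triple mutations (`TATACT→TGTCCC`, `TAAAAT→TGACAC`, both m10 = 2) fall below
threshold — promoter knockout is therefore an exact, discrete event in this
model. Overlapping hits (−10 centres within 10 bp, same strand) are merged
keeping the best (ties: spacer closest to 17, then 5′-most). The +1 is
placed 7 nt downstream of the −10 3′ end; the offset is a config knob
(`promoter.tss_offset`), chosen so the predicted antitoxin transcript on the
reference locus architecture is 74 nt.

No trained position-weight matrix is used; the scorer's virtue is that every
call is auditable by counting matches.

## Terminator model

An intrinsic (rho-independent) terminator is an inverted repeat followed by
a T-tract on the coding strand. The scanner enumerates every loop placement
(loop 3–9 nt) and, per placement, **every** stem length from `min_stem` (5)
up to the maximal outward extension with at most one non-Watson–Crick
position (stems must start and end on a paired base). Enumerating sub-stems
matters: the maximal stem can swallow the T-tract when the upstream flank is
A-rich, and the canonical terminator is then a shorter stem followed
immediately by the T run. The T-tract is the contiguous run of T starting
directly after the hairpin, counted within an 8-nt window; at least 4 are
required. Score = 2·(G·C pairs) + 1·(A·T pairs) + T-tract length; ties
prefer the longer T-tract, then the leftmost hairpin. No nearest-neighbour
free energies are computed — hairpin-level detection, not thermodynamics, is
the goal.

## ORFs, GRAVY and ribosome binding sites

Six-frame exhaustive scan; within each stop-to-stop segment the 5′-most ATG
(or GTG — a documented alternative initiator in this toxin family) defines
the ORF, which must terminate at an in-frame stop. Peptides of 20–40 residues
are retained, and their mean Kyte–Doolittle hydropathy (GRAVY) is computed;
candidates require GRAVY ≥ 0.8, a permissive surrogate for "Fst-like
hydrophobic" (no published numeric cutoff exists; the reference peptides
score well above 1.5). The Shine–Dalgarno search scores every 6-mer whose 3′
end lies 4–14 nt upstream of the start codon against AGGAGG (best contiguous
identity count, ties toward offset 8, minimum 3).

## RNA structure and the toxin/antitoxin duplex

Single-RNA structure uses Nussinov base-pair maximization (Watson–Crick +
G·U, min loop 3) with a deterministic traceback (pairing preferred over
bifurcation on ties; smallest split first). Hairpins are extracted as
maximal strictly stacked runs with unpaired loops; the **UH** annotation is
the 5′-most hairpin whose stem starts within the first 10 nt, and **SL** the
first distinct hairpin downstream — the architecture in which SL sequesters
the RBS. Base-pair maximization is a deliberate simplification: the testable
claims are hairpin-level, not minimum-free-energy structures, so no
partition function or pairing probabilities are computed.

Intermolecular complementarity uses an exhaustive antiparallel scan
(Watson–Crick only by default — the repeat is DNA-templated): reported
matches are containment-maximal runs that start and end on a paired
position, with at most ⌊0.1·length⌋ mismatches and length ≥ 15. The
direct-repeat annotation keeps the longest match overlapping the toxin
start codon. The mismatch budget is a knob, not a claim: whether natural
repeats are perfect duplexes varies by locus.

## Locus assembly and ranking

Each promoter is paired with its nearest same-strand downstream terminator
(transcript = +1 through the end of the T-tract, 30–400 nt). Convergent
opposite-strand pairs whose 3′ ends overlap or lie within 120 bp are
evaluated: the toxin transcript must contain exactly one qualifying
hydrophobic ORF with an RBS and a start-codon-spanning duplex with the
partner; the partner must be 50–200 nt and ORF-free (an ORF-bearing second
transcript disqualifies the pair rather than being reclassified).
Candidates sharing the same ORF and antitoxin transcript are one locus; the
best-scoring representative is kept. Composite-score weights (1, 0.5, 0.3,
2, 0.5) are a ranking heuristic with no biological meaning, documented as
such; ranking is what is tested, not the score values.

## AFM promoter occupancy

Positions are converted from nm to bp with a per-molecule scale
(contour_nm / template_bp) rather than the nominal 0.34 nm/bp rise, removing
molecule-to-molecule contour variation; the nominal rise is used only to
flag molecules whose contour deviates more than ±25% from B-form. Because
the template ends are indistinguishable, classification tests both a
position and its end reflection against every promoter centre and takes the
smallest distance; a complex is "specific" within ±40 bp of a −10 centre.
Wilson 95% intervals are used for occupancy fractions (robust at small n).

This ±40 bp classification is a *biased* estimator of the generating
mixture: uniformly placed nonspecific complexes fall inside a promoter
window (or its reflection image) at a rate set by the window geometry, and a
small Gaussian tail of specific complexes escapes it.
`expected_classified_fractions` computes the model-implied expectation of
the classified fractions for any generating mixture by numerical
integration with the same classification rule; parameter-recovery tests
check Wilson-interval coverage of these expectations per category. When a
published classified split (e.g. 66/17/17%) is to be emulated, the
generating mixture is obtained by inverting this linear classification
operator, and the split is then re-measured end to end.

The AFM simulator draws a category per molecule, places specific complexes
at Normal(centre, σ) and nonspecific ones uniformly, reflects positions with
probability 0.5, and applies 3% lognormal-like contour noise. σ defaults to
15 bp — no empirical position noise is published for such data; 15 bp is
well below the 222 bp promoter separation, so classification remains
identifiable, and it is exposed in the API. The simulator does not model
tip convolution, polymerase-induced DNA bending or wrapping, or contour
measurement error correlated with position.

## Synthetic locus generator

`make_ta_locus` plants the full architecture left to right: toxin −35 /
spacer / −10 / +1, an engineered 46-nt 5′ UTR (UH hairpin at the 5′ end, a
linker carrying an in-frame stop that isolates the ORF's reading frame, an
SL hairpin whose 3′ stem *is* the SD sequence, an 8-nt SD-to-start offset),
the back-translated toxin ORF, a G/C-stem terminator with T-tract, a
convergence gap, and — on the bottom strand, right to left — the antitoxin
unit, whose template carries a direct DNA copy of the `dr_len` nt around the
toxin start codon so that the two RNAs are antiparallel-complementary
exactly there. Defaults encode the reference architecture: −10 hexamers
TATACT/TAAAAT, spacers 20/17 bp, a 29-residue hydrophobic peptide
(GRAVY ≥ 1.5), a 24-nt repeat with 0 mismatches, and antitoxin geometry
summing to a 74-nt transcript.

Recovery of the planted truth is **deterministic by construction**, not
probabilistic. Guard bases are set at element boundaries (non-complementary
6-nt zones flanking the repeat copy, non-extending bases next to stems and
T-tracts), and after assembly the generator rescans its own sequence with
the default scanners and surgically rewrites single background bases — only
at positions designated as free background — until (i) each planted
promoter and terminator is re-detected at exactly its coordinates, (ii) no
background hairpin pre-empts a planted terminator under nearest-terminator
pairing, (iii) no background transcript could stand in for a knocked-out
planted unit (including antisense transcripts across the toxin start
codon), and (iv) the full finder reports exactly the planted candidate on
the wild type and none on either −10 mutant. Everything is a pure function
of the config and seed; reruns are byte-identical.

What the generator therefore does *not* emulate: real plasmid background
(its background is i.i.d. at 42% GC with chance motifs surgically ablated),
sequence context shared between loci, RNA processing (experimentally mapped
5′ ends of such toxins sit downstream of the predicted +1), or promoter
strength differences beyond hexamer/spacer composition. Passing the
recovery tests shows the pipeline is correct and self-consistent on data
satisfying its model assumptions; it does not measure sensitivity or
specificity on natural sequence, where weak chance promoters and terminators
are real and ranking, not uniqueness, is the relevant behaviour.

## Homolog panel and identity

Needleman–Wunsch global alignment (match 2, mismatch −1, gap −2, linear)
selects, among score-optimal alignments, the one maximizing matches and
then minimizing columns — a lexicographic objective that makes the reported
identity canonical and symmetric in its arguments; remaining traceback ties
prefer diagonal > up > left. Identity is computed over **all** alignment
columns, gap columns counting as non-matches (database percent-identity
columns rarely state their denominator; this one is documented). Default
grouping is exact peptide identity; single-linkage clustering at a given
identity threshold is available for sensitivity analysis. The synthetic
panel plants `n_groups` distinct hydrophobic peptides with lengths cycling
29, 30, … 34 aa across `k` loci, mirroring the observed length range of
this toxin family.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use: 100 randomized planted loci
(spacers 15–21, peptides 20–40 aa, repeats 20–30 nt) for recovery; 50 loci ×
2 mutations for knockouts; 200 replicates of n = 500 molecules (σ = 15 bp)
for AFM coverage plus one n = 20,000 run for the occupancy split; a 13-locus
/ 6-peptide panel for grouping. Exhaustive oracles run at the sizes where
enumeration is exact and fast: all nested structures to length 12, quadratic
duplex enumeration to ~150 nt, all global alignments to 8 residues, 6-frame
ORF brute force at 2 kb. Every random draw flows from an explicit seed
through `numpy.random.default_rng`; every pipeline output embeds the
resolved configuration, and identical seed + config give byte-identical
files.

## Known limitations

* Consensus-mismatch promoter scoring has no notion of extended −10 or UP
  elements and is untrained; thresholds transfer poorly outside AT-rich
  plasmid backgrounds without recalibration.
* Terminator detection ignores thermodynamics; a weak hairpin with a strong
  T-tract and a strong hairpin with a marginal tract can tie.
* Base-pair maximization overpredicts pairing; UH/SL annotations are
  architecture checks, not structure predictions.
* The finder's nearest-terminator rule is greedy; on natural sequence a
  weak intervening hairpin can truncate a transcript, which is why ranking
  (not exact boundaries) is the tested behaviour on anything but planted
  data.
* The AFM model assumes position-independent Gaussian noise and a clean
  two-promoter template; crowded templates or end-bound complexes would need
  an explicit end-artifact class.
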