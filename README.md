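# talocus

Detection and analysis of **type I toxin–antitoxin (TA) loci** on bacterial
plasmids, of the kind exemplified by the Fst/Lpt family in lactobacilli: a
small hydrophobic toxin peptide encoded by one RNA, silenced by a convergently
transcribed antisense non-coding RNA.

`talocus` is aimed at microbiologists and bioinformaticians who want to
screen plasmid sequences for this architecture, validate candidate promoters
against single-molecule AFM data, and compare toxin peptides across plasmid
panels — with a fully synthetic data generator so every stage can be tested
without any wet-lab input or database download.

## What it detects

A type I TA locus is called when a plasmid region contains, on opposite
strands and transcribed toward each other:

* a **toxin mRNA**: a σ70 promoter (−35 `TTGACA` / −10 `TATAAT` consensus
  scoring, spacer 15–21 bp, penalty λ·|spacer−17|), a 5′ UTR folding an
  upstream helix (UH) and a stem-loop (SL) that sequesters the
  Shine–Dalgarno sequence (`AGGAGG`, offset 4–14 nt), a 20–40-codon ORF with
  high Kyte–Doolittle hydropathy (GRAVY), and a rho-independent terminator
  (G/C-rich hairpin + contiguous T-tract);
* an **antitoxin ncRNA**: a short (50–200 nt) ORF-free transcript containing
  a sequence antiparallel-complementary to a **direct repeat (DR)** that
  spans the toxin start codon — the antisense interaction that blocks toxin
  translation.

Secondary structure is annotated by Nussinov base-pair maximization
(deterministic traceback); intermolecular complementarity by an exhaustive
duplex scan with a fractional mismatch budget. Candidates get a composite
score `w₁·(promoter scores) + w₂·(terminator scores) + w₃·|DR|·(1−mismatch
fraction) + w₄·max(GRAVY,0) + w₅·SD score` — a documented ranking heuristic,
not a probability.

Two further analyses round out the toolkit:

* **AFM promoter occupancy** — given per-molecule DNA contour lengths and
  RNA-polymerase positions (nm), positions are converted to bp with a
  per-molecule scale, classified against predicted promoter centres within a
  ±40 bp window (testing both ends of the unlabelled template), and reported
  as occupancy fractions with Wilson 95% intervals and a promoter strength
  ratio.
* **Homolog comparison** — toxin peptides extracted from a panel of locus
  regions, pairwise Needleman–Wunsch identity, and grouping into distinct
  toxin peptide classes.

## Worked example

Generate a synthetic locus with the reference architecture and detect it:

```bash
talocus simulate locus --seed 1 --out sim
talocus find sim/locus.fasta --json report.json --gff locus.gff3
```

The JSON report contains one candidate:

```text
candidates: 1
toxin peptide (29 aa, GRAVY 2.66): MIVVVLMAILTVAFLFIAFGIMALTLASF
toxin RNA: 167 nt  antitoxin RNA: 74 nt
spacers: 20 / 17 bp
direct repeat: 24 nt, 0 mismatches, spans start codon: True
```

i.e. a 29-residue hydrophobic toxin whose start codon is covered by a
24-nt duplex with the 74-nt antitoxin RNA; the toxin and antitoxin promoters
have 20 and 17 bp spacers. Mutating either planted −10 hexamer with the
inactivating triple mutation (`TATACT→TGTCCC`, `TAAAAT→TGACAC`) removes the
corresponding transcript and the candidate with it.

Simulate an AFM promoter-mapping experiment (1065 bp template, promoter −10
centres at 276 and 498 bp from one end) and estimate occupancy:

```bash
talocus simulate afm --seed 2 --n 1000 --out sim
talocus afm --measurements sim/afm.tsv --promoter RNAII:276 --promoter RNAI:498 \
            --template-bp 1065 --ratio RNAII/RNAI --json occ.json
```

```text
RNAII   0.660   [0.630, 0.689]
RNAI    0.206   [0.182, 0.232]
nonspecific     0.134   [0.114, 0.157]
```

66% of complexes sit at the antitoxin (RNAII) promoter and ~21% at the toxin
(RNAI) promoter (strength ratio ≈ 3.2 in this run), with the remainder
nonspecific — the antitoxin promoter recruits polymerase several-fold more
efficiently than the toxin promoter.

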