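# Methods

This note records the models behind each `defensescan` stage, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Coordinates and formats

All internal coordinates are 0-based half-open on the plus strand.
Conversions happen only at I/O boundaries: GFF3 is 1-based inclusive, the
CX cytosine report is 1-based, BED is already half-open. Strands are
strictly `+`/`-`; a `.` strand is a format error wherever strand carries
meaning. Tabular outputs carry `#`-prefixed provenance headers (package
version, config hash, seed); FASTA cannot hold comments, so run-level
provenance is duplicated in `provenance.yaml`.

## RIP detection

**Model.** RIP converts C to T on one strand of duplexed repetitive DNA.
Given a repeat family's aligned copies, the pre-RIP ancestor is
reconstructed per column and each consensus-C/copy-T (or G/A) difference
is one RIP event, with its ancestral dinucleotide context (the C plus its
3′ neighbour, read on the affected strand, from the consensus). Each copy
contributes independently, so a column with three T copies yields three
events. Columns whose 3′ neighbour is a gap, or that fall off the
alignment edge, are skipped.

**Pre-RIP reconstruction.** Columns whose bases are exclusively C/T
reconstruct to C, and exclusively G/A to G, *regardless of counts*: RIP
creates T from C but never the reverse, so any C in a pure C/T column is
ancestral. Majority voting is used for all other columns, with ties broken
toward C/G (the GC-richer ancestor). Plain majority was rejected because a
heavily RIPed column (most copies mutated) would reconstruct to T and
silently erase its events; the asymmetric rule recovers planted sites
exactly at mutation rates up to at least 0.2 per eligible site. The cost
is a known bias in noisy data: a genuine ancestral-T column in which one
copy gained a random C is misread as an ancestral C with many RIP events.
At the ≤ few-percent background divergence typical of young repeat
families this inflates the C:G→T:A spectrum share only marginally, and in
the RIP-dominated regime it biases in the same direction the data already
points. A `highest-gc` reference model (use the most GC-rich copy as the
pre-RIP state) is available as an alternative.

**Alignment.** Families are aligned with a center-star progressive scheme
(first copy as center) over Biopython's global pairwise aligner, scoring
match +1, mismatch −1, gap open −5, gap extend −1. For the ≥ 80 %-identity,
substitution-dominated families admitted to RIP analysis, the aligner
choice does not move called sites; pre-aligned multi-FASTA input bypasses
it. Families enter only if every copy is ≥ 400 bp (ungapped) and the mean
pairwise identity over shared columns is ≥ 0.80.

**Indices.** Product index TpA/ApT, substrate index
(CpA+TpG)/(ApC+GpT), CRI = product − substrate, counted over overlapping
dinucleotides of the window on the given strand. Zero denominators give
NA; no pseudocounts are added, so low-complexity windows cannot fabricate
signal. Window tracks default to 500 bp windows at 100 bp steps tiling
[0, L−window]; an optional truncated tail window is off by default.

**CRI and context preference.** The CRI responds directly to CpA-type RIP
(each CpA→TpA gains a product-numerator dinucleotide and loses a
substrate-numerator one) and we verify strict dose-response under
CpA-dominant simulation. CpG-type RIP — the preference this package's
default scenario plants — instead converts CpG to TpG, feeding the
*substrate* numerator, so CRI is nearly flat in CpG dosage. Genomes with
CpG-preferring RIP are therefore better scanned with the RIP-site and 5mC
density tracks; the CRI track remains most informative for the canonical
CpA-type signature.

**Spectrum.** Every consensus-vs-copy substitution (not only RIP-like) is
classified into the six strand-symmetric classes {CG→TA, CG→AT, CG→GC,
AT→GC, AT→CG, AT→TA}; counting is per mutation event, not per variant
column (a flag could aggregate per column, but per-event matches how the
spectrum figures of RIP surveys are built).

## Methylome

A methylation *site* is a cytosine passing `binary_call`: coverage
≥ `min_cov` (default 4) and methylated fraction ≥ `min_frac` (default
0.5), both inclusive. These thresholds are explicit configuration — site
counting conventions differ between studies, and no attempt is made to
infer one. Contexts (CpG; CHG; CHH with H ∈ {A,C,T}) are always recomputed
from the genome on the call's own strand; calls within 2 bp of the 3′
chromosome end fall back to CHH and are flagged by an N-padded
trinucleotide.

Feature-level methylation is sites per kilobase, strand-agnostic, so the
two strands of a symmetric CpG count as two sites. The CpG-dinucleotide
methylation fraction, by contrast, counts each CpG once in the denominator
and marks it methylated if either strand carries a passing call — the two
statistics answer different questions (how dense is methylation vs how
much of the CpG complement is used) and are deliberately not
interchangeable. Gene/exon/intron additivity (sites in a gene = sum over a
partition into exons and introns) holds exactly and is property-tested.

## Small-RNA loci

Reads on either strand closer than `max_gap` (50 bp) merge into candidate
loci. A candidate survives scanning if it reaches the density floor
(reads/kb over the merged span) *and* holds at least `min_reads` = 10
reads. The support floor is not in the original criteria but is necessary:
two overlapping background reads span ~25 bp and already exceed
60 reads/kb by geometry alone, so a pure density threshold cannot keep
empty regions call-free. Ten reads is far below any genuine locus and
unreachable by Poisson background at ≤ a few reads/kb.

milRNA criteria, checked in the order strand-bias → density → energy →
stem: (1) ≥ 10-fold one-strand dominance (a zero minor strand counts as
infinite ratio and passes); (2) density > 270 reads/kb; (4) the precursor —
locus ± `flank` (80 bp, a choice; the original flank length is not
published) on the dominant strand — folds with MFE ≤ −20 kcal/mol and
MFEI > 0.8; (3) the mature candidate (most abundant 18–25 nt read) lies on
the stem, tolerating unpaired interruptions of ≤ 2 nt.
MFEI = (|MFE|/precursor length × 100)/GC%, the standard index for
separating miRNA-like precursors from other transcripts. disiRNA: strand
ratio ≤ `balance_max` (2.0 — "similar abundance" quantified here as a
config default) and density ≥ 60 reads/kb, skipping loci already called
milRNA. Densities are computed on raw read counts (sum of collapsed copy
numbers); multi-mapped reads contribute 1/hits weight by default
(`fractional`), with `all`/`unique` modes available. Raising any threshold
can only shrink the accepted set (property-tested monotonicity).

**Folding backends.** The default `bundled` folder is a maximum-weight
base-pairing dynamic program (Nussinov recursion, 3-nt minimum loop) with
pair weights on an approximate stacking-energy scale: G:C −3, A:U −2,
G:U −1 kcal/mol. It is deterministic, dependency-free, and exact for its
own objective (verified against exhaustive enumeration on short
sequences). Its energies track thermodynamic MFEs closely on clean
hairpins (within ~25 % on planted precursors) but it ignores loop
penalties and so over-stabilises diffuse pairings; it is intended as a
reproducible screen, with ViennaRNA (`vienna` backend, used when its
python bindings are installed) as the thermodynamic reference.

## TE-silencing integration

A TE is *RIP-affected* with ≥ 1 called RIP site in its interval and
*methylated* with ≥ 1 passing 5mC site (both floors configurable; no
per-TE minimum is standard). Expression requires ≥ 1 overlapping RNA-seq
read surviving two filters: ≤ 2 mismatches and a unique hit. The input is
single-end BED6+2 (mismatch count, hit count); discordant-pair filtering
cannot be expressed in that record and is assumed done upstream by the
aligner. The cross-tab reports counts and percentages of the grand total
per superfamily, rounded half-up to 2 decimals; partition identities
(RIP + Non-RIP = Total, 5mC + Non-5mC = Total, per expression stratum)
hold exactly. Silencing fractions condition on class I
(LINE/LTR/DIRS/PLE) records and return NA when nothing matches.

Defense regions require all four hallmarks per window — GC ≤ gc_max,
CRI ≥ cri_min, RIP sites ≥ rip_min, 5mC sites ≥ mc_min — over
≥ `min_windows` (5) consecutive windows. Default thresholds are derived
from the track itself (mean GC − 1 SD; CRI ≥ 0; 90th percentile of
nonzero event counts): the four hallmarks are qualitative in the
literature and no numeric cutoffs exist to adopt, so the defaults are
declared, self-calibrating choices.

## Synthetic-data generator

The generator is the benchmark substrate: every downstream caller is
scored against its manifest.

* Background sequence is i.i.d. per base at `gc_background` (default
  0.556, a typical high-GC basidiomycete genome). No higher-order
  composition is modelled — sufficient for window statistics, not for
  k-mer-sensitive analyses.
* Repeat families: copies diverge from a family master at per-base rate
  (1 − target_identity)/2, giving ≈ the target pairwise identity;
  `target_identity=1.0` yields the RIP-only regime. RIP then hits each
  eligible cytosine (context CpN, read on the copy's own strand) with
  probability `rip_rate` × normalised context weight (defaults CpG 0.6,
  CpA 0.3, CpC/CpT 0.05 — a CpG-preferring process with CpA second).
  Minus-strand copies are mutated in copy orientation and appear as G→A
  on the plus strand.
* Methylome: within each region class (TE/genic/intergenic; defaults
  0.15/0.005/0.005) the per-site probability is shaped per context as
  s(ctx) = rate × N_region × w(ctx)/n(region, ctx), capped at 1, so the
  regional methylated fraction *and* the context share among methylated
  calls (default 98.7 % CpG) are both met in expectation. Coverage is
  4 + Poisson(6) and methylated sites are fully methylated — every planted
  call is recoverable by the default thresholds by construction, so the
  benchmark tests the summaries, not caller robustness to marginal
  coverage.
* Small RNAs: milRNA loci sit on hairpins written into the genome — exact
  inverted repeats spanning locus ± flank, redrawn until the bundled
  folder scores MFE ≤ −20 and MFEI > 0.8 — with two-thirds of
  dominant-strand reads as one mature 21-mer on the 5′ arm (60:3 strand
  counts by default); disiRNA loci scatter 40:38 reads over 500 bp;
  background reads are Poisson at 0.5 reads/kb. Identical reads collapse
  into one BED record with score = copy count.
* RNA-seq: a configurable fraction (0.33) of TE copies is expressed with
  clean unique reads; every TE also receives one decoy read (3 mismatches
  or multi-hit) so the expression filters are actually exercised.

Everything is driven by `numpy.random.default_rng` seeded from the config;
identical configs give byte-identical outputs (stage streams use child
seeds `[seed, stage]`).

**What passing does not show.** The generator has no sequencing error, no
quality scores, no diploidy, no partial methylation, no indel mutation
within families beyond what alignment testing injects, and background
reads are uniform. Exact-recovery results therefore validate the
bookkeeping and decision rules end to end, not robustness to real-library
noise; the statistical recovery tests (3σ bands on rates, shares and
context preferences) validate the forward models' calibration at the
planted parameter values.

## Problem sizes and tolerances

Tests and the acceptance script run on 60–500 kb genomes, 20-seed
replicate sets, and 1,000-sequence oracle comparisons — sizes chosen so
the full suite completes in well under an hour on one core while leaving
every statistical check ≥ 3σ-powered. Statistical recoveries use 3σ
binomial/multinomial bands; exact checks (recovery of planted sites and
loci, partition identities, byte-reproducibility) use equality.
Percentages meant for human-readable tables round half-up to 2 decimals;
nothing else is rounded.
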