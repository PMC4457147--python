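# defensescan

Fungal genomes defend themselves against transposable elements (TEs) and
other invasive DNA through three interlocking mechanisms: repeat-induced
point mutation (RIP), which peppers duplicated sequence with C→T
transitions during the sexual cycle; cytosine DNA methylation (5mC),
concentrated on the relics RIP leaves behind; and small-RNA silencing by
microRNA-like RNAs (milRNAs) and dicer-independent siRNAs (disiRNAs).
`defensescan` is a toolkit for reading those three signals out of a
genome — aimed at anyone analysing repeat decay, methylomes or small-RNA
libraries in basidiomycete or ascomycete fungi — and for joining them into
a per-TE account of silencing.

## What it computes

**RIP analysis.** Repeat-family copies (≥ 400 bp, ≥ 80 % identity) are
aligned and their pre-RIP ancestor reconstructed column by column; every
consensus-C/copy-T difference (G/A on the other strand) becomes a RIP site
with its ancestral CpN dinucleotide context. The module reports the
six-class strand-symmetric mutation spectrum and its C:G→T:A fraction, the
CpN preference of RIP, and sliding-window (500 bp / 100 bp) tracks of GC
content, RIP-site and 5mC density, and the RIP indices

- product index = f(TpA)/f(ApT),
- substrate index = (f(CpA)+f(TpG))/(f(ApC)+f(GpT)),
- CRI (composite RIP index) = product − substrate,

with zero-denominator windows reported as NA rather than padded.

**Methylome.** Per-cytosine bisulfite calls (CX-report TSV) are classified
into CpG/CHG/CHH contexts recomputed from the genome, thresholded into
binary methylation sites (coverage ≥ 4, methylated fraction ≥ 0.5 by
default), and summarised as genome-wide rates, context compositions,
per-feature sites·kb⁻¹ levels, and the fraction of CpG dinucleotides
methylated on either strand.

**Small RNAs.** Strand-specific 18–30 nt alignments (BED6, score =
collapsed copy number) are merged into loci and classified: milRNA when
reads are ≥ 10-fold one-stranded, denser than 270 reads/kb, and the locus
± 80 bp folds into a hairpin with MFE ≤ −20 kcal/mol, MFEI > 0.8 and the
mature read on the stem; disiRNA when both strands contribute similar
abundance above 60 reads/kb. Folding uses a bundled deterministic
maximum-pairing backend or ViennaRNA. Library utilities cover
unique-sequence collapsing, shared/tissue-specific partitions, TPM and
5′-nucleotide bias.

**Integration.** TEs are flagged expressed from mismatch- and
multihit-filtered RNA-seq reads, marked RIP-affected and methylated from
the upstream calls, cross-tabulated by superfamily
(expressed × {Total, RIP, Non-RIP, 5mC, Non-5mC, RIP&5mC, …}), and
summarised as silencing fractions. Windows that are simultaneously
low-GC, high-CRI, RIP-enriched and 5mC-enriched merge into "defense
regions".

**Synthetic data.** A first-class generator plants every signal with a
ground-truth manifest — RIPed repeat families, a CpG-skewed TE methylome,
hairpin-backed milRNA and balanced disiRNA loci over background reads, and
RNA-seq evidence — so each caller can be scored for exact recovery.

## Worked example

```
$ defensescan run --config configs/golden_200kb.yaml
```

simulates a 2 × 100 kb genome (seed 42) and runs every stage on it. The
summary it prints (abridged):

```
sim_planted_rip_sites            49
rip_sites                        163
mc_context_CpG                   0.9892682926829268
mean_level_TE                    85.35353535353535
mean_level_gene                  2.6666666666666665
loci_milRNA                      2
loci_disiRNA                     2
te_expressed                     5
silencing_fraction_classI_rip_mc 0.3333333333333333
```

Reading it: 49 RIP events were planted and 163 sites called — the surplus
is real C→T/G→A divergence from the families' background substitution
process (copies are planted at 95 %/92 % identity), which the caller
rightly reports; on families where RIP is the only process the two numbers
match exactly. 98.9 % of methylated cytosines sit in CpG context (planted
98.7 %), TE methylation (85 sites/kb) dwarfs genic methylation
(2.7 sites/kb), both planted milRNA and both disiRNA loci are recovered
with zero background calls, and a third of the class I TEs carrying both
RIP and 5mC marks are expressed in this small cohort.

Each stage is also available separately (`defensescan simulate | rip |
methylome | smrna | integrate`); outputs are plain FASTA/GFF3/BED/TSV with
provenance headers.

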