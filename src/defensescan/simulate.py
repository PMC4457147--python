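"""Synthetic genome generator with planted ground truth for every stage.

The generator emulates the data a genome-defense analysis consumes:

* a background genome drawn i.i.d. per base at a configurable GC content;
* repeat families (>= 400 bp units, >= 80% copy identity) whose copies are
  first diverged from a family master at a background substitution rate
  derived from the target identity, then subjected to a forward model of
  RIP: C→T transitions on each copy's own strand, drawn per eligible site
  with probability rip_rate x normalised CpN context weight;
* a methylome concentrated at CpG sites inside TE intervals, emitted as a
  per-cytosine CX report with contexts recomputed from the genome;
* strand-biased hairpin (milRNA) loci — an inverted repeat is written into
  the genome so the precursor genuinely folds — and strand-balanced
  disiRNA loci, over a uniform background of small-RNA reads;
* RNA-seq evidence (BED6+2 with mismatch and hit counts) marking a
  configurable fraction of TE copies as expressed.

Every planted event is recorded in a :class:`GroundTruth` manifest so each
downstream caller can be scored for exact recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import fold as _fold
from .io import (
    BedRecord,
    Feature,
    write_bed6,
    write_cx,
    write_fasta,
    write_gff3,
)
from .rip import RipSite, revcomp

BASES = np.array(list("ACGT"))

_CLASS_OF_SUPERFAMILY = {
    "LINE": "I", "LTR": "I", "DIRS": "I", "PLE": "I",
    "TIR": "II", "helitron": "II", "MITE": "II", "unclassified": "II",
}


class ConfigError(ValueError):
    """A SimConfig field failed validation; the message names the field."""


@dataclass
class FamilySpec:
    family_id: str
    unit_length: int = 600
    n_copies: int = 6
    target_identity: float = 0.95
    strand_mix: float = 0.3          # fraction of copies planted on minus strand
    superfamily: str = "LTR"
    gc: float | None = None          # family GC content; None = background

    @property
    def te_class(self) -> str:
        return _CLASS_OF_SUPERFAMILY.get(self.superfamily, "II")


@dataclass
class LocusSpec:
    locus_id: str
    kind: str                        # "milRNA" or "disiRNA"
    length: int = 100
    chrom: str | None = None         # None -> placed by the generator
    start: int | None = None
    strand: str = "+"                # dominant strand (milRNA)
    reads_dominant: int = 60         # milRNA: dominant-strand reads
    reads_minor: int = 3             # milRNA: opposite-strand reads
    reads_plus: int = 40             # disiRNA per-strand read counts
    reads_minus: int = 38
    read_len_min: int = 18
    read_len_max: int = 30
    mature_length: int = 21


@dataclass
class SimConfig:
    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 100_000
    gc_background: float = 0.556
    families: list[FamilySpec] = field(default_factory=lambda: [
        FamilySpec("fam1", superfamily="LTR"),
        FamilySpec("fam2", unit_length=450, n_copies=5,
                   target_identity=0.92, strand_mix=0.5, superfamily="TIR"),
    ])
    rip_rate: float = 0.1
    rip_context_weights: dict[str, float] = field(default_factory=lambda: {
        "CpA": 0.3, "CpC": 0.05, "CpG": 0.6, "CpT": 0.05,
    })
    meth_rate_te: float = 0.15
    meth_rate_genic: float = 0.005
    meth_rate_intergenic: float = 0.005
    meth_context_weights: dict[str, float] = field(default_factory=lambda: {
        "CpG": 0.987, "CHG": 0.0065, "CHH": 0.0065,
    })
    mean_coverage: float = 10.0
    n_genes: int = 20                # per chromosome
    gene_length: int = 1500
    smrna_loci: list[LocusSpec] = field(default_factory=lambda: [
        LocusSpec("mil1", "milRNA"),
        LocusSpec("mil2", "milRNA", strand="-"),
        LocusSpec("disi1", "disiRNA", length=500),
        LocusSpec("disi2", "disiRNA", length=500),
    ])
    background_read_rate: float = 0.5    # reads per kb
    smrna_flank: int = 80                # hairpin precursor flank
    te_expressed_fraction: float = 0.33
    rnaseq_reads_per_te: int = 5


@dataclass
class TruthLocus:
    locus_id: str
    kind: str
    chrom: str
    start: int
    end: int
    plus_reads: int
    minus_reads: int


@dataclass
class GroundTruth:
    rip_sites: list[RipSite] = field(default_factory=list)
    eligible_context_counts: dict[str, int] = field(default_factory=dict)
    methylation: pd.DataFrame | None = None      # planted methylated calls
    loci: list[TruthLocus] = field(default_factory=list)
    expressed_te_ids: set[str] = field(default_factory=set)


@dataclass
class FamilyCopyPlacement:
    copy_id: str
    family_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str        # copy-orientation sequence currently in the genome


@dataclass
class GenomeBuild:
    sequences: dict[str, str]
    features: list[Feature]
    family_copies: dict[str, list[FamilyCopyPlacement]]
    locus_placements: list[LocusSpec]


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    features: list[Feature]
    family_copies: dict[str, list[FamilyCopyPlacement]]
    cx_report: pd.DataFrame
    smrna_reads: list[BedRecord]
    rnaseq_reads: list[BedRecord]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Validation


def validate_config(cfg: SimConfig) -> None:
    def _frac(name: str, value: float) -> None:
        if not (0.0 <= value <= 1.0):
            raise ConfigError(f"{name} must be in [0, 1], got {value}")

    if cfg.n_chrom < 1:
        raise ConfigError(f"n_chrom must be >= 1, got {cfg.n_chrom}")
    _frac("gc_background", cfg.gc_background)
    _frac("rip_rate", cfg.rip_rate)
    _frac("meth_rate_te", cfg.meth_rate_te)
    _frac("meth_rate_genic", cfg.meth_rate_genic)
    _frac("meth_rate_intergenic", cfg.meth_rate_intergenic)
    _frac("te_expressed_fraction", cfg.te_expressed_fraction)
    for name, weights in (
        ("rip_context_weights", cfg.rip_context_weights),
        ("meth_context_weights", cfg.meth_context_weights),
    ):
        if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
            raise ConfigError(f"{name} must be nonnegative with positive sum")
    largest = 0
    for fam in cfg.families:
        if fam.unit_length < 400:
            raise ConfigError(
                f"families[{fam.family_id}].unit_length must be >= 400"
            )
        if fam.n_copies < 2:
            raise ConfigError(f"families[{fam.family_id}].n_copies must be >= 2")
        if not (0.80 <= fam.target_identity <= 1.0):
            raise ConfigError(
                f"families[{fam.family_id}].target_identity must be in [0.80, 1]"
            )
        _frac(f"families[{fam.family_id}].strand_mix", fam.strand_mix)
        if fam.gc is not None:
            _frac(f"families[{fam.family_id}].gc", fam.gc)
        largest = max(largest, fam.unit_length)
    for spec in cfg.smrna_loci:
        if spec.kind not in ("milRNA", "disiRNA"):
            raise ConfigError(
                f"smrna_loci[{spec.locus_id}].kind must be milRNA or disiRNA"
            )
        largest = max(largest, spec.length + 2 * cfg.smrna_flank)
        if spec.start is not None and spec.start + spec.length > cfg.chrom_length:
            raise ConfigError(
                f"smrna_loci[{spec.locus_id}] extends past chrom_length"
            )
    largest = max(largest, cfg.gene_length)
    if cfg.chrom_length < largest:
        raise ConfigError(
            f"chrom_length {cfg.chrom_length} smaller than largest planted "
            f"feature ({largest} bp)"
        )
    if cfg.background_read_rate < 0:
        raise ConfigError("background_read_rate must be >= 0")


# ---------------------------------------------------------------------------
# Genome construction


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


class _Placer:
    """Samples non-overlapping intervals on each chromosome."""

    def __init__(self, chrom_lengths: dict[str, int], margin: int = 100) -> None:
        self.lengths = chrom_lengths
        self.margin = margin
        self.occupied: dict[str, list[tuple[int, int]]] = {
            c: [] for c in chrom_lengths
        }

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.occupied[chrom].append((start - self.margin, end + self.margin))

    def place(self, rng: np.random.Generator, length: int,
              chrom: str | None = None, pad: int = 0) -> tuple[str, int]:
        chroms = [chrom] if chrom else list(self.lengths)
        for _ in range(2000):
            c = chroms[rng.integers(len(chroms))]
            hi = self.lengths[c] - length - pad
            if hi <= pad:
                continue
            start = int(rng.integers(pad, hi))
            span = (start - pad, start + length + pad)
            if all(
                span[1] <= s or span[0] >= e for s, e in self.occupied[c]
            ):
                self.reserve(c, *span)
                return c, start
        raise ConfigError(
            "chrom_length too small to place all features without overlap"
        )


def _diverge(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base to a different one with the given probability."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _plant_hairpin(rng: np.random.Generator, precursor_len: int,
                   loop_len: int = 20, gc: float = 0.5,
                   mfe_max: float = -20.0, mfei_min: float = 0.8,
                   max_tries: int = 20) -> str:
    """An inverted repeat whose bundled-backend fold clears the thresholds.

    Arms are exact reverse complements (100% complementarity, above the
    80% floor for a planted hairpin); the generator redraws until the
    precursor attains MFE <= mfe_max and MFEI > mfei_min.
    """
    arm_len = (precursor_len - loop_len) // 2
    loop_actual = precursor_len - 2 * arm_len
    folder = _fold.BundledFolder()
    for _ in range(max_tries):
        arm = _random_seq(rng, arm_len, gc)
        loop = _random_seq(rng, loop_actual, gc)
        precursor = arm + loop + revcomp(arm)
        result = folder.fold(precursor)
        gcp = _fold.gc_percent(precursor)
        if result.mfe <= mfe_max and _fold.mfei(result.mfe, len(precursor), gcp) > mfei_min:
            return precursor
    raise RuntimeError("failed to draw a qualifying hairpin precursor")


def generate_genome(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> GenomeBuild:
    """Background genome plus planted (pre-RIP) repeat copies, genes and
    hairpin loci, with GFF3-ready annotations.

    Deterministic for a fixed config: the same seed yields byte-identical
    FASTA and GFF output.
    """
    validate_config(cfg)
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 0])
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    seqs = {
        c: _random_seq(rng, cfg.chrom_length, cfg.gc_background)
        for c in chrom_names
    }
    placer = _Placer({c: cfg.chrom_length for c in chrom_names})
    features: list[Feature] = []

    # hairpin smRNA loci first (they rewrite the largest windows)
    placements: list[LocusSpec] = []
    for spec in cfg.smrna_loci:
        spec = LocusSpec(**asdict(spec))
        if spec.start is None:
            spec.chrom, spec.start = placer.place(
                rng, spec.length, chrom=spec.chrom, pad=cfg.smrna_flank
            )
        else:
            if spec.chrom is None:
                spec.chrom = chrom_names[0]
            placer.reserve(spec.chrom, spec.start - cfg.smrna_flank,
                           spec.start + spec.length + cfg.smrna_flank)
        if spec.kind == "milRNA":
            p_start = spec.start - cfg.smrna_flank
            p_len = spec.length + 2 * cfg.smrna_flank
            if p_start < 0 or p_start + p_len > cfg.chrom_length:
                raise ConfigError(
                    f"smrna_loci[{spec.locus_id}] hairpin window outside genome"
                )
            hairpin = _plant_hairpin(rng, p_len)
            if spec.strand == "-":
                hairpin = revcomp(hairpin)
            s = seqs[spec.chrom]
            seqs[spec.chrom] = s[:p_start] + hairpin + s[p_start + p_len:]
        placements.append(spec)

    # repeat families: one master per family, copies diverged from it
    family_copies: dict[str, list[FamilyCopyPlacement]] = {}
    for fam in cfg.families:
        master = _random_seq(
            rng, fam.unit_length,
            cfg.gc_background if fam.gc is None else fam.gc,
        )
        div_rate = (1.0 - fam.target_identity) / 2.0
        copies: list[FamilyCopyPlacement] = []
        for i in range(fam.n_copies):
            copy_seq = _diverge(rng, master, div_rate)
            strand = "-" if rng.random() < fam.strand_mix else "+"
            chrom, start = placer.place(rng, fam.unit_length)
            end = start + fam.unit_length
            inserted = revcomp(copy_seq) if strand == "-" else copy_seq
            s = seqs[chrom]
            seqs[chrom] = s[:start] + inserted + s[end:]
            copy_id = f"{fam.family_id}_c{i + 1}"
            copies.append(FamilyCopyPlacement(
                copy_id, fam.family_id, chrom, start, end, strand, copy_seq,
            ))
            features.append(Feature(
                chrom=chrom, start=start, end=end, strand=strand,
                type="dispersed_repeat", id=copy_id,
                attributes={
                    "family_id": fam.family_id,
                    "te_class": fam.te_class,
                    "superfamily": fam.superfamily,
                    "feature_class": "TE",
                },
            ))
        family_copies[fam.family_id] = copies

    # genes
    for c in chrom_names:
        for g in range(cfg.n_genes):
            chrom, start = placer.place(rng, cfg.gene_length, chrom=c)
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(Feature(
                chrom=chrom, start=start, end=start + cfg.gene_length,
                strand=strand, type="gene", id=f"{c}_g{g + 1}",
                attributes={"feature_class": "gene"},
            ))

    features.sort(key=lambda f: (f.chrom, f.start))
    return GenomeBuild(
        sequences=seqs, features=features, family_copies=family_copies,
        locus_placements=placements,
    )


# ---------------------------------------------------------------------------
# RIP forward model


def apply_rip(
    copies: Sequence[tuple[str, str]],
    rip_rate: float,
    context_weights: dict[str, float],
    seed: int | np.random.Generator = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, int, str]], dict[str, int]]:
    """Introduce C→T transitions into ungapped copies on their own strand.

    ``copies`` is a list of (copy_id, sequence) in copy orientation.  A
    cytosine with 3' neighbour N is eligible with probability
    ``rip_rate x w(CpN) / sum(w)``.  Returns (mutated copies, planted
    sites as (copy_id, offset, context), eligible-context counts).
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    total_w = sum(context_weights.values())
    if total_w <= 0:
        raise ConfigError("rip_context_weights must have positive sum")
    norm = {k: w / total_w for k, w in context_weights.items()}
    mutated: list[tuple[str, str]] = []
    sites: list[tuple[str, int, str]] = []
    eligible: dict[str, int] = {k: 0 for k in norm}
    for copy_id, seq in copies:
        arr = list(seq)
        for i in range(len(arr) - 1):
            if arr[i] != "C":
                continue
            context = "Cp" + seq[i + 1]
            if context not in norm:
                continue
            eligible[context] += 1
            if rng.random() < rip_rate * norm[context]:
                arr[i] = "T"
                sites.append((copy_id, i, context))
        mutated.append((copy_id, "".join(arr)))
    return mutated, sites, eligible


# ---------------------------------------------------------------------------
# Methylome forward model


def _cytosine_table(seq: str, chrom: str) -> pd.DataFrame:
    """Every cytosine on both strands with its context, vectorised."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    frames = []
    # plus strand: C at i; context from i+1, i+2
    pos = np.nonzero(arr == b"C")[0]
    if len(pos):
        nxt = np.full(len(pos), b"N", dtype="S1")
        nxt2 = np.full(len(pos), b"N", dtype="S1")
        ok1 = pos + 1 < len(arr)
        ok2 = pos + 2 < len(arr)
        nxt[ok1] = arr[pos[ok1] + 1]
        nxt2[ok2] = arr[pos[ok2] + 2]
        ctx = np.where(nxt == b"G", "CpG", np.where(nxt2 == b"G", "CHG", "CHH"))
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "strand": "+", "context": ctx,
        }))
    # minus strand: G at i is a C on the minus strand; 3' neighbours at i-1, i-2
    pos = np.nonzero(arr == b"G")[0]
    if len(pos):
        comp = {b"A": b"T", b"C": b"G", b"G": b"C", b"T": b"A"}
        nxt = np.full(len(pos), b"N", dtype="S1")
        nxt2 = np.full(len(pos), b"N", dtype="S1")
        ok1 = pos - 1 >= 0
        ok2 = pos - 2 >= 0
        raw1 = arr[np.maximum(pos - 1, 0)]
        raw2 = arr[np.maximum(pos - 2, 0)]
        nxt[ok1] = raw1[ok1]
        nxt2[ok2] = raw2[ok2]
        nxt = np.array([comp.get(b, b"N") for b in nxt], dtype="S1")
        nxt2 = np.array([comp.get(b, b"N") for b in nxt2], dtype="S1")
        ctx = np.where(nxt == b"G", "CpG", np.where(nxt2 == b"G", "CHG", "CHH"))
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "strand": "-", "context": ctx,
        }))
    return pd.concat(frames, ignore_index=True)


def _region_codes(length: int, features: Sequence[Feature], chrom: str) -> np.ndarray:
    """0 = intergenic, 1 = genic, 2 = TE (TE wins on overlap)."""
    codes = np.zeros(length, dtype=np.int8)
    for f in features:
        if f.chrom != chrom:
            continue
        if f.attributes.get("feature_class") == "gene" or f.type == "gene":
            codes[f.start:f.end] = np.maximum(codes[f.start:f.end], 1)
    for f in features:
        if f.chrom != chrom:
            continue
        if f.attributes.get("feature_class") == "TE":
            codes[f.start:f.end] = 2
    return codes


def simulate_methylome(
    genome: dict[str, str],
    features: Sequence[Feature],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-cytosine CX report with methylation planted by region and context.

    Within each region class (TE / genic / intergenic) the per-site
    methylation probability is shaped so that, in expectation, the overall
    methylated fraction equals the region's configured rate *and* the
    context shares among methylated calls equal the configured context
    weights: s(ctx) = rate x N_region x w(ctx) / n(region, ctx), capped
    at 1.  Contexts are recomputed from the genome, never assumed.
    """
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 2])
    w = cfg.meth_context_weights
    total_w = sum(w.values())
    wn = {k: v / total_w for k, v in w.items()}
    rates = {0: cfg.meth_rate_intergenic, 1: cfg.meth_rate_genic,
             2: cfg.meth_rate_te}
    tables = []
    for chrom, seq in genome.items():
        tab = _cytosine_table(seq, chrom)
        codes = _region_codes(len(seq), features, chrom)
        tab["region"] = codes[tab["pos"].to_numpy()]
        tables.append(tab)
    calls = pd.concat(tables, ignore_index=True)
    # planted probability per (region, context)
    prob = np.zeros(len(calls))
    for region, rate in rates.items():
        in_region = calls["region"].to_numpy() == region
        n_region = int(in_region.sum())
        if n_region == 0:
            continue
        for ctx, w_ctx in wn.items():
            sel = in_region & (calls["context"].to_numpy() == ctx)
            n_ctx = int(sel.sum())
            if n_ctx == 0:
                continue
            prob[sel] = min(1.0, rate * n_region * w_ctx / n_ctx)
    meth = rng.random(len(calls)) < prob
    coverage = 4 + rng.poisson(max(cfg.mean_coverage - 4, 0), size=len(calls))
    calls["count_methylated"] = np.where(meth, coverage, 0)
    calls["count_unmethylated"] = np.where(meth, 0, coverage)
    calls["planted_methylated"] = meth
    calls["trinucleotide"] = _trinucleotides(genome, calls)
    calls = calls.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
    return calls


def _trinucleotides(genome: dict[str, str], calls: pd.DataFrame) -> np.ndarray:
    out = np.empty(len(calls), dtype=object)
    comp = str.maketrans("ACGT", "TGCA")
    for chrom, grp in calls.groupby("chrom"):
        seq = genome[chrom]
        L = len(seq)
        for idx, pos, strand in zip(grp.index, grp["pos"], grp["strand"]):
            if strand == "+":
                out[idx] = seq[pos:pos + 3].ljust(3, "N")
            else:
                tri = seq[max(pos - 2, 0):pos + 1].translate(comp)[::-1]
                out[idx] = tri.ljust(3, "N")
    return out


# ---------------------------------------------------------------------------
# Small-RNA forward model


def _collapse_reads(
    raw: list[tuple[str, int, int, str]]
) -> list[BedRecord]:
    """Collapse identical (chrom, start, end, strand) reads; score = count."""
    counts: dict[tuple[str, int, int, str], int] = {}
    for key in raw:
        counts[key] = counts.get(key, 0) + 1
    records = [
        BedRecord(chrom=c, start=s, end=e, name="", score=n, strand=st)
        for (c, s, e, st), n in sorted(counts.items())
    ]
    for i, rec in enumerate(records):
        rec.name = f"sr{i + 1}"
    return records


def simulate_smrna(
    genome: dict[str, str],
    locus_specs: Sequence[LocusSpec],
    background_read_rate: float,
    rng: np.random.Generator | int = 0,
) -> tuple[list[BedRecord], list[TruthLocus]]:
    """Strand-specific small-RNA alignments (BED6) with planted loci.

    milRNA loci emit most reads as one mature sequence on the dominant
    strand (placed on the hairpin's 5' arm) plus scattered same-strand
    reads; disiRNA loci emit scattered reads from both strands; background
    reads fall uniformly at ``background_read_rate`` per kb.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    raw: list[tuple[str, int, int, str]] = []
    truth: list[TruthLocus] = []

    def _scatter(spec: LocusSpec, n: int, strand: str) -> None:
        for _ in range(n):
            length = int(rng.integers(spec.read_len_min,
                                      min(spec.read_len_max, spec.length) + 1))
            start = spec.start + int(rng.integers(0, spec.length - length + 1))
            raw.append((spec.chrom, start, start + length, strand))

    for spec in locus_specs:
        if spec.chrom is None or spec.start is None:
            raise ConfigError(
                f"smrna_loci[{spec.locus_id}] has no placement; run "
                "generate_genome first"
            )
        if spec.start + spec.length > len(genome[spec.chrom]):
            raise ConfigError(
                f"smrna_loci[{spec.locus_id}] lies outside the genome"
            )
        if spec.kind == "milRNA":
            minor = "-" if spec.strand == "+" else "+"
            # mature read: fixed position early in the locus (on the 5' arm
            # of the planted hairpin), two thirds of the dominant reads
            n_mature = max((2 * spec.reads_dominant) // 3, 1)
            if spec.strand == "+":
                m_start = spec.start + 5
            else:
                m_start = spec.start + spec.length - 5 - spec.mature_length
            for _ in range(n_mature):
                raw.append((spec.chrom, m_start, m_start + spec.mature_length,
                            spec.strand))
            _scatter(spec, spec.reads_dominant - n_mature, spec.strand)
            _scatter(spec, spec.reads_minor, minor)
            plus = spec.reads_dominant if spec.strand == "+" else spec.reads_minor
            minus = spec.reads_minor if spec.strand == "+" else spec.reads_dominant
        else:
            _scatter(spec, spec.reads_plus, "+")
            _scatter(spec, spec.reads_minus, "-")
            plus, minus = spec.reads_plus, spec.reads_minus
        truth.append(TruthLocus(
            spec.locus_id, spec.kind, spec.chrom, spec.start,
            spec.start + spec.length, plus, minus,
        ))

    for chrom, seq in genome.items():
        n_bg = rng.poisson(background_read_rate * len(seq) / 1000.0)
        for _ in range(n_bg):
            length = int(rng.integers(18, 31))
            start = int(rng.integers(0, len(seq) - length))
            strand = "+" if rng.random() < 0.5 else "-"
            raw.append((chrom, start, start + length, strand))

    return _collapse_reads(raw), truth


# ---------------------------------------------------------------------------
# RNA-seq forward model


def simulate_rnaseq(
    te_features: Sequence[Feature],
    expressed_fraction: float,
    reads_per_te: int,
    rng: np.random.Generator | int = 0,
    read_length: int = 75,
) -> tuple[list[BedRecord], set[str]]:
    """BED6+2 RNA-seq alignments (mismatches, hit count) over expressed TEs.

    A configurable fraction of TE copies is marked expressed and receives
    uniquely-mapping reads with <= 2 mismatches; every TE additionally
    receives one decoy read that fails the filters (3 mismatches or
    multi-hit), exercising the expression caller's filtering rules.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    records: list[BedRecord] = []
    expressed: set[str] = set()
    n = 0
    for te in te_features:
        rl = min(read_length, te.length)
        is_expressed = rng.random() < expressed_fraction
        if is_expressed:
            expressed.add(te.id)
            for _ in range(reads_per_te):
                start = te.start + int(rng.integers(0, te.length - rl + 1))
                n += 1
                records.append(BedRecord(
                    chrom=te.chrom, start=start, end=start + rl,
                    name=f"rna{n}", score=1, strand=te.strand,
                    extra=(str(int(rng.integers(0, 3))), "1"),
                ))
        # decoy read failing criterion 1 or 3
        start = te.start + int(rng.integers(0, te.length - rl + 1))
        n += 1
        if rng.random() < 0.5:
            extra = ("3", "1")          # too many mismatches
        else:
            extra = ("1", "4")          # multi-mapped
        records.append(BedRecord(
            chrom=te.chrom, start=start, end=start + rl,
            name=f"rna{n}", score=1, strand=te.strand, extra=extra,
        ))
    records.sort(key=lambda r: (r.chrom, r.start))
    return records, expressed


# ---------------------------------------------------------------------------
# Orchestration


def simulate(cfg: SimConfig) -> SimResult:
    """Run the full forward model and collect the ground-truth manifest."""
    validate_config(cfg)
    build = generate_genome(cfg, rng=np.random.default_rng([cfg.seed, 0]))
    truth = GroundTruth()
    rip_rng = np.random.default_rng([cfg.seed, 1])
    genome = build.sequences
    eligible_total: dict[str, int] = {}
    for family_id, copies in build.family_copies.items():
        pairs = [(c.copy_id, c.sequence) for c in copies]
        mutated, site_tuples, eligible = apply_rip(
            pairs, cfg.rip_rate, cfg.rip_context_weights, seed=rip_rng
        )
        for k, v in eligible.items():
            eligible_total[k] = eligible_total.get(k, 0) + v
        by_id = {c.copy_id: c for c in copies}
        for copy_id, seq in mutated:
            placement = by_id[copy_id]
            placement.sequence = seq
            inserted = revcomp(seq) if placement.strand == "-" else seq
            s = genome[placement.chrom]
            genome[placement.chrom] = (
                s[:placement.start] + inserted + s[placement.end:]
            )
        for copy_id, offset, context in site_tuples:
            p = by_id[copy_id]
            position = (
                p.start + offset if p.strand == "+" else p.end - 1 - offset
            )
            truth.rip_sites.append(RipSite(
                family_id=family_id, copy_id=copy_id, column=offset,
                chrom=p.chrom, position=position, strand=p.strand,
                ancestral="C", observed="T", context=context,
            ))
    truth.eligible_context_counts = eligible_total

    cx = simulate_methylome(
        genome, build.features, cfg, rng=np.random.default_rng([cfg.seed, 2])
    )
    truth.methylation = cx.loc[
        cx["planted_methylated"], ["chrom", "pos", "strand", "context", "region"]
    ].reset_index(drop=True)

    smrna_reads, loci = simulate_smrna(
        genome, build.locus_placements, cfg.background_read_rate,
        rng=np.random.default_rng([cfg.seed, 3]),
    )
    truth.loci = loci

    te_features = [
        f for f in build.features if f.attributes.get("feature_class") == "TE"
    ]
    rnaseq_reads, expressed = simulate_rnaseq(
        te_features, cfg.te_expressed_fraction, cfg.rnaseq_reads_per_te,
        rng=np.random.default_rng([cfg.seed, 4]),
    )
    truth.expressed_te_ids = expressed

    return SimResult(
        config=cfg, genome=genome, features=build.features,
        family_copies=build.family_copies, cx_report=cx,
        smrna_reads=smrna_reads, rnaseq_reads=rnaseq_reads, truth=truth,
    )


def write_outputs(result: SimResult, outdir: str | Path,
                  header_lines: Sequence[str] = ()) -> dict[str, Path]:
    """Write FASTA, GFF3, CX report, BEDs and the ground-truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "annotations": outdir / "annotations.gff3",
        "cx": outdir / "methylome.cx.tsv",
        "smrna": outdir / "smrna.bed",
        "rnaseq": outdir / "rnaseq.bed",
        "truth_rip": outdir / "truth_rip.tsv",
        "truth_meth": outdir / "truth_methylation.tsv",
        "truth_loci": outdir / "truth_loci.tsv",
        "truth_expressed": outdir / "truth_expressed_tes.tsv",
        "params": outdir / "params.yaml",
    }
    write_fasta(result.genome, paths["genome"])
    write_gff3(result.features, paths["annotations"], header_lines=header_lines)
    write_cx(result.cx_report, paths["cx"], header_lines=header_lines)
    write_bed6(result.smrna_reads, paths["smrna"], header_lines=header_lines)
    write_bed6(result.rnaseq_reads, paths["rnaseq"], header_lines=header_lines)
    rip_df = pd.DataFrame([
        {
            "family_id": s.family_id, "copy_id": s.copy_id,
            "chrom": s.chrom, "position": s.position, "strand": s.strand,
            "context": s.context,
        }
        for s in result.truth.rip_sites
    ])
    rip_df.to_csv(paths["truth_rip"], sep="\t", index=False)
    result.truth.methylation.to_csv(paths["truth_meth"], sep="\t", index=False)
    pd.DataFrame([asdict(t) for t in result.truth.loci]).to_csv(
        paths["truth_loci"], sep="\t", index=False
    )
    pd.DataFrame({"te_id": sorted(result.truth.expressed_te_ids)}).to_csv(
        paths["truth_expressed"], sep="\t", index=False
    )
    with open(paths["params"], "w") as fh:
        yaml.safe_dump(_config_to_dict(result.config), fh, sort_keys=True)
    return paths


def _config_to_dict(cfg: SimConfig) -> dict:
    return asdict(cfg)


def config_from_dict(data: dict) -> SimConfig:
    data = dict(data)
    if "families" in data:
        data["families"] = [
            f if isinstance(f, FamilySpec) else FamilySpec(**f)
            for f in data["families"]
        ]
    if "smrna_loci" in data:
        data["smrna_loci"] = [
            s if isinstance(s, LocusSpec) else LocusSpec(**s)
            for s in data["smrna_loci"]
        ]
    return SimConfig(**data)
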