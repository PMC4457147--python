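"""Small-RNA library summaries and milRNA / disiRNA locus calling.

Strand-specific small-RNA reads (18–30 nt) aligned to the genome are
clustered into loci and classified:

milRNA (microRNA-like RNA) — reads come overwhelmingly from one DNA strand
(>= 10-fold over the other), pile up densely (> 270 reads/kb), and the
locus plus flanking sequence folds into a hairpin whose stem carries the
mature small RNA, with MFE below -20 kcal/mol and MFEI above 0.8.

disiRNA (dicer-independent siRNA) — reads come in similar abundance from
both strands of a locus whose density clears a background floor of
60 reads/kb.

Library-level summaries (unique-sequence collapsing, shared/specific
partitions between tissues, TPM, 5'-terminal nucleotide bias) operate on
raw read sequences before any genome mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .fold import FoldResult, gc_percent, get_folder, mfei
from .io import BedRecord
from .rip import revcomp

DEFAULT_MIN_DENSITY_MIL = 270.0   # reads/kb, milRNA enrichment threshold
DEFAULT_MIN_DENSITY_DISI = 60.0   # reads/kb, disiRNA background floor
DEFAULT_STRAND_FOLD = 10.0        # milRNA one-strand dominance
DEFAULT_BALANCE_MAX = 2.0         # disiRNA "similar abundance" ceiling
DEFAULT_MFE_MAX = -20.0           # kcal/mol
DEFAULT_MFEI_MIN = 0.8
DEFAULT_FLANK = 80                # bp of context on each side of a locus
DEFAULT_MAX_GAP = 50              # bp between reads merged into one locus
DEFAULT_MIN_READS = 10            # noise floor: reads needed to seed a locus
MATURE_MIN, MATURE_MAX = 18, 25   # nt, mature milRNA length range
READ_MIN, READ_MAX = 18, 30       # nt, small-RNA size selection


@dataclass
class UniqueSeqTable:
    counts: dict[str, int]

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())


@dataclass
class HairpinEvaluation:
    precursor: str
    mfe: float
    gc_percent: float
    mfei: float
    structure: str
    mature_start: int | None = None    # mature interval on the precursor
    mature_end: int | None = None
    mature_on_stem: bool = False


@dataclass
class SmallRnaLocus:
    chrom: str
    start: int
    end: int
    plus_reads: float
    minus_reads: float
    classification: str = "none"       # milRNA / disiRNA / none
    hairpin: HairpinEvaluation | None = None
    reads: list[BedRecord] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def total_reads(self) -> float:
        return self.plus_reads + self.minus_reads

    @property
    def density(self) -> float:
        """Reads per kilobase over the merged interval."""
        return self.total_reads / (self.length / 1000.0)

    @property
    def strand_ratio(self) -> float:
        """Dominant/minor strand read ratio; infinite when one strand is empty."""
        lo = min(self.plus_reads, self.minus_reads)
        hi = max(self.plus_reads, self.minus_reads)
        if lo == 0:
            return float("inf")
        return hi / lo

    @property
    def dominant_strand(self) -> str:
        return "+" if self.plus_reads >= self.minus_reads else "-"


# ---------------------------------------------------------------------------
# Library summaries


def collapse_unique(reads: Iterable[str]) -> UniqueSeqTable:
    """Collapse reads to exact-sequence counts (no mismatch tolerance)."""
    counts: dict[str, int] = {}
    for r in reads:
        counts[r] = counts.get(r, 0) + 1
    return UniqueSeqTable(counts)


def _round_half_up(x: float, places: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -places,
                                           rounding=ROUND_HALF_UP))


def partition_libraries(table_a: UniqueSeqTable, table_b: UniqueSeqTable) -> dict:
    """Shared / a-specific / b-specific unique-sequence partition.

    Percentages are relative to the union of unique sequences, rounded
    half-up to 2 decimals.
    """
    a, b = set(table_a.counts), set(table_b.counts)
    shared = a & b
    total = len(a | b)
    out = {
        "shared": len(shared),
        "a_specific": len(a - shared),
        "b_specific": len(b - shared),
        "total_unique": total,
    }
    for key in ("shared", "a_specific", "b_specific"):
        out[f"{key}_pct"] = (
            _round_half_up(out[key] / total * 100.0) if total else 0.0
        )
    return out


def partition_from_counts(shared: int, a_specific: int, b_specific: int) -> dict:
    """The same partition arithmetic from pre-tabulated per-class counts."""
    total = shared + a_specific + b_specific
    out = {
        "shared": shared,
        "a_specific": a_specific,
        "b_specific": b_specific,
        "total_unique": total,
    }
    for key in ("shared", "a_specific", "b_specific"):
        out[f"{key}_pct"] = (
            _round_half_up(out[key] / total * 100.0) if total else 0.0
        )
    return out


def length_filter(reads: Iterable[str], min_len: int = READ_MIN,
                  max_len: int = READ_MAX) -> list[str]:
    """Keep reads with length in [min_len, max_len] (inclusive bounds)."""
    return [r for r in reads if min_len <= len(r) <= max_len]


def tpm(counts: Sequence[float]) -> list[float]:
    """Reads-per-million normalisation: count_i / total * 1e6."""
    total = float(sum(counts))
    if total <= 0:
        raise ValueError("tpm requires a nonempty library with reads")
    return [c / total * 1e6 for c in counts]


def five_prime_bias(reads: Iterable[str]) -> dict[str, float]:
    """Fraction of reads starting with each nucleotide (T reported as U)."""
    counts: dict[str, int] = {}
    n = 0
    for r in reads:
        if not r:
            continue
        first = r[0].upper().replace("T", "U")
        counts[first] = counts.get(first, 0) + 1
        n += 1
    if n == 0:
        return {}
    return {k: v / n for k, v in sorted(counts.items())}


# ---------------------------------------------------------------------------
# Locus discovery


def _read_weight(record: BedRecord, hits: dict[str, int], multimap: str) -> float:
    if multimap == "all":
        return record.score
    if multimap == "unique":
        return record.score if hits.get(record.name, 1) == 1 else 0.0
    if multimap == "fractional":
        return record.score / hits.get(record.name, 1)
    raise ValueError(f"unknown multimap mode {multimap!r}")


def scan_loci(
    alignments: Sequence[BedRecord],
    min_density: float = DEFAULT_MIN_DENSITY_DISI,
    max_gap: int = DEFAULT_MAX_GAP,
    min_reads: float = DEFAULT_MIN_READS,
    multimap: str = "fractional",
) -> list[SmallRnaLocus]:
    """Merge sorted read alignments into candidate loci.

    Reads on either strand closer than ``max_gap`` bp are merged; a merged
    interval survives if its raw-read density reaches ``min_density``
    reads/kb and it holds at least ``min_reads`` reads (a noise floor: a
    pair of overlapping background reads already exceeds 60 reads/kb by
    length alone).  Scores in BED column 5 are collapsed read counts;
    multi-mapped reads contribute fractional weight by default.
    """
    for prev, cur in zip(alignments, alignments[1:]):
        if (cur.chrom, cur.start) < (prev.chrom, prev.start):
            raise ValueError(
                "alignments must be sorted by (chrom, start); sort the BED "
                "input first"
            )
    hits: dict[str, int] = {}
    for rec in alignments:
        hits[rec.name] = hits.get(rec.name, 0) + 1
    loci: list[SmallRnaLocus] = []
    cluster: list[BedRecord] = []

    def _flush() -> None:
        if not cluster:
            return
        start = min(r.start for r in cluster)
        end = max(r.end for r in cluster)
        plus = sum(
            _read_weight(r, hits, multimap) for r in cluster if r.strand == "+"
        )
        minus = sum(
            _read_weight(r, hits, multimap) for r in cluster if r.strand == "-"
        )
        locus = SmallRnaLocus(
            chrom=cluster[0].chrom, start=start, end=end,
            plus_reads=plus, minus_reads=minus, reads=list(cluster),
        )
        if locus.total_reads >= min_reads and locus.density >= min_density:
            loci.append(locus)

    cluster_end = None
    for rec in alignments:
        if (
            cluster
            and rec.chrom == cluster[0].chrom
            and rec.start <= cluster_end + max_gap
        ):
            cluster.append(rec)
            cluster_end = max(cluster_end, rec.end)
        else:
            _flush()
            cluster = [rec]
            cluster_end = rec.end
    _flush()
    return loci


def _most_abundant_mature(locus: SmallRnaLocus, genome: dict[str, str]) -> tuple[str, int, int] | None:
    """Most abundant 18-25 nt read on the dominant strand: (seq, start, end)."""
    best = None
    for rec in locus.reads:
        if rec.strand != locus.dominant_strand:
            continue
        if not (MATURE_MIN <= rec.end - rec.start <= MATURE_MAX):
            continue
        if best is None or rec.score > best.score:
            best = rec
    if best is None:
        return None
    seq = genome[best.chrom][best.start : best.end]
    if best.strand == "-":
        seq = revcomp(seq)
    return seq, best.start, best.end


def _mature_on_stem(structure: str, start: int, end: int,
                    max_unpaired_run: int = 2) -> bool:
    """Every mature base pairs within the stem, allowing <=2-nt unpaired runs."""
    region = structure[start:end]
    run = 0
    for ch in region:
        if ch == ".":
            run += 1
            if run > max_unpaired_run:
                return False
        else:
            run = 0
    return True


def call_milrna(
    locus: SmallRnaLocus,
    genome: dict[str, str],
    folder=None,
    flank: int = DEFAULT_FLANK,
    strand_fold: float = DEFAULT_STRAND_FOLD,
    min_density: float = DEFAULT_MIN_DENSITY_MIL,
    mfe_max: float = DEFAULT_MFE_MAX,
    mfei_min: float = DEFAULT_MFEI_MIN,
) -> SmallRnaLocus:
    """Classify a candidate locus as milRNA if all four criteria hold.

    Criteria, checked in order: (1) reads at least ``strand_fold``-fold
    biased to one strand; (2) density over ``min_density`` reads/kb;
    (4) precursor (locus +/- flank on the dominant strand) folds with
    MFE <= ``mfe_max`` kcal/mol and MFEI > ``mfei_min``; (3) the mature
    candidate (most abundant 18-25 nt read) lies on the hairpin stem.
    """
    if folder is None:
        folder = get_folder("bundled")
    locus.classification = "none"
    if locus.strand_ratio < strand_fold:                      # criterion 1
        return locus
    if locus.density <= min_density:                          # criterion 2
        return locus
    seq = genome[locus.chrom]
    p_start = max(locus.start - flank, 0)
    p_end = min(locus.end + flank, len(seq))
    precursor = seq[p_start:p_end]
    if locus.dominant_strand == "-":
        precursor = revcomp(precursor)
    result: FoldResult = folder.fold(precursor)
    gc = gc_percent(precursor)
    index = mfei(result.mfe, len(precursor), gc) if gc > 0 else 0.0
    hairpin = HairpinEvaluation(
        precursor=precursor, mfe=result.mfe, gc_percent=gc, mfei=index,
        structure=result.structure,
    )
    locus.hairpin = hairpin
    if not (result.mfe <= mfe_max and index > mfei_min):      # criterion 4
        return locus
    mature = _most_abundant_mature(locus, genome)
    if mature is None:
        return locus
    m_seq, m_start, m_end = mature
    if locus.dominant_strand == "+":
        rel_start, rel_end = m_start - p_start, m_end - p_start
    else:
        rel_start, rel_end = p_end - m_end, p_end - m_start
    hairpin.mature_start, hairpin.mature_end = rel_start, rel_end
    hairpin.mature_on_stem = _mature_on_stem(
        result.structure, rel_start, rel_end
    )
    if not hairpin.mature_on_stem:                            # criterion 3
        return locus
    locus.classification = "milRNA"
    return locus


def call_disirna(
    locus: SmallRnaLocus,
    balance_max: float = DEFAULT_BALANCE_MAX,
    min_density: float = DEFAULT_MIN_DENSITY_DISI,
) -> SmallRnaLocus:
    """Classify a locus as disiRNA: strand-balanced and above the density floor.

    A locus already classified milRNA is left untouched.
    """
    if locus.classification == "milRNA":
        return locus
    if locus.strand_ratio <= balance_max and locus.density >= min_density:
        locus.classification = "disiRNA"
    else:
        locus.classification = "none"
    return locus


def classify_loci(
    alignments: Sequence[BedRecord],
    genome: dict[str, str],
    folder=None,
    **kwargs,
) -> list[SmallRnaLocus]:
    """scan_loci then milRNA and disiRNA calling with the quoted defaults."""
    scan_kwargs = {
        k: kwargs[k] for k in ("max_gap", "min_reads", "multimap") if k in kwargs
    }
    mil_kwargs = {
        k: kwargs[k]
        for k in ("flank", "strand_fold", "mfe_max", "mfei_min") if k in kwargs
    }
    loci = scan_loci(
        alignments,
        min_density=kwargs.get("min_density_disi", DEFAULT_MIN_DENSITY_DISI),
        **scan_kwargs,
    )
    for locus in loci:
        call_milrna(
            locus, genome, folder=folder,
            min_density=kwargs.get("min_density_mil", DEFAULT_MIN_DENSITY_MIL),
            **mil_kwargs,
        )
        call_disirna(
            locus,
            balance_max=kwargs.get("balance_max", DEFAULT_BALANCE_MAX),
            min_density=kwargs.get("min_density_disi", DEFAULT_MIN_DENSITY_DISI),
        )
    return loci
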