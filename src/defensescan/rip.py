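"""Repeat-induced point mutation (RIP) detection and index scans.

RIP is a fungal genome-defense process that introduces C→T transitions into
repetitive DNA during the sexual cycle, with a preference for particular
CpN dinucleotides.  Its footprint in a genome is read out three ways here:

* an alignment-based caller that reconstructs the pre-RIP state of each
  repeat family (majority consensus, ties broken toward the GC-richer
  ancestral base) and emits one :class:`RipSite` per C→T (or G→A, i.e. a
  minus-strand C→T) difference between consensus and copy;
* a mutation spectrum over the six strand-symmetric substitution classes,
  from which the C:G→T:A fraction characteristic of RIP is computed;
* dinucleotide RIP indices in sliding windows: the product index
  TpA/ApT, the substrate index (CpA+TpG)/(ApC+GpT), and their difference,
  the composite RIP index (CRI).  Positive CRI marks RIP-affected sequence.

Families enter the analysis only if their copies are at least 400 bp long
and at least 80% identical on average, the standard inclusion rule for
RIP scans of transposable elements.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

log = logging.getLogger(__name__)

GAP = "-"
_COMP = str.maketrans("ACGT", "TGCA")

MIN_COPY_LENGTH = 400
MIN_FAMILY_IDENTITY = 0.80

CPN_CONTEXTS = ("CpA", "CpC", "CpG", "CpT")

SPECTRUM_CLASSES = ("CG_TA", "CG_AT", "CG_GC", "AT_GC", "AT_CG", "AT_TA")

# (consensus base, observed base) -> strand-symmetric class
_SUBSTITUTION_CLASS = {
    ("C", "T"): "CG_TA", ("G", "A"): "CG_TA",
    ("C", "A"): "CG_AT", ("G", "T"): "CG_AT",
    ("C", "G"): "CG_GC", ("G", "C"): "CG_GC",
    ("A", "G"): "AT_GC", ("T", "C"): "AT_GC",
    ("A", "C"): "AT_CG", ("T", "G"): "AT_CG",
    ("A", "T"): "AT_TA", ("T", "A"): "AT_TA",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class RepeatCopy:
    copy_id: str
    chrom: str
    start: int          # 0-based half-open genome interval
    end: int
    strand: str         # strand the copy was extracted from
    gapped_seq: str     # alignment row, copy's own orientation


@dataclass
class RepeatFamilyAlignment:
    family_id: str
    copies: list[RepeatCopy]
    consensus: str = ""

    @property
    def column_count(self) -> int:
        return len(self.copies[0].gapped_seq) if self.copies else 0

    def mean_pairwise_identity(self) -> float:
        rows = [c.gapped_seq for c in self.copies]
        idents = []
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                a, b = rows[i], rows[j]
                shared = match = 0
                for x, y in zip(a, b):
                    if x == GAP and y == GAP:
                        continue
                    shared += 1
                    if x == y:
                        match += 1
                idents.append(match / shared if shared else 0.0)
        return float(np.mean(idents)) if idents else 1.0

    def passes_inclusion(
        self,
        min_length: int = MIN_COPY_LENGTH,
        min_identity: float = MIN_FAMILY_IDENTITY,
    ) -> bool:
        if any(len(c.gapped_seq.replace(GAP, "")) < min_length for c in self.copies):
            return False
        return self.mean_pairwise_identity() >= min_identity


@dataclass
class RipSite:
    family_id: str
    copy_id: str
    column: int
    chrom: str
    position: int       # plus-strand genome coordinate of the mutated base
    strand: str         # strand carrying the C->T event
    ancestral: str      # always "C" on the affected strand
    observed: str       # always "T" on the affected strand
    context: str        # ancestral dinucleotide, one of CpA/CpC/CpG/CpT


@dataclass
class MutationSpectrum:
    counts: dict[str, int]
    total: int

    @property
    def fractions(self) -> dict[str, float]:
        if self.total == 0:
            return {}
        return {k: v / self.total for k, v in self.counts.items()}

    @property
    def fraction_CG_to_TA(self) -> float | None:
        if self.total == 0:
            return None
        return self.counts["CG_TA"] / self.total


@dataclass
class RipIndices:
    product: float | None       # TpA / ApT
    substrate: float | None     # (CpA + TpG) / (ApC + GpT)

    @property
    def cri(self) -> float | None:
        if self.product is None or self.substrate is None:
            return None
        return self.product - self.substrate


@dataclass
class WindowTrack:
    chrom: str
    start: int
    end: int
    gc_fraction: float
    indices: RipIndices
    rip_site_count: int
    mc_count: int


# ---------------------------------------------------------------------------
# Family alignment


def _pairwise_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def align_family(
    family_id: str,
    copies: Sequence[tuple[str, str, int, int, str, str]],
) -> RepeatFamilyAlignment:
    """Progressively align family copies (center-star, first copy as center).

    ``copies`` holds (copy_id, chrom, start, end, strand, ungapped_seq)
    tuples with the sequence in the copy's own orientation.  Substitution-
    dominated families (the RIP regime) align without gaps; indels relative
    to the center copy are merged into shared columns.
    """
    if len(copies) < 2:
        raise ValueError("a repeat family needs at least 2 copies to align")
    center = copies[0][5]
    aligner = _pairwise_aligner()
    n_ref = len(center)
    # per copy: aligned char (or gap) for each center position, and the
    # query substring inserted before each center position (index 0..n_ref)
    aligned_chars: list[list[str]] = []
    insertions: list[list[str]] = []
    for (_cid, _chrom, _s, _e, _strand, seq) in copies:
        if seq is center or seq == center:
            aligned_chars.append(list(center))
            insertions.append([""] * (n_ref + 1))
            continue
        aln = aligner.align(center, seq)[0]
        chars = [GAP] * n_ref
        ins = [""] * (n_ref + 1)
        ref_pos = 0
        qry_pos = 0
        blocks_ref, blocks_qry = aln.aligned
        for (rs, re), (qs, qe) in zip(blocks_ref, blocks_qry):
            if qs > qry_pos:  # insertion relative to center, before ref rs
                ins[rs] += seq[qry_pos:qs]
            ref_pos, qry_pos = rs, qs
            for k in range(re - rs):
                chars[rs + k] = seq[qs + k]
            ref_pos, qry_pos = re, qe
        if qry_pos < len(seq):
            ins[n_ref] += seq[qry_pos:]
        aligned_chars.append(chars)
        insertions.append(ins)
    # merge: at each center position the widest insertion defines extra columns
    max_ins = [max(len(ins[k]) for ins in insertions) for k in range(n_ref + 1)]
    rows: list[str] = []
    for chars, ins in zip(aligned_chars, insertions):
        parts: list[str] = []
        for k in range(n_ref):
            parts.append(ins[k].ljust(max_ins[k], GAP))
            parts.append(chars[k])
        parts.append(ins[n_ref].ljust(max_ins[n_ref], GAP))
        rows.append("".join(parts))
    out_copies = [
        RepeatCopy(cid, chrom, s, e, strand, row)
        for (cid, chrom, s, e, strand, _), row in zip(copies, rows)
    ]
    return RepeatFamilyAlignment(family_id=family_id, copies=out_copies)


def family_from_prealigned(
    family_id: str,
    copies: Sequence[tuple[str, str, int, int, str, str]],
) -> RepeatFamilyAlignment:
    """Build a family from already-gapped rows, bypassing the aligner."""
    lengths = {len(c[5]) for c in copies}
    if len(lengths) != 1:
        raise ValueError("pre-aligned rows must all have equal gapped length")
    out = [RepeatCopy(cid, chrom, s, e, strand, seq)
           for cid, chrom, s, e, strand, seq in copies]
    return RepeatFamilyAlignment(family_id=family_id, copies=out)


def families_from_annotations(
    genome: dict[str, str],
    repeat_features,
    min_length: int = MIN_COPY_LENGTH,
    min_identity: float = MIN_FAMILY_IDENTITY,
) -> list[RepeatFamilyAlignment]:
    """Extract, orient and align repeat-family copies from genome + GFF.

    Features carrying a ``family_id`` attribute are grouped into families;
    minus-strand copies are reverse-complemented into copy orientation
    before alignment.  Families failing the length/identity inclusion rule
    are dropped (logged).
    """
    groups: dict[str, list] = {}
    for f in repeat_features:
        fam = f.attributes.get("family_id")
        if fam is None:
            continue
        seq = genome[f.chrom][f.start:f.end]
        if f.strand == "-":
            seq = revcomp(seq)
        groups.setdefault(fam, []).append(
            (f.id, f.chrom, f.start, f.end, f.strand, seq)
        )
    families = []
    for fam_id, copies in sorted(groups.items()):
        if len(copies) < 2:
            log.info("family %s has <2 copies; skipped", fam_id)
            continue
        family = align_family(fam_id, copies)
        if not family.passes_inclusion(min_length, min_identity):
            log.info("family %s fails length/identity inclusion; excluded", fam_id)
            continue
        families.append(family)
    return families


# ---------------------------------------------------------------------------
# Consensus and RIP-site calling

_TIE_PRIORITY = {"C": 0, "G": 1, "A": 2, "T": 3}


def build_consensus(gapped_copies: Sequence[str]) -> str:
    """Per-column pre-RIP consensus of an aligned repeat family.

    The consensus models the GC-richer pre-RIP ancestor.  RIP only ever
    converts C to T (G to A on the other strand), so a column whose bases
    are all C/T must have been ancestrally C no matter how many copies
    carry the derived T — majority voting there would erase heavily
    mutated sites.  Columns of mixed other bases take the majority, with
    ties broken toward C/G over T/A for the same reason.  A gap is emitted
    only when gaps hold a strict majority of the column.
    """
    if len(gapped_copies) < 2:
        raise ValueError("consensus requires at least 2 copies")
    length = len(gapped_copies[0])
    if any(len(s) != length for s in gapped_copies):
        raise ValueError("gapped copies must have equal length")
    n = len(gapped_copies)
    out = []
    for col in range(length):
        column = [s[col] for s in gapped_copies]
        n_gap = column.count(GAP)
        if n_gap * 2 > n:
            out.append(GAP)
            continue
        bases = [b for b in column if b != GAP]
        present = set(bases)
        if present <= {"C", "T"} and "C" in present:
            out.append("C")
            continue
        if present <= {"G", "A"} and "G" in present:
            out.append("G")
            continue
        counts: dict[str, int] = {}
        for b in bases:
            counts[b] = counts.get(b, 0) + 1
        best = max(counts, key=lambda b: (counts[b], -_TIE_PRIORITY.get(b, 9)))
        out.append(best)
    return "".join(out)


def highest_gc_copy(family: RepeatFamilyAlignment) -> str:
    """Alternative pre-RIP model: the copy with the highest GC content."""
    def gc(row: str) -> float:
        s = row.replace(GAP, "")
        return (s.count("G") + s.count("C")) / len(s) if s else 0.0
    best = max(family.copies, key=lambda c: gc(c.gapped_seq))
    return best.gapped_seq


def _genome_position(copy: RepeatCopy, ungapped_offset: int) -> int:
    if copy.strand == "+":
        return copy.start + ungapped_offset
    return copy.end - 1 - ungapped_offset


def call_rip_sites(
    family: RepeatFamilyAlignment, model: str = "consensus"
) -> list[RipSite]:
    """Emit one RipSite per consensus-C/copy-T column difference.

    Reading the alignment in copy orientation, consensus C with copy T is a
    C→T on the copy's strand; consensus G with copy A is the same event on
    the opposite strand (context read from the reverse complement of the
    consensus).  Contexts come from the consensus: the mutated C plus its
    3' neighbour on the affected strand; columns whose neighbour is a gap
    or falls off the alignment are skipped.  Every copy contributes
    independently, so a column with three T copies yields three sites.
    """
    if model == "consensus":
        reference = family.consensus or build_consensus(
            [c.gapped_seq for c in family.copies]
        )
    elif model == "highest-gc":
        reference = highest_gc_copy(family)
    else:
        raise ValueError(f"unknown pre-RIP model {model!r}")
    family.consensus = reference
    ncol = len(reference)
    sites: list[RipSite] = []
    for copy in family.copies:
        row = copy.gapped_seq
        offset = -1  # ungapped offset of the current column within the copy
        for col in range(ncol):
            c_obs = row[col]
            if c_obs != GAP:
                offset += 1
            c_ref = reference[col]
            if c_obs == GAP or c_ref == GAP:
                continue
            if c_ref == "C" and c_obs == "T":
                if col + 1 >= ncol or reference[col + 1] == GAP:
                    continue
                context = "Cp" + reference[col + 1]
                if context not in CPN_CONTEXTS:
                    continue
                affected = copy.strand
            elif c_ref == "G" and c_obs == "A":
                if col == 0 or reference[col - 1] == GAP:
                    continue
                neighbour = reference[col - 1].translate(_COMP)
                context = "Cp" + neighbour
                if context not in CPN_CONTEXTS:
                    continue
                affected = "-" if copy.strand == "+" else "+"
            else:
                continue
            sites.append(
                RipSite(
                    family_id=family.family_id,
                    copy_id=copy.copy_id,
                    column=col,
                    chrom=copy.chrom,
                    position=_genome_position(copy, offset),
                    strand=affected,
                    ancestral="C",
                    observed="T",
                    context=context,
                )
            )
    return sites


def mutation_spectrum(families: Iterable[RepeatFamilyAlignment]) -> MutationSpectrum:
    """Classify every consensus-vs-copy substitution (not only RIP-like).

    Counts are per mutation event: each copy differing from the consensus
    at a column contributes one event.
    """
    counts = {k: 0 for k in SPECTRUM_CLASSES}
    for family in families:
        reference = family.consensus or build_consensus(
            [c.gapped_seq for c in family.copies]
        )
        family.consensus = reference
        for copy in family.copies:
            for c_ref, c_obs in zip(reference, copy.gapped_seq):
                if c_ref == GAP or c_obs == GAP or c_ref == c_obs:
                    continue
                cls = _SUBSTITUTION_CLASS.get((c_ref, c_obs))
                if cls is not None:
                    counts[cls] += 1
    return MutationSpectrum(counts=counts, total=sum(counts.values()))


def dinucleotide_preference(sites: Iterable[RipSite]) -> dict[str, float]:
    """Frequency of each ancestral CpN context among RIP sites."""
    counts: dict[str, int] = {}
    for s in sites:
        counts[s.context] = counts.get(s.context, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {k: v / total for k, v in sorted(counts.items())}


def dinucleotide_counts(sites: Iterable[RipSite]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in sites:
        counts[s.context] = counts.get(s.context, 0) + 1
    return dict(sorted(counts.items()))


# ---------------------------------------------------------------------------
# RIP indices and window tracks


def _dinucleotide_count(seq: str, dinuc: str) -> int:
    count = start = 0
    while True:
        idx = seq.find(dinuc, start)
        if idx == -1:
            return count
        count += 1
        start = idx + 1


def rip_indices(window: str) -> RipIndices:
    """RIP product/substrate indices and CRI for one sequence window.

    Overlapping dinucleotides are counted on the given strand.  An index is
    undefined (None) when its denominator is zero; no pseudocounts are
    applied, so low-complexity windows report NA rather than fabricated
    signal.
    """
    if len(window) < 2:
        raise ValueError("window must be at least 2 bases")
    seq = window.upper()
    tpa = _dinucleotide_count(seq, "TA")
    apt = _dinucleotide_count(seq, "AT")
    cpa = _dinucleotide_count(seq, "CA")
    tpg = _dinucleotide_count(seq, "TG")
    apc = _dinucleotide_count(seq, "AC")
    gpt = _dinucleotide_count(seq, "GT")
    product = tpa / apt if apt > 0 else None
    substrate = (cpa + tpg) / (apc + gpt) if (apc + gpt) > 0 else None
    return RipIndices(product=product, substrate=substrate)


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def windowed_tracks(
    chrom: str,
    sequence: str,
    rip_positions: Sequence[int] = (),
    mc_positions: Sequence[int] = (),
    window: int = 500,
    step: int = 100,
    include_tail: bool = False,
) -> list[WindowTrack]:
    """GC, RIP indices/CRI, RIP-site and 5mC densities in sliding windows.

    Windows of ``window`` bp advance by ``step`` bp and tile
    ``[0, L - window]``; with ``include_tail`` a final truncated window
    covers the chromosome tail when ``L`` is not a multiple of ``step``.
    """
    if step < 1 or window < step:
        raise ValueError("require window >= step >= 1")
    L = len(sequence)
    if window > L:
        warnings.warn(f"window {window} exceeds sequence length {L}; empty track")
        return []
    rip_sorted = np.sort(np.asarray(rip_positions, dtype=int))
    mc_sorted = np.sort(np.asarray(mc_positions, dtype=int))
    starts = list(range(0, L - window + 1, step))
    bounds = [(s, s + window) for s in starts]
    if include_tail and L % step != 0 and bounds and bounds[-1][1] < L:
        bounds.append((starts[-1] + step, L))
    tracks: list[WindowTrack] = []
    for start, end in bounds:
        sub = sequence[start:end]
        tracks.append(
            WindowTrack(
                chrom=chrom,
                start=start,
                end=end,
                gc_fraction=gc_fraction(sub),
                indices=rip_indices(sub),
                rip_site_count=int(
                    np.searchsorted(rip_sorted, end) - np.searchsorted(rip_sorted, start)
                ),
                mc_count=int(
                    np.searchsorted(mc_sorted, end) - np.searchsorted(mc_sorted, start)
                ),
            )
        )
    return tracks
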