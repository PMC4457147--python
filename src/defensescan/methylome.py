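"""Per-cytosine bisulfite-call handling and methylation summaries.

A methylome arrives as a cytosine report (CX dialect): one row per assayed
cytosine with strand, methylated/unmethylated read counts and sequence
context.  Contexts follow the usual three-way classification on the
cytosine's own strand — CpG when the next base is G, CHG when the base
after next is G, CHH otherwise (H = A, C or T).

A cytosine counts as a methylation *site* when it passes a coverage and
methylated-fraction threshold (``binary_call``); feature-level methylation
is then the number of such sites per kilobase of feature, and genome-level
summaries are fractions of assayed cytosines (or of CpG dinucleotides)
that are methylated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Feature

_COMP = str.maketrans("ACGT", "TGCA")

DEFAULT_MIN_COV = 4
DEFAULT_MIN_FRAC = 0.5


@dataclass
class MethylCall:
    chrom: str
    position: int          # 0-based plus-strand coordinate of the C
    strand: str
    context: str           # CpG / CHG / CHH
    count_methylated: int
    count_unmethylated: int
    is_methylated: bool


@dataclass
class FeatureMethylation:
    feature_id: str
    feature_type: str      # TE / gene / exon / intron
    length: int
    mc_sites: int

    @property
    def level(self) -> float:
        """Methylated cytosines per kilobase of feature."""
        return self.mc_sites / (self.length / 1000.0)


def classify_context(genome: dict[str, str], chrom: str, position: int,
                     strand: str) -> str:
    """Classify the context of the cytosine at ``position`` on ``strand``.

    Positions within 2 bp of the strand's 3' chromosome end that lack the
    bases needed to decide fall back to CHH (flagged via
    :func:`trinucleotide`, which pads with N).
    """
    seq = genome[chrom]
    base = seq[position] if strand == "+" else seq[position].translate(_COMP)
    if base != "C":
        raise ValueError(
            f"{chrom}:{position}({strand}) is {base!r}, not C"
        )
    if strand == "+":
        nxt = seq[position + 1] if position + 1 < len(seq) else None
        nxt2 = seq[position + 2] if position + 2 < len(seq) else None
    else:
        nxt = seq[position - 1].translate(_COMP) if position - 1 >= 0 else None
        nxt2 = seq[position - 2].translate(_COMP) if position - 2 >= 0 else None
    if nxt == "G":
        return "CpG"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


def trinucleotide(genome: dict[str, str], chrom: str, position: int,
                  strand: str) -> str:
    """The C plus its two 3' neighbours on ``strand``; N-padded near ends.

    A trinucleotide containing N marks a context truncated by the
    chromosome end (classified CHH by fallback).
    """
    seq = genome[chrom]
    if strand == "+":
        tri = seq[position : position + 3]
        return tri.ljust(3, "N")
    tri = seq[max(position - 2, 0) : position + 1].translate(_COMP)[::-1]
    return tri.ljust(3, "N")


def binary_call(count_methylated: int, count_unmethylated: int,
                min_cov: int = DEFAULT_MIN_COV,
                min_frac: float = DEFAULT_MIN_FRAC) -> bool:
    """True iff coverage >= min_cov and methylated fraction >= min_frac."""
    cov = count_methylated + count_unmethylated
    if cov < min_cov:
        return False
    return count_methylated / cov >= min_frac


def apply_binary_call(calls: pd.DataFrame,
                      min_cov: int = DEFAULT_MIN_COV,
                      min_frac: float = DEFAULT_MIN_FRAC) -> pd.DataFrame:
    """Vectorised binary_call over a CX DataFrame; adds ``is_methylated``."""
    cov = calls["count_methylated"] + calls["count_unmethylated"]
    frac = np.where(cov > 0, calls["count_methylated"] / cov.replace(0, 1), 0.0)
    out = calls.copy()
    out["is_methylated"] = (cov >= min_cov) & (frac >= min_frac)
    return out


def calls_from_cx(cx: pd.DataFrame,
                  min_cov: int = DEFAULT_MIN_COV,
                  min_frac: float = DEFAULT_MIN_FRAC) -> list[MethylCall]:
    df = apply_binary_call(cx, min_cov=min_cov, min_frac=min_frac)
    return [
        MethylCall(
            chrom=r.chrom, position=int(r.pos), strand=r.strand,
            context=r.context, count_methylated=int(r.count_methylated),
            count_unmethylated=int(r.count_unmethylated),
            is_methylated=bool(r.is_methylated),
        )
        for r in df.itertuples()
    ]


def context_composition(calls: pd.DataFrame) -> dict[str, float]:
    """Fractions of CpG/CHG/CHH among methylated sites (empty if none)."""
    if "is_methylated" not in calls.columns:
        calls = apply_binary_call(calls)
    meth = calls[calls["is_methylated"]]
    if meth.empty:
        return {}
    frac = meth["context"].value_counts(normalize=True)
    return {k: float(frac[k]) for k in sorted(frac.index)}


def genome_methylation_rate(calls: pd.DataFrame) -> float:
    """Fraction of assayed cytosines that are methylated."""
    if "is_methylated" not in calls.columns:
        calls = apply_binary_call(calls)
    if len(calls) == 0:
        return 0.0
    return float(calls["is_methylated"].mean())


def feature_methylation(
    features: list[Feature],
    calls: pd.DataFrame,
    min_cov: int = DEFAULT_MIN_COV,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> list[FeatureMethylation]:
    """Per-feature methylated-site counts and per-kb levels (strand-agnostic).

    Plus- and minus-strand calls at a symmetric CpG count as two sites, as
    per-kb site counting treats each assayed cytosine independently.
    """
    if not features:
        raise ValueError("no features supplied")
    if any(f.length == 0 for f in features):
        bad = next(f for f in features if f.length == 0)
        raise ValueError(f"zero-length feature {bad.id!r}")
    df = apply_binary_call(calls, min_cov=min_cov, min_frac=min_frac)
    meth = df[df["is_methylated"]]
    by_chrom = {
        chrom: np.sort(grp["pos"].to_numpy())
        for chrom, grp in meth.groupby("chrom")
    }
    out = []
    for f in features:
        pos = by_chrom.get(f.chrom, np.empty(0, dtype=int))
        n = int(np.searchsorted(pos, f.end) - np.searchsorted(pos, f.start))
        ftype = f.attributes.get("feature_class", f.type)
        out.append(FeatureMethylation(f.id, ftype, f.length, n))
    return out


def mean_level_by_type(records: list[FeatureMethylation]) -> dict[str, float]:
    """Mean per-kb methylation level per feature type (TE, gene, ...)."""
    levels: dict[str, list[float]] = {}
    for r in records:
        levels.setdefault(r.feature_type, []).append(r.level)
    return {k: float(np.mean(v)) for k, v in sorted(levels.items())}


def cpg_site_methylation_fraction(
    genome: dict[str, str],
    calls: pd.DataFrame,
    regions: list[Feature] | None = None,
    min_cov: int = DEFAULT_MIN_COV,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> float | None:
    """Fraction of CpG dinucleotides carrying methylation on either strand.

    The denominator is every CpG dinucleotide in ``regions`` (whole genome
    when None); the numerator is CpGs whose plus-strand C (at the CpG
    position) or minus-strand C (position + 1) passes the methylation
    call.  Returns None when the regions contain no CpG.
    """
    df = apply_binary_call(calls, min_cov=min_cov, min_frac=min_frac)
    meth = df[df["is_methylated"]]
    meth_keys = set(zip(meth["chrom"], meth["pos"], meth["strand"]))
    total = methylated = 0
    if regions is None:
        regions = [
            Feature(chrom, 0, len(seq), "+", "region", chrom)
            for chrom, seq in genome.items()
        ]
    for region in regions:
        seq = genome[region.chrom]
        start = region.start
        sub = seq[region.start : region.end]
        idx = 0
        while True:
            idx = sub.find("CG", idx)
            if idx == -1:
                break
            pos = start + idx
            total += 1
            if (region.chrom, pos, "+") in meth_keys or (
                region.chrom, pos + 1, "-",
            ) in meth_keys:
                methylated += 1
            idx += 1
    if total == 0:
        return None
    return methylated / total
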