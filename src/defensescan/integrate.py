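"""Integration of RIP, methylation and expression evidence on TEs.

Each transposable-element copy gets three boolean marks — expressed (from
filtered RNA-seq reads), RIP-affected (>= 1 called RIP site inside its
interval) and methylated (>= 1 methylated cytosine inside its interval) —
and the cohort is cross-tabulated by superfamily into an
expressed/non-expressed matrix over the Total / RIP / Non-RIP / 5mC /
Non-5mC / RIP&5mC / NonRIP&non-5mC partitions, with cells as percentages
of the grand total.  Silencing fractions (the share of class I TEs under a
given modification that are not expressed) quantify how strongly the
combined marks associate with TE inactivation.

A genome-scan view is also provided: windows that are simultaneously
low-GC, high-CRI, RIP-enriched and methylation-enriched are merged into
"defense regions", the joint RIP/methylation footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .io import BedRecord, Feature
from .rip import WindowTrack

SUPERFAMILIES = ("LINE", "LTR", "DIRS", "PLE", "TIR", "helitron", "MITE",
                 "unclassified")
_CLASS_I = {"LINE", "LTR", "DIRS", "PLE"}

CROSSTAB_ROWS = (
    ("Total", lambda r: True),
    ("RIP", lambda r: r.rip_affected),
    ("Non-RIP", lambda r: not r.rip_affected),
    ("5mC", lambda r: r.methylated),
    ("Non-5mC", lambda r: not r.methylated),
    ("RIP & 5mC", lambda r: r.rip_affected and r.methylated),
    ("Non-RIP & non-5mC", lambda r: not r.rip_affected and not r.methylated),
)


@dataclass
class TEActivityRecord:
    te_id: str
    superfamily: str
    expressed: bool
    rip_affected: bool
    methylated: bool

    @property
    def te_class(self) -> str:
        return "I" if self.superfamily in _CLASS_I else "II"


@dataclass
class DefenseRegion:
    chrom: str
    start: int
    end: int
    window_count: int
    flags: dict = field(default_factory=lambda: {
        "low_gc": True, "high_cri": True, "rip_enriched": True,
        "mc_enriched": True,
    })


@dataclass
class DefenseThresholds:
    """Window-qualification thresholds for defense-region detection.

    Defaults are derived from the track itself: gc_max is the mean window
    GC minus one SD, cri_min is 0 (positive CRI = RIP-affected), and the
    event-count floors are the 90th percentile of nonzero window counts.
    """

    gc_max: float | None = None
    cri_min: float = 0.0
    rip_min: float | None = None
    mc_min: float | None = None
    min_windows: int = 5

    def resolved(self, tracks: Sequence[WindowTrack]) -> "DefenseThresholds":
        gc = np.array([t.gc_fraction for t in tracks])
        rip = np.array([t.rip_site_count for t in tracks])
        mc = np.array([t.mc_count for t in tracks])
        gc_max = self.gc_max
        if gc_max is None:
            gc_max = float(gc.mean() - gc.std())
        rip_min = self.rip_min
        if rip_min is None:
            nz = rip[rip > 0]
            rip_min = float(np.percentile(nz, 90)) if len(nz) else 1.0
        mc_min = self.mc_min
        if mc_min is None:
            nz = mc[mc > 0]
            mc_min = float(np.percentile(nz, 90)) if len(nz) else 1.0
        return DefenseThresholds(gc_max, self.cri_min, rip_min, mc_min,
                                 self.min_windows)


# ---------------------------------------------------------------------------
# Expression flags


def filter_rnaseq(reads: Sequence[BedRecord], max_mismatches: int = 2,
                  unique_only: bool = True) -> list[BedRecord]:
    """Apply the mismatch and multi-hit read filters (BED6+2 extension).

    Column 7 holds the mismatch count and column 8 the number of hits for
    the read.  Reads with more than ``max_mismatches`` mismatches, or with
    multiple hits when ``unique_only``, are removed.
    """
    kept = []
    for r in reads:
        if len(r.extra) < 2:
            raise ValueError(
                f"read {r.name!r}: BED6+2 requires mismatch and hit-count "
                "columns"
            )
        mismatches, hits = int(r.extra[0]), int(r.extra[1])
        if mismatches > max_mismatches:
            continue
        if unique_only and hits != 1:
            continue
        kept.append(r)
    return kept


def flag_te_expression(
    te_features: Sequence[Feature],
    rnaseq: Sequence[BedRecord],
    max_mismatches: int = 2,
    unique_only: bool = True,
    min_reads: int = 1,
) -> dict[str, bool]:
    """TE id -> expressed flag from filtered overlapping RNA-seq reads."""
    surviving = filter_rnaseq(rnaseq, max_mismatches, unique_only)
    by_chrom: dict[str, list[BedRecord]] = {}
    for r in surviving:
        by_chrom.setdefault(r.chrom, []).append(r)
    flags: dict[str, bool] = {}
    for te in te_features:
        reads = by_chrom.get(te.chrom, [])
        n = sum(1 for r in reads if r.start < te.end and r.end > te.start)
        flags[te.id] = n >= min_reads
    return flags


def mark_te_records(
    te_features: Sequence[Feature],
    expressed: dict[str, bool],
    rip_positions: dict[str, np.ndarray],
    mc_positions: dict[str, np.ndarray],
    min_rip_sites: int = 1,
    min_mc_sites: int = 1,
) -> list[TEActivityRecord]:
    """Assemble activity records from per-chromosome sorted event positions."""
    records = []
    for te in te_features:
        rip = rip_positions.get(te.chrom, np.empty(0, dtype=int))
        mc = mc_positions.get(te.chrom, np.empty(0, dtype=int))
        n_rip = int(np.searchsorted(rip, te.end) - np.searchsorted(rip, te.start))
        n_mc = int(np.searchsorted(mc, te.end) - np.searchsorted(mc, te.start))
        records.append(TEActivityRecord(
            te_id=te.id,
            superfamily=te.attributes.get("superfamily", "unclassified"),
            expressed=expressed.get(te.id, False),
            rip_affected=n_rip >= min_rip_sites,
            methylated=n_mc >= min_mc_sites,
        ))
    return records


# ---------------------------------------------------------------------------
# Cross-tabulation


def _pct(count: int, total: int) -> float:
    if total == 0:
        return 0.0
    return float(
        Decimal(repr(count / total * 100.0)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def crosstab(records: Sequence[TEActivityRecord]) -> pd.DataFrame:
    """Expression-by-modification matrix over TE superfamilies.

    Rows: each modification partition x expressed (Yes/No).  ``Num`` is
    the record count; superfamily cells are percentages of the grand total
    of records, rounded half-up to 2 decimals.
    """
    total = len(records)
    rows = []
    for label, predicate in CROSSTAB_ROWS:
        for expressed, exp_label in ((True, "Yes"), (False, "No")):
            subset = [
                r for r in records
                if predicate(r) and r.expressed is expressed
            ]
            row: dict = {"TE": label, "Exp": exp_label, "Num": len(subset)}
            for sf in SUPERFAMILIES:
                row[sf] = _pct(
                    sum(1 for r in subset if r.superfamily == sf), total
                )
            rows.append(row)
    return pd.DataFrame(rows)


def silencing_fraction(
    records: Sequence[TEActivityRecord],
    condition: Callable[[TEActivityRecord], bool] | str = "rip&mc",
) -> float | None:
    """Fraction of class I TEs matching ``condition`` that are not expressed.

    ``condition`` may be "rip", "mc", "rip&mc" or a predicate.  Returns
    None when no class I record matches.
    """
    if isinstance(condition, str):
        named: dict[str, Callable[[TEActivityRecord], bool]] = {
            "rip": lambda r: r.rip_affected,
            "mc": lambda r: r.methylated,
            "rip&mc": lambda r: r.rip_affected and r.methylated,
            "any": lambda r: r.rip_affected or r.methylated,
        }
        try:
            condition = named[condition]
        except KeyError:
            raise ValueError(f"unknown condition {condition!r}") from None
    matching = [r for r in records if r.te_class == "I" and condition(r)]
    if not matching:
        return None
    return sum(1 for r in matching if not r.expressed) / len(matching)


# ---------------------------------------------------------------------------
# Defense regions


def detect_defense_regions(
    tracks: Sequence[WindowTrack],
    thresholds: DefenseThresholds | None = None,
) -> list[DefenseRegion]:
    """Merge runs of windows that carry all four defense hallmarks.

    A window qualifies iff it is low-GC (gc <= gc_max), high-CRI
    (cri >= cri_min, undefined CRI never qualifies), RIP-enriched and
    5mC-enriched; at least ``min_windows`` consecutive qualifying windows
    (per chromosome, in track order) merge into one region.
    """
    if not tracks:
        return []
    th = (thresholds or DefenseThresholds()).resolved(tracks)
    regions: list[DefenseRegion] = []
    run: list[WindowTrack] = []

    def _flush() -> None:
        if len(run) >= th.min_windows:
            regions.append(DefenseRegion(
                chrom=run[0].chrom, start=run[0].start, end=run[-1].end,
                window_count=len(run),
            ))

    prev = None
    for t in tracks:
        cri = t.indices.cri
        ok = (
            t.gc_fraction <= th.gc_max
            and cri is not None and cri >= th.cri_min
            and t.rip_site_count >= th.rip_min
            and t.mc_count >= th.mc_min
        )
        contiguous = prev is not None and t.chrom == prev.chrom
        if ok and (not run or contiguous):
            run.append(t)
        else:
            _flush()
            run = [t] if ok else []
        prev = t
    _flush()
    return regions
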