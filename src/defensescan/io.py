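"""Readers and writers for the plain-text formats the pipeline exchanges.

One internal coordinate convention is used everywhere: 0-based half-open
intervals with positions given on the plus strand.  GFF3 (1-based inclusive)
and CX reports (1-based) are converted at this boundary and nowhere else;
BED is already 0-based half-open and passes through unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

VALID_STRANDS = {"+", "-"}

CX_CONTEXTS = {"CpG", "CHG", "CHH"}


class FormatError(ValueError):
    """A file violated the expected dialect."""


@dataclass
class Feature:
    """A genomic feature in internal coordinates (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    type: str
    id: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(
                f"feature {self.id!r}: end {self.end} < start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BedRecord:
    """One BED6(+N) record; coordinates are 0-based half-open as in BED."""

    chrom: str
    start: int
    end: int
    name: str
    score: float
    strand: str
    extra: tuple = ()

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(f"BED record {self.name!r}: end < start")
        if self.strand not in VALID_STRANDS:
            raise FormatError(
                f"BED record {self.name!r}: strand must be '+' or '-', got "
                f"{self.strand!r}"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Sequences are uppercased (with a warning if lowercase was present) and
    validated against the IUPAC DNA alphabet.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq)
        if s != s.upper():
            warnings.warn(f"record {rec.id!r}: lowercase bases uppercased")
            s = s.upper()
        bad = set(s) - IUPAC_DNA
        if bad:
            # locate the first offending character for the error message
            for lineno, ch in _first_bad_char(path, bad):
                raise FormatError(
                    f"{path}: non-IUPAC character {ch!r} at line {lineno}"
                )
        seqs[rec.id] = s
    return seqs


def _first_bad_char(path: str | Path, bad: set[str]):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            for ch in line.strip():
                if ch.upper() in bad:
                    yield lineno, ch
                    return


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3


def _parse_gff_attributes(text: str) -> dict:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k] = v
    return attrs


def read_gff3(path: str | Path) -> list[Feature]:
    """Read GFF3 features, converting 1-based inclusive to 0-based half-open."""
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attr = cols
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise FormatError(f"{path}:{lineno}: end < start")
            if strand not in VALID_STRANDS:
                raise FormatError(
                    f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}"
                )
            attrs = _parse_gff_attributes(attr)
            feats.append(
                Feature(
                    chrom=chrom,
                    start=start_i - 1,
                    end=end_i,
                    strand=strand,
                    type=ftype,
                    id=attrs.get("ID", f"{ftype}_{lineno}"),
                    attributes=attrs,
                )
            )
    return feats


def write_gff3(
    features: Iterable[Feature], path: str | Path, source: str = "defensescan",
    header_lines: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header_lines:
            fh.write(f"#{line}\n")
        for f in features:
            attrs = {"ID": f.id, **{k: v for k, v in f.attributes.items() if k != "ID"}}
            attr_text = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        source,
                        f.type,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attr_text,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED


def read_bed6(path: str | Path, extra_cols: int = 0) -> list[BedRecord]:
    """Read BED6 (optionally BED6+N) records; coordinates pass through."""
    records: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6 + extra_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected at least {6 + extra_cols} columns"
                )
            chrom, start, end, name, score, strand = cols[:6]
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise FormatError(f"{path}:{lineno}: end < start")
            if strand not in VALID_STRANDS:
                raise FormatError(
                    f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}"
                )
            records.append(
                BedRecord(
                    chrom=chrom,
                    start=start_i,
                    end=end_i,
                    name=name,
                    score=float(score),
                    strand=strand,
                    extra=tuple(cols[6 : 6 + extra_cols]),
                )
            )
    return records


def write_bed6(
    records: Iterable[BedRecord], path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"#{line}\n")
        for r in records:
            score = int(r.score) if float(r.score).is_integer() else r.score
            cols = [r.chrom, str(r.start), str(r.end), r.name, str(score), r.strand]
            cols.extend(str(x) for x in r.extra)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# CX report (per-cytosine bisulfite calls)

CX_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "count_methylated",
    "count_unmethylated",
    "context",
    "trinucleotide",
]


def read_cx(path: str | Path) -> pd.DataFrame:
    """Read a cytosine-report TSV into a DataFrame with 0-based positions.

    The dialect is seven tab-separated columns: chrom, 1-based position,
    strand, methylated read count, unmethylated read count, context
    (CpG/CHG/CHH) and trinucleotide.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=CX_COLUMNS,
        dtype={"chrom": str, "strand": str, "context": str, "trinucleotide": str},
    )
    if not df["strand"].isin(VALID_STRANDS).all():
        bad = df.loc[~df["strand"].isin(VALID_STRANDS), "strand"].iloc[0]
        raise FormatError(f"{path}: invalid strand {bad!r} in CX report")
    if not df["context"].isin(CX_CONTEXTS).all():
        bad = df.loc[~df["context"].isin(CX_CONTEXTS), "context"].iloc[0]
        raise FormatError(f"{path}: unknown context string {bad!r}")
    df["pos"] = df["pos"].astype(int) - 1  # 1-based -> internal 0-based
    return df


def write_cx(
    df: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """Write a CX report from an internal-coordinate DataFrame (0-based)."""
    out = df[CX_COLUMNS].copy()
    out["pos"] = out["pos"].astype(int) + 1
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"#{line}\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(
    rows: Iterable[tuple[str, int, int, float]], path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"#{line}\n")
        for chrom, start, end, value in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
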