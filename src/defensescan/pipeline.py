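"""End-to-end pipeline: simulate -> rip -> methylome -> smrna -> integrate.

A :class:`RunConfig` round-trips losslessly through YAML and drives every
stage; outputs land under one output directory with a provenance header
(package version, config hash, seed) on every tabular file and a
``provenance.yaml`` for the run.  Reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import integrate as integrate_mod
from . import methylome as methylome_mod
from . import rip as rip_mod
from . import smallrna as smallrna_mod
from . import simulate as simulate_mod
from .fold import get_folder
from .io import (
    BedRecord,
    read_bed6,
    read_cx,
    read_fasta,
    read_gff3,
    write_bed6,
    write_bedgraph,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "defensescan_out"
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)     # SimConfig overrides
    inputs: dict = field(default_factory=dict)       # or explicit input paths
    rip: dict = field(default_factory=lambda: {
        "min_length": 400, "min_identity": 0.80,
        "window": 500, "step": 100, "model": "consensus",
    })
    methylome: dict = field(default_factory=lambda: {
        "min_cov": 4, "min_frac": 0.5,
    })
    smrna: dict = field(default_factory=lambda: {
        "min_density_mil": 270.0, "min_density_disi": 60.0,
        "strand_fold": 10.0, "balance_max": 2.0,
        "mfe_max": -20.0, "mfei_min": 0.8, "flank": 80,
        "max_gap": 50, "min_reads": 10, "fold_backend": "bundled",
    })
    integrate: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        base = cls()
        for key, value in data.items():
            if not hasattr(base, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(base, key), dict) and key != "simulate" \
                    and key != "inputs" and isinstance(value, dict):
                merged = {**getattr(base, key), **value}
                setattr(base, key, merged)
            else:
                setattr(base, key, value)
        return base

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths and logging excluded)."""
        data = asdict(self)
        data.pop("outdir", None)
        data.pop("log_level", None)
        text = yaml.safe_dump(data, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> list[str]:
    return [
        f" defensescan={__version__}",
        f" config_sha256={config.config_hash()}",
        f" seed={config.seed}",
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in dependency order; returns a summary dict.

    Inputs come either from the synthetic generator (``simulate`` section)
    or from explicit file paths (``inputs`` section with genome,
    annotations, cx, smrna, rnaseq keys).  Any stage error aborts the run.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _provenance(config)
    summary: dict[str, object] = {}

    # ----- inputs -------------------------------------------------------
    if config.inputs:
        required = {"genome", "annotations", "cx", "smrna", "rnaseq"}
        missing = [k for k in required if k not in config.inputs]
        if missing:
            raise FileNotFoundError(
                f"inputs section missing keys: {', '.join(sorted(missing))}"
            )
        for key in required:
            if not Path(config.inputs[key]).exists():
                raise FileNotFoundError(
                    f"input path for {key!r} does not exist: "
                    f"{config.inputs[key]}"
                )
        genome = read_fasta(config.inputs["genome"])
        features = read_gff3(config.inputs["annotations"])
        cx = read_cx(config.inputs["cx"])
        smrna_reads = read_bed6(config.inputs["smrna"])
        rnaseq_reads = read_bed6(config.inputs["rnaseq"], extra_cols=2)
    else:
        sim_cfg = simulate_mod.config_from_dict(
            {"seed": config.seed, **config.simulate}
        )
        sim = simulate_mod.simulate(sim_cfg)
        simulate_mod.write_outputs(sim, outdir / "sim", header_lines=header)
        genome = sim.genome
        features = sim.features
        cx = sim.cx_report
        smrna_reads = sim.smrna_reads
        rnaseq_reads = sim.rnaseq_reads
        summary["sim_planted_rip_sites"] = len(sim.truth.rip_sites)
        summary["sim_planted_loci"] = len(sim.truth.loci)

    te_features = [
        f for f in features
        if f.attributes.get("feature_class") == "TE"
        or f.type in ("dispersed_repeat", "transposable_element")
    ]

    # ----- RIP ----------------------------------------------------------
    rip_dir = outdir / "rip"
    rip_dir.mkdir(exist_ok=True)
    rp = config.rip
    families = rip_mod.families_from_annotations(
        genome, te_features,
        min_length=rp.get("min_length", 400),
        min_identity=rp.get("min_identity", 0.80),
    )
    sites: list[rip_mod.RipSite] = []
    for family in families:
        sites.extend(rip_mod.call_rip_sites(family, model=rp.get("model", "consensus")))
    spectrum = rip_mod.mutation_spectrum(families)
    preference = rip_mod.dinucleotide_preference(sites)
    write_bed6(
        [
            BedRecord(s.chrom, s.position, s.position + 1,
                      f"{s.family_id}:{s.copy_id}", 1, s.strand,
                      extra=(s.context,))
            for s in sorted(sites, key=lambda s: (s.chrom, s.position))
        ],
        rip_dir / "rip_sites.bed", header_lines=header,
    )
    pd.DataFrame(
        [{"class": k, "count": v} for k, v in spectrum.counts.items()]
        + [{"class": "total", "count": spectrum.total}]
    ).to_csv(_headered(rip_dir / "spectrum.tsv", header), sep="\t", index=False)
    pd.DataFrame(
        [{"context": k, "fraction": v} for k, v in preference.items()]
    ).to_csv(_headered(rip_dir / "preference.tsv", header), sep="\t", index=False)
    summary["rip_sites"] = len(sites)
    summary["rip_fraction_CG_to_TA"] = spectrum.fraction_CG_to_TA

    # ----- methylome ----------------------------------------------------
    meth_dir = outdir / "methylome"
    meth_dir.mkdir(exist_ok=True)
    mp = config.methylome
    calls = methylome_mod.apply_binary_call(
        cx, min_cov=mp.get("min_cov", 4), min_frac=mp.get("min_frac", 0.5)
    )
    meth_sites = calls[calls["is_methylated"]]
    composition = methylome_mod.context_composition(calls)
    rate = methylome_mod.genome_methylation_rate(calls)
    feature_records = methylome_mod.feature_methylation(
        list(features), calls,
        min_cov=mp.get("min_cov", 4), min_frac=mp.get("min_frac", 0.5),
    )
    mean_levels = methylome_mod.mean_level_by_type(feature_records)
    write_bed6(
        [
            BedRecord(r.chrom, int(r.pos), int(r.pos) + 1, "mC", 1, r.strand)
            for r in meth_sites.itertuples()
        ],
        meth_dir / "methylated_sites.bed", header_lines=header,
    )
    pd.DataFrame(
        [
            {"feature_id": r.feature_id, "feature_type": r.feature_type,
             "length": r.length, "mc_sites": r.mc_sites, "level": r.level}
            for r in feature_records
        ]
    ).to_csv(_headered(meth_dir / "features.tsv", header), sep="\t", index=False)
    pd.DataFrame(
        [{"context": k, "fraction": v} for k, v in composition.items()]
    ).to_csv(_headered(meth_dir / "contexts.tsv", header), sep="\t", index=False)
    summary["methylation_rate"] = rate
    summary["mc_sites"] = int(len(meth_sites))
    for ctx, frac in composition.items():
        summary[f"mc_context_{ctx}"] = frac
    for ftype, level in mean_levels.items():
        summary[f"mean_level_{ftype}"] = level

    # ----- window tracks ------------------------------------------------
    rip_pos = {
        c: np.sort(np.array([s.position for s in sites if s.chrom == c]))
        for c in genome
    }
    mc_pos = {
        c: np.sort(meth_sites.loc[meth_sites["chrom"] == c, "pos"].to_numpy())
        for c in genome
    }
    tracks = []
    for chrom, seq in genome.items():
        tracks.extend(rip_mod.windowed_tracks(
            chrom, seq, rip_pos[chrom], mc_pos[chrom],
            window=rp.get("window", 500), step=rp.get("step", 100),
        ))
    track_df = pd.DataFrame([
        {
            "chrom": t.chrom, "start": t.start, "end": t.end,
            "gc": t.gc_fraction,
            "product_index": t.indices.product,
            "substrate_index": t.indices.substrate,
            "cri": t.indices.cri,
            "rip_sites": t.rip_site_count, "mc_sites": t.mc_count,
        }
        for t in tracks
    ])
    track_df.to_csv(_headered(rip_dir / "windows.tsv", header), sep="\t",
                    index=False, na_rep="NA")
    for metric in ("gc", "cri", "rip_sites", "mc_sites"):
        write_bedgraph(
            (
                (t["chrom"], t["start"], t["end"], t[metric])
                for _, t in track_df.iterrows() if pd.notna(t[metric])
            ),
            rip_dir / f"{metric}.bedgraph", header_lines=header,
        )

    # ----- small RNA ----------------------------------------------------
    sm_dir = outdir / "smrna"
    sm_dir.mkdir(exist_ok=True)
    sp = dict(config.smrna)
    folder = get_folder(sp.pop("fold_backend", "bundled"))
    loci = smallrna_mod.classify_loci(
        sorted(smrna_reads, key=lambda r: (r.chrom, r.start)),
        genome, folder=folder, **sp,
    )
    write_bed6(
        [
            BedRecord(l.chrom, l.start, l.end, l.classification,
                      int(l.total_reads), l.dominant_strand,
                      extra=(f"{l.density:.2f}",
                             "inf" if l.strand_ratio == float("inf")
                             else f"{l.strand_ratio:.2f}"))
            for l in loci
        ],
        sm_dir / "loci.bed", header_lines=header,
    )
    mil = [l for l in loci if l.classification == "milRNA"]
    pd.DataFrame([
        {
            "chrom": l.chrom, "start": l.start, "end": l.end,
            "mfe": l.hairpin.mfe, "gc_percent": l.hairpin.gc_percent,
            "mfei": l.hairpin.mfei,
            "mature_start": l.hairpin.mature_start,
            "mature_end": l.hairpin.mature_end,
        }
        for l in mil if l.hairpin is not None
    ]).to_csv(_headered(sm_dir / "milrna.tsv", header), sep="\t", index=False)
    summary["loci_total"] = len(loci)
    summary["loci_milRNA"] = sum(1 for l in loci if l.classification == "milRNA")
    summary["loci_disiRNA"] = sum(1 for l in loci if l.classification == "disiRNA")

    # ----- integration --------------------------------------------------
    int_dir = outdir / "integrate"
    int_dir.mkdir(exist_ok=True)
    ip = config.integrate
    expressed = integrate_mod.flag_te_expression(
        te_features, rnaseq_reads,
        max_mismatches=ip.get("max_mismatches", 2),
        min_reads=ip.get("min_reads", 1),
    )
    records = integrate_mod.mark_te_records(
        te_features, expressed, rip_pos, mc_pos,
        min_rip_sites=ip.get("min_rip_sites", 1),
        min_mc_sites=ip.get("min_mc_sites", 1),
    )
    table = integrate_mod.crosstab(records)
    table.to_csv(_headered(int_dir / "crosstab.tsv", header), sep="\t",
                 index=False)
    pd.DataFrame([
        {"te_id": r.te_id, "te_class": r.te_class,
         "superfamily": r.superfamily, "expressed": r.expressed,
         "rip_affected": r.rip_affected, "methylated": r.methylated}
        for r in records
    ]).to_csv(_headered(int_dir / "te_status.tsv", header), sep="\t",
              index=False)
    regions = integrate_mod.detect_defense_regions(
        tracks,
        integrate_mod.DefenseThresholds(
            gc_max=ip.get("gc_max"), cri_min=ip.get("cri_min", 0.0),
            rip_min=ip.get("rip_min"), mc_min=ip.get("mc_min"),
            min_windows=ip.get("min_windows", 5),
        ),
    )
    write_bed6(
        [
            BedRecord(r.chrom, r.start, r.end, f"defense_region_{i + 1}",
                      r.window_count, "+")
            for i, r in enumerate(regions)
        ],
        int_dir / "defense_regions.bed", header_lines=header,
    )
    summary["te_records"] = len(records)
    summary["te_expressed"] = sum(1 for r in records if r.expressed)
    frac = integrate_mod.silencing_fraction(records, "rip&mc")
    summary["silencing_fraction_classI_rip_mc"] = frac
    summary["defense_regions"] = len(regions)

    # ----- summary + provenance ----------------------------------------
    with open(outdir / "summary.tsv", "w") as fh:
        for line in header:
            fh.write(f"#{line}\n")
        for key, value in summary.items():
            fh.write(f"{key}\t{_fmt(value)}\n")
    with open(outdir / "provenance.yaml", "w") as fh:
        yaml.safe_dump(
            {"defensescan": __version__, "config_sha256": config.config_hash(),
             "seed": config.seed},
            fh, sort_keys=True,
        )
    return summary


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


class _AppendPath:
    """File-like that appends below an already-written provenance header."""

    def __init__(self, path: Path) -> None:
        self.path = path
        self._fh = open(path, "a")

    def write(self, text: str) -> int:
        return self._fh.write(text)

    def flush(self) -> None:
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()


def _headered(path: Path, header_lines) -> _AppendPath:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"#{line}\n")
    return _AppendPath(path)
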