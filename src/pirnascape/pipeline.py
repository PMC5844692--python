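"""Stage orchestration: simulate -> clusters -> signatures -> chemistry ->
sexlink -> splicing, driven by a YAML config.

Each stage reads its inputs from the output directory (or from paths in
the config), writes its outputs atomically, and records a manifest with
the parameters, input checksums and package version. Stage dependencies
are checked up front so a missing prerequisite fails with the name of
the stage that produces it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import yaml

import pirnascape
from pirnascape import emclust, rio, sexlink, sigstats, simkit, splicesup
from pirnascape.chem3p import oxunox_table, pair_duplexes, trimming_fraction

logger = logging.getLogger("pirnascape")

STAGES = ["simulate", "clusters", "signatures", "chemistry", "sexlink", "splicing"]


@dataclass
class PipelineConfig:
    """Per-stage parameter blocks plus paths and seed."""

    outdir: Path
    seed: int = 0
    reads: Path | None = None
    genome: Path | None = None
    window: int = 5000
    length_min: int = 23
    length_max: int = 35
    em_tolerance: float = 0.001
    em_max_iter: int = 1000
    min_rpkm: float = 10.0
    max_gap_windows: int = 1
    lag_max: int = 30
    pingpong_focal: int = 10
    min_mapq: int = 20
    coverage_floor: float = 0.05
    min_junction_reads: int = 10
    min_entropy: float = 2.0
    oxunox_depletion: float = 5.0
    stage_params: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "outdir" not in raw:
            raise ValueError("config must set 'outdir'")
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["outdir"] = Path(kwargs["outdir"])
        for key in ("reads", "genome"):
            if kwargs.get(key):
                kwargs[key] = Path(kwargs[key])
        return cls(**kwargs)


def _checksum(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _atomic_write(path: Path, writer: Callable[[Path], None]) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        os.unlink(tmp)
        raise


def _write_manifest(outdir: Path, stage: str, params: dict, inputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "version": pirnascape.__version__,
        "parameters": params,
        "inputs": {str(p): _checksum(p) for p in inputs if p.exists()},
    }
    with open(outdir / f"manifest_{stage}.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)


def _require(outdir: Path, filename: str, producer: str) -> Path:
    path = outdir / filename
    if not path.exists():
        raise FileNotFoundError(
            f"{filename} required; run the '{producer}' stage first"
        )
    return path


def _stage_simulate(config: PipelineConfig) -> None:
    out = config.outdir
    sim = simkit.SimConfig(seed=config.seed, window=config.window)
    genome, truth = simkit.simulate_genome(sim)
    reads = simkit.simulate_pirna_reads(genome, truth, sim)
    rio.write_fasta(genome.sequences, out / "genome.fa")
    rio.write_intervals(reads, out / "reads.bed")
    with open(out / "repeats.tsv", "w") as handle:
        handle.write("#contig\tstart\tend\tstrand\tfamily\tdivergence\n")
        for rep in genome.repeats:
            handle.write(
                f"{rep.contig}\t{rep.start}\t{rep.end}\t{rep.strand}\t"
                f"{rep.family}\t{rep.divergence}\n"
            )
    viral_genome, viral_reads, viral_truth = simkit.simulate_viral_reads(sim)
    rio.write_fasta(viral_genome.sequences, out / "viral.fa")
    rio.write_alignments(viral_reads, out / "viral_reads.sam", format="sam")
    duplex_records, _ = simkit.simulate_duplexes(sim)
    rio.write_intervals(duplex_records, out / "duplex_reads.bed")
    male = simkit.simulate_dna_coverage(genome, "male", 40.0, config.seed + 10)
    female = simkit.simulate_dna_coverage(genome, "female", 40.0, config.seed + 11)
    rio.write_intervals(male, out / "coverage_male.bed")
    rio.write_intervals(female, out / "coverage_female.bed")
    junctions = [
        simkit.JunctionPlan("autosome_1", 22_000, 23_000, spliced_fraction=0.2),
        simkit.JunctionPlan("autosome_3", 40_000, 41_000, spliced_fraction=0.8),
    ]
    jx_reads, _ = simkit.simulate_junction_reads(genome, junctions, config.seed + 12)
    rio.write_alignments(jx_reads, out / "rna_reads.sam", format="sam")
    rng_species = np.random.default_rng(config.seed + 13)
    species = [
        (
            "".join(np.array(list("ACGU"))[rng_species.integers(0, 4, 21)]),
            float(rng_species.uniform(20, 200)),
            bool(i % 2),
        )
        for i in range(60)
    ]
    unox, ox, unox_stats, ox_stats, pair_truth = simkit.simulate_library_pair(
        species, depletion=config.oxunox_depletion, seed=config.seed + 14
    )
    for name, table, stats in (
        ("reads_unox.tsv", unox, unox_stats),
        ("reads_ox.tsv", ox, ox_stats),
    ):
        with open(out / name, "w") as handle:
            handle.write(f"#cluster_mapped={stats.cluster_mapped_reads}\n")
            handle.write("#sequence\tcount\n")
            for seq in sorted(table):
                handle.write(f"{seq}\t{table[seq]}\n")
    with open(out / "truth.json", "w") as handle:
        json.dump(
            {
                "clusters": [asdict(c) for c in truth.clusters],
                "sex_labels": truth.sex_labels,
                "methylation": pair_truth.methylation,
                "tails": viral_truth.tails,
                "junctions": [asdict(j) for j in junctions],
            },
            handle,
            indent=2,
            sort_keys=True,
        )


def _stage_clusters(config: PipelineConfig) -> None:
    out = config.outdir
    reads_path = config.reads or _require(out, "reads.bed", "simulate")
    genome_path = config.genome or _require(out, "genome.fa", "simulate")
    records = rio.read_alignments(reads_path, format="bed6")
    genome = rio.GenomeIndex.from_fasta(genome_path)
    grid = emclust.bin_reads(
        records, genome, width=config.window,
        length_range=(config.length_min, config.length_max),
    )
    grid, trace = emclust.em_apportion(
        grid, tolerance_fraction=config.em_tolerance, max_iter=config.em_max_iter
    )
    logger.info(
        "EM converged=%s in %d iterations (final Manhattan distance %.4g)",
        trace.converged, trace.n_iterations,
        trace.distances[-1] if trace.distances else 0.0,
    )
    for i, d in enumerate(trace.distances, start=1):
        logger.debug("EM iteration %d: Manhattan distance %.6g", i, d)
    stats = simkit.library_stats(records)
    clusters = emclust.call_clusters(
        grid, stats, min_rpkm=config.min_rpkm, max_gap_windows=config.max_gap_windows
    )

    def write(tmp: Path) -> None:
        with open(tmp, "w") as handle:
            handle.write(
                "#chrom\tstart\tend\tname\tscore\tstrand\twatson\tcrick\t"
                "rpkm\tstrandedness\n"
            )
            for cl in clusters:
                handle.write(
                    f"{cl.contig}\t{cl.start}\t{cl.end}\t{cl.name}\t0\t.\t"
                    f"{cl.watson_count:.2f}\t{cl.crick_count:.2f}\t"
                    f"{cl.rpkm:.3f}\t{cl.strandedness}\n"
                )

    _atomic_write(out / "clusters.bed", write)
    _write_manifest(
        out, "clusters",
        {"window": config.window, "min_rpkm": config.min_rpkm,
         "tolerance": config.em_tolerance},
        [reads_path, genome_path],
    )


def _read_clusters_bed(path: Path) -> list[emclust.Cluster]:
    clusters = []
    with open(path) as handle:
        for line in handle:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            clusters.append(
                emclust.Cluster(
                    contig=f[0], start=int(f[1]), end=int(f[2]), name=f[3],
                    watson_count=float(f[6]), crick_count=float(f[7]),
                    unique_count=0.0, ppm_unique=0.0, ppm_all=0.0,
                    rpkm=float(f[8]), strandedness=f[9],
                )
            )
    return clusters


def _stage_signatures(config: PipelineConfig) -> None:
    out = config.outdir
    reads_path = config.reads or _require(out, "reads.bed", "simulate")
    records = rio.read_alignments(reads_path, format="bed6")
    spectra = {
        "pingpong": sigstats.ping_pong_z(
            records, (1, config.lag_max), focal=config.pingpong_focal
        ),
        "phasing": sigstats.distance_spectrum(
            records, "dist_3p_5p_same", (1, config.lag_max)
        ),
        "periodicity": sigstats.distance_spectrum(
            records, "dist_5p_5p_same", (1, config.lag_max)
        ),
    }

    def write(tmp: Path) -> None:
        with open(tmp, "w") as handle:
            handle.write("#mode\tlag\tweight\tis_focal\tz\n")
            for label, spec in spectra.items():
                for lag, weight in zip(spec.lags, spec.weights):
                    handle.write(
                        f"{label}\t{lag}\t{weight:.3f}\t"
                        f"{int(lag == spec.focal)}\t{spec.z_focal:.4f}\n"
                    )

    _atomic_write(out / "signatures.tsv", write)
    _write_manifest(out, "signatures", {"lag_max": config.lag_max}, [reads_path])


def _read_species_tsv(path: Path) -> tuple[dict[str, float], float]:
    table: dict[str, float] = {}
    cluster_mapped = 0.0
    with open(path) as handle:
        for line in handle:
            if line.startswith("#cluster_mapped="):
                cluster_mapped = float(line.split("=", 1)[1])
                continue
            if line.startswith("#"):
                continue
            seq, count = line.split("\t")
            table[seq] = float(count)
    return table, cluster_mapped


def _stage_chemistry(config: PipelineConfig) -> None:
    out = config.outdir
    unox_path = _require(out, "reads_unox.tsv", "simulate")
    ox_path = _require(out, "reads_ox.tsv", "simulate")
    unox, unox_cm = _read_species_tsv(unox_path)
    ox, ox_cm = _read_species_tsv(ox_path)
    depth = sum(unox.values()) + unox_cm
    unox_stats = rio.LibraryStats(depth, depth, unox_cm)
    depth_ox = sum(ox.values()) + ox_cm
    ox_stats = rio.LibraryStats(depth_ox, depth_ox, ox_cm)
    table, median = oxunox_table(unox, ox, unox_stats, ox_stats)

    def write_ratios(tmp: Path) -> None:
        with open(tmp, "w") as handle:
            handle.write(f"#median_ratio={median:.4f}\n")
            table.to_csv(handle, sep="\t", index=False)

    _atomic_write(out / "oxunox.tsv", write_ratios)

    viral_path = _require(out, "viral_reads.sam", "simulate")
    viral_records = rio.read_alignments(viral_path, format="sam")
    duplex_path = _require(out, "duplex_reads.bed", "simulate")
    _, duplex_summary = pair_duplexes(rio.read_alignments(duplex_path))
    short_frac, prefix_frac = trimming_fraction(viral_records)

    def write_chem(tmp: Path) -> None:
        with open(tmp, "w") as handle:
            handle.write("#metric\tvalue\n")
            handle.write(f"median_oxunox_ratio\t{median:.4f}\n")
            handle.write(f"trimmed_read_fraction\t{short_frac:.5f}\n")
            handle.write(
                f"trimmed_prefix_fraction\t"
                f"{prefix_frac if prefix_frac is not None else 'NA'}\n"
            )
            for key, val in duplex_summary.items():
                handle.write(f"duplex_{key}\t{val}\n")

    _atomic_write(out / "chemistry.tsv", write_chem)
    _write_manifest(
        out, "chemistry", {"depletion": config.oxunox_depletion},
        [unox_path, ox_path, viral_path],
    )


def _stage_sexlink(config: PipelineConfig) -> None:
    out = config.outdir
    male_path = _require(out, "coverage_male.bed", "simulate")
    female_path = _require(out, "coverage_female.bed", "simulate")
    genome_path = config.genome or _require(out, "genome.fa", "simulate")
    genome = rio.GenomeIndex.from_fasta(genome_path)
    male = sexlink.contig_coverage(
        rio.read_alignments(male_path), genome, min_mapq=config.min_mapq
    )
    female = sexlink.contig_coverage(
        rio.read_alignments(female_path), genome, min_mapq=config.min_mapq
    )
    calls = sexlink.classify_linkage(male, female, floor=config.coverage_floor)

    def write(tmp: Path) -> None:
        with open(tmp, "w") as handle:
            handle.write("#contig\tmale_cov\tfemale_cov\tmf_ratio\tlabel\n")
            for call in calls:
                handle.write(
                    f"{call.contig}\t{call.male_cov:.4f}\t{call.female_cov:.4f}\t"
                    f"{call.mf_ratio:.4f}\t{call.label}\n"
                )

    _atomic_write(out / "linkage.tsv", write)
    _write_manifest(
        out, "sexlink", {"min_mapq": config.min_mapq},
        [male_path, female_path],
    )


def _stage_splicing(config: PipelineConfig) -> None:
    out = config.outdir
    rna_path = _require(out, "rna_reads.sam", "simulate")
    clusters_path = _require(out, "clusters.bed", "clusters")
    records = rio.read_alignments(rna_path, format="sam")
    junctions = splicesup.detect_junctions(
        records, min_reads=config.min_junction_reads, min_entropy=config.min_entropy
    )
    for jx in junctions:
        splicesup.splicing_efficiency(jx, records)
    clusters = _read_clusters_bed(clusters_path)
    summary = splicesup.compare_regions(junctions, clusters)

    def write(tmp: Path) -> None:
        with open(tmp, "w") as handle:
            handle.write(
                "#contig\tdonor\tacceptor\tstrand\tn_spanning\tentropy\t"
                "n_unspliced\tefficiency\tin_cluster\n"
            )
            for jx in junctions:
                eff = f"{jx.efficiency:.4f}" if jx.efficiency is not None else "NA"
                handle.write(
                    f"{jx.contig}\t{jx.donor}\t{jx.acceptor}\t{jx.strand}\t"
                    f"{jx.n_spanning}\t{jx.entropy:.4f}\t{jx.n_unspliced}\t"
                    f"{eff}\t{jx.in_cluster}\n"
                )
            for key, val in summary.items():
                handle.write(f"#{key}={val}\n")

    _atomic_write(out / "junctions.tsv", write)
    _write_manifest(
        out, "splicing",
        {"min_reads": config.min_junction_reads, "min_entropy": config.min_entropy},
        [rna_path, clusters_path],
    )


_STAGE_FUNCS: dict[str, Callable[[PipelineConfig], None]] = {
    "simulate": _stage_simulate,
    "clusters": _stage_clusters,
    "signatures": _stage_signatures,
    "chemistry": _stage_chemistry,
    "sexlink": _stage_sexlink,
    "splicing": _stage_splicing,
}


def run_stage(name: str, config: PipelineConfig) -> None:
    """Run one pipeline stage, writing outputs into ``config.outdir``."""
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; stages are {STAGES}")
    config.outdir.mkdir(parents=True, exist_ok=True)
    logger.info("running stage %s", name)
    try:
        _STAGE_FUNCS[name](config)
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"stage {name!r}: {exc}") from exc


def run_all(config: PipelineConfig, simulate: bool = True) -> None:
    """Run every stage in dependency order."""
    stages = STAGES if simulate else [s for s in STAGES if s != "simulate"]
    for name in stages:
        run_stage(name, config)
    logger.info("pipeline complete; outputs in %s", config.outdir)
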