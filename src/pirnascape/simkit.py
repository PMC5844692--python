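"""Synthetic small-RNA data with planted ground truth.

The generator emulates the statistical structure every downstream stage
assumes, on a desk-scale multi-contig genome:

- autosome / Z / W contigs of random sequence, with transposon copies
  (carrying per-copy divergence) concentrated in planted piRNA clusters
  and an elevated repeat load on the W;
- uni- and dual-strand piRNA clusters emitting 23-35-nt reads with a
  first-nucleotide uridine bias, a configurable fraction of
  opposite-strand ping-pong pairs (5' ends overlapping by 10 nt), and a
  configurable fraction of multimapping species placed at several loci;
- a sparse, low-copy background outside clusters, mirroring the near-zero
  inter-cluster piRNA levels seen in real libraries;
- a two-segment viral replicon emitting phased 20-nt siRNAs with
  configurable phasing fidelity, non-templated 3' tails and 5'-prefix
  trimming;
- siRNA duplexes with two-nucleotide 3' overhangs and planted
  guide:passenger asymmetry;
- oxidized/unoxidized library pairs where unmethylated species are
  depleted by a known factor, with a methylated piRNA pool serving as the
  normalization denominator;
- male (ZZ) and female (ZW) DNA coverage with Poisson noise and MAPQ
  values straddling the mapping-quality filter;
- spliced/unspliced junction reads with planted splicing fractions and
  offset diversity.

All outputs are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from pirnascape.rio import AlignmentRecord, GenomeIndex, LibraryStats, RepeatCopy

__all__ = [
    "PlantedCluster",
    "ViralSegment",
    "JunctionPlan",
    "SimConfig",
    "SimTruth",
    "simulate_genome",
    "simulate_pirna_reads",
    "simulate_viral_reads",
    "simulate_duplexes",
    "simulate_library_pair",
    "simulate_dna_coverage",
    "simulate_junction_reads",
    "library_stats",
]

_NT = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedCluster:
    """A planted piRNA-producing locus."""

    contig: str
    start: int
    end: int
    strandedness: str = "uni"  # uni | dual
    main_strand: str = "+"
    emission_rate: float = 2000.0  # read copies per kb
    species_per_kb: float = 20.0
    transposon_fraction: float = 0.6  # of cluster bases under repeat copies
    antisense_fraction: float = 0.75  # repeat copies opposite the read strand

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ViralSegment:
    """One segment of the viral replicon producing phased siRNAs."""

    name: str
    length: int = 3000
    sirna_length: int = 20
    phasing_fidelity: float = 1.0
    tail_rate: float = 0.0669  # fraction of reads with a non-templated tail
    trim_rate: float = 0.0105  # fraction of reads shortened to 18-19 nt
    copies_per_site: float = 50.0


@dataclass(frozen=True)
class JunctionPlan:
    """A planted splice junction."""

    contig: str
    donor: int
    acceptor: int
    strand: str = "+"
    spliced_fraction: float = 0.5
    n_offsets: int = 6
    depth: int = 200


@dataclass
class SimConfig:
    """Scenario parameters for the synthetic-data generator.

    Defaults describe the reference scenario: a 500-kb genome of three
    autosomes plus one Z and one W contig, four planted clusters (the W
    one spanning nearly the whole contig), cluster emission ~20,000x the
    sparse single-copy background, 30% multimapping species, a 0.7
    first-nucleotide uridine bias and 30% ping-pong pairs in dual-strand
    clusters.
    """

    seed: int = 0
    n_autosomes: int = 3
    z_contigs: int = 1
    w_contigs: int = 1
    contig_length: int = 100_000
    window: int = 5000
    clusters: list[PlantedCluster] | None = None
    u_bias: float = 0.7
    pingpong_fraction: float = 0.3
    multimapper_fraction: float = 0.3
    uni_strand_purity: float = 0.975
    background_species_per_kb: float = 0.1
    viral_segments: list[ViralSegment] = field(
        default_factory=lambda: [
            ViralSegment(name="viral_RNA1", length=3000),
            ViralSegment(name="viral_RNA2", length=2000),
        ]
    )
    tail_composition: dict[str, float] = field(
        default_factory=lambda: {"U": 0.496, "A": 0.252, "C": 0.126, "G": 0.126}
    )
    junctions: list[JunctionPlan] | None = None
    divergence_mean: float = 10.0
    divergence_sd: float = 5.0
    w_repeat_fraction: float = 0.6

    def default_clusters(self) -> list[PlantedCluster]:
        w = self.window
        return [
            PlantedCluster("autosome_1", 4 * w, 8 * w, "uni", "+"),
            PlantedCluster("autosome_2", 10 * w, 14 * w, "dual"),
            PlantedCluster("Z_1", 2 * w, 6 * w, "uni", "-"),
            PlantedCluster("W_1", 1 * w, 19 * w, "dual"),
        ]


@dataclass
class SimTruth:
    """Planted ground truth for one simulated scenario."""

    clusters: list[PlantedCluster] = field(default_factory=list)
    sex_labels: dict[str, str] = field(default_factory=dict)
    methylation: dict[str, bool] = field(default_factory=dict)
    duplex_ratios: dict[str, float] = field(default_factory=dict)
    junctions: list[JunctionPlan] = field(default_factory=list)
    tails: dict[str, str] = field(default_factory=dict)
    trimmed_ids: set[str] = field(default_factory=set)

    def cluster_base_set(self) -> set[tuple[str, int]]:
        bases: set[tuple[str, int]] = set()
        for cl in self.clusters:
            bases.update((cl.contig, p) for p in range(cl.start, cl.end))
        return bases


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=length)])


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTU", "TGCAA"))[::-1]


def simulate_genome(config: SimConfig) -> tuple[GenomeIndex, SimTruth]:
    """Random-sequence contigs with sex labels, repeats and planted clusters."""
    rng = np.random.default_rng(config.seed)
    names = (
        [f"autosome_{i+1}" for i in range(config.n_autosomes)]
        + [f"Z_{i+1}" for i in range(config.z_contigs)]
        + [f"W_{i+1}" for i in range(config.w_contigs)]
    )
    sex_labels = {
        name: ("A" if name.startswith("a") else name[0]) for name in names
    }
    sequences = {name: _random_seq(rng, config.contig_length) for name in names}
    lengths = {name: config.contig_length for name in names}

    clusters = (
        config.clusters if config.clusters is not None else config.default_clusters()
    )
    for cl in clusters:
        if cl.contig not in lengths:
            raise ValueError(f"cluster contig {cl.contig!r} not in genome")
        if cl.start < 0 or cl.end > lengths[cl.contig]:
            raise ValueError(
                f"cluster {cl.contig}:{cl.start}-{cl.end} overlaps contig end"
            )

    repeats: list[RepeatCopy] = []
    copy_len = 1000
    for ci, cl in enumerate(clusters):
        n_copies = int(cl.transposon_fraction * cl.length / copy_len)
        starts = rng.choice(
            np.arange(cl.start, cl.end - copy_len, copy_len),
            size=min(n_copies, max(1, (cl.length - copy_len) // copy_len)),
            replace=False,
        )
        for s in np.sort(starts):
            anti = rng.random() < cl.antisense_fraction
            read_strand = cl.main_strand if cl.strandedness == "uni" else "+"
            strand = ("-" if read_strand == "+" else "+") if anti else read_strand
            div = float(np.clip(rng.normal(config.divergence_mean,
                                           config.divergence_sd), 0.1, 60.0))
            repeats.append(
                RepeatCopy(cl.contig, int(s), int(s) + copy_len, strand,
                           f"family_{ci % 5}", round(div, 2))
            )
    # elevated repeat load on W contigs outside clusters
    cluster_ivs = {(cl.contig, cl.start, cl.end) for cl in clusters}
    for name in names:
        if sex_labels[name] != "W":
            continue
        occupied = [
            (s, e) for (c, s, e) in cluster_ivs if c == name
        ]
        pos = 0
        while pos + copy_len <= lengths[name]:
            inside = any(s <= pos < e for s, e in occupied)
            if not inside and rng.random() < config.w_repeat_fraction:
                div = float(np.clip(rng.normal(config.divergence_mean,
                                               config.divergence_sd), 0.1, 60.0))
                repeats.append(
                    RepeatCopy(name, pos, pos + copy_len,
                               "+" if rng.random() < 0.5 else "-",
                               "family_W", round(div, 2))
                )
            pos += 2 * copy_len

    genome = GenomeIndex(
        lengths=lengths, sequences=sequences, repeats=repeats, sex_labels=sex_labels
    )
    truth = SimTruth(clusters=list(clusters), sex_labels=dict(sex_labels))
    return genome, truth


def _draw_sequence(
    genome: GenomeIndex, rec: AlignmentRecord, rng: np.random.Generator, u_bias: float
) -> str:
    seq = genome.fetch(rec.contig, rec.start, rec.end)
    if rec.strand == "-":
        seq = _revcomp(seq)
    seq = seq.replace("T", "U")
    if rng.random() < u_bias:
        first = "U"
    else:
        first = "ACG"[rng.integers(0, 3)]
    return first + seq[1:]


def simulate_pirna_reads(
    genome: GenomeIndex, truth: SimTruth, config: SimConfig
) -> list[AlignmentRecord]:
    """Emit collapsed piRNA species from planted clusters plus background.

    Species counts follow the configured emission rates; a
    ``multimapper_fraction`` of cluster species receive one or two extra
    placements (in another cluster or at a random background locus) and
    n_loci set accordingly. Dual-strand clusters emit a
    ``pingpong_fraction`` of species as opposite-strand pairs whose 5'
    ends overlap by exactly 10 nt.
    """
    rng = np.random.default_rng(config.seed + 1)
    records: list[AlignmentRecord] = []
    counter = 0
    clusters = truth.clusters

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"p{counter}"

    def emit(contig: str, five: int, strand: str, length: int,
             copies: int, read_id: str | None = None,
             n_loci: int = 1) -> AlignmentRecord:
        if strand == "+":
            start, end = five, five + length
        else:
            start, end = five - length + 1, five + 1
        rec = AlignmentRecord(
            read_id=read_id or new_id(),
            contig=contig,
            start=start,
            end=end,
            strand=strand,
            copies=copies,
            n_loci=n_loci,
        )
        rec.sequence = _draw_sequence(genome, rec, rng, config.u_bias)
        return rec

    for cl in clusters:
        kb = cl.length / 1000.0
        n_species = int(rng.poisson(cl.species_per_kb * kb))
        if cl.emission_rate == 0 or n_species == 0:
            continue
        mean_copies = max(1.0, cl.emission_rate * kb / n_species)
        for _ in range(n_species):
            copies = 1 + int(rng.poisson(mean_copies - 1))
            length = int(rng.integers(23, 36))
            if cl.strandedness == "uni":
                strand = (
                    cl.main_strand
                    if rng.random() < config.uni_strand_purity
                    else ("-" if cl.main_strand == "+" else "+")
                )
            else:
                strand = "+" if rng.random() < 0.5 else "-"
            margin = 40
            five = int(rng.integers(cl.start + margin, cl.end - margin))
            is_pingpong = (
                cl.strandedness == "dual" and rng.random() < config.pingpong_fraction
            )
            if is_pingpong:
                # responder on the opposite strand, 5' ends overlapping 10 nt
                plus_five = five
                minus_five = plus_five + 9
                len2 = int(rng.integers(23, 36))
                records.append(emit(cl.contig, plus_five, "+", length, copies))
                records.append(
                    emit(cl.contig, minus_five, "-", len2,
                         max(1, int(copies * rng.uniform(0.5, 1.0))))
                )
                continue
            if rng.random() < config.multimapper_fraction and len(clusters) > 1:
                n_extra = int(rng.integers(1, 3))
                read_id = new_id()
                placements = [(cl.contig, five, strand)]
                for _ in range(n_extra):
                    if rng.random() < 0.5:
                        other = clusters[int(rng.integers(0, len(clusters)))]
                        o_five = int(
                            rng.integers(other.start + margin, other.end - margin)
                        )
                        placements.append((other.contig, o_five, strand))
                    else:  # decoy placement outside any cluster
                        contig = list(genome.lengths)[
                            int(rng.integers(0, len(genome.lengths)))
                        ]
                        o_five = int(
                            rng.integers(margin, genome.lengths[contig] - margin)
                        )
                        placements.append((contig, o_five, strand))
                for contig, p_five, p_strand in placements:
                    records.append(
                        emit(contig, p_five, p_strand, length, copies,
                             read_id=read_id, n_loci=len(placements))
                    )
            else:
                records.append(emit(cl.contig, five, strand, length, copies))

    # sparse single-copy background outside clusters
    for contig, size in genome.lengths.items():
        n_bg = rng.poisson(config.background_species_per_kb * size / 1000.0)
        for _ in range(int(n_bg)):
            five = int(rng.integers(40, size - 40))
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(emit(contig, five, strand, int(rng.integers(23, 36)), 1))
    return records


def simulate_viral_reads(
    config: SimConfig,
) -> tuple[GenomeIndex, list[AlignmentRecord], SimTruth]:
    """Phased 20-nt siRNAs from a viral replicon, with tails and trimming.

    Reads tile one-after-another from each segment's 5' end; at fidelity
    f each step continues in phase with probability f, otherwise the
    register slips by 1-19 nt. Tails are appended as soft-clipped,
    non-templated sequence whose first nucleotide is guaranteed to
    mismatch the genomic continuation, so the planted tail string is
    exactly recoverable. Trimmed reads are 18-19-nt 5' prefixes of phased
    species.
    """
    rng = np.random.default_rng(config.seed + 2)
    mutable = {
        seg.name: list(_random_seq(rng, seg.length))
        for seg in config.viral_segments
    }
    truth = SimTruth()
    records: list[AlignmentRecord] = []
    comp_letters = list(config.tail_composition)
    comp_probs = np.array([config.tail_composition[l] for l in comp_letters])
    comp_probs = comp_probs / comp_probs.sum()
    counter = 0

    def draw_tail() -> str:
        tail_len = min(int(rng.geometric(0.6)), 3)
        return "".join(
            str(rng.choice(comp_letters, p=comp_probs)) for _ in range(tail_len)
        )

    for seg in config.viral_segments:
        if seg.length < 200:
            raise ValueError("viral segments must be >= 200 nt")
        contig = mutable[seg.name]
        pos = 0
        L = seg.sirna_length
        while pos + L <= seg.length:
            counter += 1
            copies = 1 + int(rng.poisson(seg.copies_per_site))
            seq = "".join(contig[pos:pos + L]).replace("T", "U")
            rec = AlignmentRecord(
                read_id=f"v{counter}",
                contig=seg.name,
                start=pos,
                end=pos + L,
                strand="+",
                copies=copies,
                sequence=seq,
            )
            if rng.random() < seg.tail_rate:
                tail = draw_tail()
                # keep the tail unambiguously non-templated: if the genomic
                # base after the read happens to equal the tail's first
                # nucleotide, mutate it (that base is only consumed by
                # downstream reads, which are drawn afterwards)
                if pos + L < seg.length:
                    nxt = contig[pos + L].replace("T", "U")
                    if nxt == tail[0]:
                        dna_tail0 = tail[0].replace("U", "T")
                        options = [b for b in "ACGT" if b != dna_tail0]
                        contig[pos + L] = options[int(rng.integers(0, 3))]
                rec.sequence = seq + tail
                rec.soft_clipped = True
                truth.tails[rec.read_id] = tail
            else:
                truth.tails[rec.read_id] = ""
            # trimming: a binomial share of this site's reads are shortened
            # to 18-19-nt 5' prefixes, so the copy-weighted short-read
            # fraction matches trim_rate in expectation
            n_trimmed = int(rng.binomial(copies, seg.trim_rate))
            rec.copies = copies - n_trimmed if copies > n_trimmed else copies
            records.append(rec)
            if n_trimmed > 0:
                counter += 1
                short_len = int(rng.integers(18, 20))
                trimmed = AlignmentRecord(
                    read_id=f"v{counter}",
                    contig=seg.name,
                    start=pos,
                    end=pos + short_len,
                    strand="+",
                    copies=n_trimmed,
                    sequence=seq[:short_len],
                )
                truth.trimmed_ids.add(trimmed.read_id)
                records.append(trimmed)
            if rng.random() < seg.phasing_fidelity:
                pos += L
            else:
                pos += L + int(rng.integers(1, 20))
    sequences = {name: "".join(chars) for name, chars in mutable.items()}
    genome = GenomeIndex(
        lengths={n: len(s) for n, s in sequences.items()}, sequences=sequences
    )
    return genome, records, truth


def simulate_duplexes(
    config: SimConfig,
    n_duplexes: int = 50,
    guide_passenger_ratio: float = 4.0,
    mean_guide_copies: float = 200.0,
    contig: str = "duplex_contig",
    contig_length: int = 50_000,
) -> tuple[list[AlignmentRecord], SimTruth]:
    """siRNA duplexes with 2-nt 3' overhangs and planted strand asymmetry.

    Each duplex is a plus species at [s, e) and a minus species at
    [s-2, e-2); guide copies are Poisson around ``mean_guide_copies`` and
    passenger copies around guide/ratio, with the guide strand chosen at
    random.
    """
    rng = np.random.default_rng(config.seed + 3)
    records: list[AlignmentRecord] = []
    truth = SimTruth()
    positions = rng.choice(
        np.arange(100, contig_length - 100, 60), size=n_duplexes, replace=False
    )
    for i, s in enumerate(np.sort(positions)):
        length = int(rng.integers(20, 23))
        guide = 1 + int(rng.poisson(mean_guide_copies))
        passenger = 1 + int(rng.poisson(mean_guide_copies / guide_passenger_ratio))
        plus_copies, minus_copies = (
            (guide, passenger) if rng.random() < 0.5 else (passenger, guide)
        )
        name = f"dup{i+1}"
        records.append(
            AlignmentRecord(f"{name}_p", contig, int(s), int(s) + length, "+",
                            copies=plus_copies)
        )
        records.append(
            AlignmentRecord(f"{name}_m", contig, int(s) - 2, int(s) + length - 2,
                            "-", copies=minus_copies)
        )
        truth.duplex_ratios[name] = max(plus_copies, minus_copies) / min(
            plus_copies, minus_copies
        )
    return records, truth


def simulate_library_pair(
    species: Sequence[tuple[str, float, bool]],
    depletion: float,
    seed: int,
    depth: int = 100_000,
    pirna_pool_weight: float | None = None,
) -> tuple[dict[str, float], dict[str, float], LibraryStats, LibraryStats, SimTruth]:
    """Matched unoxidized/oxidized libraries by multinomial resampling.

    ``species`` is (sequence, abundance, methylated). In the oxidized
    library the sampling weight of every unmethylated species is divided
    by ``depletion``; methylated species are untouched. A fully
    methylated piRNA pool (weight = total siRNA weight unless given) is
    co-sampled and its counts reported as each library's cluster-mapped
    denominator, mirroring normalization to piRNA-cluster-mapping reads.
    """
    if depletion <= 1:
        raise ValueError("depletion factor must exceed 1")
    if any(a <= 0 for _, a, _ in species):
        raise ValueError("species abundances must be positive")
    rng = np.random.default_rng(seed)
    abundances = np.array([a for _, a, _ in species], dtype=float)
    meth = np.array([m for _, _, m in species], dtype=bool)
    pool = float(abundances.sum()) if pirna_pool_weight is None else pirna_pool_weight

    def sample(weights: np.ndarray) -> tuple[dict[str, float], LibraryStats]:
        w = np.append(weights, pool)
        counts = rng.multinomial(depth, w / w.sum())
        table = {
            seq: float(c) for (seq, _, _), c in zip(species, counts[:-1])
        }
        cluster_mapped = float(counts[-1])
        stats = LibraryStats(
            total_reads=float(depth),
            unique_mapped_reads=float(depth),
            cluster_mapped_reads=cluster_mapped,
        )
        return table, stats

    unox_table, unox_stats = sample(abundances)
    ox_weights = np.where(meth, abundances, abundances / depletion)
    ox_table, ox_stats = sample(ox_weights)
    truth = SimTruth(methylation={seq: bool(m) for (seq, _, m), _ in
                                  zip(species, meth)})
    return unox_table, ox_table, unox_stats, ox_stats, truth


def simulate_dna_coverage(
    genome: GenomeIndex,
    sex: str,
    depth: float,
    seed: int,
    read_length: int = 100,
    low_mapq_fraction: float = 0.1,
    w_residual_male: float = 0.11,
) -> list[AlignmentRecord]:
    """DNA-seq reads whose depth encodes the contig's sex linkage.

    Per-haplotype depth is ``depth / 2``: autosomes carry two copies in
    both sexes, Z two in males (ZZ) and one in females (ZW), W one in
    females and none in males apart from a small confidently-mapped
    residual (``w_residual_male`` of the per-haplotype rate, mimicking
    W-homologous sequence shared with the rest of the genome). A
    ``low_mapq_fraction`` of reads on every contig gets MAPQ < 20, and
    males additionally receive a burst of low-MAPQ cross-mapped reads on
    W contigs, so the MAPQ filter is genuinely load-bearing.
    """
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    if genome.sex_labels is None:
        raise ValueError("genome carries no sex labels")
    rng = np.random.default_rng(seed)
    per_hap = depth / 2.0
    records: list[AlignmentRecord] = []
    counter = 0
    for contig, size in sorted(genome.lengths.items()):
        label = genome.sex_labels[contig]
        if label == "A":
            copies = 2.0
        elif label == "Z":
            copies = 2.0 if sex == "male" else 1.0
        else:  # W
            copies = w_residual_male if sex == "male" else 1.0
        target_cov = per_hap * copies
        n_reads = int(rng.poisson(target_cov * size / read_length))
        n_noise = 0
        if label == "W" and sex == "male":
            # repetitive cross-mapping reads, all low quality
            n_noise = int(rng.poisson(per_hap * size / read_length))
        for _ in range(n_reads + n_noise):
            counter += 1
            start = int(rng.integers(0, max(1, size - read_length)))
            if _ >= n_reads or rng.random() < low_mapq_fraction:
                mapq = int(rng.integers(0, 20))
            else:
                mapq = int(rng.integers(30, 61))
            records.append(
                AlignmentRecord(
                    read_id=f"d{counter}",
                    contig=contig,
                    start=start,
                    end=start + read_length,
                    strand="+" if rng.random() < 0.5 else "-",
                    mapq=mapq,
                )
            )
    return records


def simulate_junction_reads(
    genome: GenomeIndex,
    junctions: Sequence[JunctionPlan],
    seed: int,
    read_flank: int = 15,
) -> tuple[list[AlignmentRecord], SimTruth]:
    """Spliced and unspliced reads across planted junctions.

    Spliced reads carry the (donor, acceptor) gap and their start offsets
    cycle round-robin over ``n_offsets`` distinct positions, planting a
    near-uniform offset distribution of entropy ~ log2(n_offsets).
    Unspliced reads span the donor without a gap.
    """
    rng = np.random.default_rng(seed)
    records: list[AlignmentRecord] = []
    truth = SimTruth(junctions=list(junctions))
    counter = 0
    for jx in junctions:
        if jx.contig not in genome.lengths:
            raise ValueError(f"junction contig {jx.contig!r} not in genome")
        n_spliced = int(rng.binomial(jx.depth, jx.spliced_fraction))
        n_unspliced = jx.depth - n_spliced
        offsets = [jx.donor - read_flank - 2 * i for i in range(jx.n_offsets)]
        for i in range(n_spliced):
            counter += 1
            start = offsets[i % jx.n_offsets]
            records.append(
                AlignmentRecord(
                    read_id=f"j{counter}",
                    contig=jx.contig,
                    start=start,
                    end=jx.acceptor + read_flank,
                    strand=jx.strand,
                    gap=(jx.donor, jx.acceptor),
                )
            )
        for _ in range(n_unspliced):
            counter += 1
            start = jx.donor - int(rng.integers(5, 25))
            records.append(
                AlignmentRecord(
                    read_id=f"j{counter}",
                    contig=jx.contig,
                    start=start,
                    end=start + 30,
                    strand=jx.strand,
                )
            )
    return records, truth


def library_stats(records: Iterable[AlignmentRecord]) -> LibraryStats:
    """Depth denominators from a record set (each read counted once)."""
    seen: dict[str, tuple[int, int]] = {}
    for rec in records:
        seen[rec.read_id] = (rec.copies, rec.n_loci)
    total = float(sum(c for c, _ in seen.values()))
    unique = float(sum(c for c, n in seen.values() if n == 1))
    return LibraryStats(total_reads=total, unique_mapped_reads=max(unique, 1.0))
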