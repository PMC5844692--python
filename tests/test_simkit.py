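import numpy as np
import pytest

from pirnascape.rio import write_fasta
from pirnascape.sigstats import transposon_family_age
from pirnascape.simkit import (
    JunctionPlan,
    PlantedCluster,
    SimConfig,
    library_stats,
    simulate_dna_coverage,
    simulate_duplexes,
    simulate_genome,
    simulate_junction_reads,
    simulate_library_pair,
    simulate_pirna_reads,
    simulate_viral_reads,
)


class TestGenome:
    def test_same_seed_gives_identical_fasta_bytes(self, tmp_path):
        for sub in ("a", "b"):
            genome, _ = simulate_genome(SimConfig(seed=3))
            write_fasta(genome.sequences, tmp_path / f"{sub}.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_no_clusters_config(self):
        config = SimConfig(seed=0, n_autosomes=1, z_contigs=0, w_contigs=0,
                           clusters=[])
        genome, truth = simulate_genome(config)
        assert truth.clusters == []
        assert list(genome.lengths) == ["autosome_1"]

    def test_sex_labels_assigned(self):
        genome, truth = simulate_genome(SimConfig(seed=0))
        labels = set(truth.sex_labels.values())
        assert labels == {"A", "Z", "W"}

    def test_cluster_overlapping_contig_end_rejected(self):
        config = SimConfig(
            seed=0,
            clusters=[PlantedCluster("autosome_1", 90_000, 120_000)],
        )
        with pytest.raises(ValueError, match="contig end"):
            simulate_genome(config)

    def test_planted_constant_divergence_yields_exact_family_age(self):
        config = SimConfig(seed=1, divergence_mean=2.0, divergence_sd=0.0)
        genome, _ = simulate_genome(config)
        fam = [(r.divergence, r.end - r.start) for r in genome.repeats]
        assert transposon_family_age(fam) == pytest.approx(2.0)


class TestPirnaReads:
    def test_zero_emission_gives_empty_cluster_read_set(self):
        config = SimConfig(
            seed=0,
            clusters=[PlantedCluster("autosome_1", 20_000, 40_000,
                                     emission_rate=0.0, species_per_kb=0.0)],
            background_species_per_kb=0.0,
        )
        genome, truth = simulate_genome(config)
        assert simulate_pirna_reads(genome, truth, config) == []

    def test_multimapper_fraction_zero_means_all_unique(self):
        config = SimConfig(seed=0, multimapper_fraction=0.0)
        genome, truth = simulate_genome(config)
        reads = simulate_pirna_reads(genome, truth, config)
        assert all(r.n_loci == 1 for r in reads)

    def test_read_lengths_in_pirna_range(self, default_scenario):
        _, _, _, reads = default_scenario
        assert all(23 <= r.length <= 35 for r in reads)

    def test_unique_cluster_reads_lie_inside_their_cluster(self):
        config = SimConfig(seed=2, multimapper_fraction=0.0,
                           background_species_per_kb=0.0)
        genome, truth = simulate_genome(config)
        reads = simulate_pirna_reads(genome, truth, config)
        intervals = [(c.contig, c.start, c.end) for c in truth.clusters]
        for rec in reads:
            assert any(
                rec.contig == c and s <= rec.start and rec.end <= e
                for c, s, e in intervals
            )

    def test_uni_strand_cluster_purity(self):
        config = SimConfig(
            seed=4,
            clusters=[PlantedCluster("autosome_1", 10_000, 60_000, "uni", "+")],
            background_species_per_kb=0.0,
            multimapper_fraction=0.0,
        )
        genome, truth = simulate_genome(config)
        reads = simulate_pirna_reads(genome, truth, config)
        plus = sum(r.copies for r in reads if r.strand == "+")
        total = sum(r.copies for r in reads)
        assert plus / total >= 0.95

    def test_first_nucleotide_bias_recovered(self, default_scenario):
        from pirnascape.sigstats import first_nt_bias

        config, _, _, reads = default_scenario
        bias = first_nt_bias(reads)
        n = sum(r.copies for r in reads)
        sigma = np.sqrt(0.7 * 0.3 / len(reads))
        assert abs(bias["U"] - config.u_bias) < 5 * sigma


class TestViralReads:
    def test_perfect_fidelity_no_tails_tiles_exactly(self):
        config = SimConfig(seed=0)
        config.viral_segments = [
            type(config.viral_segments[0])(
                name="v", length=400, phasing_fidelity=1.0, tail_rate=0.0,
                trim_rate=0.0,
            )
        ]
        _, reads, truth = simulate_viral_reads(config)
        assert [r.start for r in reads] == list(range(0, 400 - 19, 20))
        assert all(t == "" for t in truth.tails.values())

    def test_tail_rate_one_uridine_composition(self):
        config = SimConfig(seed=1, tail_composition={"U": 1.0})
        config.viral_segments = [
            type(config.viral_segments[0])(
                name="v", length=600, tail_rate=1.0, trim_rate=0.0,
            )
        ]
        _, reads, truth = simulate_viral_reads(config)
        full_length = [r for r in reads if r.length == 20]
        assert all(truth.tails[r.read_id] != "" for r in full_length)
        assert all(set(t) == {"U"} for t in truth.tails.values() if t)

    def test_same_seed_reproducible(self):
        a = simulate_viral_reads(SimConfig(seed=5))
        b = simulate_viral_reads(SimConfig(seed=5))
        assert [(r.start, r.copies, r.sequence) for r in a[1]] == [
            (r.start, r.copies, r.sequence) for r in b[1]
        ]

    def test_segment_too_short_rejected(self):
        config = SimConfig(seed=0)
        config.viral_segments = [type(config.viral_segments[0])(name="v", length=100)]
        with pytest.raises(ValueError):
            simulate_viral_reads(config)


class TestLibraryPair:
    species = [("A" * 21, 100.0, True), ("G" * 21, 100.0, False)]

    def test_same_seed_identical_tables(self):
        a = simulate_library_pair(self.species, 5.0, seed=2)
        b = simulate_library_pair(self.species, 5.0, seed=2)
        assert a[0] == b[0] and a[1] == b[1]

    def test_all_methylated_keeps_ratio_near_one(self):
        species = [(f"{'ACGU'[i % 4] * 21}", 100.0, True) for i in range(4)]
        unox, ox, us, os_, _ = simulate_library_pair(species, 5.0, seed=3,
                                                     depth=200_000)
        for seq in unox:
            unox_norm = unox[seq] / us.cluster_mapped_reads
            ox_norm = ox[seq] / os_.cluster_mapped_reads
            assert ox_norm / unox_norm == pytest.approx(1.0, abs=0.1)

    def test_depletion_below_one_rejected(self):
        with pytest.raises(ValueError):
            simulate_library_pair(self.species, 1.0, seed=0)


class TestDnaCoverage:
    def test_male_w_coverage_far_below_female(self):
        genome, _ = simulate_genome(SimConfig(seed=6, contig_length=20_000, clusters=[]))
        male = simulate_dna_coverage(genome, "male", 30.0, seed=1)
        female = simulate_dna_coverage(genome, "female", 30.0, seed=2)

        def high_quality_bases(records, contig):
            return sum(r.length for r in records
                       if r.contig == contig and r.mapq >= 20)

        f_bases = high_quality_bases(female, "W_1")
        m_bases = high_quality_bases(male, "W_1")
        assert f_bases > 0
        # only the small residual of confidently-mapped W reads remains
        assert m_bases < 0.3 * f_bases

    def test_male_w_cross_mapping_noise_is_low_mapq(self):
        genome, _ = simulate_genome(SimConfig(seed=6, contig_length=20_000, clusters=[]))
        male = simulate_dna_coverage(genome, "male", 30.0, seed=1)
        w_reads = [r for r in male if r.contig == "W_1"]
        low = sum(1 for r in w_reads if r.mapq < 20)
        assert w_reads and low / len(w_reads) > 0.5

    def test_mapq_values_straddle_filter(self):
        genome, _ = simulate_genome(SimConfig(seed=6, contig_length=20_000, clusters=[]))
        reads = simulate_dna_coverage(genome, "female", 30.0, seed=3)
        assert any(r.mapq < 20 for r in reads)
        assert any(r.mapq >= 20 for r in reads)


class TestJunctionReads:
    def _genome(self):
        genome, _ = simulate_genome(SimConfig(seed=0, n_autosomes=1,
                                              z_contigs=0, w_contigs=0,
                                              clusters=[]))
        return genome

    def test_spliced_fraction_zero_gives_no_gapped_reads(self):
        plan = JunctionPlan("autosome_1", 50_000, 51_000, spliced_fraction=0.0)
        reads, _ = simulate_junction_reads(self._genome(), [plan], seed=0)
        assert all(r.gap is None for r in reads)

    def test_offset_diversity_planted(self):
        plan = JunctionPlan("autosome_1", 50_000, 51_000, spliced_fraction=0.5,
                            n_offsets=4, depth=400)
        reads, _ = simulate_junction_reads(self._genome(), [plan], seed=1)
        offsets = {r.start for r in reads if r.gap is not None}
        assert len(offsets) == 4

    def test_planted_efficiency_recovered_within_binomial_ci(self):
        plan = JunctionPlan("autosome_1", 50_000, 51_000, spliced_fraction=0.8,
                            depth=1000)
        reads, _ = simulate_junction_reads(self._genome(), [plan], seed=2)
        spliced = sum(1 for r in reads if r.gap is not None)
        unspliced = len(reads) - spliced
        eff = spliced / unspliced
        sigma = np.sqrt(0.8 * 0.2 / 1000) / (1 - 0.8) ** 2  # delta method on p/(1-p)
        assert abs(eff - 4.0) < 3 * sigma


class TestDuplexSim:
    def test_planted_geometry_always_valid(self):
        records, truth = simulate_duplexes(SimConfig(seed=9))
        from pirnascape.chem3p import pair_duplexes

        duplexes, summary = pair_duplexes(records)
        assert summary["n_duplexes"] == len(truth.duplex_ratios)


def test_library_stats_counts_each_read_once():
    from conftest import make_record

    records = [
        make_record(read_id="m", start=0, end=25, copies=4, n_loci=2),
        make_record(read_id="m", start=100, end=125, copies=4, n_loci=2),
        make_record(read_id="u", start=50, end=75, copies=3),
    ]
    stats = library_stats(records)
    assert stats.total_reads == 7
    assert stats.unique_mapped_reads == 3
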