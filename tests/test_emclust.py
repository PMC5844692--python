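import numpy as np
import pandas as pd
import pytest

from pirnascape.emclust import (
    Cluster,
    bin_reads,
    call_clusters,
    classify_strandedness,
    cluster_stats,
    differential_clusters,
    em_apportion,
)
from pirnascape.rio import GenomeIndex, LibraryStats, RepeatCopy

from _oracles import em_fixed_point
from conftest import make_record


def _genome(n_windows=4, width=5000, contig="chr1"):
    return GenomeIndex(lengths={contig: n_windows * width})


def _unique_reads(window, count, width=5000, strand="+", contig="chr1", prefix="u"):
    recs = []
    for i in range(count):
        five = window * width + 100 + i * 40
        start = five if strand == "+" else five - 24
        recs.append(
            make_record(contig=contig, start=start, end=start + 25, strand=strand,
                        read_id=f"{prefix}{window}_{i}")
        )
    return recs


def _multimapper(windows, width=5000, copies=1, read_id="m1", contig="chr1"):
    recs = []
    for w in windows:
        start = w * width + 200
        recs.append(
            make_record(contig=contig, start=start, end=start + 25, copies=copies,
                        read_id=read_id, n_loci=len(windows))
        )
    return recs


class TestBinReads:
    def test_five_prime_boundary_containment(self):
        rec = make_record(start=4999, end=5024)
        grid = bin_reads([rec], _genome())
        assert grid.unique[0] == 1 and grid.unique[1] == 0

    def test_minus_strand_five_prime_rule(self):
        rec = make_record(start=4990, end=5015, strand="-")
        grid = bin_reads([rec], _genome())
        assert grid.unique[1] == 1  # 5' at 5014 lands in window 1

    def test_short_reads_excluded_by_length_filter(self):
        rec = make_record(start=0, end=20)  # 20-nt siRNA, below piRNA range
        grid = bin_reads([rec], _genome())
        assert grid.total_mass == 0

    def test_nonpositive_window_width_rejected(self):
        with pytest.raises(ValueError):
            bin_reads([], _genome(), width=0)


class TestEmApportion:
    def test_worked_example_converges_to_closed_form(self):
        # u = (3, 1) plus one multimapper touching both windows:
        # n1 = 3 + n1/(n1+n2), n1+n2 = 5 => (3.75, 1.25)
        records = (
            _unique_reads(0, 3) + _unique_reads(1, 1) + _multimapper([0, 1])
        )
        grid = bin_reads(records, _genome(n_windows=2))
        grid, trace = em_apportion(grid, tolerance_fraction=1e-12)
        assert trace.converged
        assert grid.apportioned == pytest.approx([3.75, 1.25], abs=1e-9)

    def test_no_multimappers_converges_immediately(self):
        records = _unique_reads(0, 3) + _unique_reads(2, 5)
        grid = bin_reads(records, _genome())
        grid, trace = em_apportion(grid)
        assert trace.n_iterations == 1
        assert grid.apportioned == pytest.approx(grid.unique)

    def test_symmetric_multimapper_splits_equally(self):
        grid = bin_reads(_multimapper([0, 1]), _genome(n_windows=2))
        grid, _ = em_apportion(grid)
        assert grid.apportioned == pytest.approx([0.5, 0.5])

    def test_mass_conserved_at_every_iteration(self):
        rng = np.random.default_rng(3)
        records = []
        for w in range(4):
            records += _unique_reads(w, int(rng.integers(0, 6)))
        for m in range(10):
            wins = sorted(rng.choice(4, size=2, replace=False))
            records += _multimapper(list(wins), read_id=f"mm{m}",
                                    copies=int(rng.integers(1, 5)))
        grid = bin_reads(records, _genome())
        total = grid.total_mass
        for cap in range(1, 8):
            g = bin_reads(records, _genome())
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    g, _ = em_apportion(g, tolerance_fraction=0.0, max_iter=cap)
            assert g.apportioned.sum() == pytest.approx(total, rel=1e-12)

    def test_matches_bruteforce_fixed_point_on_random_grids(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n_win = int(rng.integers(2, 8))
            genome = _genome(n_windows=n_win)
            records = []
            for w in range(n_win):
                records += _unique_reads(w, int(rng.integers(0, 4)))
            placements, copies = [], []
            for m in range(int(rng.integers(1, 10))):
                k = int(rng.integers(2, min(4, n_win) + 1))
                wins = sorted(int(x) for x in rng.choice(n_win, size=k, replace=False))
                c = int(rng.integers(1, 6))
                records += _multimapper(wins, read_id=f"mm{m}", copies=c)
                placements.append(wins)
                copies.append(float(c))
            grid = bin_reads(records, genome)
            grid, _ = em_apportion(grid, tolerance_fraction=1e-12, max_iter=20_000)
            expected, masses = em_fixed_point(
                list(grid.unique), placements, copies
            )
            np.testing.assert_allclose(grid.apportioned, expected, atol=1e-9)
            total = grid.total_mass
            assert all(abs(m - total) < 1e-9 * max(total, 1) for m in masses)

    def test_order_invariance(self):
        records = (
            _unique_reads(0, 3) + _unique_reads(1, 2)
            + _multimapper([0, 1], read_id="a") + _multimapper([1, 3], read_id="b")
        )
        grid1, _ = em_apportion(bin_reads(records, _genome()))
        grid2, _ = em_apportion(bin_reads(records[::-1], _genome()))
        np.testing.assert_allclose(grid1.apportioned, grid2.apportioned)

    def test_empty_grid_errors_and_zero_reads_ok(self):
        genome = _genome()
        grid, trace = em_apportion(bin_reads([], genome))
        assert trace.converged and grid.apportioned.sum() == 0


class TestCallClusters:
    def _grid_with_seeds(self, seeds, n_windows=8):
        # ~50 copies in a seed window yields rpkm 10_000 at these stats
        records = []
        for w in seeds:
            records += _unique_reads(w, 50, prefix=f"s{w}_")
        return bin_reads(records, _genome(n_windows=n_windows))

    stats = LibraryStats(total_reads=1e6, unique_mapped_reads=1e6)

    def test_gap_bridging_merges_runs(self):
        grid, _ = em_apportion(self._grid_with_seeds([2, 3, 5]))
        clusters = call_clusters(grid, self.stats, min_rpkm=10, max_gap_windows=1)
        assert len(clusters) == 1
        assert (clusters[0].start, clusters[0].end) == (10_000, 30_000)

    def test_no_gap_allowance_splits_runs(self):
        grid, _ = em_apportion(self._grid_with_seeds([2, 3, 5]))
        clusters = call_clusters(grid, self.stats, min_rpkm=10, max_gap_windows=0)
        assert [(c.start, c.end) for c in clusters] == [
            (10_000, 20_000), (25_000, 30_000)
        ]

    def test_no_window_above_threshold(self):
        grid, _ = em_apportion(self._grid_with_seeds([1]))
        assert call_clusters(grid, self.stats, min_rpkm=1e9) == []

    def test_missing_stats_rejected(self):
        grid, _ = em_apportion(self._grid_with_seeds([1]))
        with pytest.raises(ValueError):
            call_clusters(grid, None)


class TestStrandedness:
    @pytest.mark.parametrize(
        "watson, crick, expected",
        [
            (100, 100, "dual"),
            (100, 10, "uni"),
            (0, 50, "uni"),
            (50, 0, "uni"),
            (100, 51, "dual"),
            (100, 50, "uni"),  # ratio exactly 2 is uni
        ],
    )
    def test_ratio_rule(self, watson, crick, expected):
        assert classify_strandedness(watson, crick) == expected

    def test_empty_cluster_errors(self):
        with pytest.raises(ValueError):
            classify_strandedness(0, 0)


class TestClusterStats:
    def _setup(self, read_specs):
        genome = GenomeIndex(
            lengths={"chr1": 20_000},
            repeats=[
                RepeatCopy("chr1", 1000, 2000, "+", "fam", 5.0),
                RepeatCopy("chr1", 3000, 4000, "-", "fam", 5.0),
            ],
        )
        cluster = Cluster(
            contig="chr1", start=0, end=10_000, watson_count=4, crick_count=0,
            unique_count=4, ppm_unique=0, ppm_all=0, rpkm=0,
        )
        records = [
            make_record(start=s, end=s + 25, strand=strand, read_id=f"r{i}")
            for i, (s, strand) in enumerate(read_specs)
        ]
        return cluster_stats(cluster, records, genome)

    def test_antisense_arithmetic(self):
        # 3 reads antisense to their repeat, 1 sense
        cluster = self._setup(
            [(1100, "-"), (1200, "-"), (3100, "+"), (1300, "+")]
        )
        assert cluster.antisense_fraction == pytest.approx(0.75)

    def test_all_antisense(self):
        cluster = self._setup([(1100, "-"), (3100, "+")])
        assert cluster.antisense_fraction == 1.0

    def test_no_repeat_overlap_leaves_fraction_missing(self):
        cluster = self._setup([(8000, "+")])
        assert cluster.antisense_fraction is None

    def test_repeat_fraction_of_bases(self):
        cluster = self._setup([(1100, "-")])
        assert cluster.repeat_fraction == pytest.approx(2000 / 10_000)


class TestDifferentialClusters:
    def test_identical_replicates_not_flagged(self):
        a = pd.DataFrame({"r1": [5.0, 9.0], "r2": [5.0, 9.0]}, index=["c1", "c2"]).T
        table = differential_clusters(a.T, a.T)
        assert (table.ratio == 1.0).all()
        assert not table.flag.any()

    def test_tenfold_ratio_reported(self):
        a = pd.DataFrame([[100.0, 110.0]], index=["c1"])
        b = pd.DataFrame([[10.0, 11.0]], index=["c1"])
        table = differential_clusters(a, b)
        assert table.loc["c1", "ratio"] == pytest.approx(10.0)

    def test_single_replicate_warns_and_skips_test(self):
        a = pd.DataFrame([[100.0]], index=["c1"])
        b = pd.DataFrame([[10.0]], index=["c1"])
        with pytest.warns(UserWarning, match="replicates"):
            table = differential_clusters(a, b)
        assert np.isnan(table.loc["c1", "pvalue"])
        assert table.loc["c1", "ratio"] == pytest.approx(10.0)

    def test_planted_fivefold_differences_recovered(self):
        rng = np.random.default_rng(5)
        n = 20
        base = rng.uniform(50, 200, size=n)
        noise = lambda: rng.normal(1.0, 0.05, size=(n, 3))
        a = pd.DataFrame(base[:, None] * 5 * noise(),
                         index=[f"c{i}" for i in range(n)])
        b = pd.DataFrame(base[:, None] * noise(), index=a.index)
        table = differential_clusters(a, b)
        assert table.flag.mean() >= 0.9

    def test_mismatched_universe_rejected(self):
        a = pd.DataFrame([[1.0, 2.0]], index=["c1"])
        b = pd.DataFrame([[1.0, 2.0]], index=["c2"])
        with pytest.raises(ValueError):
            differential_clusters(a, b)
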