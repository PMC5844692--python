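"""piRNA cluster discovery by EM apportionment of multimapping reads.

Small RNAs in the piRNA length range are counted in fixed genomic windows
(default 5 kb) by their 5' position. Uniquely mapped reads are assigned
unambiguously; reads mapping to several loci are apportioned among the
windows they touch by expectation-maximization:

- all windows start with the same weight;
- E step: window counts are the unique counts plus each multimapper's
  copies split across its windows proportionally to the window weights;
- M step: window weights are set to the E-step counts;
- iteration stops when the Manhattan distance between consecutive count
  vectors drops below a fraction (default 0.1%) of total read copies.

Windows above an rpkm threshold are merged into clusters, which are then
classified as uni- or dual-strand from their Watson/Crick read ratio and
annotated with transposon antisense and repeat-base fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from pirnascape.rio import AlignmentRecord, GenomeIndex, LibraryStats, normalize

__all__ = [
    "WindowGrid",
    "Cluster",
    "ConvergenceTrace",
    "bin_reads",
    "em_apportion",
    "call_clusters",
    "classify_strandedness",
    "cluster_stats",
    "differential_clusters",
]

DEFAULT_WINDOW = 5000
PIRNA_LENGTH_RANGE = (23, 35)


@dataclass
class WindowGrid:
    """Fixed-width windows with unique counts and multimapper incidence.

    Windows are indexed globally; ``window_index[contig]`` gives the offset
    of a contig's first window. Multimapper placements are stored flat:
    ``placement_window[i]`` is the window of placement ``i`` and
    ``placement_read[i]`` the index of the read it belongs to.
    """

    width: int
    contigs: list[str]
    window_index: dict[str, int]
    n_windows_per_contig: dict[str, int]
    window_length: np.ndarray  # nt per window (last window may be short)
    unique: np.ndarray  # unique read copies per window
    unique_watson: np.ndarray
    unique_crick: np.ndarray
    placement_window: np.ndarray  # int, flat placements
    placement_read: np.ndarray  # int, read index per placement
    placement_watson: np.ndarray  # bool, placement strand is +
    read_copies: np.ndarray  # copies per multimapping read
    apportioned: np.ndarray | None = None
    watson: np.ndarray | None = None
    crick: np.ndarray | None = None
    n_discarded_high_multiplicity: int = 0

    @property
    def n_windows(self) -> int:
        return len(self.window_length)

    @property
    def total_mass(self) -> float:
        return float(self.unique.sum() + self.read_copies.sum())

    def locate(self, contig: str, position: int) -> int:
        """Global index of the window containing ``position``."""
        return self.window_index[contig] + position // self.width

    def window_interval(self, global_idx: int) -> tuple[str, int, int]:
        for contig in self.contigs:
            off = self.window_index[contig]
            n = self.n_windows_per_contig[contig]
            if off <= global_idx < off + n:
                local = global_idx - off
                start = local * self.width
                return contig, start, start + int(self.window_length[global_idx])
        raise IndexError(global_idx)


@dataclass
class ConvergenceTrace:
    """Per-iteration Manhattan distances of the EM count vector."""

    distances: list[float]
    tolerance: float
    converged: bool

    @property
    def n_iterations(self) -> int:
        return len(self.distances)


@dataclass
class Cluster:
    """A called piRNA-producing genomic interval."""

    contig: str
    start: int
    end: int
    watson_count: float
    crick_count: float
    unique_count: float
    ppm_unique: float
    ppm_all: float
    rpkm: float
    strandedness: str = "uni"
    antisense_fraction: float | None = None
    repeat_fraction: float | None = None
    sex_link: str | None = None
    name: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def total_count(self) -> float:
        return self.watson_count + self.crick_count

    @property
    def strand(self) -> str:  # for BED output
        return "."


def bin_reads(
    records: Iterable[AlignmentRecord],
    genome: GenomeIndex,
    width: int = DEFAULT_WINDOW,
    length_range: tuple[int, int] = PIRNA_LENGTH_RANGE,
    max_loci: int = 100,
) -> WindowGrid:
    """Count reads into fixed windows by 5' position.

    Reads outside ``length_range`` are excluded. Reads whose placements all
    fall on one window group are unique mass; reads with several placement
    records form the multimapper incidence. Reads with more than
    ``max_loci`` placements are discarded (with a count kept on the grid).
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    contigs = sorted(genome.lengths)
    window_index: dict[str, int] = {}
    n_per: dict[str, int] = {}
    lengths: list[int] = []
    off = 0
    for contig in contigs:
        size = genome.lengths[contig]
        n_win = max(1, -(-size // width))
        window_index[contig] = off
        n_per[contig] = n_win
        for i in range(n_win):
            lengths.append(min(width, size - i * width))
        off += n_win
    window_length = np.array(lengths, dtype=float)
    n_windows = len(lengths)

    unique = np.zeros(n_windows)
    uw = np.zeros(n_windows)
    uc = np.zeros(n_windows)

    lo, hi = length_range
    by_read: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        if not (lo <= rec.length <= hi):
            continue
        if rec.contig not in window_index:
            raise KeyError(f"record contig {rec.contig!r} not in genome")
        by_read.setdefault(rec.read_id, []).append(rec)

    p_window: list[int] = []
    p_read: list[int] = []
    p_watson: list[bool] = []
    r_copies: list[float] = []
    n_discarded = 0
    # sort for order invariance of the grid itself
    for read_id in sorted(by_read):
        group = by_read[read_id]
        if len(group) == 1:
            rec = group[0]
            w = window_index[rec.contig] + rec.five_prime // width
            unique[w] += rec.copies
            (uw if rec.strand == "+" else uc)[w] += rec.copies
            continue
        if len(group) > max_loci:
            n_discarded += 1
            continue
        ridx = len(r_copies)
        r_copies.append(group[0].copies)
        for rec in sorted(group, key=lambda r: (r.contig, r.start, r.strand)):
            w = window_index[rec.contig] + rec.five_prime // width
            p_window.append(w)
            p_read.append(ridx)
            p_watson.append(rec.strand == "+")

    return WindowGrid(
        width=width,
        contigs=contigs,
        window_index=window_index,
        n_windows_per_contig=n_per,
        window_length=window_length,
        unique=unique,
        unique_watson=uw,
        unique_crick=uc,
        placement_window=np.array(p_window, dtype=np.int64),
        placement_read=np.array(p_read, dtype=np.int64),
        placement_watson=np.array(p_watson, dtype=bool),
        read_copies=np.array(r_copies, dtype=float),
        n_discarded_high_multiplicity=n_discarded,
    )


def _e_step(grid: WindowGrid, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One E step: apportioned counts and per-placement fractions."""
    n = grid.unique.copy()
    if len(grid.read_copies) == 0:
        return n, np.empty(0)
    theta_p = theta[grid.placement_window]
    denom = np.bincount(
        grid.placement_read, weights=theta_p, minlength=len(grid.read_copies)
    )
    counts = np.bincount(grid.placement_read, minlength=len(grid.read_copies))
    # tie rule: a read whose windows all have zero weight splits equally
    zero = denom[grid.placement_read] == 0
    frac = np.empty_like(theta_p)
    nz = ~zero
    frac[nz] = theta_p[nz] / denom[grid.placement_read[nz]]
    frac[zero] = 1.0 / counts[grid.placement_read[zero]]
    mass = grid.read_copies[grid.placement_read] * frac
    np.add.at(n, grid.placement_window, mass)
    return n, frac


def em_apportion(
    grid: WindowGrid,
    tolerance_fraction: float = 0.001,
    max_iter: int = 1000,
) -> tuple[WindowGrid, ConvergenceTrace]:
    """Apportion multimappers among windows by EM.

    Fills ``grid.apportioned`` (and its Watson/Crick split) in place and
    also returns the grid alongside the convergence trace. Read mass is
    conserved at every iteration.
    """
    if grid.n_windows == 0:
        raise ValueError("empty window grid")
    total = grid.total_mass
    if total == 0:
        grid.apportioned = grid.unique.copy()
        grid.watson = grid.unique_watson.copy()
        grid.crick = grid.unique_crick.copy()
        return grid, ConvergenceTrace(distances=[0.0], tolerance=0.0, converged=True)
    tau = tolerance_fraction * total
    theta = np.ones(grid.n_windows)
    n_prev, _ = _e_step(grid, theta)  # counts under the uniform init
    distances: list[float] = []
    converged = False
    frac = np.empty(0)
    n_cur = n_prev
    for _ in range(max_iter):
        theta = n_cur
        n_cur, frac = _e_step(grid, theta)
        dist = float(np.abs(n_cur - n_prev).sum())
        distances.append(dist)
        n_prev = n_cur
        if dist < tau:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations "
            f"(last Manhattan distance {distances[-1]:.3g} >= {tau:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    grid.apportioned = n_cur
    watson = grid.unique_watson.copy()
    crick = grid.unique_crick.copy()
    if len(grid.read_copies):
        mass = grid.read_copies[grid.placement_read] * frac
        np.add.at(watson, grid.placement_window[grid.placement_watson],
                  mass[grid.placement_watson])
        np.add.at(crick, grid.placement_window[~grid.placement_watson],
                  mass[~grid.placement_watson])
    grid.watson = watson
    grid.crick = crick
    return grid, ConvergenceTrace(distances=distances, tolerance=tau, converged=converged)


def classify_strandedness(watson: "float | Cluster", crick: float | None = None) -> str:
    """Label a cluster uni- or dual-strand from its Watson/Crick ratio.

    Dual-strand means both strands contribute comparably:
    0.5 < Watson/Crick < 2. A cluster with all reads on one strand is
    uni-strand. Accepts either a :class:`Cluster` or the two strand counts.
    """
    if isinstance(watson, Cluster):
        watson, crick = watson.watson_count, watson.crick_count
    if crick is None:
        raise TypeError("crick count required when not passing a Cluster")
    if watson + crick <= 0:
        raise ValueError("cluster has no reads")
    if crick == 0 or watson == 0:
        return "uni"
    ratio = watson / crick
    return "dual" if 0.5 < ratio < 2.0 else "uni"


def call_clusters(
    grid: WindowGrid,
    stats: LibraryStats,
    min_rpkm: float = 10.0,
    max_gap_windows: int = 1,
) -> list[Cluster]:
    """Merge above-threshold windows into piRNA clusters.

    Windows whose apportioned abundance is at least ``min_rpkm`` seed
    clusters; runs of seeds on the same contig are merged, bridging up to
    ``max_gap_windows`` consecutive sub-threshold windows.
    """
    if grid.apportioned is None:
        raise ValueError("grid not apportioned; run em_apportion first")
    if stats is None:
        raise ValueError("library stats required for normalization")
    n = grid.apportioned
    rpkm = np.array(
        [
            normalize(n[i], stats, "rpkm", length_nt=int(grid.window_length[i]))
            for i in range(grid.n_windows)
        ]
    )
    clusters: list[Cluster] = []
    for contig in grid.contigs:
        off = grid.window_index[contig]
        n_win = grid.n_windows_per_contig[contig]
        seeds = [i for i in range(n_win) if rpkm[off + i] >= min_rpkm]
        if not seeds:
            continue
        runs: list[tuple[int, int]] = []
        run_start = seeds[0]
        prev = seeds[0]
        for s in seeds[1:]:
            if s - prev - 1 <= max_gap_windows:
                prev = s
            else:
                runs.append((run_start, prev))
                run_start = prev = s
        runs.append((run_start, prev))
        for first, last in runs:
            start = first * grid.width
            end = min(last * grid.width + int(grid.window_length[off + last]),
                      genome_limit(grid, contig))
            idx = slice(off + first, off + last + 1)
            watson = float(grid.watson[idx].sum())
            crick = float(grid.crick[idx].sum())
            total = float(n[idx].sum())
            uniq = float(grid.unique[idx].sum())
            clusters.append(
                Cluster(
                    contig=contig,
                    start=start,
                    end=end,
                    watson_count=watson,
                    crick_count=crick,
                    unique_count=uniq,
                    ppm_unique=normalize(total, stats, "ppm_unique"),
                    ppm_all=normalize(total, stats, "ppm_total"),
                    rpkm=normalize(total, stats, "rpkm", length_nt=end - start),
                    strandedness=classify_strandedness(watson, crick)
                    if watson + crick > 0
                    else "uni",
                )
            )
    for i, cl in enumerate(clusters, start=1):
        cl.name = f"cluster_{i}"
    return clusters


def genome_limit(grid: WindowGrid, contig: str) -> int:
    off = grid.window_index[contig]
    n_win = grid.n_windows_per_contig[contig]
    return (n_win - 1) * grid.width + int(grid.window_length[off + n_win - 1])


def cluster_stats(
    cluster: Cluster,
    records: Iterable[AlignmentRecord],
    genome: GenomeIndex,
) -> Cluster:
    """Fill transposon antisense fraction and repeat-base fraction.

    A read overlapping a transposon copy counts as antisense when its
    strand is opposite that of the copy it overlaps most. The repeat
    fraction is the proportion of cluster bases under the repeat
    annotation.
    """
    if not genome.repeats:
        raise ValueError("genome carries no repeat annotation")
    tree = IntervalTree()
    for rep in genome.repeats:
        if rep.contig == cluster.contig:
            tree.addi(rep.start, rep.end, rep)

    anti = 0.0
    total = 0.0
    for rec in records:
        if rec.contig != cluster.contig:
            continue
        if not (cluster.start <= rec.five_prime < cluster.end):
            continue
        hits = tree.overlap(rec.start, rec.end)
        if not hits:
            continue
        best = max(
            hits, key=lambda iv: min(iv.end, rec.end) - max(iv.begin, rec.start)
        )
        total += rec.copies
        if best.data.strand != rec.strand:
            anti += rec.copies
    cluster.antisense_fraction = (anti / total) if total > 0 else None

    covered = IntervalTree()
    for iv in tree.overlap(cluster.start, cluster.end):
        covered.addi(max(iv.begin, cluster.start), min(iv.end, cluster.end))
    covered.merge_overlaps()
    rep_bases = sum(iv.end - iv.begin for iv in covered)
    cluster.repeat_fraction = rep_bases / cluster.length
    if genome.sex_labels is not None:
        cluster.sex_link = genome.sex_labels.get(cluster.contig)
    return cluster


def differential_clusters(
    abundance_a: pd.DataFrame,
    abundance_b: pd.DataFrame,
    ratio_bounds: tuple[float, float] = (2.0, 0.5),
    max_fdr: float = 0.1,
) -> pd.DataFrame:
    """Flag differentially expressed clusters between two replicate sets.

    Inputs are cluster x replicate tables of normalized abundance sharing
    an index (the merged cluster universe). Each cluster gets a two-sided
    t-test across replicates, Benjamini-Hochberg FDR, and a flag set when
    the mean ratio is > 2 or < 0.5 and FDR < 0.1.
    """
    if not abundance_a.index.equals(abundance_b.index):
        raise ValueError("cluster universes differ between the two sides")
    a = abundance_a.to_numpy(dtype=float)
    b = abundance_b.to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean_b > 0, mean_a / mean_b, np.inf)
    hi, lo = ratio_bounds
    out = pd.DataFrame(index=abundance_a.index.copy())
    out["mean_a"] = mean_a
    out["mean_b"] = mean_b
    out["ratio"] = ratio
    if a.shape[1] < 2 or b.shape[1] < 2:
        warnings.warn(
            "fewer than 2 replicates per side; t-test skipped", UserWarning,
            stacklevel=2,
        )
        out["pvalue"] = np.nan
        out["fdr"] = np.nan
        out["flag"] = False
        return out
    pvals = sps.ttest_ind(a, b, axis=1).pvalue
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    fdr = sps.false_discovery_control(pvals, method="bh")
    out["pvalue"] = pvals
    out["fdr"] = fdr
    out["flag"] = ((ratio > hi) | (ratio < lo)) & (fdr < max_fdr)
    return out
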