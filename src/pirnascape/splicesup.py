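"""Splice-junction detection and splicing-efficiency scoring.

Junctions are read directly from gapped RNA-seq alignments and kept only
when supported by enough reads (default 10) whose alignment start offsets
are diverse enough (Shannon entropy >= 2 bits) — a low-entropy pile of
identical offsets is the footprint of PCR duplication, not of
independent spliced molecules.

Splicing efficiency E = spliced / unspliced compares junction-spanning
reads against ungapped reads crossing the donor site. piRNA precursor
transcripts are spliced far less efficiently than ordinary mRNAs, so the
ratio of median efficiency outside versus inside piRNA clusters measures
cluster-specific splicing suppression.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from pirnascape.rio import AlignmentRecord
from pirnascape.emclust import Cluster

__all__ = [
    "Junction",
    "shannon_entropy",
    "detect_junctions",
    "splicing_efficiency",
    "compare_regions",
]


@dataclass
class Junction:
    contig: str
    donor: int  # first intronic base (0-based)
    acceptor: int  # first exonic base after the intron
    strand: str
    n_spanning: int
    offsets: tuple[int, ...]  # leftmost alignment starts of spanning reads
    entropy: float
    n_unspliced: int | None = None
    efficiency: float | None = None
    in_cluster: bool | None = None


def shannon_entropy(offsets: Iterable[int]) -> float:
    """Shannon entropy (bits) of the offset multiset."""
    counts = np.array(list(Counter(offsets).values()), dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def detect_junctions(
    records: Sequence[AlignmentRecord],
    min_reads: int = 10,
    min_entropy: float = 2.0,
) -> list[Junction]:
    """Group gapped reads into junctions and apply support/entropy filters.

    Each spliced read must carry exactly one gap (donor, acceptor).
    A junction is retained iff it has >= ``min_reads`` spanning reads and
    the entropy of their start offsets is >= ``min_entropy`` bits.
    """
    groups: dict[tuple[str, int, int, str], list[int]] = defaultdict(list)
    for rec in records:
        if rec.gap is None:
            continue
        donor, acceptor = rec.gap
        if not (rec.start < donor < acceptor < rec.end):
            raise ValueError(
                f"gap ({donor}, {acceptor}) inconsistent with read "
                f"interval [{rec.start}, {rec.end})"
            )
        for _ in range(rec.copies):
            groups[(rec.contig, donor, acceptor, rec.strand)].append(rec.start)
    junctions = []
    for (contig, donor, acceptor, strand), offsets in sorted(groups.items()):
        h = shannon_entropy(offsets)
        if len(offsets) >= min_reads and h >= min_entropy:
            junctions.append(
                Junction(
                    contig=contig,
                    donor=donor,
                    acceptor=acceptor,
                    strand=strand,
                    n_spanning=len(offsets),
                    offsets=tuple(sorted(offsets)),
                    entropy=h,
                )
            )
    return junctions


def splicing_efficiency(
    junction: Junction,
    records: Sequence[AlignmentRecord],
    min_flank: int = 3,
) -> Junction:
    """Fill the spliced/unspliced ratio for a junction.

    An unspliced read is an ungapped read on the junction's contig whose
    alignment crosses the donor (exon/intron boundary) with at least
    ``min_flank`` nt on each side. E = spanning / unspliced; left missing
    (None) when no unspliced reads exist.
    """
    n_unspliced = 0
    for rec in records:
        if rec.gap is not None or rec.contig != junction.contig:
            continue
        if rec.start + min_flank <= junction.donor <= rec.end - min_flank:
            n_unspliced += rec.copies
    junction.n_unspliced = n_unspliced
    junction.efficiency = (
        junction.n_spanning / n_unspliced if n_unspliced > 0 else None
    )
    return junction


def compare_regions(
    junctions: Sequence[Junction],
    clusters: Sequence[Cluster],
    by_strandedness: bool = False,
) -> dict[str, float | None]:
    """Median splicing efficiency inside vs outside piRNA clusters.

    A junction is in-cluster iff its donor lies within a cluster interval.
    ``fold_difference`` = median(outside) / median(inside); None when a
    class is empty. With ``by_strandedness`` the in-cluster medians are
    additionally split by the host cluster's uni/dual label.
    """
    by_contig: dict[str, list[Cluster]] = defaultdict(list)
    for cl in clusters:
        by_contig[cl.contig].append(cl)

    inside: list[float] = []
    outside: list[float] = []
    inside_by_label: dict[str, list[float]] = {"uni": [], "dual": []}
    for j in junctions:
        if j.efficiency is None:
            continue
        host = next(
            (
                cl
                for cl in by_contig.get(j.contig, ())
                if cl.start <= j.donor < cl.end
            ),
            None,
        )
        j.in_cluster = host is not None
        if host is not None:
            inside.append(j.efficiency)
            if host.strandedness in inside_by_label:
                inside_by_label[host.strandedness].append(j.efficiency)
        else:
            outside.append(j.efficiency)

    med_in = float(np.median(inside)) if inside else None
    med_out = float(np.median(outside)) if outside else None
    fold = (
        med_out / med_in if med_in not in (None, 0) and med_out is not None else None
    )
    summary: dict[str, float | None] = {
        "median_inside": med_in,
        "median_outside": med_out,
        "fold_difference": fold,
        "n_inside": float(len(inside)),
        "n_outside": float(len(outside)),
    }
    if by_strandedness:
        for label, vals in inside_by_label.items():
            summary[f"median_inside_{label}"] = (
                float(np.median(vals)) if vals else None
            )
    return summary
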