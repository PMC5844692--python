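"""ZW sex-chromosome linkage from male/female DNA coverage.

Lepidopteran females are the heterogametic sex (ZW) and males are ZZ, so
the male:female (M:F) ratio of median-normalized sequencing coverage is
~2 for Z-linked contigs, ~0 for W-linked contigs, and ~1 for autosomes.
Contigs are classified with the thresholds M:F > 1.5 (Z) and M:F < 0.5
(W); contigs with coverage below a floor in both sexes are called
ambiguous rather than forced into a class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from pirnascape.rio import AlignmentRecord, GenomeIndex

__all__ = ["LinkageCall", "contig_coverage", "classify_linkage", "dosage_ratios"]

Z_THRESHOLD = 1.5
W_THRESHOLD = 0.5


@dataclass(frozen=True)
class LinkageCall:
    contig: str
    male_cov: float
    female_cov: float
    mf_ratio: float
    label: str  # autosome | Z | W | ambiguous


def contig_coverage(
    records: Iterable[AlignmentRecord],
    genome: GenomeIndex,
    min_mapq: int = 20,
) -> dict[str, float]:
    """Median-normalized per-base coverage per contig.

    Only alignments with MAPQ >= ``min_mapq`` contribute (repetitive,
    ambiguously placed reads would otherwise blur the sex signal).
    Raw coverage is mapped bases divided by contig length, then divided
    by the median across contigs so an ordinary autosome sits at ~1.
    """
    bases = {contig: 0.0 for contig in genome.lengths}
    seen = False
    for rec in records:
        seen = True
        if rec.mapq is None or rec.mapq < min_mapq:
            continue
        if rec.contig in bases:
            bases[rec.contig] += rec.length * rec.copies
    if not seen:
        raise ValueError("empty record set")
    raw = {c: bases[c] / genome.lengths[c] for c in bases}
    median = float(np.median(list(raw.values())))
    if median == 0:
        raise ValueError("median coverage is zero; cannot normalize")
    return {c: v / median for c, v in raw.items()}


def classify_linkage(
    male: Mapping[str, float],
    female: Mapping[str, float],
    floor: float = 0.05,
) -> list[LinkageCall]:
    """Call each contig autosomal, Z-linked, W-linked or ambiguous.

    ``male`` and ``female`` are median-normalized coverage maps over the
    same contig universe. A zero female coverage with male signal gives
    an infinite M:F ratio, hence a Z call; contigs below ``floor`` in
    both sexes are ambiguous (unmappable rather than W-linked).
    """
    if set(male) != set(female):
        raise ValueError("male and female coverage maps cover different contigs")
    calls = []
    for contig in sorted(male):
        m, f = male[contig], female[contig]
        if m < floor and f < floor:
            label, ratio = "ambiguous", float("nan")
        else:
            ratio = m / f if f > 0 else float("inf")
            if ratio > Z_THRESHOLD:
                label = "Z"
            elif ratio < W_THRESHOLD:
                label = "W"
            else:
                label = "autosome"
        calls.append(LinkageCall(contig, m, f, ratio, label))
    return calls


def dosage_ratios(
    expression: Mapping[str, float],
    linkage: Mapping[str, str],
    min_genes: int = 10,
) -> float:
    """Z-to-autosome dosage ratio: median Z-linked over median autosomal.

    Only expressed genes (abundance > 0) enter the medians. In male (ZZ)
    soma partial dosage compensation puts this near 0.7 rather than the
    uncompensated 0.5 or the fully compensated 1.0.
    """
    z_vals = [
        v for g, v in expression.items() if v > 0 and linkage.get(g) == "Z"
    ]
    a_vals = [
        v for g, v in expression.items() if v > 0 and linkage.get(g) == "A"
    ]
    if not z_vals or not a_vals:
        raise ValueError("need expressed genes in both the Z and autosome classes")
    if len(z_vals) < min_genes or len(a_vals) < min_genes:
        import warnings

        warnings.warn(
            f"fewer than {min_genes} expressed genes in a class; "
            "dosage ratio will be noisy",
            UserWarning,
            stacklevel=2,
        )
    return float(np.median(z_vals) / np.median(a_vals))
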