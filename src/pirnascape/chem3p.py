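"""3'-end chemistry of small RNAs.

2'-O-methylation of a small RNA's 3' end makes it resistant to periodate
oxidation, so a methylated species keeps its abundance in a library
prepared from oxidized RNA while an unmethylated species is depleted. The
per-species oxidized/unoxidized (ox/unox) ratio of normalized counts is
therefore ~1 for methylated species and << 1 for unmethylated ones.

This module also classifies non-templated 3' additions (tailing), detects
3'-to-5' trimming (short reads that are 5' prefixes of longer species),
and reconstructs siRNA duplexes from the characteristic two-nucleotide
3' overhangs Dicer leaves on both ends.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from pirnascape.rio import AlignmentRecord, GenomeIndex, LibraryStats

__all__ = [
    "TailCall",
    "Duplex",
    "oxunox_table",
    "detect_tail",
    "trimming_fraction",
    "pair_duplexes",
]

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


@dataclass(frozen=True)
class TailCall:
    """Decomposition of a read into templated prefix + non-templated tail."""

    sequence: str
    prefix_length: int
    tail: str
    tail_class: str  # none | mono-U | oligo-U | A | other

    def __post_init__(self) -> None:
        assert self.sequence[self.prefix_length:].upper().replace("T", "U") == \
            self.tail.upper().replace("T", "U")


@dataclass(frozen=True)
class Duplex:
    """A reconstructed siRNA duplex with 2-nt 3' overhangs at both ends."""

    contig: str
    plus_start: int
    plus_end: int
    plus_copies: float
    minus_start: int
    minus_end: int
    minus_copies: float

    @property
    def guide_strand(self) -> str:
        """The more abundant strand (presumed Argonaute-loaded guide)."""
        return "+" if self.plus_copies >= self.minus_copies else "-"

    @property
    def ratio(self) -> float:
        hi = max(self.plus_copies, self.minus_copies)
        lo = min(self.plus_copies, self.minus_copies)
        return hi / lo


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def oxunox_table(
    unox: Mapping[str, float],
    ox: Mapping[str, float],
    unox_stats: LibraryStats,
    ox_stats: LibraryStats,
    pirna_species: Iterable[str] | None = None,
    min_unox_count: int = 5,
) -> tuple[pd.DataFrame, float]:
    """Per-species ox/unox ratio table and the median ratio.

    Counts are normalized to each library's piRNA-cluster-mapping reads
    (per million). Species that are exact 5' prefixes of a 23-35 nt
    species in ``pirna_species`` are dropped first, since piRNA
    degradation products masquerade as siRNAs. The median is taken over
    species detected in the unoxidized library at or above
    ``min_unox_count`` copies.
    """
    if unox_stats.cluster_mapped_reads <= 0 or ox_stats.cluster_mapped_reads <= 0:
        raise ValueError("cluster-mapped read counts must be positive")

    prefixes_of_pirnas: set[str] = set()
    if pirna_species:
        long_species = [
            _rna(s) for s in pirna_species if 23 <= len(s) <= 35
        ]
        by_first = defaultdict(list)
        for s in long_species:
            by_first[s[:10]].append(s)
        for seq in set(unox) | set(ox):
            r = _rna(seq)
            for cand in by_first.get(r[:10], ()):
                if cand.startswith(r) and len(cand) > len(r):
                    prefixes_of_pirnas.add(seq)
                    break

    rows = []
    for seq in sorted(set(unox) | set(ox)):
        if seq in prefixes_of_pirnas:
            continue
        u = float(unox.get(seq, 0))
        o = float(ox.get(seq, 0))
        u_norm = u / unox_stats.cluster_mapped_reads * 1e6
        o_norm = o / ox_stats.cluster_mapped_reads * 1e6
        rows.append(
            {
                "sequence": seq,
                "unox_count": u,
                "ox_count": o,
                "unox_norm": u_norm,
                "ox_norm": o_norm,
                "ratio": o_norm / u_norm if u_norm > 0 else np.nan,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["sequence", "unox_count", "ox_count", "unox_norm", "ox_norm", "ratio"],
    )
    eligible = table[(table.unox_norm > 0) & (table.unox_count >= min_unox_count)]
    median = float(eligible.ratio.median()) if len(eligible) else float("nan")
    return table, median


def detect_tail(
    sequence: str,
    contig: str,
    five_prime: int,
    strand: str,
    genome: GenomeIndex,
    min_anchor: int = 16,
) -> TailCall:
    """Split a read into its templated prefix and non-templated 3' tail.

    The read is compared nucleotide-by-nucleotide (5'-to-3', T and U
    equivalent) against the genome at its placement; the templated prefix
    is the longest matching prefix. At least ``min_anchor`` nt must match
    or the placement is rejected.
    """
    seq = _rna(sequence)
    n = len(seq)
    contig_seq = genome.sequences[contig] if genome.sequences else None
    if contig_seq is None:
        raise ValueError("genome has no sequence loaded")

    prefix = 0
    for i in range(n):
        if strand == "+":
            pos = five_prime + i
            if pos >= len(contig_seq):
                break
            templ = contig_seq[pos]
        else:
            pos = five_prime - i
            if pos < 0:
                break
            templ = contig_seq[pos].translate(_COMPLEMENT)
        if _rna(templ) != seq[i]:
            break
        prefix += 1
    if prefix < min_anchor:
        raise ValueError(
            f"read anchors only {prefix} nt at {contig}:{five_prime}({strand}); "
            f"placement invalid (need >= {min_anchor})"
        )
    tail = seq[prefix:]
    if not tail:
        cls = "none"
    elif set(tail) == {"U"}:
        cls = "mono-U" if len(tail) == 1 else "oligo-U"
    elif set(tail) == {"A"}:
        cls = "A"
    else:
        cls = "other"
    return TailCall(sequence=seq, prefix_length=prefix, tail=tail, tail_class=cls)


def trimming_fraction(
    records: Sequence[AlignmentRecord],
    short_lengths: tuple[int, int] = (18, 19),
    reference_min: int = 20,
) -> tuple[float, float | None]:
    """Fraction of short (trimmed-length) reads and how many are prefixes.

    Returns (copy-weighted fraction of all reads that are 18-19 nt,
    copy-weighted fraction of those sharing contig/strand/5' position
    with a >= 20-nt species — the operational signature of 3'-to-5'
    trimming). The second value is None when no reference species exist.
    """
    lo, hi = short_lengths
    short = [r for r in records if lo <= r.length <= hi]
    reference = [r for r in records if r.length >= reference_min]
    total = sum(r.copies for r in records)
    short_copies = sum(r.copies for r in short)
    short_fraction = short_copies / total if total else 0.0
    if not reference:
        return short_fraction, None
    anchors = {(r.contig, r.strand, r.five_prime) for r in reference}
    prefix_copies = sum(
        r.copies for r in short if (r.contig, r.strand, r.five_prime) in anchors
    )
    prefix_fraction = prefix_copies / short_copies if short_copies else None
    return short_fraction, prefix_fraction


def pair_duplexes(
    records: Sequence[AlignmentRecord],
    length_range: tuple[int, int] = (20, 22),
) -> tuple[list[Duplex], dict[str, float]]:
    """Reconstruct siRNA duplexes from 2-nt 3' overhang geometry.

    A plus-strand species at [s, e) pairs with a minus-strand species at
    [s - 2, e - 2): the minus strand's 3' end sits two nucleotides before
    the plus strand's 5' end and vice versa, the double overhang Dicer
    leaves. Copies of identical placements are aggregated into species
    first. Returns the duplex list and a summary with the fraction of
    duplexes at guide/passenger ratio >= 2, plus median and mean ratios.
    """
    lo, hi = length_range
    plus: dict[tuple[str, int, int], float] = defaultdict(float)
    minus: dict[tuple[str, int, int], float] = defaultdict(float)
    for rec in records:
        if not (lo <= rec.length <= hi):
            continue
        key = (rec.contig, rec.start, rec.end)
        (plus if rec.strand == "+" else minus)[key] += rec.copies

    duplexes: list[Duplex] = []
    for (contig, s, e), p_copies in sorted(plus.items()):
        m_key = (contig, s - 2, e - 2)
        m_copies = minus.get(m_key)
        if m_copies:
            duplexes.append(
                Duplex(
                    contig=contig,
                    plus_start=s,
                    plus_end=e,
                    plus_copies=p_copies,
                    minus_start=s - 2,
                    minus_end=e - 2,
                    minus_copies=m_copies,
                )
            )
    ratios = np.array([d.ratio for d in duplexes])
    summary = {
        "n_duplexes": float(len(duplexes)),
        "fraction_ratio_ge_2": float((ratios >= 2).mean()) if len(ratios) else float("nan"),
        "median_ratio": float(np.median(ratios)) if len(ratios) else float("nan"),
        "mean_ratio": float(ratios.mean()) if len(ratios) else float("nan"),
    }
    return duplexes, summary
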