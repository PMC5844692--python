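"""Signature statistics on aligned small RNAs.

Three pairwise distance spectra diagnose small-RNA biogenesis:

- ``overlap_5p_opposite`` — ping-pong: opposite-strand read pairs whose 5'
  ends overlap by k nt; PIWI-mediated reciprocal cleavage concentrates
  weight at k = 10.
- ``dist_5p_5p_same`` — same-strand 5'-to-5' distances; processive Dicer
  phasing of 20-nt siRNAs concentrates weight at the siRNA length.
- ``dist_3p_5p_same`` — distance from one read's 3' end to the next read's
  5' end on the same strand; head-to-tail (phased) production gives a
  peak at 1 (Z1).

Each spectrum carries a standard score of the focal lag against the
remaining lags in the window. Pair weight is min(copies, copies) per 5'
position pair by default, so one abundant species cannot dominate.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from pirnascape.rio import AlignmentRecord

__all__ = [
    "Spectrum",
    "ping_pong_z",
    "distance_spectrum",
    "first_nt_bias",
    "length_distribution",
    "transposon_family_age",
]

MODES = ("overlap_5p_opposite", "dist_5p_5p_same", "dist_3p_5p_same")


@dataclass
class Spectrum:
    """Lag-indexed pair-weight spectrum with a focal-lag Z score."""

    mode: str
    lags: np.ndarray
    weights: np.ndarray
    focal: int
    z_focal: float

    def weight_at(self, lag: int) -> float:
        idx = np.where(self.lags == lag)[0]
        return float(self.weights[idx[0]]) if len(idx) else 0.0

    @property
    def p_value(self) -> float:
        """One-sided normal upper-tail probability of the focal Z.

        A convention, not a calibrated null: lags are treated as an
        iid background.
        """
        from scipy.stats import norm

        return float(norm.sf(self.z_focal))


def _z_score(weights: np.ndarray, lags: np.ndarray, focal: int) -> float:
    mask = lags == focal
    if not mask.any():
        raise ValueError(f"focal lag {focal} outside lag range")
    s_focal = float(weights[mask][0])
    background = weights[~mask]
    sd = float(background.std(ddof=1)) if len(background) > 1 else 0.0
    if sd == 0:
        return 0.0
    return (s_focal - float(background.mean())) / sd


def _positions(
    records: Iterable[AlignmentRecord],
) -> dict[tuple[str, str], Counter]:
    """(contig, strand) -> Counter of 5' positions weighted by copies."""
    table: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for rec in records:
        table[(rec.contig, rec.strand)][rec.five_prime] += rec.copies
    return table


def ping_pong_z(
    records: Sequence[AlignmentRecord],
    lag_range: tuple[int, int] = (1, 30),
    focal: int = 10,
    pair_weight: str = "min",
) -> Spectrum:
    """Ping-pong spectrum: opposite-strand 5'-end overlap counts.

    A plus-strand read with 5' end at p and a minus-strand read with 5'
    end at p + k - 1 overlap by k nt. The Z score compares the focal lag
    (10, the PIWI ping-pong offset) against all other lags in the range.
    """
    lo, hi = lag_range
    lags = np.arange(lo, hi + 1)
    weights = np.zeros(len(lags))
    table = _positions(records)
    contigs = {c for c, _ in table}
    both = [c for c in contigs if (c, "+") in table and (c, "-") in table]
    if not both:
        import warnings

        warnings.warn("no contig with reads on both strands; Z = 0", UserWarning,
                      stacklevel=2)
        return Spectrum("overlap_5p_opposite", lags, weights, focal, 0.0)
    for contig in both:
        plus = table[(contig, "+")]
        minus = table[(contig, "-")]
        for p, c_plus in plus.items():
            for i, k in enumerate(lags):
                c_minus = minus.get(p + k - 1)
                if c_minus:
                    weights[i] += (
                        min(c_plus, c_minus)
                        if pair_weight == "min"
                        else c_plus * c_minus
                    )
    return Spectrum(
        "overlap_5p_opposite", lags, weights, focal, _z_score(weights, lags, focal)
    )


def distance_spectrum(
    records: Sequence[AlignmentRecord],
    mode: str,
    lag_range: tuple[int, int] = (1, 30),
    focal: int | None = None,
    pair_weight: str = "min",
) -> Spectrum:
    """Same-strand 5'-5' or 3'-5' distance spectrum.

    Distances run downstream in transcript orientation, so the minus
    strand is scanned right-to-left. ``dist_3p_5p_same`` measures the gap
    from a read's 3' end to the next read's 5' end: immediately adjacent
    phased reads give distance 1. Default focal lags: 20 for 5'-5'
    (one siRNA length) and 1 for 3'-5' (head-to-tail phasing, Z1).
    """
    if mode not in ("dist_5p_5p_same", "dist_3p_5p_same"):
        raise ValueError(f"unknown mode {mode!r}")
    if focal is None:
        focal = 20 if mode == "dist_5p_5p_same" else 1
    lo, hi = lag_range
    lags = np.arange(lo, hi + 1)
    weights = np.zeros(len(lags))

    five: dict[tuple[str, str], Counter] = defaultdict(Counter)
    three: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for rec in records:
        key = (rec.contig, rec.strand)
        five[key][rec.five_prime] += rec.copies
        three[key][rec.three_prime] += rec.copies

    def pair_mass(a: float, b: float) -> float:
        return min(a, b) if pair_weight == "min" else a * b

    def accumulate_all(src: Counter, dst: Counter, sign: int) -> None:
        for p, c_src in src.items():
            for i, k in enumerate(lags):
                c_dst = dst.get(p + sign * k)
                if c_dst:
                    weights[i] += pair_mass(c_src, c_dst)

    def accumulate_next(src: Counter, dst: Counter, sign: int) -> None:
        # each 3' end pairs only with the nearest downstream 5' end:
        # head-to-tail neighbours, not every read further along
        for p, c_src in src.items():
            for i, k in enumerate(lags):
                c_dst = dst.get(p + sign * k)
                if c_dst:
                    weights[i] += pair_mass(c_src, c_dst)
                    break

    for (contig, strand), fives in five.items():
        sign = 1 if strand == "+" else -1
        if sum(fives.values()) == 0:
            continue
        if mode == "dist_5p_5p_same":
            accumulate_all(fives, fives, sign)
        else:
            accumulate_next(three[(contig, strand)], fives, sign)

    if weights.sum() == 0:
        return Spectrum(mode, lags, weights, focal, 0.0)
    return Spectrum(mode, lags, weights, focal, _z_score(weights, lags, focal))


def first_nt_bias(records: Iterable[AlignmentRecord]) -> dict[str, float]:
    """Copy-weighted fractions of A/C/G/U at read position 1.

    piRNAs typically begin with uridine (the 1U bias); siRNAs do not.
    """
    counts = Counter()
    total = 0.0
    for rec in records:
        if rec.sequence is None:
            continue
        nt = rec.sequence[0].upper().replace("T", "U")
        counts[nt] += rec.copies
        total += rec.copies
    if total == 0:
        raise ValueError("no records carry sequences")
    return {nt: counts.get(nt, 0) / total for nt in "ACGU"}


def length_distribution(
    records: Sequence[AlignmentRecord],
) -> tuple[dict[int, float], float, int]:
    """Copy-weighted length histogram, plus median and modal length.

    The median is computed on the copy-expanded multiset; ties on the
    mode resolve to the smallest length.
    """
    if not records:
        raise ValueError("empty record set")
    hist: Counter = Counter()
    for rec in records:
        hist[rec.length] += rec.copies
    lengths = np.array(sorted(hist))
    counts = np.array([hist[l] for l in lengths], dtype=float)
    cum = np.cumsum(counts)
    total = cum[-1]
    # weighted median of the expanded multiset
    lo_idx = int(np.searchsorted(cum, (total + 1) / 2 - 0.5, side="left"))
    hi_idx = int(np.searchsorted(cum, total / 2 + 0.5, side="left"))
    median = (float(lengths[lo_idx]) + float(lengths[hi_idx])) / 2.0
    mode = int(lengths[int(np.argmax(counts))])
    return dict(zip((int(l) for l in lengths), counts)), median, mode


def transposon_family_age(copies: Sequence[tuple[float, float]]) -> float:
    """Length-weighted mean percent divergence of a transposon family.

    Each copy's divergence is weighted by its length:
    sum(d_i * l_i) / sum(l_i). Young (recently active) families have low
    weighted divergence.
    """
    if not copies:
        raise ValueError("empty transposon family")
    num = 0.0
    den = 0.0
    for divergence, length in copies:
        if length <= 0:
            raise ValueError("copy length must be positive")
        num += divergence * length
        den += length
    return num / den
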