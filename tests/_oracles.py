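"""Independent brute-force oracles, coded with plain Python loops.

These deliberately avoid the package's vectorized code paths so that
agreement between an oracle and the implementation is evidence, not
tautology.
"""

from __future__ import annotations

from collections import Counter


def em_fixed_point(
    unique: list[float],
    placements: list[list[int]],
    copies: list[float],
    tol: float = 1e-13,
    max_iter: int = 20_000,
    fixed_iterations: int | None = None,
) -> tuple[list[float], list[float]]:
    """Fixed point of the window-apportionment iteration, loop by loop.

    Returns (final counts, per-iteration total masses) so callers can
    check read-mass conservation at every step. With ``fixed_iterations``
    the loop runs exactly that many E steps (first with uniform weights)
    instead of stopping on step size.
    """
    n_windows = len(unique)
    total = sum(unique) + sum(copies)
    theta = [1.0] * n_windows
    masses = []
    n_prev = None
    n_steps = fixed_iterations if fixed_iterations is not None else max_iter
    for _ in range(n_steps):
        n = list(unique)
        for wins, c in zip(placements, copies):
            denom = sum(theta[w] for w in wins)
            if denom == 0:
                for w in wins:
                    n[w] += c / len(wins)
            else:
                for w in wins:
                    n[w] += c * theta[w] / denom
        masses.append(sum(n))
        if (
            fixed_iterations is None
            and n_prev is not None
            and sum(abs(a - b) for a, b in zip(n, n_prev)) < tol * max(total, 1.0)
        ):
            return n, masses
        n_prev = n
        theta = n
    return n_prev, masses


def pingpong_spectrum(records, lags) -> dict[int, float]:
    """All-pairs enumeration of opposite-strand 5' overlaps."""
    weights = {k: 0.0 for k in lags}
    plus = [r for r in records if r.strand == "+"]
    minus = [r for r in records if r.strand == "-"]
    for a in plus:
        for b in minus:
            if a.contig != b.contig:
                continue
            overlap = b.five_prime - a.five_prime + 1
            if overlap in weights:
                weights[overlap] += min(a.copies, b.copies)
    return weights


def pingpong_weights_minconv(records, lags) -> dict[int, float]:
    """Per-5'-position-pair weights (min of copies), matching the
    position-collapsed convention the implementation uses."""
    plus = Counter()
    minus = Counter()
    for r in records:
        (plus if r.strand == "+" else minus)[(r.contig, r.five_prime)] += r.copies
    weights = {k: 0.0 for k in lags}
    for (contig, p), cp in plus.items():
        for k in lags:
            cm = minus.get((contig, p + k - 1))
            if cm:
                weights[k] += min(cp, cm)
    return weights


def duplex_pairs_bruteforce(records):
    """O(n^2) scan for 2-nt 3'-overhang duplex geometry over species."""
    species = {}
    for r in records:
        if not (20 <= r.length <= 22):
            continue
        key = (r.contig, r.start, r.end, r.strand)
        species[key] = species.get(key, 0) + r.copies
    pairs = set()
    for (c1, s1, e1, st1), n1 in species.items():
        for (c2, s2, e2, st2), n2 in species.items():
            if st1 != "+" or st2 != "-" or c1 != c2:
                continue
            minus_three = s2
            minus_five = e2 - 1
            plus_five = s1
            plus_three = e1 - 1
            if minus_three == plus_five - 2 and minus_five == plus_three - 2:
                pairs.add(((c1, s1, e1), (c2, s2, e2), n1, n2))
    return pairs


def weighted_median_by_expansion(hist: dict[int, float]) -> float:
    """Median of the copy-expanded multiset, by literal expansion."""
    expanded = []
    for value, count in hist.items():
        expanded.extend([value] * int(count))
    expanded.sort()
    n = len(expanded)
    mid = n // 2
    if n % 2 == 1:
        return float(expanded[mid])
    return (expanded[mid - 1] + expanded[mid]) / 2.0
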