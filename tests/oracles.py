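"""Independent brute-force oracles used to check the implementation.

These deliberately avoid scipy and the package's own code paths: Fisher's
exact test by direct hypergeometric enumeration over all tables with the
observed margins, Spearman's rho by midranking and a hand-written Pearson
formula, and uATG detection by scanning every trinucleotide.
"""

from __future__ import annotations

import math
from fractions import Fraction


def _table_prob(a: int, row1: int, row2: int, col1: int) -> Fraction:
    """Hypergeometric probability of cell a given fixed margins."""
    n = row1 + row2
    return Fraction(
        math.comb(row1, a) * math.comb(row2, col1 - a), math.comb(n, col1)
    )


def fisher_enumerate(
    a: int, b: int, c: int, d: int, sided: str = "two_tailed",
    direction: str | None = None,
) -> float:
    """Exact Fisher P by enumeration of all tables with the same margins.

    ``one_tailed``: tail in the direction of the observed association
    (or a fixed ``direction`` for cell a, 'greater'/'less').
    ``two_tailed``: sum of probabilities of tables whose point probability
    is at most the observed one (with a tiny relative tolerance for
    exactness; Fractions make it truly exact here).
    """
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    if 0 in (row1, row2, col1, col2):
        return 1.0
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    probs = {x: _table_prob(x, row1, row2, col1) for x in range(lo, hi + 1)}
    observed = probs[a]
    if sided == "one_tailed":
        if direction is None:
            expected_a = Fraction(row1 * col1, row1 + row2)
            direction = "greater" if a >= expected_a else "less"
        if direction == "greater":
            tail = sum(p for x, p in probs.items() if x >= a)
        else:
            tail = sum(p for x, p in probs.items() if x <= a)
        return float(tail)
    total = sum(p for p in probs.values() if p <= observed)
    return float(total)


def midranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_brute(xs, ys) -> float:
    """Pearson correlation of midranks, written out longhand."""
    rx, ry = midranks(list(xs)), midranks(list(ys))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)


def atg_positions(sequence: str) -> set[int]:
    return {
        i for i in range(len(sequence) - 2) if sequence[i : i + 3] == "ATG"
    }


def uatg_oracle(sequence: str, position: int, alt: str, cds_offset: int):
    """Scan all trinucleotides before and after the edit."""
    edited = sequence[:position] + alt + sequence[position + 1 :]
    new = atg_positions(edited) - atg_positions(sequence)
    overlapping = {p for p in new if p <= position <= p + 2}
    if not overlapping:
        return False, None
    return True, any((cds_offset - p) % 3 == 0 for p in overlapping)
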