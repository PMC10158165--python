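"""Independent brute-force / arbitrary-precision oracles used by the tests.

These deliberately avoid the code paths they check: exact rational
enumeration for the hypergeometric tail, a naive step-up loop for BH, the
closed-form Pearson statistic for 2x2 tables, and high-precision decimal
logarithms for the alien index.
"""

from decimal import Decimal, getcontext
from fractions import Fraction
from math import comb


def alien_index_oracle(e_in: float, e_out: float) -> float:
    getcontext().prec = 60
    eps = Decimal("1e-200")
    return float((Decimal(e_in) + eps).ln() - (Decimal(e_out) + eps).ln())


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact."""
    total = comb(N, n)
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return Fraction(num, total)


def bh_stepup(ps):
    """Benjamini-Hochberg adjusted p-values by the naive step-up rule."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(ps[i] * m / rank, running)
        adj[i] = running
    return adj


def pearson_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> float:
    """Closed-form Pearson chi-square of the 2x2 table [[a, b], [c, d]]."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        return 0.0
    num = abs(a * d - b * c)
    if yates:
        num = max(num - n / 2.0, 0.0)
    return n * num * num / (r1 * r2 * c1 * c2)


def cooccurrence_counts(og_members):
    """Brute-force shared-OG weights: for every OG, every present species
    pair gets +1."""
    weights = {}
    for by_sp in og_members.values():
        present = sorted(sp for sp, genes in by_sp.items() if genes)
        for i, a in enumerate(present):
            for b in present[i + 1 :]:
                weights[(a, b)] = weights.get((a, b), 0) + 1
    return weights
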