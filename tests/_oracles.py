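"""Independent oracles used by the test suite.

Everything here is computed with exact big-integer rational arithmetic
(fractions.Fraction over math.factorial), deliberately sharing no code with
the package's log-space implementation.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial

__all__ = [
    "exact_conditional_prob",
    "enumerate_tables",
    "multinomial_weight",
    "bootstrap_reference_p",
]


def exact_conditional_prob(D: int, H: int, R: int) -> Fraction:
    """P = N!/(2N)! (2D+H)! (H+2R)! 2^H / (D! H! R!), exactly."""
    N = D + H + R
    nA, na = 2 * D + H, H + 2 * R
    num = factorial(N) * factorial(nA) * factorial(na) * 2**H
    den = factorial(2 * N) * factorial(D) * factorial(H) * factorial(R)
    return Fraction(num, den)


def enumerate_tables(N: int):
    """All two-allele genotype count triples (D, H, R) with D+H+R = N."""
    for D in range(N + 1):
        for H in range(N - D + 1):
            yield (D, H, N - D - H)


def multinomial_weight(table: tuple[int, int, int], probs) -> Fraction:
    """Exact multinomial probability of the table under class probs
    (probs given as Fractions)."""
    D, H, R = table
    N = D + H + R
    coef = Fraction(factorial(N), factorial(D) * factorial(H) * factorial(R))
    return coef * probs[0] ** D * probs[1] ** H * probs[2] ** R


def bootstrap_reference_p(D: int, H: int, R: int) -> Fraction:
    """Exact expectation of the Monte-Carlo bootstrap p-value.

    Replaces the t simulated draws by exhaustive enumeration of every
    multinomial outcome of size N under HW proportions at the observed
    allele frequencies, accumulating the weight of outcomes whose own
    conditional probability P_i (computed with the outcome's own allele
    counts, as the parametric bootstrap prescribes) is <= P_0.  All
    comparisons are exact rational comparisons.
    """
    N = D + H + R
    p = Fraction(2 * D + H, 2 * N)
    q = 1 - p
    g = (p * p, 2 * p * q, q * q)
    p0 = exact_conditional_prob(D, H, R)
    total = Fraction(0)
    for table in enumerate_tables(N):
        if exact_conditional_prob(*table) <= p0:
            total += multinomial_weight(table, g)
    return total
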