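"""Allele frequencies, Hardy-Weinberg expectations, and the conditional
sample probability shared by every exact test.

The central quantity is the probability of observing a particular genotype
table given its own allele counts, under random union of gametes:

    P = N! / (2N)! * prod_a n_a! * 2^h / prod_g c_g!

where n_a are the allele copy counts, c_g the genotype class counts and h
the total number of heterozygous individuals.  For two alleles this is the
classical conditional (Levene) distribution of the heterozygote count, whose
support moves in steps of 2 because the allele counts are fixed.  All
probabilities are computed and compared in log-space: factorials overflow
double precision near N ~ 90, while log-gamma is exact to rounding at any N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .counts import CountsLike, TwoAlleleCounts, allele_counts, as_multi, as_two

__all__ = [
    "AlleleFrequencies",
    "ConditionalDistribution",
    "allele_frequencies",
    "expected_hw_counts",
    "conditional_log_prob",
    "enumerate_two_allele_conditional",
    "fixation_index",
    "LOG_TIE_RTOL",
]

#: Relative tolerance for tie detection when comparing log-probabilities.
LOG_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class AlleleFrequencies:
    """Relative allele frequencies p_i = n_i / 2N (sum to 1)."""

    labels: tuple[str, ...]
    p: np.ndarray

    @property
    def q(self) -> float:
        """Frequency of the second allele (two-allele shorthand)."""
        if len(self.p) != 2:
            raise ValueError("q is defined for two alleles only")
        return float(self.p[1])

    def __getitem__(self, i: int) -> float:
        return float(self.p[i])


@dataclass(frozen=True)
class ConditionalDistribution:
    """Distribution of the heterozygote count h given allele counts (nA, na).

    Support shares the parity of nA and steps by 2; probabilities are the
    exponentiated conditional log-probabilities and sum to 1.
    """

    nA: int
    na: int
    support: np.ndarray  # heterozygote counts h
    log_probs: np.ndarray

    @property
    def probs(self) -> np.ndarray:
        return np.exp(self.log_probs)

    def genotype_counts(self, h: int) -> TwoAlleleCounts:
        return TwoAlleleCounts((self.nA - h) // 2, h, (self.na - h) // 2)


def allele_frequencies(c: CountsLike) -> AlleleFrequencies:
    m = as_multi(c)
    if m.N < 1:
        raise ValueError("allele frequencies require N >= 1")
    ac = allele_counts(m)
    return AlleleFrequencies(labels=m.labels, p=ac.n / (2 * m.N))


def expected_hw_counts(c: CountsLike) -> np.ndarray:
    """Expected genotype counts under HW proportions: N p_i^2 on the diagonal,
    2 N p_i p_j off it.  Returned as a lower-triangular k x k array summing to
    N."""
    m = as_multi(c)
    p = allele_frequencies(m).p
    e = 2 * m.N * np.outer(p, p)
    e[np.diag_indices_from(e)] /= 2
    return np.tril(e)


def conditional_log_prob(c: CountsLike) -> float:
    """ln P of the genotype table given its own allele counts.

    P = N!/(2N)! * prod_a(n_a!) * 2^h / prod_g(c_g!), with h the total
    heterozygote count.  For two alleles this is
    N!/(2N)! * (2D+H)! (H+2R)! 2^H / (D! H! R!).
    """
    m = as_multi(c)
    n = allele_counts(m).n.astype(float)
    cc = m.class_counts.astype(float)
    N = float(m.N)
    return float(
        gammaln(N + 1)
        - gammaln(2 * N + 1)
        + gammaln(n + 1).sum()
        + m.het_total * np.log(2.0)
        - gammaln(cc + 1).sum()
    )


def conditional_log_prob_batch(
    class_counts: np.ndarray, allele_incidence: np.ndarray, is_het: np.ndarray
) -> np.ndarray:
    """Vectorized ln P for a (t, m) matrix of genotype class-count rows.

    ``allele_incidence`` is the (m, k) matrix mapping class counts to allele
    copy counts (2 for a homozygote's allele, 1 for each of a heterozygote's);
    ``is_het`` flags heterozygous classes.  Each row is scored against its
    OWN allele counts, which is what the parametric bootstrap requires.
    """
    cc = np.asarray(class_counts, dtype=float)
    N = cc.sum(axis=1)
    n = cc @ allele_incidence
    h = cc @ is_het.astype(float)
    return (
        gammaln(N + 1)
        - gammaln(2 * N + 1)
        + gammaln(n + 1).sum(axis=1)
        + h * np.log(2.0)
        - gammaln(cc + 1).sum(axis=1)
    )


def allele_incidence(k: int) -> tuple[np.ndarray, np.ndarray]:
    """(m, k) class-to-allele-copy matrix and heterozygote flag vector for the
    canonical class ordering (i, j), i >= j."""
    classes = [(i, j) for i in range(k) for j in range(i + 1)]
    A = np.zeros((len(classes), k))
    het = np.zeros(len(classes), dtype=bool)
    for g, (i, j) in enumerate(classes):
        if i == j:
            A[g, i] = 2
        else:
            A[g, i] = 1
            A[g, j] = 1
            het[g] = True
    return A, het


def enumerate_two_allele_conditional(nA: int, na: int) -> ConditionalDistribution:
    """Full conditional distribution of h for two alleles.

    Support runs over h = min-parity .. min(nA, na) in steps of 2 (h must
    share the parity of nA since D = (nA - h)/2 is an integer).
    """
    if nA < 0 or na < 0:
        raise ValueError("allele counts must be non-negative")
    if (nA + na) % 2 != 0:
        raise ValueError(f"nA + na = {nA + na} must be even (2N allele copies)")
    if nA + na < 2:
        raise ValueError("at least one individual (two allele copies) required")
    start = nA % 2
    support = np.arange(start, min(nA, na) + 1, 2, dtype=np.int64)
    log_probs = np.array(
        [
            conditional_log_prob(
                TwoAlleleCounts((nA - h) // 2, int(h), (na - h) // 2)
            )
            for h in support
        ]
    )
    return ConditionalDistribution(nA=nA, na=na, support=support, log_probs=log_probs)


def fixation_index(c: CountsLike) -> float:
    """Fixation index F = 1 - (H/N)/(2pq), the standardized heterozygote
    deficit; F = 0 at HW proportions, F = 1 with no heterozygotes, F = -1
    when all individuals are heterozygous (p = q = 1/2)."""
    t = as_two(c)
    f = allele_frequencies(t)
    p, q = f[0], f[1]
    if p == 0.0 or p == 1.0:
        raise ValueError("fixation index undefined for a monomorphic sample")
    return 1.0 - (t.H / t.N) / (2 * p * q)


def log_tie_le(log_a: np.ndarray, log_b: float, rtol: float = LOG_TIE_RTOL) -> np.ndarray:
    """Elementwise a <= b on log-probabilities, counting near-ties as <=.

    Discrete exact tests must include outcomes exactly as probable as the
    observed one; floating-point log-gamma makes exact equality unreliable, so
    ties are detected within a relative tolerance and counted into the tail.
    """
    tol = rtol * np.maximum(1.0, np.abs(log_b))
    return np.asarray(log_a) <= log_b + tol
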