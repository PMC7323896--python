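"""Asymptotic goodness-of-fit tests against Hardy-Weinberg proportions.

Four families are provided for two alleles — Pearson chi-squared and the G
(log-likelihood ratio) test, each with and without continuity correction —
plus two refinements that account for the sampling being conditional on the
observed allele counts: the Hogben/Levene chi-squared against the exact
conditional expectations, and the Cannings & Edwards correction that
recognizes the step-2 support of the heterozygote count.  For k alleles only
the uncorrected Pearson chi-squared applies (df = k(k-1)/2); the continuity
correction is appropriate only in the two-allele case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .core import allele_counts, allele_frequencies, expected_hw_counts
from .counts import CountsLike, as_multi, as_two

__all__ = [
    "TestResult",
    "chi_square_test",
    "g_test",
    "levene_hogben_test",
    "cannings_edwards_test",
    "PVALUE_CAUTION",
]

#: Below this p-value, a caution is attached: such extreme results could
#: result exclusively from genotyping errors with a large probability.
PVALUE_CAUTION = 1e-6

_CAUTION_NOTE = (
    "P < 1e-6: consider this result cautiously; it could result exclusively "
    "from genotyping errors"
)


@dataclass(frozen=True)
class TestResult:
    """One test's outcome: statistic and df where an asymptotic reference
    distribution exists, the p-value always, replicate info for Monte-Carlo
    tests."""

    method: str
    p_value: float
    statistic: float | None = None
    df: int | None = None
    correction: bool = False
    replicates: int | None = None
    extreme: int | None = None  # Monte-Carlo tail count T in p = T/t
    notes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _with_caution(notes: tuple[str, ...], p: float) -> tuple[str, ...]:
    if p < PVALUE_CAUTION:
        return notes + (_CAUTION_NOTE,)
    return notes


def _finish(method, stat, df, correction=False) -> TestResult:
    p = float(chi2_dist.sf(stat, df))
    return TestResult(
        method=method,
        statistic=float(stat),
        df=df,
        p_value=p,
        correction=correction,
        notes=_with_caution((), p),
    )


def chi_square_test(c: CountsLike, correction: bool = False) -> TestResult:
    """Pearson chi-squared against HW expectations, df = k(k-1)/2.

    With ``correction`` (two alleles only) each |o - e| is reduced by 0.5,
    floored at 0, before squaring (Yates).  Cells with zero expectation (and
    hence zero observation, since e derives from o) contribute nothing.
    """
    m = as_multi(c)
    o = m.class_counts.astype(float)
    e = expected_hw_counts(m)
    e = np.array([e[i, j] for i, j in m.genotype_classes])
    if correction and m.k != 2:
        raise ValueError("continuity correction is appropriate only for two alleles")
    assert not np.any((e == 0) & (o > 0)), "observed count in a zero-expectation cell"
    mask = e > 0
    dev = np.abs(o[mask] - e[mask])
    if correction:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float(np.sum(dev**2 / e[mask]))
    df = m.k * (m.k - 1) // 2
    name = "Chi-squared" + (" with continuity correction" if correction else "")
    return _finish(name, stat, df, correction)


def g_test(c: CountsLike, correction: bool = False) -> TestResult:
    """G (log-likelihood ratio) test, G = 2 sum o ln(o/e), df = 1.

    The continuity-corrected variant moves the observed counts half a lattice
    step toward their expectations before forming the log terms (the
    heterozygote count by 1, each homozygote by 0.5, never crossing), the
    Yates analogue for this design.  With observed allele frequencies the
    three deviations are locked together (D - e_D = R - e_R = -(H - e_H)/2),
    so the shrinkage moves along that line: it preserves N and the allele
    counts, and G decreases monotonically along it, so the corrected G never
    exceeds the uncorrected one.
    """
    t = as_two(c)
    o = np.array([t.D, t.H, t.R], dtype=float)
    e = expected_hw_counts(t)
    e = np.array([e[0, 0], e[1, 0], e[1, 1]])
    if correction:
        x = o[1] - e[1]  # heterozygote deviation drives all three
        shrink = np.sign(x) * min(1.0, abs(x))
        o = o + np.array([shrink / 2.0, -shrink, shrink / 2.0])
    mask = o > 0
    stat = float(2.0 * np.sum(o[mask] * np.log(o[mask] / e[mask])))
    stat = max(stat, 0.0)
    name = "G-test" + (" with continuity correction" if correction else "")
    return _finish(name, stat, 1, correction)


def levene_hogben_test(c: CountsLike) -> TestResult:
    """Chi-squared against the exact conditional (Levene) expectations.

    Conditioning on the observed allele counts (nA, na) gives
    E[H] = nA na / (2N - 1), E[D] = nA(nA-1) / (2(2N-1)),
    E[R] = na(na-1) / (2(2N-1)); these sum to N exactly.
    """
    t = as_two(c)
    nA, na = (int(x) for x in allele_counts(t).n)
    if nA == 0 or na == 0:
        raise ValueError("Levene expectations undefined for a monomorphic sample")
    N = t.N
    denom = 2 * N - 1
    eD = nA * (nA - 1) / (2 * denom)
    eH = nA * na / denom
    eR = na * (na - 1) / (2 * denom)
    o = np.array([t.D, t.H, t.R], dtype=float)
    e = np.array([eD, eH, eR])
    mask = e > 0
    stat = float(np.sum((o[mask] - e[mask]) ** 2 / e[mask]))
    return _finish("Hogben/Levene chi-squared", stat, 1)


def cannings_edwards_test(c: CountsLike) -> TestResult:
    """Step-aware continuity-corrected chi-squared.

    Given fixed allele counts the heterozygote count moves in steps of 2, so
    its deviation from expectation is reduced by 1 (half a step) while each
    homozygote deviation is reduced by 0.5, all floored at 0; the corrected
    deviations are squared against the unconditional HW expectations.
    """
    t = as_two(c)
    f = allele_frequencies(t)
    if f[0] in (0.0, 1.0):
        raise ValueError("test undefined for a monomorphic sample")
    e = expected_hw_counts(t)
    e = np.array([e[0, 0], e[1, 0], e[1, 1]])
    o = np.array([t.D, t.H, t.R], dtype=float)
    reduction = np.array([0.5, 1.0, 0.5])
    dev = np.maximum(np.abs(o - e) - reduction, 0.0)
    stat = float(np.sum(dev**2 / e))
    return _finish("Cannings & Edwards chi-squared", stat, 1, correction=True)
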