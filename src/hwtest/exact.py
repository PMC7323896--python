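"""Conditional exact tests and the Monte-Carlo (parametric bootstrap) exact
test.

Fisher's and Haldane's tests enumerate the full conditional distribution of
the heterozygote count given the observed allele counts; they differ only in
how "at least as extreme" is ordered.  Fisher sums the probabilities of all
outcomes no more probable than the observed one (probability ordering);
Haldane sums those at least as far from the conditional mean
E[h] = nA na / (2N - 1) (deviation ordering).  The two agree whenever the
conditional distribution is symmetric.

The bootstrap exact test works for any number of alleles: t samples of size
N are drawn from HW proportions at the observed allele frequencies, each
simulated sample's conditional probability P_i is computed with that
sample's OWN allele counts, and the p-value is P = T/t where T counts the
replicates with P_i <= P_0.  This is a parametric bootstrap — the allele
frequencies are re-estimated within each replicate — and is deliberately
distinct from conditional permutation schemes that hold allele counts fixed.
"""

from __future__ import annotations

import numpy as np

from .asymptotic import TestResult, _with_caution
from .core import (
    allele_counts,
    allele_frequencies,
    allele_incidence,
    conditional_log_prob,
    conditional_log_prob_batch,
    enumerate_two_allele_conditional,
    log_tie_le,
)
from .counts import CountsLike, as_multi, as_two
from .simulate import hw_probs, sample_class_counts, task_rng

__all__ = [
    "fisher_exact",
    "haldane_exact",
    "bootstrap_exact",
    "DEFAULT_REPLICATES",
]

#: Default number of Monte-Carlo replicates for the bootstrap exact test.
DEFAULT_REPLICATES = 1000


def fisher_exact(c: CountsLike) -> TestResult:
    """Conditional exact test with probability ordering.

    p = sum of conditional probabilities of all heterozygote counts whose
    probability is <= that of the observed count (ties included).
    """
    t = as_two(c)
    nA, na = (int(x) for x in allele_counts(t).n)
    dist = enumerate_two_allele_conditional(nA, na)
    log_p_obs = conditional_log_prob(t)
    tail = log_tie_le(dist.log_probs, log_p_obs)
    p = float(min(dist.probs[tail].sum(), 1.0))
    return TestResult(
        method="Fisher's exact test", p_value=p, notes=_with_caution((), p)
    )


def haldane_exact(c: CountsLike) -> TestResult:
    """Conditional exact test with deviation ordering around the conditional
    mean E[h] = nA na / (2N - 1)."""
    t = as_two(c)
    nA, na = (int(x) for x in allele_counts(t).n)
    dist = enumerate_two_allele_conditional(nA, na)
    e_h = nA * na / (2 * t.N - 1)
    obs_dev = abs(t.H - e_h)
    tail = np.abs(dist.support - e_h) >= obs_dev - 1e-9
    p = float(min(dist.probs[tail].sum(), 1.0))
    return TestResult(
        method="Haldane's exact test", p_value=p, notes=_with_caution((), p)
    )


def bootstrap_exact(
    c: CountsLike,
    t: int = DEFAULT_REPLICATES,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> TestResult:
    """Monte-Carlo exact test for 2 or k alleles, p = T/t.

    P_0 is the conditional probability of the observed table; each of the t
    replicates is a fresh sample of size N from HW proportions at the
    observed allele frequencies, scored by the same formula with its own
    allele counts.  T counts replicates with P_i <= P_0 (log-space
    comparison, near-ties counted as <=).  Deterministic given the seed.
    """
    m = as_multi(c)
    if t < 1:
        raise ValueError("replicate count must be >= 1")
    if rng is None:
        rng = task_rng(seed, "bootstrap_test")
    log_p0 = conditional_log_prob(m)
    probs = hw_probs(allele_frequencies(m))
    counts = sample_class_counts(probs, m.N, t, rng)
    A, het = allele_incidence(m.k)
    log_pi = conditional_log_prob_batch(counts, A, het)
    T = int(np.count_nonzero(log_tie_le(log_pi, log_p0)))
    p = T / t
    return TestResult(
        method="Bootstrap exact test",
        p_value=p,
        replicates=t,
        extreme=T,
        notes=_with_caution((), p),
    )
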