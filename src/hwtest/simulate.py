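"""Seeded simulation of genotype samples by the cumulative-uniform method.

Each simulated individual is classified by drawing one uniform number in
[0, 1] and comparing it against the cumulative genotype probabilities: a
draw smaller than or equal to the first boundary is the first genotype
class, and so on.  This per-individual scheme is the shared engine behind
the Monte-Carlo exact test, the bootstrap confidence intervals and the
scatter clouds of the de Finetti diagram.

A single root seed drives everything; each task (bootstrap test, confidence
intervals, plot clouds) draws from its own deterministically derived
substream so results are reproducible piecewise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AlleleFrequencies
from .counts import MultiAlleleCounts

__all__ = [
    "GenotypeProbabilities",
    "hw_probs",
    "observed_probs",
    "sample_genotypes",
    "sample_class_counts",
    "task_rng",
]

# stable substream identifiers per task; the root seed plus one of these
# forms the SeedSequence entropy, so tasks never share a stream
_TASK_IDS = {
    "bootstrap_test": 1,
    "ci_observed": 2,
    "ci_expected": 3,
    "cloud_hw": 4,
    "cloud_observed": 5,
}


def task_rng(seed: int, task: str) -> np.random.Generator:
    """Independent, reproducible generator for a named task."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _TASK_IDS[task]]))


@dataclass(frozen=True)
class GenotypeProbabilities:
    """Probabilities over the k(k+1)/2 genotype classes, in canonical class
    order ((0,0), (1,0), (1,1), ...; AA, Aa, aa for two alleles)."""

    labels: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        s = float(np.sum(self.probs))
        if abs(s - 1.0) > 1e-12 or np.any(np.asarray(self.probs) < 0):
            raise ValueError(f"genotype probabilities must sum to 1, got {s}")

    @property
    def k(self) -> int:
        return len(self.labels)


def hw_probs(f: AlleleFrequencies) -> GenotypeProbabilities:
    """HW genotype probabilities: p_i^2 for homozygotes, 2 p_i p_j for
    heterozygotes."""
    p = np.asarray(f.p, dtype=float)
    k = len(p)
    probs = np.array(
        [p[i] ** 2 if i == j else 2 * p[i] * p[j] for i in range(k) for j in range(i + 1)]
    )
    probs = probs / probs.sum()  # remove rounding drift; exact sum is 1
    return GenotypeProbabilities(labels=f.labels, probs=probs)


def observed_probs(c: MultiAlleleCounts) -> GenotypeProbabilities:
    """Observed relative genotype frequencies {d, h, r, ...} = counts / N."""
    if c.N < 1:
        raise ValueError("observed frequencies require N >= 1")
    return GenotypeProbabilities(labels=c.labels, probs=c.class_counts / c.N)


def _classify(u: np.ndarray, probs: np.ndarray) -> np.ndarray:
    # "smaller than or equal to" the cumulative boundary => the earlier class
    cum = np.cumsum(probs)
    idx = np.searchsorted(cum, u, side="left")
    return np.minimum(idx, len(probs) - 1)  # guard u > cum[-1] rounding slack


def sample_class_counts(
    g: GenotypeProbabilities, n: int, t: int, rng: np.random.Generator
) -> np.ndarray:
    """(t, m) matrix of genotype class counts: t independent samples of n
    individuals each, classified per individual by the cumulative-uniform
    method."""
    if n < 1 or t < 1:
        raise ValueError("n and t must be >= 1")
    m = len(g.probs)
    u = rng.random((t, n))
    idx = _classify(u, g.probs)
    flat = idx + np.arange(t)[:, None] * m
    return np.bincount(flat.ravel(), minlength=t * m).reshape(t, m)


def sample_genotypes(
    g: GenotypeProbabilities, n: int, rng: np.random.Generator
) -> MultiAlleleCounts:
    """One simulated sample of n individuals as a genotype count table."""
    counts = sample_class_counts(g, n, 1, rng)[0]
    return MultiAlleleCounts.from_class_counts(g.labels, counts)
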