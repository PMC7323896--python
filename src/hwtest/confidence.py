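"""95% confidence intervals for observed and expected genotype frequencies.

Two flavors per class: the Gaussian (Wald) approximation for a binomial
proportion, f +/- 1.96 sqrt(f(1-f)/N), and percentile bootstrap intervals
(2.5th-97.5th empirical percentiles over simulated replicates).  Observed-
frequency bootstrap intervals resample at the observed class frequencies;
expected-frequency intervals resample at HW proportions and recompute each
replicate's expected frequencies from that replicate's own allele counts,
mirroring the parametric resampling of the bootstrap test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import allele_incidence, allele_frequencies, expected_hw_counts
from .counts import CountsLike, as_multi
from .simulate import hw_probs, observed_probs, sample_class_counts, task_rng

__all__ = ["ClassInterval", "IntervalReport", "wald_intervals", "bootstrap_intervals"]

Z95 = 1.96  # fixed 95% level


@dataclass
class ClassInterval:
    label: str
    observed: float
    expected: float
    wald_obs: tuple[float, float] | None = None
    wald_exp: tuple[float, float] | None = None
    boot_obs: tuple[float, float] | None = None
    boot_exp: tuple[float, float] | None = None


@dataclass
class IntervalReport:
    classes: list[ClassInterval]
    replicates: int | None = None

    def __getitem__(self, label: str) -> ClassInterval:
        for ci in self.classes:
            if ci.label == label:
                return ci
        raise KeyError(label)


def _wald(f: np.ndarray, N: int) -> tuple[np.ndarray, np.ndarray]:
    half = Z95 * np.sqrt(f * (1.0 - f) / N)
    return np.clip(f - half, 0.0, 1.0), np.clip(f + half, 0.0, 1.0)


def _base_report(m) -> IntervalReport:
    o = m.class_counts / m.N
    e_tab = expected_hw_counts(m)
    e = np.array([e_tab[i, j] for i, j in m.genotype_classes]) / m.N
    return IntervalReport(
        classes=[
            ClassInterval(label=lab, observed=float(fo), expected=float(fe))
            for lab, fo, fe in zip(m.class_labels, o, e)
        ]
    )


def wald_intervals(c: CountsLike) -> IntervalReport:
    """Wald 95% intervals for each class's observed and expected frequency,
    clipped to [0, 1]; a frequency of 0 or 1 has zero Wald variance."""
    m = as_multi(c)
    rep = _base_report(m)
    o = np.array([ci.observed for ci in rep.classes])
    e = np.array([ci.expected for ci in rep.classes])
    o_lo, o_hi = _wald(o, m.N)
    e_lo, e_hi = _wald(e, m.N)
    for i, ci in enumerate(rep.classes):
        ci.wald_obs = (float(o_lo[i]), float(o_hi[i]))
        ci.wald_exp = (float(e_lo[i]), float(e_hi[i]))
    return rep


def _percentiles(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = np.percentile(freqs, 2.5, axis=0)
    hi = np.percentile(freqs, 97.5, axis=0)
    return np.clip(lo, 0.0, 1.0), np.clip(hi, 0.0, 1.0)


def bootstrap_intervals(
    c: CountsLike,
    t: int = 1000,
    rng_obs: np.random.Generator | None = None,
    rng_exp: np.random.Generator | None = None,
    seed: int = 0,
) -> IntervalReport:
    """Percentile bootstrap 95% intervals, t >= 100 replicates.

    Observed part: t samples of size N at the observed class frequencies;
    the 2.5/97.5 percentiles of each class's relative frequency.  Expected
    part: t samples at HW proportions; each replicate's expected class
    frequencies are recomputed from its own allele counts before taking
    percentiles.  Deterministic given the seed.
    """
    m = as_multi(c)
    if t < 100:
        raise ValueError("bootstrap intervals need at least 100 replicates")
    if rng_obs is None:
        rng_obs = task_rng(seed, "ci_observed")
    if rng_exp is None:
        rng_exp = task_rng(seed, "ci_expected")
    rep = _base_report(m)

    obs_counts = sample_class_counts(observed_probs(m), m.N, t, rng_obs)
    o_lo, o_hi = _percentiles(obs_counts / m.N)

    hw_counts = sample_class_counts(hw_probs(allele_frequencies(m)), m.N, t, rng_exp)
    A, _ = allele_incidence(m.k)
    p_rep = (hw_counts @ A) / (2.0 * m.N)  # (t, k) per-replicate allele freqs
    classes = m.genotype_classes
    e_freq = np.empty((t, len(classes)))
    for g, (i, j) in enumerate(classes):
        if i == j:
            e_freq[:, g] = p_rep[:, i] ** 2
        else:
            e_freq[:, g] = 2.0 * p_rep[:, i] * p_rep[:, j]
    e_lo, e_hi = _percentiles(e_freq)

    for g, ci in enumerate(rep.classes):
        ci.boot_obs = (float(o_lo[g]), float(o_hi[g]))
        ci.boot_exp = (float(e_lo[g]), float(e_hi[g]))
    rep.replicates = t
    return rep
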