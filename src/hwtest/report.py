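"""Plain-text report rendering for the CLI."""

from __future__ import annotations

import numpy as np

from .asymptotic import TestResult
from .confidence import IntervalReport
from .core import allele_counts, allele_frequencies, expected_hw_counts, fixation_index
from .counts import MultiAlleleCounts, ValidationReport

__all__ = ["format_report"]


def _sig(x: float, digits: int = 6) -> str:
    return f"{x:.{digits}g}"


def _interval(iv: tuple[float, float] | None) -> str:
    if iv is None:
        return "-"
    return f"[{_sig(iv[0])}, {_sig(iv[1])}]"


def _test_line(t: TestResult) -> list[str]:
    parts = [f"{t.method}:"]
    if t.statistic is not None:
        parts.append(f"statistic = {_sig(t.statistic)}")
    if t.df is not None:
        parts.append(f"df = {t.df}")
    if t.replicates is not None and t.extreme is not None:
        parts.append(f"P = {t.extreme}/{t.replicates} = {_sig(t.p_value)}")
    else:
        parts.append(f"P = {_sig(t.p_value)}")
    lines = ["  " + "  ".join(parts)]
    for note in t.notes:
        lines.append(f"    note: {note}")
    return lines


def format_report(
    c: MultiAlleleCounts,
    validation: ValidationReport,
    tests: list[TestResult],
    intervals: IntervalReport | None = None,
) -> str:
    """Assemble the full text report: counts, frequencies, expectations,
    test results, confidence intervals and advisories."""
    lines: list[str] = []
    lines.append(f"Hardy-Weinberg test report  (k = {c.k} alleles, N = {c.N})")
    lines.append("")

    freqs = allele_frequencies(c)
    ac = allele_counts(c)
    lines.append("Allele counts and frequencies:")
    for lab, n, p in zip(c.labels, ac.n, freqs.p):
        lines.append(f"  {lab}: n = {int(n)}  freq = {_sig(float(p))}")
    if c.k == 2 and 0.0 < freqs[0] < 1.0:
        lines.append(f"  fixation index F = {_sig(fixation_index(c))}")
    lines.append("")

    e_tab = expected_hw_counts(c)
    lines.append("Genotype counts (observed / HW expected):")
    for (i, j), lab, o in zip(c.genotype_classes, c.class_labels, c.class_counts):
        lines.append(f"  {lab}: {int(o)} / {_sig(float(e_tab[i, j]))}")
    lines.append("")

    lines.append("Tests:")
    for t in tests:
        lines.extend(_test_line(t))
    lines.append("  (tests are applied to the same data and are not independent)")
    lines.append("")

    if intervals is not None:
        lines.append("95% confidence intervals for genotype frequencies:")
        header = (
            f"  {'class':<8}{'obs':>10}{'Wald obs':>24}{'boot obs':>24}"
            f"{'exp':>10}{'Wald exp':>24}{'boot exp':>24}"
        )
        lines.append(header)
        for ci in intervals.classes:
            lines.append(
                f"  {ci.label:<8}{_sig(ci.observed):>10}"
                f"{_interval(ci.wald_obs):>24}{_interval(ci.boot_obs):>24}"
                f"{_sig(ci.expected):>10}"
                f"{_interval(ci.wald_exp):>24}{_interval(ci.boot_exp):>24}"
            )
        if intervals.replicates:
            lines.append(
                f"  (bootstrap intervals from {intervals.replicates} replicates)"
            )
        lines.append("")

    for w in validation.warnings:
        lines.append(f"Advisory: {w}")
    return "\n".join(lines).rstrip() + "\n"
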