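"""Genotype count containers, validation rules and the counts-CSV reader.

Genotype data enter as absolute counts only: for two alleles the triple
(D, H, R) = (n_AA, n_Aa, n_aa), and for k alleles a lower-triangular table
c_ij (1 <= j <= i <= k) where the diagonal holds homozygote counts and the
off-diagonal cells unordered heterozygote counts.  Validation mirrors the
program's input rules: samples of total size below 5 or with two empty
genotype classes are rejected outright in the two-allele case, and small
samples (N <= 20, or N <= 10k for k alleles) only earn an advisory, because
the Hardy-Weinberg null is essentially never rejectable at such sizes.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "TwoAlleleCounts",
    "MultiAlleleCounts",
    "AlleleCounts",
    "ValidationReport",
    "validate_two_allele",
    "validate_multi_allele",
    "allele_counts",
    "read_counts_file",
    "write_counts_file",
    "as_multi",
    "as_two",
]


@dataclass(frozen=True)
class TwoAlleleCounts:
    """Observed genotype counts for a biallelic autosomal locus."""

    D: int  # AA homozygotes
    H: int  # Aa heterozygotes
    R: int  # aa homozygotes

    def __post_init__(self) -> None:
        for name in ("D", "H", "R"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def N(self) -> int:
        return int(self.D + self.H + self.R)

    def to_multi(self, labels: tuple[str, str] = ("A", "a")) -> "MultiAlleleCounts":
        table = np.zeros((2, 2), dtype=np.int64)
        table[0, 0] = self.D
        table[1, 0] = self.H
        table[1, 1] = self.R
        return MultiAlleleCounts(labels=tuple(labels), table=table)


class MultiAlleleCounts:
    """Lower-triangular k x k genotype count table, k >= 2.

    ``table[i, j]`` for i >= j holds the count of genotype (allele_i,
    allele_j); the strict upper triangle must be zero (genotype cells are
    unordered).  Genotype classes are ordered row-major over the lower
    triangle: (0,0), (1,0), (1,1), (2,0), ... which for two alleles labelled
    (A, a) is the conventional (AA, Aa, aa).
    """

    def __init__(self, labels: Sequence[str], table: np.ndarray) -> None:
        labels = tuple(str(x) for x in labels)
        if len(labels) < 2:
            raise ValueError("at least two alleles are required")
        if len(set(labels)) != len(labels):
            raise ValueError(f"allele labels must be unique: {labels}")
        table = np.asarray(table)
        k = len(labels)
        if table.shape != (k, k):
            raise ValueError(f"table must be {k}x{k}, got {table.shape}")
        if not np.issubdtype(table.dtype, np.integer):
            if not np.all(table == np.floor(table)):
                raise ValueError("genotype counts must be integers")
            table = table.astype(np.int64)
        if np.any(table < 0):
            raise ValueError("genotype counts must be non-negative")
        if np.any(np.triu(table, k=1) != 0):
            raise ValueError("strict upper triangle must be zero (unordered cells)")
        self.labels = labels
        self.table = table.astype(np.int64)
        self.table.setflags(write=False)

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def N(self) -> int:
        return int(self.table.sum())

    @property
    def genotype_classes(self) -> list[tuple[int, int]]:
        """Index pairs (i, j), i >= j, in class order."""
        return [(i, j) for i in range(self.k) for j in range(i + 1)]

    @property
    def class_labels(self) -> list[str]:
        return [
            self.labels[j] + self.labels[i] if i != j else self.labels[i] * 2
            for i, j in self.genotype_classes
        ]

    @property
    def class_counts(self) -> np.ndarray:
        """Counts as a vector in class order."""
        return np.array([self.table[i, j] for i, j in self.genotype_classes])

    @property
    def het_total(self) -> int:
        """Total number of heterozygous individuals."""
        return int(self.table.sum() - np.trace(self.table))

    def to_two_allele(self) -> TwoAlleleCounts:
        if self.k != 2:
            raise ValueError(f"table has {self.k} alleles, not 2")
        return TwoAlleleCounts(
            int(self.table[0, 0]), int(self.table[1, 0]), int(self.table[1, 1])
        )

    @classmethod
    def from_class_counts(
        cls, labels: Sequence[str], counts: Sequence[int]
    ) -> "MultiAlleleCounts":
        k = len(labels)
        counts = list(counts)
        if len(counts) != k * (k + 1) // 2:
            raise ValueError(
                f"expected {k * (k + 1) // 2} genotype classes, got {len(counts)}"
            )
        table = np.zeros((k, k), dtype=np.int64)
        pos = 0
        for i in range(k):
            for j in range(i + 1):
                table[i, j] = counts[pos]
                pos += 1
        return cls(labels, table)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, MultiAlleleCounts)
            and self.labels == other.labels
            and np.array_equal(self.table, other.table)
        )

    def __repr__(self) -> str:
        return f"MultiAlleleCounts(labels={self.labels!r}, N={self.N})"


@dataclass(frozen=True)
class AlleleCounts:
    """Allele copy counts n_i = 2*c_ii + sum_{j != i} c_ij; sums to 2N."""

    labels: tuple[str, ...]
    n: np.ndarray

    @property
    def total(self) -> int:
        return int(self.n.sum())


@dataclass
class ValidationReport:
    """Fatal errors and advisories from input validation.

    Violations are reported, never raised: the CLI prints the advisory
    language and exits, while a library caller may choose its own strictness.
    """

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


CountsLike = Union[TwoAlleleCounts, MultiAlleleCounts]


def as_multi(c: CountsLike) -> MultiAlleleCounts:
    return c.to_multi() if isinstance(c, TwoAlleleCounts) else c


def as_two(c: CountsLike) -> TwoAlleleCounts:
    return c if isinstance(c, TwoAlleleCounts) else c.to_two_allele()


def validate_two_allele(c: TwoAlleleCounts) -> ValidationReport:
    """Apply the two-allele input rules.

    Fatal: N < 5, or two (or more) of the three genotype classes empty.
    Advisory: N <= 20 (the null is rarely rejectable at such sizes, and a
    rejection more likely reflects genotyping error than real disequilibrium).
    Complete heterozygote absence with both homozygote classes present is
    accepted: that is the interesting disequilibrium case, not a data defect.
    """
    rep = ValidationReport()
    if c.N < 5:
        rep.errors.append(
            f"total sample size N = {c.N} is below the minimum of 5"
        )
    zeros = sum(1 for v in (c.D, c.H, c.R) if v == 0)
    if zeros >= 2:
        rep.errors.append(
            "two (or more) genotype classes are empty; "
            "the data are degenerate for Hardy-Weinberg testing"
        )
    if rep.ok and c.N <= 20:
        rep.warnings.append(
            f"N = {c.N} <= 20: the null hypothesis of HW proportions is rarely "
            "rejected with such small sample sizes; a rejection here should "
            "raise suspicion of genotyping error"
        )
    return rep


def validate_multi_allele(c: MultiAlleleCounts) -> ValidationReport:
    """Apply the k-allele input rules (advisories only beyond N >= 1)."""
    rep = ValidationReport()
    if c.N < 1:
        rep.errors.append("empty table: at least one genotype observation required")
        return rep
    if c.N <= 10 * c.k:
        rep.warnings.append(
            f"N = {c.N} <= 10k = {10 * c.k}: sample too small for a meaningful "
            f"test with k = {c.k} alleles"
        )
    n = allele_counts(c).n
    n_classes = c.k * (c.k + 1) // 2
    zero_cells = int(np.sum(c.class_counts == 0))
    if np.any(n == 0) or zero_cells > n_classes // 2:
        rep.warnings.append(
            "unobserved alleles or many empty genotype cells: consider "
            "agglutinating rare allele classes to improve the power of the "
            "test"
        )
    if n_classes > c.N:
        rep.warnings.append(
            f"more genotype classes ({n_classes}) than observations ({c.N})"
        )
    return rep


def allele_counts(c: CountsLike) -> AlleleCounts:
    """Allele copy counts: n_i = 2*c_ii + sum over heterozygote cells with i."""
    m = as_multi(c)
    sym = m.table + m.table.T  # doubles the diagonal, symmetrizes the rest
    return AlleleCounts(labels=m.labels, n=sym.sum(axis=1))


# ---------------------------------------------------------------------------
# counts-CSV dialect
#
#   # comment lines ignored
#   alleles,<label1>,<label2>,...
#   <rowlabel>,<c_i1>,...,<c_ii>        (lower-triangular; blank upper cells
#                                        permitted; symmetric duplicates must
#                                        agree)
# ---------------------------------------------------------------------------


class CountsParseError(ValueError):
    """Raised when a counts-CSV file violates the dialect."""


def _parse_cell(text: str, where: str) -> int:
    try:
        value = int(text)
    except ValueError:
        raise CountsParseError(f"non-integer count {text!r} at {where}") from None
    if value < 0:
        raise CountsParseError(f"negative count {value} at {where}")
    return value


def read_counts_file(path: Union[str, Path, io.TextIOBase]) -> MultiAlleleCounts:
    """Read a genotype count table in the counts-CSV dialect.

    The number of alleles k is inferred from the header; rows may carry the
    full k cells (symmetric entries must then agree) or only the first i
    (lower-triangular form).
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
        name = getattr(path, "name", "<stream>")
    else:
        name = str(path)
        lines = Path(path).read_text(encoding="utf-8").splitlines()
    rows = [
        r
        for r in csv.reader(lines)
        if r and not r[0].lstrip().startswith("#") and any(x.strip() for x in r)
    ]
    if not rows:
        raise CountsParseError(f"{name}: empty counts file")
    header = [x.strip() for x in rows[0]]
    if header[0].lower() != "alleles" or len(header) < 3:
        raise CountsParseError(
            f"{name}: first line must be 'alleles,<label1>,<label2>,...'"
        )
    labels = header[1:]
    if len(set(labels)) != len(labels):
        raise CountsParseError(f"{name}: duplicate allele labels in header")
    k = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    table = np.full((k, k), -1, dtype=np.int64)  # -1 = not yet given
    for r, row in enumerate(rows[1:], start=2):
        cells = [x.strip() for x in row]
        lab = cells[0]
        if lab not in index:
            raise CountsParseError(f"{name}:{r}: unknown row label {lab!r}")
        i = index[lab]
        if len(cells) - 1 > k:
            raise CountsParseError(f"{name}:{r}: more than {k} count cells")
        for col, text in enumerate(cells[1:]):
            if text == "":
                continue
            j = col
            value = _parse_cell(text, f"{name}:{r} column {j + 2}")
            lo, hi = (i, j) if i >= j else (j, i)
            if table[lo, hi] >= 0 and table[lo, hi] != value:
                raise CountsParseError(
                    f"{name}:{r}: symmetric cell ({labels[lo]},{labels[hi]}) "
                    f"given twice with different values "
                    f"({table[lo, hi]} vs {value})"
                )
            table[lo, hi] = value
    table[table < 0] = 0
    return MultiAlleleCounts(labels=labels, table=table)


def write_counts_file(c: MultiAlleleCounts, path: Union[str, Path]) -> None:
    """Write a table in the counts-CSV dialect (lower-triangular rows)."""
    lines = ["alleles," + ",".join(c.labels)]
    for i in range(c.k):
        cells = [str(int(c.table[i, j])) for j in range(i + 1)]
        lines.append(c.labels[i] + "," + ",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
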