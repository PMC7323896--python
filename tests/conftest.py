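import numpy as np
import pytest

from hwtest import MultiAlleleCounts, TwoAlleleCounts


@pytest.fixture
def worked() -> TwoAlleleCounts:
    """The worked two-allele sample: 119 AA, 42 Aa, 39 aa (N = 200)."""
    return TwoAlleleCounts(119, 42, 39)


@pytest.fixture
def hw_perfect() -> TwoAlleleCounts:
    """A sample exactly in HW proportions at p = 0.7, N = 200."""
    return TwoAlleleCounts(98, 84, 18)


@pytest.fixture
def four_allele() -> MultiAlleleCounts:
    """A 4-allele table with all classes populated, N = 120."""
    table = np.zeros((4, 4), dtype=int)
    table[0, 0] = 18
    table[1, 0] = 22
    table[1, 1] = 12
    table[2, 0] = 14
    table[2, 1] = 13
    table[2, 2] = 8
    table[3, 0] = 10
    table[3, 1] = 9
    table[3, 2] = 8
    table[3, 3] = 6
    return MultiAlleleCounts(labels=("A", "B", "C", "D"), table=table)


def random_valid_two_allele(rng: np.random.Generator, max_count: int = 200) -> TwoAlleleCounts:
    """A random two-allele table passing validation with both alleles seen."""
    while True:
        D, H, R = (int(x) for x in rng.integers(0, max_count, 3))
        c = TwoAlleleCounts(D, H, R)
        zeros = sum(v == 0 for v in (D, H, R))
        if c.N >= 5 and zeros <= 1 and 2 * D + H > 0 and H + 2 * R > 0:
            return c
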