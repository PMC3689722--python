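"""2x2 chi-square tests on transition and node counts."""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2_contingency

__all__ = ["ChiSquareResult", "chisq_2x2", "min_expected_count"]


@dataclass(frozen=True)
class ChiSquareResult:
    """Pearson chi-square on a 2x2 table, df 1, right-tail p, no correction."""

    statistic: float
    df: int
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]


def chisq_2x2(count_a: int, total_a: int, count_b: int, total_b: int) -> ChiSquareResult:
    """Test whether a count occurs at different rates in two groups.

    Builds the table ``[[count_a, total_a - count_a],
    [count_b, total_b - count_b]]`` and applies the Pearson chi-square test
    with one degree of freedom and no continuity correction (the published
    statistics reproduce only without Yates' correction).

    Raises ``ValueError`` when a marginal of the table is zero (the test is
    undefined there).
    """
    for count, total, side in [(count_a, total_a, "a"), (count_b, total_b, "b")]:
        if not 0 <= count <= total:
            raise ValueError(f"need 0 <= count_{side} <= total_{side}")
    table = ((count_a, total_a - count_a), (count_b, total_b - count_b))
    if count_a + count_b == 0 or (total_a - count_a) + (total_b - count_b) == 0:
        raise ValueError("zero column marginal: chi-square test undefined")
    if total_a == 0 or total_b == 0:
        raise ValueError("zero row marginal: chi-square test undefined")
    stat, p, df, _ = chi2_contingency(table, correction=False)
    # the survival function underflows to 0 for huge statistics; the
    # right-tail p is defined on (0, 1], so clamp at the smallest positive
    p = max(float(p), 5e-324)
    return ChiSquareResult(float(stat), int(df), p, table)


def min_expected_count(count_a: int, total_a: int, count_b: int, total_b: int) -> float:
    """Smallest expected cell count of the 2x2 table under independence.

    The Pearson chi-square approximation is only trusted when every
    expected count is at least 5 (Cochran's rule); calibration checks use
    this to decide which edges count as testable.
    """
    n = total_a + total_b
    col1 = count_a + count_b
    col2 = n - col1
    return min(
        total_a * col1 / n,
        total_a * col2 / n,
        total_b * col1 / n,
        total_b * col2 / n,
    )
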