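"""Two-sided Fisher exact test on 2x2 allele-count tables.

The test conditions on both margins of the table

    alt      ref
    a        b      (population A)
    c        d      (population B)

so that under the null the count ``a`` follows a hypergeometric law.  The
two-sided p-value sums the probabilities of every table with the same
margins whose point probability does not exceed the observed one (with a
``1 + 1e-7`` relative tolerance absorbing floating-point noise) — the
convention used by R's ``fisher.test`` and most statistical software.

Point probabilities are evaluated in log space via ``gammaln``, so tables
with tens of thousands of chromosomes per row are handled without
overflow.  Significance is flagged at ``p <= alpha`` inclusive and no
multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .frequency import reconstruct_allele_count
from .types import FrequencyTable, PopulationManifest

_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Allele counts: row 1 = population A (alt, ref), row 2 = population B."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is all zero")


@dataclass(frozen=True)
class ComparisonResult:
    """Exact-test outcome for one variant and one population pair."""

    variant_id: str
    population_a: str
    population_b: str
    p_value: float | None
    significant: bool | None
    table: ContingencyTable2x2 | None = None

    @property
    def testable(self) -> bool:
        return self.p_value is not None


def _log_binom(n: float, k: np.ndarray | float) -> np.ndarray | float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_log_pmf(k: int, N: int, K: int, n: int) -> float:
    """log P[X = k] for X ~ Hypergeometric(N, K, n).

    ``N`` items, ``K`` of them marked, ``n`` drawn without replacement,
    ``k`` marked among the draw.  Raises ``ValueError`` outside the support.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if not (max(0, n - (N - K)) <= k <= min(K, n)):
        raise ValueError(f"k={k} outside support for N={N}, K={K}, n={n}")
    return float(_log_binom(K, k) + _log_binom(N - K, n - k) - _log_binom(N, n))


def _support_log_pmf(N: int, K: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    ks = np.arange(max(0, n - (N - K)), min(K, n) + 1)
    logp = _log_binom(K, ks) + _log_binom(N - K, n - ks) - _log_binom(N, n)
    return ks, logp


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    A table with an all-zero margin is degenerate (only one table is
    compatible with the margins) and returns 1 by convention.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    N = a + b + c + d
    K = a + b  # row-A margin
    n = a + c  # alt-column margin
    if K == 0 or c + d == 0 or n == 0 or b + d == 0:
        return 1.0
    ks, logp = _support_log_pmf(N, K, n)
    observed = logp[np.searchsorted(ks, a)]
    cutoff = observed + math.log1p(_REL_TOL)
    p = float(np.exp(logsumexp(logp[logp <= cutoff])))
    return min(p, 1.0)


def build_contingency(
    freq_a: float, chrom_a: int, freq_b: float, chrom_b: int
) -> ContingencyTable2x2:
    """Rebuild an allele-count table from rounded frequencies and chromosome counts."""
    alt_a = reconstruct_allele_count(freq_a, chrom_a)
    alt_b = reconstruct_allele_count(freq_b, chrom_b)
    return ContingencyTable2x2(a=alt_a, b=chrom_a - alt_a, c=alt_b, d=chrom_b - alt_b)


def compare_all(
    freq_table: FrequencyTable,
    manifest: PopulationManifest,
    reference_pop: str = "IND",
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Exact-test every variant between the reference population and each other population.

    Chromosome denominators come from the frequency table where recorded
    (positive) and fall back to twice the manifest size otherwise.  A cell
    with an undefined frequency yields an untestable result (``p_value``
    and ``significant`` both ``None``) rather than being dropped.
    """
    if reference_pop not in freq_table.populations:
        raise KeyError(f"reference population {reference_pop!r} not in table")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")

    def _chroms(pop: str, vid: str) -> int:
        recorded = int(freq_table.chromosomes.loc[pop, vid])
        if recorded > 0:
            return recorded
        return manifest.chromosomes(pop)

    results: list[ComparisonResult] = []
    others = [p for p in freq_table.populations if p != reference_pop]
    for vid in freq_table.variant_ids:
        f_ref = freq_table.frequencies.loc[reference_pop, vid]
        for pop in others:
            f_other = freq_table.frequencies.loc[pop, vid]
            if np.isnan(f_ref) or np.isnan(f_other):
                results.append(ComparisonResult(vid, reference_pop, pop, None, None))
                continue
            tab = build_contingency(
                float(f_ref), _chroms(reference_pop, vid), float(f_other), _chroms(pop, vid)
            )
            p = fisher_exact_two_sided(tab)
            results.append(
                ComparisonResult(vid, reference_pop, pop, p, p <= alpha, tab)
            )
    return results


def count_significant(results: list[ComparisonResult], population: str) -> int:
    """Number of variants flagged significant against ``population``."""
    return sum(
        1
        for r in results
        if population in (r.population_a, r.population_b) and r.significant
    )
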