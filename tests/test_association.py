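"""Fisher exact engine: oracle equivalence, symmetry, comparison matrix."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, strategies as st

import popdiff as P
from popdiff.association import (
    ComparisonResult,
    ContingencyTable2x2,
    build_contingency,
    compare_all,
    count_significant,
    fisher_exact_two_sided,
    hypergeometric_log_pmf,
)
from oracles import fisher_two_sided_enumeration

cell = st.integers(0, 15)
tables = st.tuples(cell, cell, cell, cell).filter(lambda t: sum(t) > 0)


@pytest.mark.parametrize(
    "args,expected",
    [((1, 2, 1, 1), math.log(0.5)), ((5, 10, 5, 5), math.log(1 / 252))],
)
def test_hypergeometric_log_pmf_closed_forms(args, expected):
    assert hypergeometric_log_pmf(*args) == pytest.approx(expected, abs=1e-12)


def test_hypergeometric_pmf_normalizes():
    N, K, n = 30, 12, 9
    total = sum(
        math.exp(hypergeometric_log_pmf(k, N, K, n))
        for k in range(max(0, n - (N - K)), min(K, n) + 1)
    )
    assert total == pytest.approx(1.0, abs=1e-12)


def test_hypergeometric_rejects_support_violations():
    with pytest.raises(ValueError):
        hypergeometric_log_pmf(6, 10, 5, 5)
    with pytest.raises(ValueError):
        hypergeometric_log_pmf(0, 10, 11, 5)


@pytest.mark.parametrize(
    "table,expected",
    [
        ((5, 5, 5, 5), 1.0),
        ((3, 1, 1, 3), 34 / 70),
        ((0, 5, 5, 0), 2 / 252),
        ((0, 10, 0, 10), 1.0),  # degenerate alt margin
        ((2, 0, 3, 0), 1.0),    # degenerate ref margin
    ],
)
def test_fisher_canonical_values(table, expected):
    assert fisher_exact_two_sided(ContingencyTable2x2(*table)) == pytest.approx(
        expected, abs=1e-12
    )


def test_fisher_matches_enumeration_oracle_on_500_random_tables():
    rng = np.random.default_rng(20210142)
    checked = 0
    while checked < 500:
        a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
        if a + b + c + d == 0:
            continue
        p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
        assert abs(p - fisher_two_sided_enumeration(a, b, c, d)) < 1e-9
        checked += 1


@given(tables)
def test_fisher_agrees_with_scipy(t):
    ours = fisher_exact_two_sided(ContingencyTable2x2(*t))
    theirs = scipy.stats.fisher_exact([[t[0], t[1]], [t[2], t[3]]])[1]
    assert ours == pytest.approx(theirs, abs=1e-9)


@given(tables)
def test_fisher_row_and_column_swap_symmetry(t):
    a, b, c, d = t
    p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
    assert fisher_exact_two_sided(ContingencyTable2x2(c, d, a, b)) == pytest.approx(p, abs=1e-12)
    assert fisher_exact_two_sided(ContingencyTable2x2(b, a, d, c)) == pytest.approx(p, abs=1e-12)


@given(tables)
def test_most_extreme_table_has_smallest_p(t):
    """Among tables with fixed margins, minimal point probability => minimal p."""
    a, b, c, d = t
    N, K, n = a + b + c + d, a + b, a + c
    if K == 0 or c + d == 0 or n == 0 or b + d == 0:
        return
    support = range(max(0, n - (N - K)), min(K, n) + 1)
    stats = [
        (
            hypergeometric_log_pmf(k, N, K, n),
            fisher_exact_two_sided(ContingencyTable2x2(k, K - k, n - k, N - K - n + k)),
        )
        for k in support
    ]
    most_extreme_p = min(stats)[1]
    assert all(most_extreme_p <= p + 1e-12 for _, p in stats)


def test_fisher_handles_large_chromosome_counts():
    # published-scale table: IND 14/126 vs a large cohort with no alt alleles
    p = fisher_exact_two_sided(ContingencyTable2x2(14, 112, 0, 8654))
    assert 0.0 < p < 1e-3


# -- contingency reconstruction and the comparison matrix --------------------

@pytest.mark.parametrize(
    "args,expected",
    [
        ((0.5078, 128, 0.1249, 10406), (65, 63, 1300, 9106)),
        ((0.0, 10, 0.0, 10), (0, 10, 0, 10)),
        ((1.0, 4, 0.0, 4), (4, 0, 0, 4)),
    ],
)
def test_build_contingency(args, expected):
    t = build_contingency(*args)
    assert (t.a, t.b, t.c, t.d) == expected


def _toy_table(freq_ind, freq_other, chrom_ind=128, chrom_other=2000):
    import pandas as pd

    freqs = pd.DataFrame(
        {"rs1": [freq_ind, freq_other]}, index=pd.Index(["IND", "POP"], name="population")
    )
    chroms = pd.DataFrame({"rs1": [chrom_ind, chrom_other]}, index=freqs.index)
    return P.FrequencyTable(frequencies=freqs, chromosomes=chroms)


def test_compare_all_identical_frequencies_never_significant(manifest):
    table = _toy_table(0.3, 0.3)
    results = compare_all(table, manifest, "IND", alpha=0.05)
    assert len(results) == 1 and results[0].p_value == pytest.approx(1.0)
    assert results[0].significant is False


def test_compare_all_extreme_difference_significant(manifest):
    results = compare_all(_toy_table(14 / 126, 0.0, 126, 2000), manifest, "IND")
    assert results[0].p_value < 1e-3 and results[0].significant


def test_compare_all_alpha_zero_flags_nothing(manifest):
    results = compare_all(_toy_table(14 / 126, 0.0, 126, 2000), manifest, "IND", alpha=0.0)
    assert not any(r.significant for r in results)


def test_compare_all_missing_cell_marked_untestable(manifest):
    results = compare_all(_toy_table(float("nan"), 0.2), manifest, "IND")
    assert len(results) == 1 and not results[0].testable
    assert results[0].significant is None


def test_compare_all_published_table_reports_counts(published_freqs, manifest):
    """Counts vs the continental cohorts are reported, not pinned: the printed
    study p-values are not reproducible from the printed marginals."""
    results = compare_all(published_freqs, manifest, "IND", alpha=0.05)
    assert len(results) == 15 * 5
    counts = {pop: count_significant(results, pop) for pop in ("AFR", "AMR", "EAS", "EUR", "SAS")}
    assert all(0 <= c <= 15 for c in counts.values())
    # the three HBOC-associated BRCA2 variants diverge from every population
    for vid in ("rs11571769", "rs144848", "rs11571707"):
        assert all(r.significant for r in results if r.variant_id == vid)


def test_count_significant_bounds():
    results = [
        ComparisonResult("rs1", "IND", "AFR", 0.01, True),
        ComparisonResult("rs2", "IND", "AFR", 1.0, False),
        ComparisonResult("rs1", "IND", "EUR", 0.04, True),
    ]
    assert count_significant(results, "AFR") == 1
    assert count_significant(results, "EUR") == 1
    assert count_significant(results, "SAS") == 0
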