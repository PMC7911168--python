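"""Wright/Nei FST, classical MDS, gap-cut clustering."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import popdiff as P
from popdiff.differentiation import (
    FstMatrix,
    UndefinedFstError,
    aggregate_fst,
    classical_mds,
    gap_cut_clusters,
    pairwise_fst_matrix,
    per_locus_fst,
)
from oracles import fst_ratio_of_sums_arithmetic

freqs = st.floats(0.0, 1.0, allow_nan=False)


def _fst_from_points(points):
    """Euclidean distance matrix of a point set, wrapped as an FstMatrix."""
    pts = np.asarray(points, float)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return FstMatrix([f"P{i}" for i in range(len(pts))], np.minimum(d, 1.0))


# -- per-locus FST -----------------------------------------------------------

@pytest.mark.parametrize(
    "p1,p2,expected",
    [
        (0.3, 0.3, 0.0),          # no differentiation
        (1.0, 0.0, 1.0),          # fixation
        (0.3203, 0.1409, 0.045349),  # study IND vs AMR at the most divergent SNP
    ],
)
def test_per_locus_fst_values(p1, p2, expected):
    assert per_locus_fst(p1, p2) == pytest.approx(expected, abs=1e-6)


def test_per_locus_fst_undefined_when_doubly_monomorphic():
    assert math.isnan(per_locus_fst(0.0, 0.0))
    assert math.isnan(per_locus_fst(1.0, 1.0))


@given(freqs, freqs)
def test_per_locus_fst_symmetric_and_relabel_invariant(p1, p2):
    a, b = per_locus_fst(p1, p2), per_locus_fst(p2, p1)
    if math.isnan(a):
        assert math.isnan(b)
        return
    assert a == pytest.approx(b, abs=1e-12)
    q1, q2 = 1 - p1, 1 - p2  # allele relabelling
    if 0.0 < q1 + q2 < 2.0:  # guard: rounding of 1-p can hit fixation exactly
        assert a == pytest.approx(per_locus_fst(q1, q2), rel=1e-6, abs=1e-12)
    assert 0.0 <= a <= 1.0


# -- aggregation -------------------------------------------------------------

def test_aggregate_single_locus_equals_per_locus():
    for method in ("ratio_of_sums", "mean_of_ratios"):
        assert aggregate_fst([(0.4, 0.1)], method) == pytest.approx(
            per_locus_fst(0.4, 0.1)
        )


def test_aggregate_identical_vectors_is_zero():
    pairs = [(0.2, 0.2), (0.7, 0.7), (0.0, 0.0)]
    assert aggregate_fst(pairs) == 0.0


def test_aggregate_all_monomorphic_raises():
    with pytest.raises(UndefinedFstError):
        aggregate_fst([(0.0, 0.0), (1.0, 1.0)])


@given(st.lists(st.tuples(freqs, freqs), min_size=1, max_size=20))
def test_ratio_of_sums_between_min_and_max_per_locus(pairs):
    defined = [p for p in pairs if 0 < sum(p) < 2]
    if not defined:
        return
    agg = aggregate_fst(pairs, "ratio_of_sums")
    values = [per_locus_fst(*p) for p in defined]
    assert min(values) - 1e-12 <= agg <= max(values) + 1e-12


def test_published_ind_vs_amr_fst_matches_arithmetic_oracle(published_freqs):
    pairs = list(
        zip(
            published_freqs.frequencies.loc["IND"],
            published_freqs.frequencies.loc["AMR"],
        )
    )
    oracle = fst_ratio_of_sums_arithmetic(pairs)
    ours = aggregate_fst(pairs, "ratio_of_sums")
    assert ours == pytest.approx(oracle, abs=1e-12)
    assert ours == pytest.approx(0.02166, abs=5e-4)
    assert aggregate_fst(pairs, "mean_of_ratios") == pytest.approx(0.0221, abs=5e-4)


# -- pairwise matrix ---------------------------------------------------------

def test_pairwise_matrix_published_structure(published_freqs):
    fst = pairwise_fst_matrix(published_freqs)
    vals = fst.values
    assert vals.shape == (6, 6)
    assert np.allclose(vals, vals.T) and np.all(np.diag(vals) == 0)
    assert ((vals >= 0) & (vals <= 1)).all()
    off = {
        pop: vals[i][np.arange(6) != i].mean()
        for i, pop in enumerate(fst.populations)
    }
    afr = off.pop("AFR")
    assert all(afr >= other for other in off.values())  # AFR most isolated


def test_pairwise_matrix_trivial_cases():
    import pandas as pd

    freqs = pd.DataFrame(
        {"rs1": [0.3, 0.3], "rs2": [0.6, 0.6]},
        index=pd.Index(["A", "B"], name="population"),
    )
    table = P.FrequencyTable(freqs, freqs * 0 + 100)
    fst = pairwise_fst_matrix(table)
    assert fst.values[0, 1] == 0.0
    single = P.FrequencyTable(freqs.iloc[:1], (freqs * 0 + 100).iloc[:1])
    assert pairwise_fst_matrix(single).values.shape == (1, 1)


def test_pairwise_matrix_names_uninformative_pair():
    import pandas as pd

    freqs = pd.DataFrame(
        {"rs1": [0.0, 0.0]}, index=pd.Index(["A", "B"], name="population")
    )
    with pytest.raises(UndefinedFstError, match="A.*B"):
        pairwise_fst_matrix(P.FrequencyTable(freqs, freqs * 0 + 10))


# -- classical MDS -----------------------------------------------------------

def test_mds_equilateral_triangle():
    fst = FstMatrix(["A", "B", "C"], np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
    emb = classical_mds(fst, 2)
    coords = emb.coordinates
    for i in range(3):
        for j in range(i + 1, 3):
            assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(1.0, abs=1e-9)
    assert coords[0, 0] >= 0 and coords[0, 1] >= 0  # sign convention


def test_mds_collinear_points_have_rank_one():
    d = np.array([[0, 0.4, 0.8], [0.4, 0, 0.4], [0.8, 0.4, 0]])
    emb = classical_mds(FstMatrix(["A", "B", "C"], d), 2)
    assert emb.eigenvalues[1] == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(emb.coordinates[:, 1], 0.0)


def test_mds_duplicate_populations_coincide():
    d = np.array(
        [[0, 0, 0.5], [0, 0, 0.5], [0.5, 0.5, 0]], float
    )
    emb = classical_mds(FstMatrix(["A", "A2", "B"], d), 2)
    assert np.allclose(emb.coordinates[0], emb.coordinates[1], atol=1e-9)


@given(
    st.lists(
        st.lists(st.floats(-0.2, 0.2), min_size=3, max_size=3),
        min_size=2,
        max_size=7,
    )
)
def test_mds_reproduces_euclidean_distances(points):
    fst = _fst_from_points(points)
    n = len(points)
    emb = classical_mds(fst, k=max(n - 1, 1))
    coords = emb.coordinates
    for i in range(n):
        for j in range(n):
            assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(
                fst.values[i, j], abs=1e-8
            )


def test_mds_pads_with_zeros_and_warns():
    fst = FstMatrix(["A", "B"], np.array([[0, 0.2], [0.2, 0]]))
    with pytest.warns(UserWarning, match="padding"):
        emb = classical_mds(fst, k=3)
    assert emb.coordinates.shape == (2, 3)
    assert np.allclose(emb.coordinates[:, 1:], 0.0)


def test_mds_eigenvalues_non_increasing(published_freqs):
    with pytest.warns(UserWarning):  # published FST matrix is non-Euclidean
        emb = classical_mds(pairwise_fst_matrix(published_freqs), 2)
    assert (np.diff(emb.eigenvalues) <= 1e-12).all()


# -- gap-cut clustering ------------------------------------------------------

def test_gap_cut_two_well_separated_blobs():
    within, between = 0.01, 0.5
    n = 6
    d = np.full((n, n), between)
    d[:3, :3] = within
    d[3:, 3:] = within
    np.fill_diagonal(d, 0.0)
    clusters = gap_cut_clusters(FstMatrix([f"P{i}" for i in range(n)], d))
    assert sorted(map(sorted, clusters)) == [["P0", "P1", "P2"], ["P3", "P4", "P5"]]


def test_gap_cut_all_equal_distances_single_cluster():
    d = np.full((4, 4), 0.3)
    np.fill_diagonal(d, 0.0)
    clusters = gap_cut_clusters(FstMatrix(list("ABCD"), d))
    assert len(clusters) == 1


def test_gap_cut_published_matrix_isolates_afr(published_freqs):
    clusters = gap_cut_clusters(pairwise_fst_matrix(published_freqs))
    assert frozenset({"AFR"}) in clusters


# -- parameter recovery through the full chain -------------------------------

@pytest.mark.parametrize("F", [0.05, 0.10, 0.20])
def test_fst_recovery_matches_analytic_pairwise_target(F):
    """Two equally drifted populations have expected pairwise Wright/Nei FST
    F/(2-F); the simulate->count->aggregate chain lands within 20% of that
    in at least 9 of 10 replicates."""
    target = F / (2.0 - F)
    hits = 0
    for seed in range(10):
        cfg = P.SimulationConfig(
            n_populations=2, n_individuals=200, n_loci=1000,
            fst=F, missing_rate=0.0, seed=seed,
        )
        table = P.frequency_table_from_genotypes(P.simulate_cohort(cfg))
        est = pairwise_fst_matrix(table, "ratio_of_sums").loc("POP1", "POP2")
        hits += abs(est - target) <= 0.2 * target
    assert hits >= 9
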