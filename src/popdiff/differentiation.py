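"""Wright's fixation index, pairwise FST matrices, classical MDS, gap-cut clustering.

FST here is the frequency-based Wright/Nei form

    FST = (HT - HS) / HT

with HS the mean within-population expected heterozygosity ``2p(1-p)``
and HT the expected heterozygosity of the pooled population at the mean
frequency, populations weighted equally.  For two populations with
frequencies ``p1`` and ``p2`` and ``s = p1 + p2`` this reduces to

    FST = (p1 - p2)^2 / (s * (2 - s)).

A locus monomorphic in both populations (s = 0 or s = 2) has HT = 0 and
an undefined FST; such loci are excluded per population pair, so each
pair is aggregated over its maximal informative locus set.  Multi-locus
aggregation defaults to the ratio-of-sums Σ(HT−HS)/ΣHT, the standard
multi-locus practice; an unweighted mean of per-locus ratios is also
available.  No sample-size bias correction is applied, since only
published frequencies (not genotype-level samples) are available for the
reference populations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .types import FrequencyTable

logger = logging.getLogger(__name__)

AggregationMethod = Literal["ratio_of_sums", "mean_of_ratios"]

_ZERO_EIGENVALUE_TOL = 1e-12


class UndefinedFstError(ValueError):
    """Every locus is monomorphic in both populations — FST is undefined."""


@dataclass
class FstMatrix:
    """Symmetric pairwise aggregate-FST matrix with a zero diagonal."""

    populations: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.populations)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("FST matrix must be symmetric")
        if np.abs(np.diag(self.values)).max(initial=0.0) > 0:
            raise ValueError("FST matrix diagonal must be exactly zero")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("FST values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.populations, columns=self.populations)

    def loc(self, pop_a: str, pop_b: str) -> float:
        i, j = self.populations.index(pop_a), self.populations.index(pop_b)
        return float(self.values[i, j])


@dataclass
class MdsEmbedding:
    """Classical (Torgerson) MDS coordinates with the centered-matrix eigenvalues."""

    populations: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        if self.coordinates.shape[0] != len(self.populations):
            raise ValueError("one coordinate row per population required")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{k + 1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.populations, columns=cols)


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

def _ht_hs(p1: np.ndarray, p2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pbar = (p1 + p2) / 2.0
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = p1 * (1.0 - p1) + p2 * (1.0 - p2)
    return ht, hs


def per_locus_fst(p1: float, p2: float) -> float:
    """Two-population Wright/Nei FST at a single locus.

    Returns NaN (flagged undefined) when the locus is monomorphic in both
    populations; such loci carry no differentiation information.
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    s = p1 + p2
    if s == 0.0 or s == 2.0:
        return float("nan")
    return (p1 - p2) ** 2 / (s * (2.0 - s))


def aggregate_fst(
    loci: Iterable[tuple[float, float]],
    method: AggregationMethod = "ratio_of_sums",
) -> float:
    """Multi-locus FST over defined (non-doubly-monomorphic) loci.

    ``ratio_of_sums`` computes Σ(HT−HS)/ΣHT; ``mean_of_ratios`` averages
    the per-locus values.  Raises :class:`UndefinedFstError` when no locus
    is defined.
    """
    pairs = np.asarray(list(loci), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("loci must be (p1, p2) pairs")
    if ((pairs < 0) | (pairs > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    s = pairs.sum(axis=1)
    defined = (s > 0.0) & (s < 2.0) & ~np.isnan(s)
    if not defined.any():
        raise UndefinedFstError("all loci are monomorphic in both populations")
    p1, p2 = pairs[defined, 0], pairs[defined, 1]
    ht, hs = _ht_hs(p1, p2)
    if method == "ratio_of_sums":
        value = float((ht - hs).sum() / ht.sum())
    elif method == "mean_of_ratios":
        value = float(np.mean((ht - hs) / ht))
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    return min(max(value, 0.0), 1.0)


def pairwise_fst_matrix(
    freq_table: FrequencyTable, method: AggregationMethod = "ratio_of_sums"
) -> FstMatrix:
    """Aggregate FST for every population pair of a frequency table.

    Loci undefined for a pair (monomorphic in both, or with a missing
    frequency in either) are excluded for that pair only.
    """
    pops = freq_table.populations
    if len(pops) < 1:
        raise ValueError("at least one population required")
    freqs = freq_table.frequencies.to_numpy(float)
    n = len(pops)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~(np.isnan(freqs[i]) | np.isnan(freqs[j]))
            try:
                fst = aggregate_fst(zip(freqs[i][both], freqs[j][both]), method)
            except (UndefinedFstError, ValueError) as exc:
                raise UndefinedFstError(
                    f"no informative loci for pair ({pops[i]}, {pops[j]})"
                ) from exc
            out[i, j] = out[j, i] = fst
    return FstMatrix(populations=list(pops), values=out)


# ---------------------------------------------------------------------------
# classical MDS (Torgerson)
# ---------------------------------------------------------------------------

def classical_mds(distances: FstMatrix, k: int = 2) -> MdsEmbedding:
    """Torgerson embedding of a dissimilarity matrix.

    Squared dissimilarities are double-centered (B = -1/2 J D² J) and
    eigendecomposed; the top ``k`` non-negative eigenpairs give the
    coordinates (eigenvectors scaled by root eigenvalues).  Eigenvalues
    within 1e-12 of zero are treated as zero and negative eigenvalues
    (non-Euclidean input) are dropped with a warning; if fewer than ``k``
    positive dimensions exist the embedding is padded with zeros.  Sign
    convention: the first population's coordinate in each retained
    dimension is non-negative.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    D = distances.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals[np.abs(eigvals) < _ZERO_EIGENVALUE_TOL] = 0.0
    if (eigvals < 0).any():
        warnings.warn(
            "dissimilarity matrix is not Euclidean-realizable; "
            f"dropping {int((eigvals < 0).sum())} negative eigenvalue(s)",
            stacklevel=2,
        )
    positive = eigvals > 0
    n_pos = int(positive.sum())
    if k > n_pos:
        warnings.warn(
            f"only {n_pos} positive dimension(s); padding embedding with zeros",
            stacklevel=2,
        )
    coords = np.zeros((n, k))
    kept = min(k, n_pos)
    coords[:, :kept] = eigvecs[:, :kept] * np.sqrt(eigvals[:kept])
    for dim in range(kept):  # deterministic sign: first row non-negative
        if coords[0, dim] < 0:
            coords[:, dim] = -coords[:, dim]
    return MdsEmbedding(
        populations=list(distances.populations),
        coordinates=coords,
        eigenvalues=eigvals,
    )


# ---------------------------------------------------------------------------
# gap-cut hierarchical grouping
# ---------------------------------------------------------------------------

def gap_cut_clusters(distances: FstMatrix) -> list[frozenset[str]]:
    """Average-linkage clusters cut at the largest gap in merge heights.

    The dendrogram's merge heights ``h_1 <= ... <= h_{n-1}`` are scanned
    for the largest gap between consecutive heights; the tree is cut in
    that gap.  Cutting above the final merge (one cluster) counts as a
    zero-width gap, so when every gap ties — e.g. all pairwise distances
    equal — the tie is broken toward fewer clusters and a single cluster
    is returned.
    """
    pops = distances.populations
    n = len(pops)
    if n < 2:
        raise ValueError("at least two populations required")
    Z = linkage(squareform(distances.values, checks=False), method="average")
    heights = Z[:, 2]
    # candidate j = number of merges applied (n - j clusters); j = n-1 -> 1 cluster
    best_j, best_gap = n - 1, 0.0
    for j in range(n - 2, 0, -1):  # descending + strict > breaks ties toward fewer clusters
        gap = heights[j] - heights[j - 1]
        if gap > best_gap:
            best_j, best_gap = j, gap
    if best_j == n - 1:
        labels = np.ones(n, dtype=int)
    else:
        threshold = (heights[best_j - 1] + heights[best_j]) / 2.0
        labels = fcluster(Z, t=threshold, criterion="distance")
    clusters: dict[int, set[str]] = {}
    for pop, lab in zip(pops, labels):
        clusters.setdefault(int(lab), set()).add(pop)
    return sorted((frozenset(c) for c in clusters.values()), key=lambda c: sorted(c))
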