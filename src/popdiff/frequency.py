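"""Gene-counting allele-frequency estimation.

The gene-counting (direct counting) estimate of an alternate-allele
frequency is

    p = (n_het + 2 * n_hom_alt) / (2 * n_called)

where ``n_called`` excludes individuals with a missing call at that
variant, so the chromosome denominator shrinks per variant with
missingness.  No inbreeding or ploidy correction is applied: within each
population the cohort is treated as a simple diploid sample.

The module also reconstructs integer allele counts from published rounded
frequencies (frequency x chromosomes, rounded half-up), which is how
contingency tables are rebuilt for reference populations whose
genotype-level data is not available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MISSING, FrequencyTable, GenotypeMatrix


class UndefinedFrequencyError(ValueError):
    """All genotypes missing — the gene-counting frequency is undefined."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts for one variant in one population."""

    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    n_missing: int

    def __post_init__(self) -> None:
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt, self.n_missing) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt + self.n_missing

    @property
    def n_called(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt


@dataclass(frozen=True)
class FrequencyEstimate:
    """An alternate-allele count over called chromosomes."""

    alt_count: int
    called_chromosomes: int

    def __post_init__(self) -> None:
        if not 0 <= self.alt_count <= self.called_chromosomes:
            raise ValueError(
                f"alt count {self.alt_count} outside [0, {self.called_chromosomes}]"
            )

    @property
    def frequency(self) -> float:
        return self.alt_count / self.called_chromosomes


def genotype_counts(
    matrix: GenotypeMatrix, variant_id: str, population: str
) -> GenotypeCounts:
    """Partition a population's individuals by genotype class at one variant."""
    j = matrix.variant_index(variant_id)
    col = matrix.calls[matrix.population_mask(population), j]
    return GenotypeCounts(
        n_hom_ref=int((col == 0).sum()),
        n_het=int((col == 1).sum()),
        n_hom_alt=int((col == 2).sum()),
        n_missing=int((col == MISSING).sum()),
    )


def gene_counting_frequency(counts: GenotypeCounts) -> FrequencyEstimate:
    """Gene-counting estimate from genotype class counts.

    Raises
    ------
    UndefinedFrequencyError
        When every genotype is missing.
    """
    if counts.n_called == 0:
        raise UndefinedFrequencyError("no called genotypes")
    return FrequencyEstimate(
        alt_count=counts.n_het + 2 * counts.n_hom_alt,
        called_chromosomes=2 * counts.n_called,
    )


def frequency_table_from_genotypes(matrix: GenotypeMatrix) -> FrequencyTable:
    """One gene-counting estimate per (population, variant).

    Cells where every genotype is missing become NaN frequencies with a
    zero chromosome denominator, never an exception.
    """
    if matrix.n_individuals == 0 or matrix.n_variants == 0:
        raise ValueError("genotype matrix is empty")
    pops = matrix.population_labels
    vids = matrix.variant_ids
    freqs = pd.DataFrame(np.nan, index=pops, columns=vids)
    chroms = pd.DataFrame(0, index=pops, columns=vids)
    for pop in pops:
        sub = matrix.calls[matrix.population_mask(pop)]
        called = sub != MISSING
        n_called = called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            freqs.loc[pop] = np.where(n_called > 0, alt / (2 * n_called), np.nan)
        chroms.loc[pop] = 2 * n_called
    freqs.index.name = "population"
    return FrequencyTable(frequencies=freqs, chromosomes=chroms, variants=list(matrix.variants))


def reconstruct_allele_count(frequency: float, chromosomes: int) -> int:
    """Integer allele count behind a rounded published frequency.

    Round-half-up of ``frequency x chromosomes`` (a fixed tie rule keeps
    reconstruction deterministic), clamped to ``[0, chromosomes]``.
    """
    if not 0.0 <= frequency <= 1.0:
        raise ValueError(f"frequency {frequency} outside [0, 1]")
    if chromosomes <= 0:
        raise ValueError("chromosomes must be positive")
    count = math.floor(frequency * chromosomes + 0.5)
    return min(max(count, 0), chromosomes)
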