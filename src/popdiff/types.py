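"""Shared data model: variants, genotype matrices, frequency and count tables.

Genotype calls count copies of the ALTERNATE allele against a fixed
reference (0, 1, 2, or missing).  This convention — rather than
minor-allele copies — is what makes published frequency tables with
values above 0.5 internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing (uncalled) genotype in a calls array.
MISSING: int = -1

#: Closed set of functional-region classes a variant may carry.
REGIONS = frozenset({"intronic", "CDS", "UTR5", "UTR3", "other"})

#: Closed four-level set of SnpEff-style impact classes, mild to severe order.
IMPACTS = ("modifier", "low", "moderate", "high")


class ValidationError(ValueError):
    """An input violated a data-model invariant."""


@dataclass(frozen=True)
class VariantRecord:
    """One annotated biallelic SNP.

    Parameters
    ----------
    variant_id : str
        dbSNP rsID (or any unique identifier).
    gene : str
        Gene symbol the variant falls in.
    region : str
        One of :data:`REGIONS`.
    ref_allele, alt_allele : str
        Single-nucleotide reference and alternate alleles; must differ.
    impact : str
        SnpEff-style predicted impact, one of :data:`IMPACTS`.
    depth : int
        Read depth supporting the call; non-negative.
    """

    variant_id: str
    gene: str
    region: str
    ref_allele: str
    alt_allele: str
    impact: str
    depth: int

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(
                f"{self.variant_id}: region {self.region!r} not in {sorted(REGIONS)}"
            )
        if self.impact not in IMPACTS:
            raise ValidationError(
                f"{self.variant_id}: impact {self.impact!r} not in {IMPACTS}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValidationError(
                f"{self.variant_id}: ref and alt alleles are both {self.ref_allele!r}"
            )
        if self.depth < 0:
            raise ValidationError(f"{self.variant_id}: negative depth {self.depth}")


@dataclass
class GenotypeMatrix:
    """Individuals x variants alternate-allele copy counts.

    ``calls[i, j]`` is the number of alternate-allele copies carried by
    individual ``i`` at variant ``j``: 0, 1, 2, or :data:`MISSING` (-1).
    Every individual carries exactly one population label and an optional
    ethnic-group label.  Missing calls are retained, never imputed;
    downstream allele-frequency denominators shrink per variant.
    """

    individuals: list[str]
    populations: list[str]
    variants: list[VariantRecord]
    calls: np.ndarray
    ethnic_groups: list[str | None] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ethnic_groups is None:
            self.ethnic_groups = [None] * len(self.individuals)
        self.calls = np.asarray(self.calls, dtype=np.int16)
        self.validate()

    def validate(self) -> None:
        n_ind, n_var = len(self.individuals), len(self.variants)
        if self.calls.shape != (n_ind, n_var):
            raise ValidationError(
                f"calls shape {self.calls.shape} != ({n_ind}, {n_var})"
            )
        if len(self.populations) != n_ind or len(self.ethnic_groups) != n_ind:
            raise ValidationError("per-individual label lists have wrong length")
        if len(set(self.individuals)) != n_ind:
            raise ValidationError("duplicate individual identifiers")
        vids = [v.variant_id for v in self.variants]
        if len(set(vids)) != n_var:
            dupes = sorted({v for v in vids if vids.count(v) > 1})
            raise ValidationError(f"duplicate variant identifiers: {dupes}")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"call {self.calls[i, j]} at individual {self.individuals[i]!r},"
                f" variant {vids[j]!r} is not in {{0, 1, 2, {MISSING}}}"
            )

    # -- convenience lookups -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def population_labels(self) -> list[str]:
        """Distinct population labels in first-appearance order."""
        return list(dict.fromkeys(self.populations))

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"unknown variant {variant_id!r}") from None

    def population_mask(self, population: str) -> np.ndarray:
        mask = np.array([p == population for p in self.populations])
        if not mask.any():
            raise KeyError(f"unknown population {population!r}")
        return mask

    def subset_variants(self, variant_ids: list[str]) -> "GenotypeMatrix":
        """Matrix restricted to ``variant_ids`` (in the given order)."""
        idx = [self.variant_index(v) for v in variant_ids]
        return GenotypeMatrix(
            individuals=list(self.individuals),
            populations=list(self.populations),
            variants=[self.variants[i] for i in idx],
            calls=self.calls[:, idx].copy(),
            ethnic_groups=list(self.ethnic_groups),
        )


class PopulationManifest(dict):
    """Population code -> number of diploid individuals (all positive)."""

    def __init__(self, sizes: dict[str, int]):
        for pop, n in sizes.items():
            if int(n) <= 0 or int(n) != n:
                raise ValidationError(f"manifest size for {pop!r} must be a positive integer, got {n}")
        super().__init__({p: int(n) for p, n in sizes.items()})

    def chromosomes(self, population: str) -> int:
        """2N for a diploid population."""
        return 2 * self[population]


@dataclass
class FrequencyTable:
    """Populations x variants alternate-allele frequencies with denominators.

    ``frequencies`` holds frequencies in [0, 1] (NaN = undefined cell);
    ``chromosomes`` holds the number of called chromosomes behind each
    frequency (0 where undefined).  ``variants`` optionally carries the
    per-variant annotations in column order.
    """

    frequencies: pd.DataFrame
    chromosomes: pd.DataFrame
    variants: list[VariantRecord] | None = None

    def __post_init__(self) -> None:
        self.frequencies = self.frequencies.astype(float)
        self.chromosomes = self.chromosomes.astype(int)
        self.validate()

    def validate(self) -> None:
        f, c = self.frequencies, self.chromosomes
        if not (f.index.equals(c.index) and f.columns.equals(c.columns)):
            raise ValidationError("frequency and chromosome tables are misaligned")
        vals = f.to_numpy(float)
        defined = ~np.isnan(vals)
        if ((vals[defined] < 0) | (vals[defined] > 1)).any():
            raise ValidationError("frequency outside [0, 1]")
        if (c.to_numpy(int) < 0).any():
            raise ValidationError("negative chromosome count")
        if self.variants is not None:
            vids = [v.variant_id for v in self.variants]
            if vids != list(f.columns):
                raise ValidationError("variant annotations do not match table columns")

    @property
    def populations(self) -> list[str]:
        return list(self.frequencies.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.frequencies.columns)

    def check_against_manifest(self, manifest: PopulationManifest) -> None:
        """Denominators may not exceed 2N for any population in the manifest."""
        for pop in self.populations:
            if pop in manifest:
                limit = manifest.chromosomes(pop)
                if (self.chromosomes.loc[pop] > limit).any():
                    raise ValidationError(
                        f"{pop}: chromosome count exceeds 2 x manifest size ({limit})"
                    )


@dataclass
class EthnicCountTable:
    """Ethnic group -> (group size, per-variant alternate-allele counts)."""

    group_sizes: pd.Series
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        self.group_sizes = self.group_sizes.astype(int)
        self.counts = self.counts.astype(int)
        self.validate()

    def validate(self) -> None:
        if not self.group_sizes.index.equals(self.counts.index):
            raise ValidationError("group sizes and counts are misaligned")
        if (self.group_sizes <= 0).any():
            raise ValidationError("group sizes must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative allele count")
        limit = 2 * self.group_sizes
        over = self.counts.gt(limit, axis=0)
        if over.to_numpy().any():
            grp = over.any(axis=1).idxmax()
            var = over.loc[grp].idxmax()
            raise ValidationError(
                f"group {grp!r}, variant {var!r}: allele count exceeds 2 x group size"
            )

    @property
    def total_individuals(self) -> int:
        return int(self.group_sizes.sum())

    def column_sum(self, variant_id: str) -> int:
        return int(self.counts[variant_id].sum())
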