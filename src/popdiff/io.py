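"""Readers and writers for the external file dialects.

Two genotype representations are supported:

* a VCFv4.2 subset — one sample column per individual, mandatory GT,
  per-variant ``DP``, ``IMPACT`` and ``REGION`` as INFO keys, population
  and ethnic-group labels carried in ``##SAMPLE=<...>`` header lines.
  Both ``/`` and ``|`` genotype separators are accepted; phasing is
  discarded.  Parsing goes through :mod:`pysam`.
* a genotype TSV — one row per individual with leading ``individual``,
  ``population``, ``ethnic_group`` columns, then one column per variant
  with cells in ``{0, 1, 2, NA}``; variant annotations ride in
  ``#variant`` comment lines above the header.

Published summary tables (population frequency table, ethnic-group
allele-count table, population-size manifest) are plain TSV.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .types import (
    MISSING,
    EthnicCountTable,
    FrequencyTable,
    GenotypeMatrix,
    PopulationManifest,
    ValidationError,
    VariantRecord,
)

_POPULATION_ORDER = ["IND", "AFR", "AMR", "EAS", "EUR", "SAS"]


class ParseError(ValueError):
    """A file did not conform to its dialect; the message locates the fault."""


# ---------------------------------------------------------------------------
# genotype TSV dialect
# ---------------------------------------------------------------------------

_VARIANT_COMMENT = re.compile(r"^#variant\t(\S+)\t(.*)$")


def _format_variant_comment(v: VariantRecord) -> str:
    return (
        f"#variant\t{v.variant_id}\tgene={v.gene}\tregion={v.region}"
        f"\tref={v.ref_allele}\talt={v.alt_allele}\timpact={v.impact}\tdepth={v.depth}"
    )


def _parse_variant_comment(line: str, lineno: int) -> VariantRecord:
    m = _VARIANT_COMMENT.match(line.rstrip("\n"))
    if m is None:
        raise ParseError(f"line {lineno}: malformed #variant annotation line")
    vid, rest = m.groups()
    kv = dict(item.split("=", 1) for item in rest.split("\t") if "=" in item)
    try:
        return VariantRecord(
            variant_id=vid,
            gene=kv["gene"],
            region=kv["region"],
            ref_allele=kv["ref"],
            alt_allele=kv["alt"],
            impact=kv["impact"],
            depth=int(kv["depth"]),
        )
    except (KeyError, ValueError, ValidationError) as exc:
        raise ParseError(f"line {lineno}: bad variant annotation for {vid}: {exc}") from exc


def _read_genotype_tsv(path: Path) -> GenotypeMatrix:
    variants: list[VariantRecord] = []
    header: list[str] | None = None
    rows: list[list[str]] = []
    row_linenos: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if line.startswith("#variant\t"):
                variants.append(_parse_variant_comment(line, lineno))
            elif line.startswith("#"):
                continue
            elif header is None:
                header = line.rstrip("\n").split("\t")
            else:
                rows.append(line.rstrip("\n").split("\t"))
                row_linenos.append(lineno)
    if header is None:
        raise ParseError(f"{path}: no header line found")
    if header[:3] != ["individual", "population", "ethnic_group"]:
        raise ParseError(
            f"{path}: header must start with individual/population/ethnic_group"
        )
    variant_ids = header[3:]
    by_id = {v.variant_id: v for v in variants}
    if set(variant_ids) != set(by_id):
        raise ParseError(
            f"{path}: #variant annotations do not match genotype columns"
        )
    ordered_variants = [by_id[v] for v in variant_ids]

    individuals, populations, groups = [], [], []
    calls = np.full((len(rows), len(variant_ids)), MISSING, dtype=np.int16)
    for i, (row, lineno) in enumerate(zip(rows, row_linenos)):
        if len(row) != len(header):
            raise ParseError(f"line {lineno}: expected {len(header)} fields, got {len(row)}")
        individuals.append(row[0])
        populations.append(row[1])
        groups.append(None if row[2] in (".", "", "NA") else row[2])
        for j, cell in enumerate(row[3:]):
            if cell == "NA":
                continue
            if cell not in ("0", "1", "2"):
                raise ParseError(
                    f"line {lineno}: genotype code {cell!r} for variant"
                    f" {variant_ids[j]!r} is not one of 0/1/2/NA"
                )
            calls[i, j] = int(cell)
    try:
        return GenotypeMatrix(individuals, populations, ordered_variants, calls, groups)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _write_genotype_tsv(matrix: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        for v in matrix.variants:
            fh.write(_format_variant_comment(v) + "\n")
        fh.write("\t".join(["individual", "population", "ethnic_group"] + matrix.variant_ids) + "\n")
        for i, ind in enumerate(matrix.individuals):
            group = matrix.ethnic_groups[i] or "."
            cells = [
                "NA" if c == MISSING else str(int(c)) for c in matrix.calls[i]
            ]
            fh.write("\t".join([ind, matrix.populations[i], group] + cells) + "\n")


# ---------------------------------------------------------------------------
# VCF dialect (pysam-backed)
# ---------------------------------------------------------------------------

_SAMPLE_META = re.compile(r"^##SAMPLE=<ID=([^,>]+),Population=([^,>]+),Group=([^,>]*)>")


def _read_vcf(path: Path) -> GenotypeMatrix:
    pop_by_sample: dict[str, str] = {}
    group_by_sample: dict[str, str | None] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            m = _SAMPLE_META.match(line)
            if m:
                sid, pop, grp = m.groups()
                pop_by_sample[sid] = pop
                group_by_sample[sid] = grp or None

    variants: list[VariantRecord] = []
    calls_rows: list[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.id is None:
                raise ParseError(f"{path}: record at {rec.chrom}:{rec.pos} has no ID")
            if rec.alts is None or len(rec.alts) != 1:
                raise ParseError(f"{path}: variant {rec.id} is not biallelic")
            info = rec.info
            try:
                variants.append(
                    VariantRecord(
                        variant_id=rec.id,
                        gene=str(info.get("GENE", rec.chrom)),
                        region=str(info.get("REGION", "other")),
                        ref_allele=rec.ref,
                        alt_allele=rec.alts[0],
                        impact=str(info["IMPACT"]),
                        depth=int(info["DP"]),
                    )
                )
            except (KeyError, ValidationError) as exc:
                raise ParseError(f"{path}: variant {rec.id}: {exc}") from exc
            row = np.empty(len(samples), dtype=np.int16)
            for k, sample in enumerate(samples):
                alleles = rec.samples[sample].get("GT", (None,))
                if alleles is None or any(a is None for a in alleles):
                    row[k] = MISSING
                    continue
                if any(a not in (0, 1) for a in alleles) or len(alleles) != 2:
                    raise ParseError(
                        f"{path}: variant {rec.id}, sample {sample}: "
                        f"genotype {alleles} outside the biallelic diploid dialect"
                    )
                row[k] = sum(alleles)
            calls_rows.append(row)

    calls = (
        np.stack(calls_rows, axis=1) if calls_rows else np.empty((len(samples), 0), np.int16)
    )
    populations = [pop_by_sample.get(s, "UNKNOWN") for s in samples]
    groups = [group_by_sample.get(s) for s in samples]
    try:
        return GenotypeMatrix(samples, populations, variants, calls, groups)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _write_vcf(matrix: GenotypeMatrix, path: Path) -> None:
    header = pysam.VariantHeader()
    for contig in dict.fromkeys(v.gene for v in matrix.variants):
        header.contigs.add(contig)
    header.info.add("DP", 1, "Integer", "Read depth supporting the variant call")
    header.info.add("IMPACT", 1, "String", "Predicted functional impact class")
    header.info.add("REGION", 1, "String", "Genic region class")
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.formats.add("GT", 1, "String", "Genotype")
    for i, sample in enumerate(matrix.individuals):
        group = matrix.ethnic_groups[i] or ""
        header.add_line(
            f"##SAMPLE=<ID={sample},Population={matrix.populations[i]},Group={group}>"
        )
        header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        pos_by_gene: dict[str, int] = {}
        for j, v in enumerate(matrix.variants):
            pos_by_gene[v.gene] = pos_by_gene.get(v.gene, 0) + 1
            rec = out.new_record(
                contig=v.gene,
                start=pos_by_gene[v.gene] - 1,
                alleles=(v.ref_allele, v.alt_allele),
                id=v.variant_id,
            )
            rec.info["DP"] = v.depth
            rec.info["IMPACT"] = v.impact
            rec.info["REGION"] = v.region
            rec.info["GENE"] = v.gene
            for i, sample in enumerate(matrix.individuals):
                c = int(matrix.calls[i, j])
                rec.samples[sample]["GT"] = (
                    (None, None) if c == MISSING else (0, 1) if c == 1 else (c // 2, c // 2)
                )
            out.write(rec)


# ---------------------------------------------------------------------------
# public genotype API
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from ``path`` in the named dialect.

    Parameters
    ----------
    path : path-like
    format : {"tsv", "vcf"}

    Raises
    ------
    ParseError
        On any malformed genotype code or annotation, naming the location.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_genotype_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(matrix: GenotypeMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write ``matrix`` to ``path`` in the named dialect (round-trip safe)."""
    path = Path(path)
    if format == "tsv":
        _write_genotype_tsv(matrix, path)
    elif format == "vcf":
        _write_vcf(matrix, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> PopulationManifest:
    """Population-size manifest TSV with columns ``population``, ``n_individuals``."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["population", "n_individuals"]:
        raise ParseError(f"{path}: expected columns population, n_individuals")
    return PopulationManifest(dict(zip(df["population"], df["n_individuals"])))


def read_frequency_table(
    path: str | Path, manifest: PopulationManifest | None = None
) -> FrequencyTable:
    """Read a published-style frequency table.

    The layout is one row per variant with annotation columns ``gene``,
    ``variant_id``, ``region``, ``change``, ``impact`` followed by one
    alternate-allele frequency column per population.  When a ``manifest``
    is given, each population's chromosome denominator is set to twice its
    manifest size; otherwise denominators are recorded as 0 (unknown).
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    required = ["gene", "variant_id", "region", "change", "impact"]
    if list(df.columns[:5]) != required:
        raise ParseError(f"{path}: expected leading columns {required}")
    pops = list(df.columns[5:])

    variants = []
    for _, row in df.iterrows():
        alleles = [a.strip() for a in str(row["change"]).split(">")]
        if len(alleles) != 2:
            raise ParseError(f"{path}: bad allele change {row['change']!r} for {row['variant_id']}")
        variants.append(
            VariantRecord(
                variant_id=row["variant_id"],
                gene=row["gene"],
                region=row["region"],
                ref_allele=alleles[0],
                alt_allele=alleles[1],
                impact=row["impact"],
                depth=0,
            )
        )
    freqs = df.set_index("variant_id")[pops].T.astype(float)
    freqs.index.name = "population"
    if ((freqs.to_numpy() < 0) | (freqs.to_numpy() > 1)).any():
        raise ValidationError(f"{path}: frequency outside [0, 1]")
    if manifest is not None:
        chrom = pd.DataFrame(
            {v: [manifest.chromosomes(p) for p in freqs.index] for v in freqs.columns},
            index=freqs.index,
        )
    else:
        chrom = pd.DataFrame(0, index=freqs.index, columns=freqs.columns)
    return FrequencyTable(frequencies=freqs, chromosomes=chrom, variants=variants or None)


def write_frequency_table(table: FrequencyTable, path: str | Path) -> None:
    """Write a :class:`FrequencyTable` in the published layout, 4-decimal frequencies."""
    variants = table.variants
    rows = []
    for j, vid in enumerate(table.variant_ids):
        v = variants[j] if variants else None
        rows.append(
            {
                "gene": v.gene if v else ".",
                "variant_id": vid,
                "region": v.region if v else ".",
                "change": f"{v.ref_allele} > {v.alt_allele}" if v else ".",
                "impact": v.impact if v else ".",
                **{
                    pop: (
                        ""
                        if np.isnan(table.frequencies.loc[pop, vid])
                        else f"{table.frequencies.loc[pop, vid]:.4f}"
                    )
                    for pop in table.populations
                },
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ethnic_counts(path: str | Path) -> EthnicCountTable:
    """Ethnic-group allele-count table: ``group``, ``n_individuals``, one count column per variant."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["group", "n_individuals"]:
        raise ParseError(f"{path}: expected leading columns group, n_individuals")
    df = df.set_index("group")
    try:
        return EthnicCountTable(
            group_sizes=df["n_individuals"], counts=df[df.columns[1:]]
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(resources.files("popdiff").joinpath("data", name))  # type: ignore[arg-type]


def load_published_manifest() -> PopulationManifest:
    """Cohort sizes as printed in the source study (IND plus five continental groups)."""
    return read_manifest(_data_path("population_manifest.tsv"))


def load_published_frequencies(
    manifest: PopulationManifest | None = None,
) -> FrequencyTable:
    """The published 15-variant x 6-population frequency table.

    Denominators come from ``manifest`` (default: the published cohort sizes).
    """
    if manifest is None:
        manifest = load_published_manifest()
    return read_frequency_table(_data_path("brca_frequency_table.tsv"), manifest)


def load_published_ethnic_counts() -> EthnicCountTable:
    """The published per-ethnic-group allele counts for the three HBOC variants.

    Kept verbatim as printed — including its two column sums that disagree
    with the study's stated allele totals (see the consistency report).
    """
    return read_ethnic_counts(_data_path("ethnic_allele_counts.tsv"))
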