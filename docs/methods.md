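# Methods

## Data model and conventions

Genotype calls count **alternate-allele copies** against a fixed reference
allele (0, 1, 2, missing). The published frequency table this package
re-analyses labels its columns "minor allele frequencies", but several
entries exceed 0.5 (e.g. AFR rs799917 = 0.8193), which is only coherent if
the values are alternate-allele frequencies relative to a fixed reference;
the package treats them as such throughout.

Missing genotypes are retained, never imputed. Every per-variant
denominator is the number of *called* chromosomes, so missingness shrinks
denominators variant by variant.

VCF input/output is a v4.2 subset handled by pysam: biallelic SNVs only,
mandatory GT (both `/` and `|` accepted, phasing discarded), per-variant
`DP`, `IMPACT`, `REGION`, `GENE` INFO keys, and per-sample population and
ethnic-group labels in `##SAMPLE=<...>` header lines. Coordinates are
1-based per the standard; no interval arithmetic is performed. The TSV
dialect is one row per individual with `{0,1,2,NA}` cells and `#variant`
annotation comment lines.

## Variant selection

Two criteria, both consumed as input annotations: read depth ≥ `min_depth`
(default 10; the threshold is inclusive — a "minimum of 10 reads" keeps a
depth-10 variant) and impact class in an allowed set (default
{modifier, moderate, high}, i.e. only *low* is excluded). The filter is
idempotent and monotone in both parameters; impact labels are never
re-derived from annotation sources.

## Gene-counting frequencies and count reconstruction

The gene-counting estimate is `p̂ = (n_het + 2 n_hom-alt) / 2 n_called`,
the maximum-likelihood estimate for a diploid sample under
Hardy–Weinberg-free direct counting. No inbreeding correction is applied.

For reference populations only rounded published frequencies and cohort
sizes are available, so integer allele counts are reconstructed as
round-half-up of `p × 2N` (half-up makes ties deterministic; any
nearest-integer rule reproduces e.g. 65 alleles from 0.5078 × 128 =
64.9984). Reconstruction is exact whenever frequencies are printed to four
decimals and denominators stay below 5000 (4-decimal rounding error ≤ 5e-5
× 5000 = 0.25 < 0.5), which covers the study cohort scale; the property
suite verifies this bound.

The packaged study fixture is reconstructed from published marginals. The
printed study frequencies force per-variant missing calls: 0.4754 is only
reachable as 58/122 (three uncalled individuals), 0.4841 as 61/126,
0.1111 as 14/126, and 0.1379 as 16/116. One printed value (0.0937) is a
truncation of 12/128 = 0.09375 rather than a rounding; fixture checks
therefore assert agreement to half a unit in the last printed digit.

## Fisher exact comparisons

The two-sided p-value for a 2×2 table conditions on both margins and sums
the hypergeometric probabilities of all tables whose point probability is
≤ the observed one, with a `1 + 1e-7` relative tolerance absorbing
floating-point noise — the convention of R's `fisher.test` and most
statistical software. Point probabilities are computed via log-gamma, so
rows with tens of thousands of chromosomes are safe from overflow. A table
with an all-zero margin admits only one configuration and returns p = 1 by
convention. Significance is `p ≤ 0.05` inclusive; no multiple-testing
correction is applied, matching the analysis the package reproduces.

The engine is validated against an exact rational-enumeration oracle and
against `scipy.stats.fisher_exact` (used only as a cross-check, never as
the implementation), and its null calibration is measured on simulated
equal-frequency tables at study-like sizes (128 vs 1000 chromosomes),
where exact tests are conservative (rejection rate < 0.05 at α = 0.05).

The published per-variant p-values themselves are *reported, not
asserted*: they are not reproducible from the printed marginals (e.g.
IND 2/128 vs AMR at 0.0845 gives p ≈ 0.003 against a printed 0.0409), and
the printed reference cohort sizes are internally inconsistent with the
1000 Genomes phase-3 release they cite. The per-population significance
counts computed here (11 vs AFR, 14 vs AMR, 8 vs EAS, 15 vs EUR, 7 vs SAS
under the printed sizes) are emitted for comparison with the published
counts (11, 10, 6, 12, 6) but carry no assertion.

## Wright's F_ST

The estimator is the frequency-based Wright/Nei form with equal population
weights: per locus `F_ST = (H_T − H_S)/H_T`, where `H_S` is the mean
within-population expected heterozygosity `2p(1−p)` and `H_T` the expected
heterozygosity at the mean frequency; for a pair this reduces to
`(p₁−p₂)²/(s(2−s))`, `s = p₁+p₂`. Only published frequencies (not
genotype-level samples) exist for the reference populations, so no
sample-size bias correction (Weir–Cockerham-style) is attempted. Loci
monomorphic in both members of a pair carry no information and are
excluded per pair, so each pair aggregates over its maximal informative
locus set. Aggregation defaults to the ratio of sums `Σ(H_T−H_S)/ΣH_T`
(standard multi-locus practice); an unweighted mean of per-locus ratios is
also provided.

**Known limitation — pairwise target under drift.** For two populations
that each drifted independently with Balding–Nichols parameter `F` from a
common ancestor, this equal-weight two-population estimator converges to
`F/(2−F)` (≈ F/2), not `F`: `E[(p₁−p₂)²] = 2F p(1−p)` while
`E[s(2−s)] = 2p(1−p)(2−F)`. This is the classical behaviour of Nei-type
G_ST with K = 2 demes — the pooled heterozygosity is computed from the
pair midpoint rather than the (unobservable) ancestral frequency. The
simulation-recovery tests therefore validate the chain against the
analytic target `F/(2−F)`. A Hudson-type estimator would target `F`
directly but would change every published-frequency F_ST value this
package reports, so it was not adopted. Relatedly, the published
IND-vs-AMR value of 0.03669 is not recovered by either aggregation of this
estimator on the published frequencies (0.02166 ratio-of-sums, 0.02211
mean-of-ratios); the originating estimator is not stated anywhere and the
value is reported, not asserted.

## MDS and clustering

Classical (Torgerson) MDS: square the dissimilarities, double-center
(`B = −½ J D² J`), eigendecompose, keep the top-k non-negative eigenpairs,
scale eigenvectors by root eigenvalues. F_ST values are fed to MDS
directly as dissimilarities (not square-rooted), matching the analysis
being reproduced. Eigenvalues within 1e-12 of zero are treated as zero;
negative eigenvalues (F_ST matrices are generally non-Euclidean) are
dropped with a warning, and requesting more dimensions than available pads
with zero coordinates. Sign convention: the first population's coordinate
in each retained dimension is non-negative, making output deterministic.

Grouping uses average-linkage agglomerative clustering (scipy linkage) cut
at the largest gap between consecutive merge heights; cutting above the
final merge (one cluster) counts as a zero-width gap, and ties break
toward fewer clusters — so an all-equal distance matrix yields a single
cluster. On the published frequencies this isolates AFR as a singleton;
whether AMR and IND form their own pair (as the original reading of the
MDS plot suggests) depends on the estimator, so only the AFR-isolation
property is asserted.

## Synthetic data

The Balding–Nichols model was chosen because it is the standard
one-parameter F_ST-generating law and makes parameter recovery well-posed:
ancestral frequency per locus from Uniform(0.05, 0.95) (or a beta law),
population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F), genotypes
Binomial(2, p_pop) under within-population HWE (the gene-counting analysis
implies no inbreeding correction). `F = 0` short-circuits to the ancestral
frequency exactly. Defaults emulate the study's conditions: 2 populations
× 64 individuals × 15 loci, F = 0.1, missing rate 0.01 (the fixture's
empirical rate is 11/960 ≈ 0.011), Poisson(50) exome-like depth, and an
impact mix (0.3, 0.2, 0.4, 0.1 over modifier/low/moderate/high) that gives
the depth/impact filter something to remove. Identical config and seed
give bit-identical output.

What the simulator does *not* emulate: linkage between loci, demographic
history, selection, genotyping error correlated with depth, and
ethnic-group substructure within a population. Passing recovery and
calibration tests therefore demonstrate correctness of the estimators
under idealized independent-locus HWE data, not robustness to real exome
artefacts.

The deterministic IND fixture places genotypes by convention where the
published marginals leave freedom: within each ethnic group,
homozygous-alternate individuals first (a minimum per group is forced
where allele counts exceed group size; the remainder is assigned greedily
in table order), then heterozygotes, lexicographic by individual id;
missing calls go to the last individuals carrying no alternate allele.
Where the ethnic-group table conflicts with the stated cohort totals
(column sums 42 vs 41 and 64 vs 65), fixture genotypes follow the cohort
totals — one allele is removed from the last positive group in table order
(rs11571707) and one added to the first group with spare chromosomes
(rs144848) — while the packaged ethnic-count table stays verbatim and the
consistency report surfaces both discrepancies.

## Validation problem sizes

The suite validates the Fisher engine on 500 fuzzed tables against exact
enumeration, null calibration on 2000 simulated tables (128 vs 1000
chromosomes), simulation recovery at F ∈ {0.05, 0.1, 0.2} with 2 × 200
individuals × 1000 loci × 10 seeds, law-of-large-numbers frequency
convergence at n = 10 000, and p-value uniformity under the null at 2000
loci. These sizes give stable pass/fail behaviour at the tolerances used
while keeping the default run fast.
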