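# Methods

## Scope

`awmpcit` implements a systems-genetics post-GWAS workflow for correlated
dairy-cattle traits: within-breed single-SNP mixed-model association,
Association Weight Matrix (AWM) construction anchored on a key trait, and
PCIT partial-correlation filtering of the row-wise co-association network.
Because the cattle datasets this workflow is normally applied to are
proprietary, the package ships a first-class synthetic data generator with
known truth; all statistical claims made by the test suite are claims
about that generator's data.

## Synthetic data generator

**Genotypes.** Each SNP receives an ancestral counted-allele frequency
drawn uniformly on a configurable interval (default 0.02–0.5), giving the
near-uniform MAF spectrum characteristic of selected SNP panels (array SNP
are pre-filtered for informativeness, unlike sequence variants). Breed
cohorts diverge by a single F-like parameter: each breed's frequency is a
Beta draw with mean p and variance F·p(1−p) (default F = 0.05, of the
order of F_ST between European dairy breeds). Dosages are binomial(2, p)
per cow — Hardy–Weinberg equilibrium within breed, linkage equilibrium
between loci. An optional block-copy LD mode (SNP within a block copy a
core SNP with a configurable mismatch rate) exists for experiments that
need non-trivial LD; it is off by default because no defensible LD
parameters are available for the target populations at desk scale.

**Gene map.** Gene lengths are exponential (default mean 15 kb, minimum
200 bp); genes are allocated to chromosomes proportionally to length and
placed with Dirichlet-distributed gaps, which guarantees non-overlap by
construction. The helper `n_genes_for_coverage` sizes the map so a target
fraction of uniformly placed SNP falls within 10 kb of a gene; with the
default demo settings (700 genes, 5 × 10 Mb chromosomes) roughly half the
genome is within 10 kb of a gene, so both the gene-assigned (set1) and
intergenic (set2) SNP classes arise, mirroring the roughly 50/50 split
reported for real 50k panels. Coordinates are 1-based inclusive
internally and converted to 0-based half-open only when writing BED.

**Phenotypes.** A configurable number of causal SNP is drawn without
replacement; each carries a dense effect vector across all 12 traits from
a multivariate normal whose correlation matrix is the target genetic
correlation — pleiotropy is universal across traits while sparsity lives
across SNP. Genetic values are dosage × effects; residuals are
independent Gaussians scaled so the realized within-breed heritability
matches the target (the within-breed convention matches both the
within-breed GWAS and the fact that yield deviations are pre-adjusted for
systematic effects). Clinical mastitis is a 0/1 trait obtained by
thresholding its latent liability at the (1 − incidence) quantile
(default incidence 0.25, consistent with a Bernoulli trait whose reported
standard deviations are 0.24–0.36). Somatic cell score is handled as a
continuous yield deviation; the transform SCS = 3 + log2(SCC/100,000) and
its exact inverse are provided for working with raw cell counts
(cells/mL).

**Default genetic parameters.** The default heritabilities and genetic
correlations are published pedigree-REML estimates for a
Montbeliarde-like population (h² from 0.03 for clinical mastitis to 0.68
for fat content; strong positive correlations within the production
block, moderate positives among udder conformation traits). Printed
tables are not guaranteed positive semi-definite, so the matrix is
projected to the nearest correlation matrix (eigenvalue clipping at 1e-6
with diagonal renormalization) once at import.

**What the generator does not emulate.** No pedigree or demographic
history, no genotyping error or imputation error (dosages are complete by
construction; missing-data handling exists only for user-supplied input),
no LD by default, no selection or assortative mating, no
repeated-lactation structure (each cow has one record per trait). Tests
passing on this generator therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to the full
messiness of field data.

## GWAS

**QC.** A SNP passes when call rate > 0.99, MAF > 0.02 in at least one
breed, and the within-breed Hardy–Weinberg 1-df chi-square p-value is
≥ 1e-4 in every breed (the reported `hwe_p` is the minimum across breeds;
testing within breed avoids flagging Wahlund-effect departures that a
pooled test would create). The report records the first failing rule per
SNP in the order call_rate, maf, hwe.

**GRM.** Exact evaluation of the standardized cross-product formula with
observed cohort allele frequencies; the analysis convention is within
breed, so the GRM is computed on the breed subset. SNP with
2p(1−p) < 1e-6 raise an error naming the SNP (or are dropped with a
warning in pipeline use, where post-QC near-monomorphism within a single
breed cohort is still possible).

**REML.** The null model y = 1μ + u + e is fitted by profiling the
residual variance and maximizing the restricted likelihood over
log(σ²_u/σ²_e) with a bounded scalar search on [−10, 10], tolerance 1e-8,
after a one-time eigendecomposition of G (eigenvalues below −1e-8
relative are rejected as non-PSD; tiny negatives are clipped to zero).
REML rather than ML avoids the downward bias in σ²_u from estimating the
mean.

**Scan.** Per SNP, the fixed-effect estimate is generalized least squares
under V = σ²_u G + σ²_e I with variance components fixed at the null fit
(a per-SNP refit is available as a slow option). The test statistic
re-estimates the residual scale from the per-SNP GLS residuals and refers
s/se to t(n−2). This choice makes the scan reduce *exactly* to the OLS
t-test when G = I, keeps type-I error calibrated under the null
(measured 0.048 at nominal 0.05 in the packaged calibration), and is
scale-invariant, so the unidentifiable σ²_u/σ²_e split under G = I is
harmless. The candidate SNP remains in G (no leave-one-chromosome-out);
with all autosomes in G this induces a small conservative shrinkage of
large effects, the standard behaviour of the convention adopted.
Constant-in-cohort SNP are reported missing with a reason. Bonferroni
uses m = panel SNP count.

## AWM

Selection thresholds use raw p < 0.05 (strict) by default; a config key
switches step 1 to Bonferroni-adjusted p for users who prefer the
conservative reading. The step-3 "at least N other traits" count defaults
to the data-driven step-2 average (rounded to nearest integer) and can be
overridden. "Udder traits" for the ≥2-udder rule are the four non-key
conformation traits (FUA, UC, UB, FTP) — the key trait cannot count as
one of its own supporting traits, and SCS/CM are health traits, not
conformation. The 10-kb annotation window is inclusive at the boundary;
distance is the bp gap from the SNP position to the nearest interval
edge, ties broken toward the lower-start gene. One SNP per gene is kept
by most-associated-traits, then lowest mean raw p across all 12 traits,
then lowest position (a deterministic final tie-break the verbal rule
lacks). Candidate rows are the pleiotropy-filtered (secondary) set; a
`keep_all_primary` flag instead retains every key-trait-associated SNP,
for sensitivity analysis of the filter. z-scoring uses the population-SD
convention computed per trait over *all* tested SNP, so cell values are
comparable across rows regardless of which SNP were selected.

Multi-breed handling: AWMs are built and PCIT is run per breed; the
cross-breed result is the three-way intersection of AWM SNP (all seven
Venn regions are reported), with a `stacked` mode that concatenates the
three breeds' trait columns over the common SNP and runs a single PCIT —
the merge order used for the published single-network analyses is not
documented, so both are provided and per-breed is the default.

## PCIT

First-order partial correlations and the mean-of-three-ratios local
tolerance are implemented exactly as specified in the original algorithm;
the packaged naive O(n³) triple loop is the correctness oracle and the
vectorized per-third-variable sweep is verified edge-identical to it on
random and adversarial (exact ±1, exact 0) inputs. Numerical guards:
correlations are clamped to |r| ≤ 1 − 1e-9 before any trio arithmetic;
ratio terms with |direct r| < 1e-12 are skipped and the tolerance
averages the remaining terms; a trio with no valid term never rejects;
edges with r exactly 0 are recorded but never significant. Above a
configurable node count (default 3,000) the filter refuses without
`force=True`, since trio enumeration is cubic.

## Pipeline and determinism

All stage seeds derive from one master seed via SeedSequence spawning.
Numeric artifacts are written with a fixed `%.10g` format, and the JSON
manifest (stage counts + sha256 of every text artifact) is byte-identical
across repeated runs with the same configuration — the packaged
end-to-end check asserts this. Every manifest count is re-derivable from
the written artifacts.

## Problem sizes used by the validation suite

Chosen as the smallest sizes at which each property is statistically
decidable: GRM oracle on 20 × 50 panels (tolerance 1e-12); null
calibration with 500 cows × 2,000 SNP × 50 trait replicates (100,000
tests, so 0.05 ± 0.01 is a ~20σ band); planted-correlation recovery with
2,000 cows, 2,000 SNP, 500 causal, 20 replicates at heritability 0.6 for
every trait. The 0.6 value is the yield-deviation worked-example
heritability; it matters because SNP-based correlations are attenuated
relative to genetic correlations by effect-estimation noise
(attenuation ≈ λ_FUA^½ λ_UB^½ with λ = signal/(signal+noise) per trait),
and yield deviations are precisely the high-heritability pseudo-phenotypes
the method is defined on. At these sizes the expected estimate is ≈ 0.3–0.45
against the planted 0.40, and the packaged experiment measures ≈ 0.41–0.47.

## Known limitations

* SNP-based correlations are attenuated at low heritability or low sample
  size; the package reports them as computed and makes no shrinkage
  correction.
* The AWM row count at desk scale is tens of rows, not thousands; network
  statistics on such small graphs are illustrative, not biological.
* No gene-ontology or pathway annotation: network export (TSV/GraphML) is
  the hand-off point to external annotation tooling.
* Pedigree-based REML genetic correlations are not computed; the
  simulator's true correlations serve as the comparison standard, and an
  externally produced table can be supplied for comparison.
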