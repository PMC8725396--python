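# Methods

This note documents the models, the synthetic-data generators, the
numerical choices and the known limitations of `petalmorph`.

## Cell-shape statistics

A cell outline is an ordered planar polygon in micrometres. Solidity is
`S = A / A_hull` with `A` the absolute shoelace area and `A_hull` the area
of the convex hull (Qhull); lobeyness is `CL = 1 − S ∈ [0, 1)`. `CL` is
invariant under any affine map of the plane (an affine map scales all
areas by the same determinant and maps the hull of a set to the hull of
its image), hence in particular under translation, rotation and uniform
scaling. `CLWR` is the ratio of the axis-aligned extents along the
declared longitudinal axis and its perpendicular; it is *not*
rotation-invariant by construction — the longitudinal axis is metadata
declared with the data (default: the y axis of the polygon file), never
inferred from the shape, because the measurements are made on oriented
image crops. Self-intersecting outlines are rejected, not repaired:
silent repair would hide digitization faults. Vertex coordinates are
centred before area computations to avoid catastrophic cancellation for
small shapes far from the origin.

Per-petal cell numbers are estimated per image as
`(cells counted / image area) × petal area`, and summarized by the
arithmetic mean and the standard error `sd/√n` over the 8–9 images of a
petal; a single image leaves the SE undefined and is an error.

## The heterochrony regression

Each response (`CL`, `log CA` with the natural log, `CLWR`) is fitted by
OLS on the full factorial expansion `(p + p²) × stage × species` with
treatment coding; the reference levels default to the flower bud and the
ancestral-type species, so lower-order terms read as the basal species'
bud curve. Observations are treated as independent — no random effects
for individual or image — mirroring the plain linear models the analysis
is built around; this understates uncertainty if individuals differ
systematically and is a documented limitation. Two-sided p values use the
t distribution with `n − 12` df. A rank-deficient design raises an error
naming the aliased columns.

The classifier for delayed differentiation evaluates three conditions on
the CL fit at level α (default 0.05): (i) a significant bud gradient in
the basal species (`p` or `p²`); (ii) a significant `p:species`
interaction of opposite sign to that gradient (the derived species' buds
are flattened); (iii) a significant `p:stage:species` interaction of the
gradient's own sign (the gradient is restored at maturity). (i)∧(ii)∧(iii)
→ `delayed_differentiation`; (i) alone → `no_delay`; otherwise
`indeterminate`. Degenerate fits (e.g. a constant response gives 0/0 t
statistics) count as non-significant. No multiple-testing correction is
applied across the three responses.

## Epidermis generator

Cells are lobed star polygons `r(θ) = R(1 + a sin kθ)` with `k = 6` lobes
(typical pavement-cell multiplicity; configurable) discretized at 72
vertices (< 0.5 % solidity discretization error for k ≤ 8). Because
solidity is affine-invariant, lobe amplitude alone controls `CL`: the
amplitude is read off a 400-point monotone calibration table of `CL(a)`
computed once per `(k, n_vertices)`, the outline is stretched along y to
the target `CLWR` and scaled uniformly to the target area, making area
and `CLWR` exact by construction and `CL` accurate to ~1e-4. The maximal
reachable lobeyness for `k = 6` is ≈ 0.566 (`a < 1` keeps the radius
positive); targets beyond it raise an error naming the image position.

Scenario presets prescribe quadratic target curves per (species, stage)
over nine equally spaced midrib positions, three individuals per species,
and a configurable number of cells per image (default 40 generated; the
measurement protocol samples 10). `pedomorphic`: basal species A carries
an apical lobeyness gradient (`0.02 + 0.50p − 0.22p²`) at both stages;
derived species B is flat (`CL ≈ 0.02`) in buds and acquires the basal
curve only at maturity. `non_pedomorphic`: both species share A's curves.
Per-cell targets receive multiplicative log-normal noise (sd 0.12),
truncated at ±3 sd — truncation keeps targets positive and inside the
reachable lobeyness range. Recorded metrics are *measured* from the
generated polygons, so the generator's tables are exactly what the
measurement stage would produce from its outlines.

What the generator does not emulate: cell packing (cells are laid out on
a grid, not tessellated), lobe-shape irregularity (all cells share the
sinusoidal lobe form and orientation), measurement/segmentation error,
and within-image spatial correlation. Passing tests therefore demonstrate
correct recovery of the planted statistical structure, not robustness to
segmentation artefacts in real SEM data.

## Count simulator

The default design matches the study's sampling: 3 bud + 4 mature
libraries for species A and 3 + 3 for species B (13 libraries). Gene
baseline means are log-normal (median 200, sd(log) 1.2); counts are
gamma–Poisson (NB) with dispersion α = 0.05 (typical for tight bulk
replicates), with a Poisson branch for α < 1e-8. Each gene is private to
either species with probability 0.2 per species (it then appears in only
that species' isoform table); shared genes receive a per-gene
stage-independent species-divergence shift `N(0, 2.0)` on the log2 scale
for species B. The sd of 2 makes roughly half to three-quarters of genes
differentially expressed between species — the magnitude seen between
genera that diverged tens of millions of years ago — and is what makes
cross-species contrasts a noisy background for signature enrichment.
Planted signatures shift their genes by `±log2fc` in one (species, stage)
group; a configurable `opposite_fraction` of each signature is shifted
the other way, reflecting that real functional modules contain members
highly expressed at either stage. The bundled demo plants a
predominantly mature-high TCWI module (40 genes, δ = 0.75, 35 % opposite)
and a predominantly bud-high ICWP module (30 genes) in species B, plus
unshifted FDM/CE sets.

Each species' gene means are split over `1 + Poisson(1.5)` isoforms by
symmetric Dirichlet proportions; isoform counts are drawn at the isoform
level. The hit table gives every isoform a true hit with e-value
10^−U(4,60) (2 % of isoforms instead draw only an above-threshold decoy
and are lost at filtering, as happens with BLAST in practice), and 15 %
gain a weaker secondary hit to a random gene to exercise best-hit
selection. Annotation descriptions carry the signature keyword vocabulary
for planted genes and neutral protein names otherwise. Library depths
vary log-normally (sd 0.25, truncated at 3 sd). The ground truth records
every planted per-gene shift and the exact log2 fold-change of each of
the four standard contrasts.

## Merge and normalization

Hit filtering reads the threshold "e ≤ 10e−3" as 1e-3 (the conventional
BLAST notation; configurable). Best-hit selection — highest bitscore,
ties by smaller e-value, then lexicographic gene id — is a determinism
choice; an all-hits mode is available behind a flag. Collapsing sums
mapped isoform counts per reference gene and drops unmapped isoforms
(count conservation is exact for mapped isoforms); the cross-species
merge is a strict inner join with a report of dropped genes.

TMM follows the weighted trimmed-mean-of-M-values recipe: reference
sample = the one whose upper-quartile/library-size ratio is closest to
the mean of those ratios; per-sample log2 factor = precision-weighted
(inverse asymptotic variance) mean of M values after trimming 30 % of M
and 5 % of A at each end, genes with a zero in either sample excluded;
factors rescaled to geometric mean 1. The implementation reproduces
edgeR's `calcNormFactors(method="TMM")` to ~1e-10 on a frozen fixture.
cpm uses the effective (factor-adjusted) library size; feature length is
deliberately not corrected for. Filtering (≥ 1 cpm in ≥ 3 samples,
boundary inclusive) is applied after normalization, never before. QC is
an SVD-based PCA of centred `log2(cpm + 1)` (deterministic sign
convention: the largest-magnitude coordinate of each component is made
positive) and average-linkage clustering on 1 − Pearson correlation.

## Differential expression

Per gene, counts follow `NB(μ_s, α_g)` with
`log μ_s = log(effective library size_s) + b0 + b1·x_s`, fitted by IRLS
(vectorized across genes, damped steps, 50 iterations, tolerance 1e-8).
The Wald statistic `b1/SE(b1)` is referred to the standard normal and
`log2FC = b1/ln 2`. Dispersion is a method-of-moments estimate
`max(0, (s² − m)/m²)` on size-normalized counts, pooled across the two
groups with `(n_g − 1)` weights, then averaged 50/50 (arithmetic) with a
mean-dispersion trend that is log-linear in the log mean. The trend is
fitted to *arithmetic bin means* of the raw estimates over 12
log-mean quantile bins: per-gene moment estimates at n = 3 are so noisy
that fitting in log space would be badly Jensen-biased downward and the
tests anticonservative. Floor 1e-8; all-zero genes are untestable (NA).
Genes with one all-zero group are flagged and get a fold-change from a
0.5 pseudo-fraction on the group means, but no Wald statistic. BH
adjustment excludes NAs from the test count.

This is deliberately *not* a DESeq2 re-implementation: no Cox–Reid
adjusted dispersion likelihood, no fold-change shrinkage, no independent
filtering, no outlier handling, and TMM-effective library sizes rather
than median-of-ratios. Downstream use (log2FC ranking and DEG counting)
needs the NB Wald machinery, not DESeq2's exact numerics; every result
table carries this note in its metadata.

## Signature enrichment

Signatures are resolved by case-insensitive substring match of the
keyword lists against all annotation description fields, with one
refinement: short all-uppercase gene-family symbols (ROP, PIN, TCP) are
matched case-sensitively at a word start, tolerating trailing
digits/capitals (PIN3) but not embedded lowercase matches — "ROP" must
not match "chlorophyll". Signature overlap (DELLA sits in both FDM and
CE) is permitted; signatures are tested independently.

Genes are ranked by descending log2 fold-change, ties broken
lexicographically, NA-statistic genes excluded. The enrichment score is
the signed extreme of the weighted running sum (weight exponent w = 1 on
|log2FC|; w = 0 gives the classical Kolmogorov–Smirnov variant): hits
advance by `|m_i|^w / Σ_hits |m|^w`, misses retreat by `1/(N − n_hits)`.
The extremes of the piecewise-linear running sum occur at hit steps, so
the implementation evaluates only the 2·n_hits candidate deviations; a
tie between the positive and negative extreme resolves to the negative
one (the convention of the common fast implementations). The permutation
null redraws the signature's positions uniformly without replacement
(equivalent to permuting the rows of the ranked table); the p value is
`(1 + #{same-signed null with |ES| ≥ |ES_obs|}) / (1 + #{same-signed
null})`. BH adjustment is applied across the signatures within each
contrast (the family the reported adjusted p most plausibly refers to;
recorded as an assumption). Whether labels or metric values are permuted
is indistinguishable here because positions, not values, are redrawn.

## Pipeline, determinism and problem sizes

A single YAML config carries all thresholds (defaults: e-value 1e-3,
1 cpm / 3 samples, FDR 0.05, α 0.05, 1000 permutations, basal levels =
bud and the ancestral-type species) and the seed; every run writes a
manifest with the config hash and SHA-256 checksums of all outputs, and
identical config + inputs reproduce identical checksums for every
deterministic stage. All randomness flows through
`numpy.random.default_rng` seeded from the config.

The test suite and the acceptance script run the full synthetic studies
at the analysis scale actually used: 1 080 measured cells per morphometric
study (2 species × 2 stages × 3 individuals × 9 images × 10 cells), 100
study replicates for verdict recovery, 200 replicates for each
permutation-calibration check, 2 000 genes × 20 replicates for the null
false-discovery fraction, and 2 000-gene demo datasets for the expression
arm — sizes chosen so a complete run takes on the order of a minute on a
single CPU while keeping Monte-Carlo error well inside the tested bands.

## Known limitations

- No mixed effects: individuals and images are treated as exchangeable.
- The NB Wald test is anticonservative deep in the tail for n = 3 vs 3
  (normal reference, noisy dispersions); BH-level behaviour is verified
  by simulation, single-gene extreme p values should not be over-read.
- The epidermis generator's cells are stylized stars; conclusions about
  segmentation-noise robustness cannot be drawn from it.
- Signature keyword matching is a stand-in for curated annotation
  pipelines; on real annotations the keyword lists should be reviewed
  against the reference transcriptome's vocabulary.
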