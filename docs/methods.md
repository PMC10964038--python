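# Methods

`morphotx` implements an individual-level imaging-transcriptomics
analysis: morphometric similarity networks (MSN) from multi-feature
cortical parcellations, a covariate-adjusted case-control t-map over
regions, partial least squares (PLS) linking that map to regional gene
expression with spin-permutation inference and bootstrap gene Z-scores,
and downstream gene-set characterization. Everything runs end-to-end on
synthetic data with planted effects, so every stage is testable without
access to an MRI cohort or a post-mortem expression atlas.

## Morphometric similarity

Each subject contributes a region × feature table of seven anatomical
measures per cortical region (cortical thickness CT, gray-matter volume
GM, surface area SA, Gaussian curvature IC, mean curvature MC, curved
index CV, folding index FD). Within a subject, each feature is
z-normalized across regions (sample SD, ddof = 1); the MSN entry
(i, j) is the Pearson correlation between regions i and j's normalized
7-feature profiles. No thresholding is applied. A region's **regional
MS strength** is the mean of its off-diagonal row — the sum convention
differs only by the constant factor (n − 1) and leaves every downstream
t-statistic unchanged (asserted in the tests); the mean is reported for
its bounded range. Correlations over only 7 feature points are noisy by
construction; that noise is part of the method, and no significance
filter is applied to network entries.

A region whose normalized profile has zero variance across features has
undefined similarity. This has probability zero for continuous data, so
it is treated as an input error rather than silently imputed.

## Case-control model

Per region, ordinary least squares of regional MS on
`[intercept, sex, age, group]` with the case − control contrast:
t = β_group / SE, two-sided p on n − 4 df, Benjamini–Hochberg FDR across
regions (default q ≤ 0.05). Sex is coded female = 0 / male = 1; the
group t is invariant to this choice (tested). Education and cognitive
scores are deliberately not covariates — the model mirrors the standard
two-covariate design. A zero-residual (perfectly separated) region is
reported with the smallest positive double as its p-value rather than
an infinite t. Descriptive outputs: Pearson correlation of mean control
regional MS with the t-map, and per-(region, score) clinical
correlations within patients under a joint FDR.

## Expression preprocessing

The microarray-like input arrives already keyed by region (sample-to-
region mapping at the coordinate level is out of scope). Per donor:

1. drop probes whose above-background fraction is < 0.5;
2. per gene, keep the probe best correlated with an RNA-seq-like
   reference profile (ties broken lexicographically by probe id);
3. normalize each gene's regional profile with the **scaled robust
   sigmoid**: `sigmoid((x − median) / (IQR / 1.35))`, then min–max
   rescale to [0, 1]. IQR/1.35 approximates the SD for Gaussian data;
   the transform is strictly order-preserving and robust to outliers.

Across donors, genes are kept when their mean across donor-pair
regional-profile correlations (differential stability) reaches the
threshold (default 0.3 — the threshold is a config value, not a claim
about any particular atlas), and donor matrices are averaged.

## PLS, spin test, bootstrap Z

Predictors (genes) are column-standardized; the response (the regional
t-map) is centered. For a univariate response, the first NIPALS weight
vector is exactly the normalized centered cross-covariance `X'y`, so
PLS1 is computed in closed form, with rank-one deflation for the second
component (two components are extracted for the variance table; only
PLS1 is propagated). Variance explained per component is the squared
correlation between the component's region scores and the response.
The component sign is fixed so that corr(scores, t-map) ≥ 0, making
PLS1+ genes those overexpressed where MS increases.

**Spin test.** Parcel centroids live on the spherical inflation of one
hemisphere — a complete unit sphere, which is what makes rotation
permutations closed. For each of `n_rotations` (5000 by default;
calibration experiments use 199) draws: a uniform random rotation (QR
decomposition of a Gaussian matrix with determinant fixed to +1),
rotation of the centroids, and a one-to-one greedy nearest-centroid
matching (optimal Hungarian matching available via
`method="hungarian"`); the spun map is an exact permutation of the
original values. p = (1 + #{null ≥ observed}) / (1 + n_rotations),
with guaranteed floor 1/(n_rotations + 1). A vectorized path
(`spin_test_pls`) evaluates all rotations in one batch of matrix
products and accepts precomputed permutations, which the calibration
experiments reuse across replicates (the spatial null does not depend
on the response values).

Two properties of discrete spin tests worth knowing:

* the null statistics of different rotations are mutually correlated
  (they are coherent transports of the same map), which makes the test
  somewhat conservative in the extreme tail for maps without spatial
  structure;
* for a map that is itself an exact smooth field on the same grid as
  the predictors, the ~0.1 rad parcel-matching error slightly roughens
  every spun map, which biases the test liberal. The realistic case — a
  t-map carrying estimation noise on top of spatial structure — sits
  between the two, and the null-calibration test checks the 5% tail
  there. The guaranteed ordering (a naive unstructured permutation is
  at least as anticonservative as the spin test on smooth maps) is
  asserted separately.

**Bootstrap Z.** Regions are resampled with replacement (the PLS
operates purely on region-level vectors, so regions — not subjects —
are the exchangeable unit); each replicate's weight vector is
sign-aligned to the original by the sign of their dot product, which
prevents the SE inflation a component sign flip would cause. SE = SD of
aligned replicate weights; Z = weight / SE; two-sided normal p with BH
q. PLS1+ = {Z > 5, q < 0.05}, PLS1− = {Z < −5, q < 0.05}; both
thresholds are configurable (a stricter q = 0.005 is also in use in the
literature; q = 0.05 is the default here).

## Gene associations and enrichment

Gene symbols match exactly after uppercasing (no alias expansion, no
external databases). Overlaps are always taken inside the background
universe. The differential-expression comparison correlates bootstrap Z
(raw weights by flag) with the signed DEG value *within each selected
PLS1 set*, per direction, with one joint FDR per battery; overlaps
below 3 genes are flagged rather than correlated. Note that at
desk-scale set sizes (tens of genes, a handful of them causal) these
per-direction correlations are noisy; the planted signal is clearest in
the union-of-sets correlation the acceptance script also reports.

Cell-type assignment draws `n_perm` random query-sized gene sets from
the background without replacement and compares observed overlaps
(p with the +1 correction, BH across the seven cell classes). Because
overlap counts are integers, these permutation p-values are
super-uniform (conservative at fixed thresholds); the calibration test
therefore checks validity at the 5% tail plus a location bound rather
than exact uniformity. Pathway over-representation is a one-sided
hypergeometric tail with fold enrichment; the multi-list comparison
reports the intersection of the two result sets' top-k terms (ties in p
broken by term name). The web-service meta-analysis this stands in for
is intentionally replaced by this transparent in-repo computation.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed and
the tests run against them.

* **Geometry** — parcels are a Fibonacci lattice on the unit sphere
  (one hemisphere's spherical inflation), 180 regions by default.
* **Anatomy** — the regional mean feature matrix is
  `M[r] = a_r·g + 0.6·f_r`: a fixed unit feature contrast `g`
  (archetype) scaled by a skewed smooth scalar field `a`
  (`hub_strength` = 1.5 times a Gaussian field plus a scaled
  chi-square-like term), plus smooth residual feature fields. Fields
  are Gaussian processes with squared-exponential covariance in
  great-circle distance, length scale `spatial_smoothness` = 0.5 rad.
  The skewed low-rank term produces the hub structure real MS maps
  show: regions resembling much of the cortex (positive regional MS)
  and differentiated regions (negative). Subjects add i.i.d. feature
  noise (`noise_sd` = 0.5); a small regionally varying sex effect
  (scale 0.2·noise_sd) makes covariate adjustment non-trivial.
* **Planted effect** — a reserved "lesion axis" (a zero-mean feature
  contrast projected out of all baseline profiles, so healthy cortex
  expresses no covariance along it). In case subjects, each effect
  region's row-centered profile is rotated toward the axis with
  displacement `effect_size·noise_sd` (effect_size = 2), signs
  alternating across effect regions; the rotation preserves the
  profile norm (so noise attenuation is untouched) and shrinks all of
  the region's correlations by the rotation cosine, moving regional MS
  toward zero. Effect regions default to the 40 regions most
  susceptible to this plant (rotation angle² × |baseline MS|) — hubs
  and anti-hubs — which also reproduces the characteristic negative
  correlation between control regional MS and the t-map. Sign
  balancing prevents lesion regions from becoming similar to each
  other and cancels column-mean artifacts of z-normalization.
* **Planted direction bookkeeping** — the per-region planted MS change
  is the Monte-Carlo expectation of the case-minus-control difference
  under the full noisy model (200 paired virtual subjects per group
  from an independent seeded stream), not the noiseless difference:
  noise attenuation is part of the generative distribution, and a
  noiseless computation misstates it.
* **Expression** — each gene an independent standardized smooth field;
  the 10 causal genes are `sign·(α·z(effect map) + √(1−α²)·field)`
  with α = 0.7, signs half positive / half negative, so their
  profile-map correlation is ≈ ±0.7 by construction. The pipeline
  passes the *realized* case-control MS change map as the effect map.
  Probe tables (1–3 probes per gene, donor shifts, low-quality probes
  with poor above-background fractions, always ≥ 1 good probe) and an
  RNA-seq-like reference emulate the microarray input; two donors by
  default.
* **Gene sets** — seven cell-type sets of 50 genes from the 500-gene
  universe; one set includes each causal gene with probability
  `min(1, enrichment_ratio · 50/500)` (ratio 5 ⇒ 0.5) and is otherwise
  filled uniformly; the remaining sets are uniform draws. DEG values
  are `sign·α` for causal genes plus Gaussian noise at SNR
  `deg_snr` = 1; the curated disease list is the causal genes plus
  random extras.

**What the generator does not emulate:** cortical geometry beyond
centroids (no meshes or folding), scanner/site effects, feature-feature
covariance structure beyond the single archetype, spatial
non-stationarity, donor-specific expression batch structure, and any
dependence of clinical scores on anatomy (clinical scores are
independent noise, matching the null result they are compared against).
Passing tests therefore demonstrate the pipeline's statistical
machinery — calibration, recovery, invariances — under an idealized but
structurally faithful model, not performance on real MRI or microarray
data.

## Calibration and recovery experiments (problem sizes)

The acceptance tests and `scripts/acceptance.py` use desk-scale
configurations chosen to make the experiments sharp and quick:

* type-I error of the regional model: 1000 null cohorts (40 regions,
  12 + 12 subjects, effect size 0);
* spin-test null: 200 replicates of a null-cohort t-map (40 + 30
  subjects, 180 regions) against independent smooth expression
  (500 genes), 199 rotations with one shared permutation set;
* cell-type null: 500 random queries of 40 genes against seven 30-gene
  sets in a 300-gene background, 199 permutations;
* recovery: 50 replicates of the full arm (85 + 62 subjects,
  180 regions, 500 genes, 10 causal at α = 0.7, 199 rotations,
  200 bootstraps);
* planted-enrichment detection: 100 replicates at ratio 5 with a
  40-gene causal query (at 10 causal genes the Bernoulli-inclusion
  construction caps detection probability below the target by simple
  binomial arithmetic, so the calibration uses the query size at which
  the planted ratio is identifiable).

## Numerical choices

Kernel matrices carry a 1e-8 jitter before Cholesky; smooth fields are
re-standardized empirically. Zero-variance predictors are an error in
the main PLS fit and floored (1e-12) inside bootstrap replicates, where
resampling can degenerate a column; degenerate bootstrap responses are
redrawn (logged). p-values are floored at the smallest positive double;
permutation p-values use the +1 correction and can never be 0. All
file outputs use a fixed float format so identical seeds give
byte-identical artifacts; the pipeline manifest records a sha256 per
artifact plus the seed and a config hash, and `resume=True` skips
stages whose artifacts verify.

## Known limitations

Spin-test biases for perfectly smooth same-grid maps (above); discrete
permutation p-values are conservative; the per-direction DEG
correlations are underpowered at desk scale; the generator's archetype
model produces a narrower regional-MS range than real cortex; 7-point
profile correlations make individual MSN edges noisy by design, and
only their aggregation over regions and subjects is interpretable.
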