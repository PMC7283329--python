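# Methods

## Imaging model

Raw counts are converted to relative reflectance per pixel and band by
white/dark balancing, `I = (I₀ − D)/(W − D)`, where `W` is the white-panel
image and `D` the dark-current image. Any pixel/band with `W − D ≤ 0` aborts
calibration with the first offending index named: a non-positive denominator
means the references are unusable, not that the pixel should be patched.
Reflectance is not clipped by default — values slightly outside [0, 1]
(specular pixels, noise) are preserved because Savitzky–Golay derivatives
downstream are sensitive to artificial flat regions; clipping is available as
an option.

Grain pixels are found on the band nearest 750 nm (nearest-band lookup, no
interpolation: at ~4 nm spacing interpolation is immaterial). Hand-drawn
regions of interest are not reproducible, so the default is an automatic
Otsu threshold with a fixed-threshold override.
Connected components under `min_area = 50 px` are removed as background
noise; surviving components are assigned to samples by majority vote over a
per-pixel sample map (or a spatial grid). The feature matrix is the
per-sample mean spectrum; per-pixel pooling is deliberately not used, since
the sample (not the grain or pixel) is the unit of genetic analysis.

## Spectral preprocessing

Eight per-spectrum operators are provided: centered moving-average smoothing
(window 5), mean/max/range normalization, SNV (sample sd, n−1), MSC
(regression on a reference spectrum, default the training-set column mean —
stored with a fitted model so test spectra are corrected without leakage),
and SG first/second derivatives (window 7, polyorder 2, polynomial edge
handling). "Smoothing" is implemented as a moving average; an SG smoother is
an equally defensible reading and the choice is flagged here. Window and
polyorder defaults are conventional chemometrics values and are exposed in
config. The pipeline default is no preprocessing: under controlled
acquisition the transforms leave downstream regressions essentially
unchanged, and the operators remain available and fully tested.

## PLS-DA, VIP and LDA

Class membership is coded as a binary indicator matrix. X is centered and
scaled to unit variance per band; Y is centered. Components are extracted by
the iterative bilinear (NIPALS) algorithm with X- and Y-deflation — chosen as
the reference algorithm because its invariants (mutually orthogonal score
vectors; full-component equivalence to least squares) are directly testable.
The component count, when not fixed, is chosen by 5-fold cross-validated
prediction error on the training rows. Validation uses a stratified,
seed-controlled 10% holdback excluded from all fitting.

VIP scores follow the standard definition with the Y-variance explained per
component as weights; mean(VIP²) = 1 holds algebraically and is asserted in
the tests. Selection keeps bands with VIP ≥ 0.8, optionally intersected with
local extrema of |β| (the exact rule combining coefficients with VIP is
underdetermined; the intersection flag covers both readings).

LDA is Fisher's canonical discriminant with equal priors (holdback sets are
class-balanced), at most C − 1 axes, nearest-class-mean classification in
canonical space, and a relative ridge of 1e-6 on the pooled within-class
covariance for the bands ≫ samples regime.

## Wavelength groups and spectral traits

Bands are clustered by K-means (20 restarts, best inertia) on their
standardized across-sample profiles — each band is a point in sample space —
and the labels are snapped to k contiguous nm ranges by a dynamic program
that maximizes agreement with the K-means labels, with blocks taking clusters
in order of mean band position. The clustering feature space is not uniquely
determined by the problem; standardized profiles were chosen because they
group bands by the *shape* of their variation, which is what ties a range to
a trait. Contiguity is enforced because spectral absorption features are
contiguous in wavelength.

Each group's spectral trait is the first principal component of its centered
columns, with the sign fixed so PC1 correlates positively with in-group mean
reflectance (chalky grains are brighter, so larger PC1 ⇒ more chalk). Trait
association is simple linear regression with the F-test p-value and
significance marks (** p < 0.01, * p < 0.05, ns otherwise). The GWAS trait is
the PC1 of the 702–922 nm range by default (the range is a parameter).

Heatmap clustering is average-linkage on 1 − Pearson r (or Euclidean)
distances after optional per-row min–max normalization to [0, 1].

## Mixed-model association scan

Genotypes are 0/1/2 alt-dosages; QC drops markers with missing rate > 20% or
MAF < 0.05 (MAF over non-missing calls). Structure covariates are the top 3
principal components of the mean-imputed, √(2pq)-standardized genotype
matrix; kinship is the VanRaden centered cross-product. Both use mean
imputation; the scan itself excludes missing calls marker-wise, which is the
cleaner choice for inference (the sub-panel kinship is re-eigendecomposed per
missingness pattern and cached).

Each marker is tested in `y = μ + Cγ + x_m β + u + ε` with
`u ~ N(0, σ²_g K)`. The variance ratio δ = σ²_e/σ²_g is re-estimated by REML
for *every marker* (no P3D/compression): rotating by the eigenvectors of K
diagonalizes the covariance, so each candidate δ costs one weighted least
squares solve; the REML criterion is minimized on a 61-point log grid over
[1e-5, 1e5] followed by bounded scalar refinement. The marker test is a Wald
t-test on β with n − q degrees of freedom — with K = I this reduces exactly
to the OLS single-coefficient F-test, which is asserted at 1e-8. Marker R² is
the incremental generalized-least-squares variance explained at the fitted δ.
The kinship estimator and test statistic are defaults chosen from mixed-model
GWAS convention, not facts of any particular upstream tool.

Multiple testing uses Storey q-values with π₀ from a cubic-spline smoother
over λ ∈ {0.05, …, 0.95}; π₀ = 1 recovers Benjamini–Hochberg exactly and is
the fallback. Genome-wide significance is a fixed p ≤ 10⁻⁶ cutoff.
Manhattan/QQ tables carry cumulative coordinates, −log₁₀ p, expected
quantiles and the genomic inflation factor λ_GC.

## Segments and candidate genes

Each significant SNP seeds a 1-based inclusive interval of ±100 kb, clipped
to [1, chromosome length]. Intervals that overlap *or abut exactly*
(stop + 1 = start) merge transitively — the only reading of "extended if
additional significant SNPs fall in the window" that yields deterministic,
order-independent segments; abutting intervals merge because a SNP at the
junction would otherwise belong to two segments. The peak SNP is the
minimum-p marker, ties broken leftmost. Overlap queries report ≥ 1 bp
intersections between internally sorted, disjoint sets; n-way queries
compose pairwise. Candidate genes are annotation spans intersecting
±150 kb around the peak; distance is span-to-point (0 when the span contains
the peak), not TSS-to-point: the search is for genes within a distance, not
for promoters.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes:

- **Genotypes**: Balding–Nichols allele frequencies around ancestral
  p₀ ~ U(0.1, 0.9), one Fst parameter (default 0.15), 3 sub-populations,
  markers on 5 chromosomes, missing calls MCAR at 2%. Causal loci are drawn
  among clearly polymorphic markers so they survive MAF filtering.
- **Chalk**: baseline 10% + additive causal effects (defaults 8, 6, 5 chalk
  percentage points per alt allele — jointly the dominant variance source) +
  sub-population and environment shifts + N(0, 3²), clipped to [0, 100].
- **Scenes**: grains as non-overlapping jittered ellipses (only masks and
  mean spectra are consumed downstream, so shape realism is irrelevant), one
  grid cell per sample, 400–1004 nm at 4 nm. A pixel's reflectance is the
  bran-class baseline (classes differ chiefly in the visible range and
  converge in the NIR), plus a chalk-proportional sine loading supported only
  on 690–920 nm (linear in chalk, matching the near-linear associations the
  chemometrics presumes), plus small environment band offsets and
  sub-population visible offsets, plus N(0, 0.01) pixel noise. Bran-class
  frequencies differ by sub-population, which is what makes sub-population
  visible in the spectra. Raw counts are constructed as D + I(W − D) with a
  smoothly varying white reference, so calibration recovers the designed
  reflectance exactly at zero noise.

Not emulated: sensor PSF, specular highlights and radiometric realism;
linkage disequilibrium beyond sub-population structure (markers are
independent given the sub-population); pedigree; pigmented (red/purple) bran.
Passing tests therefore demonstrate correctness of the algorithms under the
assumed structure, not performance on real instruments or real panels — in
particular, real chalk–reflectance relations are noisier and classification
accuracies on synthetic scenes run higher than field data would give.

## Problem sizes and numerics

Default study size is 132 samples (a realistic non-pigmented-bran panel) with
3000 SNPs; simulation-based checks use n = 200 with 2000 markers (null
calibration, 5 seeds) and 5000 markers (causal recovery, 5 seeds), sizes at
which the per-marker REML scan completes in seconds-to-minutes on one CPU.
Determinism is end-to-end: a single config seed feeds every stochastic stage
through independent child generators, and re-running a config reproduces
byte-identical artifacts. Numerical tie-breaks are fixed (leftmost peak SNP,
PC1 sign convention, K-means restarts with a seeded best-inertia rule);
degenerate inputs (constant spectra, zero-variance groups, empty panels,
non-PSD kinship) raise typed errors rather than producing silent output.

## Known limitations

- Storey's π₀ smoother can be unstable for small marker panels; the BH
  fallback (π₀ = 1) engages automatically.
- Per-marker REML with marker-wise missing-call exclusion re-eigendecomposes
  the sub-panel kinship per missingness pattern; for panels with pervasive
  unique patterns this dominates runtime (caching helps only when patterns
  repeat).
- The contiguity dynamic program assumes clusters occupy mostly disjoint
  wavelength stretches; heavily interleaved labels would be snapped
  arbitrarily (at k = 5 on smooth spectra this does not occur).
- Segment definition is distance-based, not linkage-disequilibrium-aware.
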