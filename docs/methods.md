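# Methods

## The ordination

`fit_rda` implements redundancy analysis directly: the genotype matrix
Y is column-centered (SNP counts keep their common 0–2 scale; only the
karyotype pseudo-locus is standardized, see below), the predictor
matrix X is column-standardized, fitted values are obtained through a
QR factorization of X, and the constrained axes come from the SVD of
QᵀY — equivalent to eigendecomposing ŶᵀŶ/(n−1) without forming Ŷ.

Numerical conventions:

- **Inertia divisor n−1** throughout. Any consistent divisor cancels in
  PVE and pseudo-F; absolute eigenvalues match software that uses
  variances (vegan's `rda`), and differ by a factor from software using
  n or trace-normalized scales.
- **Axis signs** are fixed so the largest-magnitude locus loading on
  each axis is positive; reports are reproducible and sign-stable.
- Axes with eigenvalues below 1e−12 of the leading one are treated as
  numerical rank and dropped.
- Locus loadings used for outlier detection are the raw eigenvectors
  ("scaling none"); a correlation-style scaling (eigenvector ×
  √eigenvalue) is available via `RDAModel.species_scores("correlation")`
  for plotting.
- Rank-deficient predictor sets abort with the dependent columns named;
  the reduction + VIF steps upstream should prevent this.

Sample scores are the linear-combination (fitted) scores Ŷv. Per-
population means are available via `RDAModel.population_scores` for
map-style displays.

## Permutation testing

All tests use pseudo-F and the add-one estimate
p = (1+#{F*≥F})/(n_perm+1), which is never 0 and is exact for
exchangeable rows. Default n_perm = 1000, the protocol value.

- **Global**: rows of X permuted as units. Implemented by permuting the
  rows of X's orthonormal basis (QR commutes with row permutation), so
  each permutation costs one small matrix product.
- **Terms**: marginal — Y and the focal predictor are residualized on
  the remaining predictors and the residualized predictor is permuted.
  Marginal tests are order-invariant, matching a protocol that reports
  every variable's individual significance.
- **Axes**: sequential — axis k is tested with the leading k−1
  constrained axes partialled out of both Y and X; the statistic is the
  leading partial eigenvalue over the full-model residual mean square.
  Reporting stops at the first axis with p > α (default α = 0.01)
  because later nested axes are uninterpretable once an earlier one
  fails.

**Exchangeability caveat.** Free sample-level permutation assumes
exchangeable samples. Genotypes carry population structure, so
population-level predictors gain significance from structure alone —
the standard behavior of this analysis in the field, and the
calibration guarantee (type-I error at nominal α, verified in the
acceptance suite) holds under an i.i.d. null. For a conservative
alternative, `strata="population"` permutes only within populations.

## The karyotype pseudo-locus

`append_karyotype` adds 2n as one extra column, flagged so the
coverage/MAF filters skip it. Default scaling is **standardized**: a
raw 69–84 column would contribute ~25 variance units against ~0.2 per
SNP and dominate the ordination; standardized, it competes on the same
footing as a typical SNP. Raw scaling is kept for sensitivity analysis.
Samples without a chromosome count are dropped only in variants that
include the column. Whether the genotype matrix is mode-imputed or must
arrive complete is a config switch (`impute`), since either convention
is defensible; mode imputation is the default as it preserves the
{0,1,2} support.

Outlier tail thresholds are computed over the **SNP loadings only**;
the karyotype is judged against those thresholds but does not shift
them. This keeps the SNP candidate list independent of whether the
karyotype entered the ordination, which is what makes the
with/without-karyotype variants comparable. Note the comparison is
near- rather than exactly identical: appending a column to Y perturbs
the SVD, so SNP loadings across variants agree to |r| > 0.999 and a
locus sitting exactly at a 2.5 % quantile boundary can flip in or out.

## Outlier detection and assignment

Quantiles are empirical order statistics (linear interpolation);
exceedance is strict, so tied loadings at the boundary are not flagged
(deterministic and conservative). A locus flagged on several axes is
reported once, on the axis of largest absolute loading. Assignment uses
Pearson correlation between the imputed genotype column (karyotype on
its analysis scale) and each retained predictor; ties break
alphabetically and are logged.

## Predictor reduction

Complete-linkage clustering on the distance 1−|r|, cut strictly below
0.3 (|r| > 0.7 merges). The cluster representative is chosen by
(1) class preference quarterly > monthly > other, (2) lowest mean |r|
with predictors outside the cluster, (3) input order — (2) and (3) are
this package's tie-breaks; only (1) is part of the protocol. Complete
linkage bounds within-cluster correlations, not between-representative
ones, so the VIF < 10 check remains the multicollinearity guarantee.
Correlations are computed on per-sample rows (population values
broadcast), matching the RDA design matrix.

## Synthetic data

`simulate(SimConfig())` emulates the sampling and signal structure the
analysis assumes:

| parameter | default | meaning |
|---|---|---|
| `n_pops`, `pop_sizes` | 34 pops, 153 samples | unbalanced field design (min 1 / median 3 / max 17 per population) |
| `n_neutral`, `n_adaptive` | 650 / 50 | biallelic SNPs before filters |
| `fst` | 0.15 | Balding–Nichols differentiation of neutral loci |
| `spatial_sd` | 0.8 | SD of per-locus latitudinal logit slopes (isolation-by-distance-like drift) |
| `effect_size` | 1.5 | &#124;β&#124; of the logistic allele-frequency cline per adaptive locus |
| `karyotype_slope` | 3.0 | chromosomes per SD of the linked predictor |
| `karyotype_dispersion` | 1.5 | within-population SD of 2n (chromosomes) |
| `karyotype_range` | 69–84 | clipping bounds of the 2n series |
| `missing_rate` | 0.10 | uniform genotype missingness |
| `maf_floor` | 0.05 | ancestral-frequency bound U(floor, 1−floor) |

Predictors come in four collinear clusters (a quarterly anchor plus
monthly/derived satellites at |r| ≈ 0.9), so the reduction step has
real work; anchors share a latitudinal component, with winter
temperature loading hardest — one climatic super-gradient dominates,
and the karyotype cline and 60 % of adaptive loci ride it, with the
rest split 20/10/10 across the other anchors. This mirrors GEA field
data, where one dominant gradient carries most outliers, and keeps the
leading eigenvalue well separated so axis identities are stable.

What the generator does **not** emulate: linkage between loci (all loci
are independent draws — no RAD-locus haplotype structure), admixture
gradients beyond the latitudinal drift, non-equilibrium demography,
genotyping-error structure in missingness, or mechanistic
fission/fusion karyotype evolution (2n is a clipped Gaussian trait).
Passing tests therefore demonstrate correctness of the statistical
machinery and recoverability of planted clines, not robustness to
linked selection or complex demography.

Because neutral loci drift along latitude while the predictors are
latitude-correlated, a sizeable share of flagged loci are structured
neutrals — the outlier FDR at default settings is around 0.6–0.8.
That is the known confounding behavior of uncorrected GEA scans under
isolation-by-distance, reproduced here deliberately; the acceptance
check asks that detection beats a random flag of equal size, not that
the FDR be small.

## Problem sizes in tests

The test suite runs compact configurations chosen for precision per
unit work: ordination oracles on 100 random instances (n ≤ 40, L ≤ 60,
p ≤ 5), permutation calibration at n = 50 × 100 with 199 permutations
and 2000 null replicates, and pipeline-level checks across 50 generator
seeds at 199 permutations (p-resolution 0.005 suffices against
α = 0.01). The acceptance script's main run uses the full 1000
permutations.

## Known limitations

- No partial (conditioned) RDA, variance partitioning, or spatial
  covariates (dbMEM); the analysis is a simple RDA by design.
- No multiple-testing correction across term tests (the protocol
  applies none).
- VCF writing emits placeholder alleles (the 012 sidecar format is the
  lossless native representation).
- Gene-window distances are measured from the SNP position to the
  nearest gene-span edge; transcription-start-site distances are not
  used.
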