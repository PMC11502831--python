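# Methods

## Model

The object of inference is the genetic covariance matrix **S** of p regional
brain phenotypes, estimated from GWAS summary statistics by LD score
regression, and a low-rank factor decomposition of its correlation form,

    R = Λ Ψ Λ' + Θ,

with Λ the p×k pattern loadings, Ψ the factor correlation matrix (unit
diagonal; factors identified by unit variance), and Θ diagonal residual
genetic variances. Each factor's supra-threshold regions define a
genetically informed network; the factor itself gets a multivariate GWAS.

## LD score regression

Univariate: `E[χ²ⱼ] = intercept + (Nⱼ h²/M) ℓⱼ`; cross-trait:
`E[Z₁ⱼZ₂ⱼ] = cross_intercept + (√(N₁ⱼN₂ⱼ) g₁₂/M) ℓⱼ`. Design choices:

* **Weights.** Heteroskedasticity weights `w = 1/[ℓ·(intercept + N h² ℓ/M)²]`
  for the univariate regression and the product form
  `w = 1/[ℓ·(a₁a₂ + a₁₂²)]` for cross-trait regressions (a's are predicted
  second moments). The IRLS is iterated to a weight fixed point
  (tolerance 1e-12, cap 50 iterations) rather than a fixed small number of
  passes: at the fixed point the univariate and cross-trait paths coincide
  exactly on duplicated traits, which keeps S internally consistent.
* **Winsorization.** χ² (and |Z₁Z₂|) capped at 80 before regression, guarding
  against single-locus leverage.
* **Intercepts** are estimated freely (no constrained two-step).
* **Jackknife.** 200 contiguous, equal-count SNP blocks by default;
  delete-one-block slopes are collected jointly across all q = p(p+1)/2
  vech(S) elements, so **V** carries the cross-element sampling covariance.
  The jackknife SE is mildly conservative at desk scale (blocks are large
  relative to the LD structure), which makes ±3·SE coverage statements safe.
* **Per-SNP N** is used by default; a mean-N mode exists because sources
  differ in whether they report per-variant sample sizes.
* **Standardization** to the correlation metric transforms V by the exact
  delta-method Jacobian of `r = s₁₂/√(s₁₁s₂₂)`; diagonal elements become
  constants (zero rows in V). **PSD smoothing** clips eigenvalues below 1e-6
  and re-normalizes the diagonal; LDSC correlation matrices can be
  indefinite and the EFA requires PSD input.

## Factor analysis

* **EFA.** Maximum-likelihood extraction on the correlation matrix via the
  profile likelihood over uniquenesses (eigendecomposition of
  ψ^-1/2 R ψ^-1/2, L-BFGS-B on log ψ, bounds [1e-3, 1]); a uniqueness at the
  lower bound is a Heywood case and flags non-convergence. Promax (power 4)
  rotation follows varimax; the varimax iteration runs from the identity
  plus three fixed orthogonal starts because perfectly symmetric loading
  patterns make the identity a saddle point. Per-factor sign convention:
  column sums of loadings are made positive.
* **Spec building.** Positive EFA loadings strictly above the cutoff
  (0.3 and 0.5 both run) are freed; factors with fewer than two indicators
  are dropped; factor correlations are free.
* **CFA.** DWLS: minimize `(s − σ(θ))' diag(V)⁻¹ (s − σ(θ))` by trust-region
  least squares with the analytic Jacobian, from three deterministic starts
  (EFA-derived, uniform 0.5, perturbed). Residual variances are bounded at
  1e-6; hitting the bound, an optimizer failure, or a rank-deficient bread
  matrix (condition number > 1e10) marks the fit non-converged with indices
  undefined. Zero-variance diagonal elements of a standardized structure
  receive the smallest positive diagonal weight so residual variances stay
  identified (they absorb the diagonal exactly).
* **Model χ².** The residual quadratic form is taken against the residuals'
  own sampling covariance under the DWLS estimator,
  `χ² = r' [(I−H) V (I−H)']⁺ r` with `H = Δ(Δ'W⁻¹Δ)⁻¹Δ'W⁻¹`, df = q − t.
  The plain `r'V⁺r` form is calibrated only for the efficient GLS estimator;
  under diagonal weighting its expectation exceeds df by ~20–30% (verified
  analytically via tr(V⁺(I−H)V(I−H)')), while the corrected form has
  E[χ²] = df to first order — confirmed by simulation (mean χ²/df ≈ 1.01
  over 200 replicates). AIC = χ² + 2t; CFI uses the independence baseline
  (free residuals only); SRMR is the RMS difference of the standardized
  observed and implied matrices over the q unique elements.
* **Comparability embedding.** Candidate specs that load only a subset of
  regions are embedded in the full region universe before fitting (excluded
  regions keep a free residual variance; their correlations count as
  misfit). Without this, χ²/AIC computed on different sub-structures are not
  comparable and small specs win AIC spuriously. Pruning preserves the
  region universe for the same reason.
* **Pruning/selection.** Greedy removal of the largest non-significant
  loading (two-sided Wald p ≥ 0.05 from sandwich SEs), refitting until all
  are significant; factors reduced below two indicators are removed with
  their correlations. Selection is minimum AIC over converged candidates;
  ties break to fewer parameters, then fewer factors.

## Factor GWAS

Per SNP, the covariance structure is expanded with
`cov(SNP, trait) = β_t · 2p(1−p)` and `var(SNP) = 2p(1−p)` (reference-panel
frequency). With the measurement model fixed at the CFA estimates (per-SNP
re-estimation of the full model is intentionally not the default; recovery
is validated by simulation instead of numerical identity with external
software), the SNP→factor paths solve the per-SNP GLS

    γ̂ = (Λ'DΛ)⁻¹ Λ'D β,   D = diag(1/se_t²),

with Λ mapped to the covariance metric via the trait genetic variances.
Effects are reported on the **per-allele** scale of the input tables (this
also makes the single-indicator pass-through identity and the effective-N
formula exact); z and p follow the normal approximation. Per-factor λ is
the median χ² over 0.4549. Exported factor summary statistics carry
`N_eff = 1/(2p(1−p)·se_f²)` capped at its 99th percentile. Clumping is
greedy: the most significant remaining genome-wide-significant SNP leads a
locus absorbing significant SNPs within ±250 kb; overlapping spans merge.

## Overlap statistics

Dice coefficient `2w(A∩B)/(w(A)+w(B))` with optional per-region weights
(weights emulate percent-volume overlap; voxel-level maps are out of
scope). Permutation null: same-size random region sets, add-one estimator
`p = (1+hits)/(1+n_iter)` (smallest attainable p at 1000 iterations is
1/1001). One BH-FDR family per comparison grid.

## Synthetic data

The generator instantiates exactly the sampling model LDSC assumes.
Defaults are the study conditions of the validation suite: p = 8 traits,
k = 2 factors with loading blocks 0.7/0.6, Ψ₁₂ = 0.7 (mirroring the high
inter-factor correlations seen in real cortical data), h² = 0.25,
N = M = 50,000, MAF ~ uniform(0.05, 0.5), INFO ≡ 1. LD scores are
log-normal (median 10, σ = 0.5), constant within sub-blocks of ~25 SNPs;
sub-blocks are assigned to the 22 autosomes round-robin so a block never
straddles a chromosome and parity splitting halves the SNPs evenly.

* *Covariance mode* draws per-SNP Z-vectors from
  `N(0, I_overlap + √(NN') ∘ S_true · ℓ/M)` — fast, used for structure
  recovery.
* *Causal mode* draws standardized factor effects `γⱼ ~ N(0, Ψ/M)` plus
  listed large-effect causal SNPs (specified per-allele, converted by
  σ_g = √(2p(1−p))), maps them to trait effects `√h²·(Λγ + e)`, and smears
  them within equicorrelated LD sub-blocks with LD-correlated noise.

What the generator does **not** emulate: realistic LD decay (blocks are
equicorrelated), allele-frequency–dependent architecture, population
stratification beyond a constant intercept, imputation error, or the
scale of real reference panels (M in the millions). Passing tests therefore
demonstrate correctness of the estimators under their assumed model, not
robustness to real-data violations of it. Note that at these desk-scale
densities (M = 5×10⁴) the per-SNP polygenic signal is ~100× denser than in
a real GWAS, so λ of a signal-bearing simulation is legitimately large;
null-inflation checks use signal-free traits.

## Problem sizes in the validation suite

The replicated benchmarks use 50 replicates for LDSC and factor-structure
recovery and for GWAS power, 200 for χ² calibration (drawn directly from
N(σ(θ), V) with V taken from one simulated even-chromosome structure —
"scaled-down" replicates that isolate the statistic from the simulation
cost), and 100,000 permutation iterations against exact enumeration.
These sizes give Monte-Carlo error comfortably below the tolerances they
are checked against.

## Known limitations

* EFA/CFA are implemented in-package (ML extraction, promax, DWLS); they
  match analytic cases and generative oracles but are not numerically
  identical to any particular external SEM software.
* The factor GWAS holds the measurement model fixed per SNP — an
  approximation that is excellent for small per-SNP effects but untested
  for loci explaining a visible share of trait variance.
* Ψ positive-definiteness is checked, not enforced, for k > 2; bounding the
  pairwise correlations suffices for the factor counts exercised here.
* rg estimates are clamped to [−1, 1] with a flag; SEs near the boundary
  are jackknife-based and approximate.
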