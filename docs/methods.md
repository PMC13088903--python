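# Methods

This note documents the statistical models the package implements, the
generative model behind the synthetic data, the conditions of the reference
validation studies, and the numerical and design choices that were genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Summary-statistics model and harmonization

All computation starts from per-trait GWAS summary statistics in a canonical
form (SNP, CHR, POS, A1, A2, BETA, SE, Z, P, FRQ, N), with A1 the effect
allele and effects on the analysis scale (log-odds for case-control GWASs;
odds ratios are log-transformed on ingest). Munging restricts variants to a
reference panel, aligns alleles to the panel's orientation (sign-flipping
BETA and Z on swaps, resolving strand flips by complementation before
comparison, dropping irreconcilable pairs), removes strand-ambiguous (A/T,
C/G) variants and low-MAF / low-INFO variants, and adopts the panel's
coordinates and frequencies. Defaults: `maf_min=0.01`, `info_min=0.9`,
ambiguous variants dropped — the standard pre-LDSC filters. Munging is
idempotent and orientation-invariant, both property-tested.

Case-control designs without a per-SNP N column get the effective sample
size 4/(1/N_cases + 1/N_controls). Observed-scale heritabilities are moved
to the liability scale with the standard threshold-model multiplier
K²(1−K)² / (z² P(1−P)), z = φ(Φ⁻¹(1−K)), applied per trait inside the
multivariate regression (covariances scale by the square roots of the two
traits' multipliers); prevalences must be supplied — none are shipped.

### Multi-trait combination (GLS meta-analysis)

`mtag_combine` implements the generalized-least-squares multi-trait
estimator for a designated target trait. The genome-wide effect-size
covariance Ω is the moment estimate S·l̄/M (l̄ the mean LD score over the
analysis SNPs), eigen-clipped to positive semidefinite; the per-SNP sampling
covariance combines the standardized SEs with the cross-trait intercept
ratio I_ik/√(I_ii I_kk) as the overlap-induced noise correlation. Limiting
cases are tested: a single input is returned unchanged, duplicated traits
scale z by √2, and a diagonal Ω leaves the target untouched. The estimator
never inflates the target's standardized SE.

## 2. LD score regression

Univariate: χ²_j regressed on x_j = N_j l_j / M, so the slope is h² directly
and the intercept is the confounding term (1 under a clean design). Weights
are the standard product of the LD-redundancy factor 1/l_j and the inverse
squared expected value, refit once after a first pass (two-pass IRLS).
Cross-trait: z₁z₂ on √(N₁N₂) l_j / M, whose intercept absorbs sample overlap
times phenotypic correlation.

Standard errors come from a delete-a-block jackknife over `n_blocks = 200`
contiguous blocks of the position-sorted analysis SNPs. The multivariate
routine runs every univariate and bivariate regression on the single
intersected SNP set with one shared block partition and recomputes **all**
entries of vech(S) per deleted block, so V captures the entries' sampling
covariances — the input genomic SEM actually needs. vech is fixed
package-wide as the lower triangle in column-major order; every index into V
assumes it (a silent mismatch here is the classic bug in this kind of
pipeline, and it is locked down by tests).

**Fixed-intercept option.** Over a desk-scale panel the LD scores span only
roughly 1–9, whereas a real reference spans two orders of magnitude; the
regression intercept is therefore nearly collinear with the slope, and
leaving it free inflates the noise in S several-fold. When an analysis
design declares no confounding and no sample overlap — as the recovery
simulations here do by construction — the intercepts are known (1 and 0) and
`multivariate_ldsc(fixed_intercepts=True)` constrains them, the same
constraint classical LDSC exposes. Calibration studies that *test* the
intercepts always leave them free. The optional two-step mode (intercept
from χ² < threshold SNPs, then the slope with the intercept fixed) is
implemented but off by default.

## 3. The SEM engine

Models are specified in a lavaan-style text syntax (`F =~ a + 0.7*b +
lab*c`, `F1 ~~ F2`, `F ~ SNP`; numeric premultipliers fix parameters,
alphanumeric ones impose equality constraints) and compiled to the RAM
parameterization: implied covariance F(I−A)⁻¹ S_sym (I−A)⁻ᵀ Fᵀ. Defaults
follow the standardized reporting convention: unit variances for exogenous
latents, free indicator residuals started at 0.5·S_ii, loadings started at
0.5, factor correlations at 0.3.

Estimation is DWLS — the discrepancy weighted by the inverse diagonal of V —
minimized by L-BFGS with an analytic Jacobian (∂σ/∂θ assembled from the RAM
derivative identities, including the chain term for residuals constrained by
a unit-total-variance rule), gradient tolerance 1e-8 on the normalized
objective, and up to five jittered restarts on non-convergence. Variances
are not bounded below; Heywood cases are flagged, never truncated. A
Gauss-Newton fast path (`fit_fast`) serves the per-SNP problems, whose one
to k free paths enter the moments almost linearly; it is verified against
the quasi-Newton path.

Uncertainty and fit: sandwich covariance
(Δ'WΔ)⁻¹ Δ'W V W Δ (Δ'WΔ)⁻¹ with W = diag(V)⁻¹; model chi-square by the
residual-based statistic ê'[V⁻¹ − V⁻¹Δ(Δ'V⁻¹Δ)⁻¹Δ'V⁻¹]ê using the full V
(pseudo-inverse, rcond 1e-10); df = moments − free parameters; AIC = χ² +
2·free; CFI against an independence model freeing only the diagonal; SRMR as
the RMS residual on the correlation metric. Moments whose sampling variance
is below 1e-11 (the fixed SNP variance) are treated as known constants and
excluded from both the fit function and the chi-square; the parameterization
guarantees their residuals are identically zero.

Exploratory analysis: maximum-likelihood factor extraction on the smoothed
genetic correlation matrix (profile likelihood over uniquenesses, started at
1 − squared multiple correlation), promax rotation (power 4) from a varimax
start for oblique solutions, salient loadings reported at |λ| ≥ 0.35.
Factor-count *selection* is reported, not automated beyond the Kaiser rule
(eigenvalues of the smoothed correlation matrix above 1), mirroring the
examine-and-decide workflow; the pipeline config can override the count or
the whole confirmatory model. The extraction is cross-checked against R's
`factanal` in the test suite.

Second-order models layer latents over the first-order factors, removing the
factor correlations. Two bookkeeping conventions are supported: residuals of
the first-order factors free (the default for ordinary hierarchical models),
or determined by the unit-total-variance constraint so the only free
parameters are the second-order loadings — the standardized convention under
which a pair of second-order factors sharing one first-order factor over a
3×3 factor covariance occupies 6 − 4 = 2 df. In that convention the loadings
of the shared factor are identified only up to scale (their products with
the partner loadings are identified); the fit flags the ridge and reports
pseudo-inverse standard errors.

## 4. Per-SNP layers

**Factor GWAS.** Each SNP is appended to (S, V) as a pseudo-variable:
cov(SNP, trait) = β_std · var(SNP) with sampling SE from the trait's SE, the
between-trait sampling correlation of these moments taken from the intercept
ratio I_ik/√(I_ii I_jj) (validated and projected to a correlation matrix —
intercept estimates are noisy), zero sampling covariance between SNP moments
and trait-trait moments, and var(SNP) = 2p(1−p) treated as known.
Internally the SNP is standardized to unit variance so one compiled model
serves the whole genome; per-allele effects are recovered by dividing by
√(2p(1−p)) with panel frequencies. The measurement model is held at its
full-data estimates during per-SNP fits (a `refit_measurement` switch
re-frees everything); only SNP paths are re-estimated.

**Q_SNP.** Heterogeneity is the chi-square difference between the
common-pathway fit (SNP → factors) and the independent-pathways fit (SNP →
every indicator), both by the residual-based statistic, with df =
indicators − factors (k − 1 for a single common factor). Negative
differences within −1e-6 are clipped to zero; anything lower is flagged as a
numerical failure and the row excluded. Rows with Q_SNP p below the
threshold (default 5e-28) are flagged `HET_REMOVED` and excluded from
clumping; the flag set is exactly {q_p < threshold}.

**Effective sample size.** N_eff is the mean of 1/(2p_j(1−p_j)·se_j²) over
SNPs with MAF in [0.1, 0.4] (per-allele SEs on the standardized scale); the
mid-frequency window avoids the unstable tails. For subtraction streams the
estimate is multiplied by the latent's share of the target's heritability,
since a stream carrying a fraction of the genetic variance is equivalent in
power to a proportionally smaller study. Note the two streams of a
subtraction model do not generally end up with equal adjusted N_eff even
under a 50/50 variance split: the common path is additionally informed by
the co-indicators' SNP moments, so its raw SE-implied sample size is larger
(in the symmetric two-trait case, N versus N/2 — derived from the GLS
information and confirmed numerically in the tests).

**Clumping.** Greedy index-variant selection: repeatedly take the
smallest-p unassigned variant with p ≤ p1 (ties broken by variant ID for
determinism) and absorb unassigned variants within the window whose panel
r² with it exceeds the threshold. Defaults p1 = 5e-8, r² = 0.1, 250 kb.
Variants absent from the panel are treated as LD-independent. The
implementation is checked for exact agreement with an independent
brute-force enumeration on hundreds of random fixtures.

**GWAS-by-subtraction.** Built from a fitted first-order model for targets
whose standardized residual variance exceeds the gate (default 0.30; the
gate is configurable because published descriptions vary between "> 0.30"
as the rule and "≥ 0.35" as the empirical set). The model is the orthogonal
Cholesky pair: Common loaded by all of the factor's indicators (loadings
re-estimated jointly; a carried-over equality label keeps constrained
measurement structures identified), Independent loaded only by the target,
unit latent variances, target uniqueness fixed to zero so the decomposition
is exhaustive. For an *untied* two-indicator factor only the pure Cholesky
is identified, so the co-indicator's uniqueness is also fixed to zero — its
"common" stream then reads "shared with the co-indicator". Reported
per-target effects are path-traced (b·λ) with delta-method SEs, and the sum
of the two streams equals the implied total by construction (recorded in
`TOTAL_CHECK` and asserted to 1e-6).

## 5. The synthetic-data generator

The generator emulates k case-control/continuous GWAS cohorts whose genetic
architecture follows a latent factor model: standardized loadings Λ (k×q),
factor correlations Ψ, residual genetic variances u = 1 − diag(ΛΨΛ'), total
SNP heritabilities h², per-cohort sample sizes N, and a sample-overlap noise
correlation matrix C. True effects are spike-and-slab with causal fraction
π: the factor-pathway causal set is a single draw without replacement shared
across factors (a shared support is what lets the factor effect vectors
carry the Ψ correlation, realized through an eigendecomposition square root
that is exact even for singular Ψ); residual causal sets are independent per
trait. Per-SD trait effects are β_i = √(h²_i)(Λ_i·γ + δ_i), so Σ_j E[β²_ij]
= h²_i — verified by Monte Carlo. Options restrict the residual pathway to
a subset of traits or silence it entirely (`common_pathway_only`), the
exact null condition of the heterogeneity statistic.

Observed statistics follow the likelihood LD score regression assumes:
within an LD block, z ~ MVN(√N·Rβ, R), with cross-trait noise correlation C
(joint covariance the Kronecker product of C and R); SE_j =
1/√(2p_j(1−p_j)N), BETA = Z·SE, frequencies and alleles from the panel, so
generated tables are already in canonical munged orientation (and pass
`munge` unchanged, a tested invariant). Case-control traits are simulated
directly on the liability/standardized scale with an effective N — no
individual-level logistic sampling; at this scale nothing downstream can
tell the difference, which is precisely why it suffices.

Panels are block-diagonal with AR(1) within-block correlation; a per-block
rho drawn from a range (default (0, 0.9)) gives the LD-score spread the
regression needs — a single shared rho makes LD scores nearly constant and
the regression unidentifiable. Positions increase within chromosomes;
chromosomes are assigned round-robin over 1–22 so odd/even splits are
meaningful; LD scores are computed exactly from R, and cross-block r² is
exactly zero, which makes the clumping oracle and the LDSC information
accounting exact.

What the generator does **not** emulate: real LD (long-range, MAF-dependent,
ancestry-specific), annotation-dependent architecture, assortative mating or
stratification confounding (intercepts deviate from 1/C only by sampling
noise), imputation error, or allele-frequency mismatch between cohort and
panel. Passing tests therefore demonstrate the estimators' correctness under
the stated generative model, not robustness to those real-data features.

## 6. Reference validation studies and their conditions

Problem sizes were chosen so each study carries statistical teeth at desk
scale (the full suite runs in minutes on one core).

1. **Factor recovery** — 8 traits, 3 correlated factors, loadings 0.65–0.89
   (chosen inside 0.5–0.9 so all residual variances stay in 0.2–0.6), factor
   correlations 0.3–0.45, h² = 0.3, π = 0.2, M = 20,000 (500 blocks of 40),
   N = 50,000, one seed. EFA (Kaiser rule) on the odd-chromosome covariance
   selects the factor count; the CFA on the even-chromosome covariance must
   land every standardized loading within 0.1 and every factor correlation
   within 0.15. Intercepts are constrained (Section 2) because the design
   declares no overlap and no confounding.
2. **LDSC calibration** — null traits (h² ≈ 0) with 50% sample overlap:
   intercept within 3 jackknife SEs of 1, cross-intercept near 0.5; h² = 0.3
   recovered within 3 SEs in ≥ 95% of 40 replicates. Intercepts free — they
   are the quantity under test.
3. **Q_SNP calibration and power** — measurement model from a varying-LD
   cohort; 2,000 independent null SNPs from an LD-free, common-pathway-only
   cohort at N = 10,000 (keeping per-SNP signal in the realistic regime);
   type-I error at α = 0.05 inside the exact binomial 95% CI. Power: a
   single-indicator z = 15 variant at N = 100,000 must fall below 5e-8.
4. **Effective-N identity** — exact algebra, machine precision.
5. **Subtraction decomposition** — target with a 50/50 common/residual
   split; factor-driven SNPs show a null independent stream and vice versa
   (|z| < 3 for ≥ 95%), and the path-tracing identity holds to 1e-6.
6. **Clumping oracle** — 200 random 20-SNP fixtures, exact agreement.
7. **Fit-index accounting** — saturated fits perfect; AIC − χ² = 2·free on
   every fit; the 8-indicator, 3-factor model occupies 36 − 19 = 17 df.

## 7. Known limitations

- No annotation-stratified LDSC, no trans-ancestry covariance, no
  liability-scale treatment of ascertainment beyond the standard multiplier.
- DWLS only; no maximum-likelihood SEM estimator, categorical-indicator
  machinery, or modification indices.
- The per-SNP chi-square difference assumes the measurement model is well
  estimated; with very strong per-SNP signal and a noisy measurement model
  the statistic drifts conservative (documented in the calibration study's
  design).
- Second-order models with a shared first-order factor under the
  standardized convention sit on an identification ridge (Section 3); only
  products of loadings should be interpreted there.
- The pipeline accepts real munged summary statistics, but nothing in the
  test suite touches real data; the access-controlled inputs of the
  motivating application are out of scope by design.
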