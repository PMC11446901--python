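# Methods

## Study design

The pipeline follows the standard two-sample, two-step mediation MR design.
Stage 1 screens each exposure against the outcome with the univariable
estimator battery; an exposure is retained when its random-effects IVW
p-value is below α (default 0.05), the plain MR-Egger intercept shows no
directional pleiotropy (p > α), and the MR-PRESSO outlier-corrected
estimate agrees in sign with IVW. Each conjunct is configurable
(`ScreeningSettings`), because published studies describe this screen
narratively rather than as a formal rule. Stage 2 estimates β₁
(exposure→mediator) for retained exposures, keeping links with p < α.
Stage 3 fits multivariable IVW of the outcome on {exposure, mediator} over
the union of both trait's instruments, re-clumped jointly, giving β₂.
Stage 4 decomposes and filters (positive mediated proportion, p ≤ α).

## Estimators

**IVW.** Explicit weighted sums (weights βX²/σY²). Fixed-effects SE is
1/√Σw; the default multiplicative random-effects model scales the SE by
max(1, √(Q/(k−1))). Both are reported by the battery. Cochran's Q uses the
per-SNP ratio estimates about the pooled value.

**Robust IVW.** Tukey-biweight M-estimation (c = 4.685, 95% normal
efficiency) of the weighted no-intercept regression, via statsmodels RLM on
precision-standardized variables, started from the weighted-median ratio;
SEs from the robust covariance. Exact-fit inputs (zero robust scale) fall
back to the least-squares solution, which the M-estimate equals there.

**Penalized IVW.** Per-SNP heterogeneity contributions q_j are referred to
χ²₁; weights are multiplied by min(1, 20·p_j) (constant configurable) and
the regression refit — least squares for the penalized variant,
Tukey-biweight for penalized-robust.

**MR-Egger.** Weighted regression with intercept after orienting all
exposure effects non-negative (Egger regression is not orientation
invariant). Slope SE and intercept SE carry the same multiplicative
overdispersion scaling, truncated at 1; the intercept test uses Student's t
with k−2 df for small-k accuracy. Penalized/robust variants reuse the
penalty and M-estimation machinery, with penalties computed from the plain
Egger fit's residuals.

**Profile maximum likelihood.** Under βX_j ~ N(γ_j, σX²),
βY_j ~ N(θγ_j, σY²), profiling out γ gives the objective
Σ(βY−θβX)²/(σY²+θ²σX²), minimized numerically from the IVW start; SE from
the numerically differentiated observed information. With σX → 0 this
reduces exactly to fixed-effects IVW.

**Debiased IVW.** θ̂ = Σ(βXβY/σY²) / Σ((βX²−σX²)/σY²): the denominator
subtracts the weak-instrument inflation E[β̂X²]−γ² = σX². The SE comes from
a delta-method variance of the estimating function T_j = βXβY − θβX² + θσX²,
Var T_j = μ²σY² + σX²σY² + θ²μ²σX² + 2θ²σX⁴ with μ² estimated by
max(βX²−σX², 0). A non-positive denominator (noise exceeding signal) is an
error, reported as such.

**Contamination mixture.** Each SNP's ratio estimate contributes the larger
of a valid-model density N(θ, se_r²) and an invalid-model density
N(0, se_r²+ψ²); θ̂ maximizes the profile log-likelihood over a grid of 500
points spanning ±3·max|ratio| (ψ defaults to 1.5 × SD of the ratios). The
CI collects grid points within χ²₁(0.95)/2 of the maximum; the reported SE
is the CI width / 3.92, a symmetric summary of a possibly asymmetric set.

**BWMR.** A Student-t–robustified hierarchical model: γ_j ~ N(0, σγ²),
w_j ~ Gamma(ν/2, ν/2) with ν = 4, β̂X_j ~ N(γ_j, σX²), and
β̂Y_j ~ N(θγ_j, (σY²+τ²)/w_j), fit by coordinate-ascent variational EM with
Gaussian q(γ) and Gamma q(w) and exact M-steps for θ, σγ² and the
overdispersion τ² (the τ² step is a guarded 1-D maximization). Every update
maximizes the ELBO in its coordinate, so the ELBO is non-decreasing — a
property the tests assert. E[w_j] is the per-SNP outlier weight; the SE is
the observed information of the E[w]-weighted marginal likelihood at θ̂,
an approximation to the posterior SD. Convergence: ELBO change < 1e-6,
at most 3000 iterations.

**MR-PRESSO.** Observed RSS from leave-one-out fixed-effects IVW
predictions; the null distribution is parametric — β*X_j ~ N(βX_j, σX²),
β*Y_j ~ N(β̂₍₋ⱼ₎βX_j, σY²) — with the LOO RSS recomputed on each of n_sim
(default 1000) simulated sets, fully vectorized. Global and per-SNP
Monte-Carlo p-values respect the (1+#exceed)/(n_sim+1) floor; per-SNP flags
are Bonferroni-adjusted at α = 0.05. Note the implied design constraint:
n_sim must exceed k/α or the p floor sits above the Bonferroni threshold and
no SNP can be flagged (the code warns). The distortion test compares the
outlier-removed estimate against removals of random same-size subsets. The
corrected estimate is IVW on the outlier-free set.

**MVMR.** Weighted no-intercept multiple regression with weights 1/σY²,
coefficient SEs scaled by max(1, √(Q/(k−p))). Exactly-zero exposure columns
are dropped and reported with a zero coefficient (the fit then reduces to
the univariable estimate for the remaining trait); linearly dependent
nonzero columns raise a collinearity error naming the traits. The
conditional instrument-strength statistic regresses each trait's effects on
the others (weighted) and scales the residual signal by the trait's
squared SEs — a Q-statistic-style approximation, not the full
Sanderson–Windmeijer conditional F.

**Decomposition.** indirect = β₁β₂ with SE √(β₁²σ₂²+β₂²σ₁²); direct =
β − β₁β₂ (the identity direct + indirect = β is exact by construction);
mediated proportion = β₁β₂/β with first-order delta-method SE treating
(β₁, β₂, β) as independent, Z = ratio/SE, p from the normal, CI =
ratio ± 1.96·SE. This construction reproduces the Z statistics of published
mediation tables from their printed ratios and CIs (SE = (UCI−LCI)/3.92),
which is how the worked-example checks are defined.

## Synthetic data

The generator draws EAF ~ U(0.05, 0.95), assigns non-palindromic allele
pairs by default (palindromic pairs opt-in), and scales normally-drawn
instrument effects so the lead variants explain exactly `instrument_h2` of
the exposure variance. Mediator-specific instruments (needed for MVMR
identification) are generated the same way. Sampling SEs use the
unit-variance approximation se = 1/√(2·N·EAF(1−EAF)); the binary outcome
uses the effective sample size 4/(1/n_cases+1/n_controls) and log-odds
scale effects. Defaults mirror the motivating data sources: exposure GWAS
N = 5,959, mediator GWAS N = 136,016, outcome 23,564 cases / 40,138
controls.

Pleiotropy modes: balanced (mean-zero per-variant outcome effects),
directional (nonzero mean, defined with respect to the exposure-increasing
allele), correlated (α tracks |γ|, violating InSIDE). Planted outliers add
±`outlier_scale` × the background pleiotropy SD (or × the mean outcome SE
when no background pleiotropy exists) and are recorded in the ground truth.
LD is block-diagonal: within a block, tag variants carry √r²-scaled copies
of the lead effect and estimation noise with the matching correlation;
blocks are positioned so that cross-block pairs fall outside the clumping
window. One seed sequence per simulation spawns per-table child streams, so
tables are reproducible bit-for-bit.

What the generator does *not* emulate: realistic human LD maps, MAF-
dependent effect-size architecture, sample overlap between the three GWAS,
liability-scale effects for the binary outcome, population stratification.
Passing calibration tests therefore demonstrates correctness of the
estimators under their stated models, not robustness to those real-data
complications.

## Calibration experiments and their conditions

The replicated experiments (`mrmediate.calibration`) use 30 instruments,
h² = 0.1, and evaluate estimators on the generator's known instrument set
without the significance screen — selection on the same data would add
winner's-curse bias that belongs to selection, not to the estimator under
test (the selection path is validated separately by the criteria-
enforcement suite).

Coverage experiments use an exposure GWAS of N = 60,000, giving mean
per-SNP F ≈ 200 — the no-measurement-error regime IVW and the independence-
based delta method are specified for. This choice matters, and is a known
limitation of the methods rather than of the implementation:

* At the microbiota-GWAS scale (N ≈ 6,000, mean F ≈ 20), plain IVW carries
  weak-instrument dilution of roughly θ/F, about one SE under these
  conditions, and its 95% CI coverage drops to ≈ 0.85. Debiased IVW is the
  battery's answer to exactly this regime.
* At the same scale the total-effect and step-1 estimates share the
  exposure-GWAS sampling noise (correlation ≈ 0.5), the independence
  assumption of the delta-method ratio SE fails conservatively, and the
  mediated-proportion CI over-covers (≈ 0.99+).

The Egger recovery experiment adds a constant μ_α = 0.05 to every outcome
effect in the Egger orientation, making the true intercept exactly μ_α;
the balanced-pleiotropy size experiment uses per-variant α ~ N(0, 0.02²).
MR-PRESSO power plants one outlier with a 10× shift among 30 SNPs at
n_sim = 1000.

## Numerical conventions

Two-sided normal p-values for all Wald-type tests; the Egger intercept uses
t(k−2). CIs use the exact normal 0.975 quantile except the mediation
decomposition, which uses 1.96 to match the published-table convention its
worked example reconstructs. Clumping ties on p-value break
lexicographically by variant id, making selection independent of row order.
Variants with βX = 0 are excluded from ratio-based estimators with a
warning. Monte-Carlo p-values never fall below 1/(n_sim+1). Harmonization
drops palindromic variants when either trait's EAF is within 0.08 of 0.5
and otherwise infers strand from frequency; variants whose alleles cannot
be reconciled by swap or complement are dropped and counted.

## Problem sizes

The default test suite and the reproducibility script run 200-replicate
coverage experiments, 100-replicate PRESSO power at n_sim = 1000,
500-replicate size experiments, and the end-to-end study at 3 exposures ×
5 mediators with 30–40 instruments per trait; the whole suite completes in
well under a minute on one CPU.
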