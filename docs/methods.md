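# Methods

`polygxe` implements a complete joint genetic–environmental analysis of a
case–control psychiatric phenotype — polygenic score construction from
GWAS summary statistics, aggregate environmental risk scoring,
multiplicative and additive gene–environment interaction inference,
liability-scale accuracy conversion and simulation-based power analysis —
and exercises it end to end on synthetic cohorts with known ground truth.
This note records the models, the defaults and why, the numerical
choices, and what the synthetic data do and do not establish.

## The synthetic study

The generator emulates the design of a hospital-based schizophrenia
spectrum disorder case–control study: 717 cases and 356 controls
ascertained from a population with lifetime risk K = 1%, genotyped
against an external reference panel, scored with East-Asian-style GWAS
summary statistics, and phenotyped with a six-domain polyenvironmental
risk instrument (paternal age, parental socioeconomic status, obstetric
complications, urbanicity, childhood adversity, recent life events) plus
an early-trauma questionnaire whose positive-schema subdomains are
reverse-scored.

**Genotypes.** Variants live in fixed-size LD blocks (default 40
variants). Within a block, two latent Gaussian haplotypes follow a
first-order autoregressive process with per-block correlation `rho` drawn
uniformly from (0.2, 0.9) by default; thresholding at Φ⁻¹(1−f) for a MAF
f ~ U(0.05, 0.5) gives Hardy–Weinberg allele draws, and the dosage is the
two-haplotype sum. Blocks are independent by construction, which makes
the implied LD banded, invertible and analytically checkable. A
heterogeneous `rho` across blocks is deliberate: it spreads the
per-variant LD scores, without which the LD-score-regression slope is
statistically unidentifiable at desk scale (a single shared `rho` may be
set for targeted tests).

**Summary statistics.** True standardized effects follow the point-normal
prior: zero with probability `1 − p_causal`, otherwise
N(0, h²/(M·p_causal)), with defaults h² = 0.3 and p_causal = 0.03
(the causal fraction the grid search is expected to favor). Marginal
estimates are sampled analytically per block as β̂ ~ N(D β, D/N) with D
the empirical panel LD and N = 50,000 — a raw training GWAS cohort is
never materialized, which keeps simulation desk-scale with identical
downstream behavior.

**Exposures.** The six domains are independent Bernoulli indicators with
configurable prevalences (defaults 0.15, 0.20, 0.10, 0.50, 0.25, 0.30 —
the source instrument's population prevalence table is not public, so
these are plausible configuration, not claims). An optional Gaussian
copula induces inter-domain correlation. Trauma subdomain counts are
binomial with the negative-schema rate shifted upward (and positive rate
downward) by the childhood-adversity indicator, so the trauma total is a
noisy proxy of one causal domain — mirroring the empirical pattern that a
narrower trauma measure associates more weakly than the aggregate
instrument. Exposures never see genotypes, giving the gene–environment
correlation screen a true null.

**Case status.** The generating score is
η = b_G·z_G + b_E·z_E + b_GE·z_G·z_E with z_G the standardized true
genetic value, z_E the standardized weighted domain sum and standardized
coefficients (0.7, 1.0, 0.3) by default. Two mechanisms are provided:
logistic, P(case) = expit(b₀ + η) with b₀ calibrated by bisection on a
200,000-draw calibration sample so the population prevalence equals K;
and liability, liability = η + ε with residual variance chosen so the
total is 1 and the case threshold set by the Monte-Carlo (1−K)-quantile
of the simulated liability (the environmental score is a standardized
Bernoulli sum, not exactly Gaussian, so the analytic Φ⁻¹ threshold would
miss K slightly). Cohorts are ascertained by rejection sampling to
exactly the target case/control counts; all randomness descends from a
single master seed through named, order-independent substreams
(panel / sumstats / exposures / cohort / calibration).

## Polygenic scoring

Posterior-mean effect sizes are computed two ways on the standardized
scale. The infinitesimal solution solves, per block,
(D + M/(N h²) I) w = β̂ — a deterministic ridge-type system. The
point-normal sampler runs per-variant Gibbs updates: the inclusion
indicator is drawn from the posterior odds
(p/(1−p)) · N(β̃; 0, σ²+1/N) / N(β̃; 0, 1/N) with σ² = h²/(M p) and β̃
the LD-residualized marginal effect, and the effect given inclusion from
N(s²Nβ̃, s²), s² = 1/(N + 1/σ²). Defaults are 100 burn-in plus 400 kept
sweeps (the reference pipeline's chain length is unpublished); the
reported weights average the kept sweeps, and a divergence guard aborts
if any |w| exceeds 2. At p = 1 the sampler provably collapses to the
infinitesimal solution, which the test suite asserts (correlation
> 0.99 at M = 2000).

LD is estimated blockwise as the Pearson correlation of standardized
dosages, with optional shrinkage (1−λ)D + λI, λ = 0.01 by default, for
invertibility. The h² fed to the prior defaults to the LD-score-
regression estimate (clipped to [0.02, 0.8]), overridable.

The causal fraction is tuned over the standard grid
{10⁻³, 3×10⁻³, 0.01, 0.03, 0.1, 0.3, 1}, scoring the analysis cohort and
keeping the AUC argmax (ties break toward smaller p). Selection happens
in-sample, replicating common applied practice; treat the selected AUC as
optimistically biased and prefer a held-out split when data allow.
Scores are standardized empirically, residualized on age and sex, and
re-standardized.

**LD score regression.** χ²_j = (β̂_j/SE_j)² is regressed on
ℓ_j = Σ_k r²_jk by two-pass weighted least squares (first pass 1/ℓ, second
pass 1/(ℓ·(fitted mean χ²)²)); h² = slope·M/N, with a delete-one block
jackknife SE over contiguous variant chunks (20 by default). At desk
scale the estimator is unbiased but noisy under sparse architectures:
with p_causal = 0.03 and M = 5000 the realized signal concentrates in a
few blocks and the slope is unidentifiable, so the recovery check runs
under p_causal = 1 (the regime the regression assumes) and averages ten
analytic GWAS replicates.

## Environmental scores

The polyenvironmental total is Σ_d w_d(level_d) with weights on the log
relative-risk scale and reference-level weight pinned to 0. The weight
table is data, not code: the shipped YAML is a clearly-labeled
placeholder and substantive use requires the instrument's own table
(published instrument weights are derived from Western-study ORs/RRs
adjusted for population exposure proportions; they are not reproduced
here). Missing domains are complete-case by default, with an optional
available-weight rescaling mode. The trauma total adds raw negative
subdomains to max−raw reversed positive subdomains, maxima configurable
(default 24 each). Standardization uses the sample SD (ddof = 1), with an
optional reference mask (e.g. standardize against controls).

## Association and interaction

Four logistic model types relate status to the adjusted PRS (G) and an
environmental total (E): G-only, E-only, G+E, and G+E+G×E, all adjusted
for age, sex and education. Continuous G and E are standardized before
the product is formed, so odds ratios are per SD (the applied literature
rarely states the unit; per-SD is adopted and documented). The logistic
fitter is iteratively reweighted least squares with tolerance 1e-8 on the
coefficient change, 100-iteration cap, covariance from the inverse
observed information, and a separation guard that rejects any fit whose
standardized-scale coefficients exceed 15 in magnitude — simpler and more
testable than a perfect-classification scan. statsmodels serves as an
independent oracle in the tests, never as the fitting path.

Multiplicative interaction is the exponentiated product coefficient with
Wald CI. Additive interaction is RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1 evaluated
at +1 SD increments in G and E (the contrast is recorded in the output);
its variance comes from the delta method with gradient
(dG(OR₁₁−OR₁₀), dE(OR₁₁−OR₀₁), dG·dE·OR₁₁), and significance is
CI-excludes-zero. A stratified case-resampling percentile bootstrap is
provided as the asymmetry-tolerant alternative; note that for this
right-skewed statistic the percentile interval is genuinely re-centered
relative to the symmetric delta interval at n ≈ 2000 (endpoint shifts of
order 10–40% of the half-width), while the interval *widths* agree
closely in moderate-effect regimes — the delta variance is what the
bootstrap can validate, and that is what the acceptance suite checks.

Subgroup odds ratios dichotomize G and E at the control-group quantile
(linear-interpolation definition, strictly-greater comparison; default
75% with 50%/25% sensitivity) and fit one model with three indicator
terms against the low/low reference. Nagelkerke's R² is
[1 − exp(2(ll₀−ll₁)/n)] / [1 − exp(2ll₀/n)]; AIC/BIC compare the base
interaction model with one adding covariate×G and covariate×E terms.
Multiple testing uses Benjamini–Hochberg. The gene–environment
correlation screen regresses each domain on the PRS plus covariates in
cases only, FDR-adjusted. Linear (OLS) interaction models serve the
symptom phenotypes.

## Accuracy on the liability scale

Under the liability threshold model with threshold t = Φ⁻¹(1−K), case
mean i = φ(t)/K and control mean v = −iK/(1−K), a predictor explaining a
liability-variance fraction ρ² yields population AUC
Φ( ρ²(i−v) / √(ρ²(1−ρ²·i(i−t)) + ρ²(1−ρ²·v(v−t))) ). The inverse map is
evaluated by bisection to 1e-8, with AUC = 0.5 mapping to exactly 0. A
second route converts Nagelkerke's R² through the threshold-model
correction with ascertainment adjustment
(C = K²(1−K)²/(z²P(1−P)), θ = d(d−t), d = (z/K)(P−K)/(1−K),
R²_l = C·R²/(1+CθR²)); treating the pseudo-R² as observed-scale R² is an
approximation, so this route is a cross-check, not the primary estimate.
Because the published conversion variant used alongside any given study
is rarely identifiable from the text, neither route claims to reproduce
externally printed liability-R² values.

## Power

Post hoc power is Monte-Carlo: G, E ~ independent standard normals,
status from the logistic model at standardized coefficients with the
intercept calibrated to the target case fraction (default 717/1073), one
interaction-model refit per replicate, success = Wald p < α on the
product term (multiplicative) or delta RERI CI excluding zero (additive).
Failed refits are counted and reported, with >10% failures an error. The
minimum n for a target power brackets by doubling through a sorted grid
and bisects on grid indices; power estimates carry binomial Monte-Carlo
SEs and the returned curve lists every evaluated point. A
liability-mechanism mode mirrors the cohort generator. Note the additive
criterion is not a type-I-calibrated test of b_GE = 0: RERI ≠ 0 whenever
both main effects are nonzero, even without a product term.

## Pipeline and problem sizes

The YAML-driven pipeline (simulate → prs → env-score → associate →
interact → subgroup → metrics → power) writes plain-text artifacts per
stage and a single `report.json`; identical configs give byte-identical
reports because every stage draws from named substreams of the master
seed and the report carries no timestamps. Disabled stages are loaded
from their on-disk artifacts, and a missing upstream artifact fails fast
naming the stage and file. Subgroup combinations whose cells empty or
separate at extreme thresholds are recorded as degenerate and skipped
rather than aborting the sensitivity sweep.

The shipped demo configuration uses M = 800 variants, a 1500-individual
reference panel and the full 717/356 cohort — sizes chosen so a complete
run, including the seven-point Gibbs grid, finishes in well under a
minute on one CPU while leaving every qualitative behavior of the
full-scale analysis intact. Estimator checks use larger dedicated sizes
(M = 2000 for the oracle equivalences, M = 5000 for heritability
recovery, 200–1000 replicate cohorts for coverage and type-I
calibration).

## What passing tests do and do not show

The generator's LD is block-banded with no long-range structure,
ancestry admixture or imputation artifacts; exposures are binary,
mutually independent by default and recalled without error; effects are
homogeneous and purely additive on the chosen link. Passing tests
therefore certify the estimators and their frequentist calibration under
the stated generative family — they do not certify robustness to real
human LD, exposure measurement error, gene–environment correlation or
ascertainment schemes other than outcome-dependent sampling. Headline
numbers from any real study of this design depend on private genotype
and questionnaire data and are not reproduction targets for the
synthetic pipeline.

Known limitations: in-sample AUC selection of the causal fraction;
per-variant Gibbs updates in Python (adequate to M ~ 10⁴, not
genome-wide); the Nagelkerke-based liability conversion inherits the
pseudo-R²-as-R² approximation; the delta-method RERI interval is
symmetric by construction and increasingly miscentered as ORs grow.
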