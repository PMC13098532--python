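# Methods

`gxekit` simulates and estimates gene–environment (G×E) interplay in the
setting of a school-entry natural experiment: a polygenic index (PGI) for
educational attainment interacted with being old-for-grade under a strict
September-1 entry cutoff.  This note documents the generative models, the
estimators, the numerical choices, and what the validation battery does and
does not establish.

## 1. Family genotype model

Founders are drawn in Hardy–Weinberg equilibrium: SNP `j` has a counted-allele
frequency `p_j` (uniform on a configurable range, default 0.2–0.8) and
genotypes Binomial(2, `p_j`).  SNPs are unlinked — there is no linkage
disequilibrium by construction — so every per-SNP derivation used downstream
holds exactly and no LD correction is needed or provided.

Assortative mating is Gaussian-copula rank matching: each mating pool is
ranked on a latent `sqrt(|r|)·score + sqrt(1−|r|)·noise` and the rankings are
paired, which induces a spousal score correlation of `r` (verified empirically
to ±0.03 at n = 10⁴).  Children receive one allele per parent per SNP
(`Bernoulli(G/2)` each), independently across SNPs and siblings.  This yields
the standard quantitative-genetics facts the tests assert: parent–child score
correlation `(1+r)/2`, sibling genotype correlation 0.5 under random mating,
allele-frequency conservation, and — the linchpin of the whole design — child
genotype that is conditionally random given both parental genotypes.

**Phenotype.**  Direct effects are per-SNP weights `b_j`; the true score is
`T = G·b`.  Genetic nurture is parameterized *at the score level*: the outcome
loads on each parent's true score with coefficients `c_m`, `c_f`.  This keeps
the probability-limit algebra closed form — a naive per-SNP regression slope
converges to `b_j (1 + (c_m + c_f)/2)` under random mating — at the cost of
making regular-GWAS weights proportional to true weights in the infinite-data
limit (per-SNP nurture heterogeneity is not modelled).  Within-family
measurement error in PGI weights therefore arises from finite discovery
samples, which is also the empirically relevant channel for family-based GWAS.
G×E blocks (`β_E·E + β_G×E·S·E + β_G²·S² + β_E²·E²`) operate on the
standardized score `S` so the coefficients are per-SD quantities.

**Environments.**  Three regimes: *exogenous* (pure noise), *predetermined*
(loads on the mid-parent score: passive rGE), and *non-predetermined*
(additionally loads on the child's own score — active/evocative rGE — and
optionally on a provisional outcome for reverse causality).  A correlated
shadow environment E\* (`corr(E, E*) = 0.5` by default) can affect the outcome
directly, which is what makes the E coefficient uninterpretable in the
endogenous columns of the bias grid.

## 2. Cohort emulator

Each child has a uniform month of birth; the running variable is months since
September (`June..November ↦ −3..2`, September = 0), treatment (old-for-grade)
is birth in September–December by default, and the estimator applies a
3-month bandwidth (June–November) so the analysis contrast is
September–November vs June–August.  Covariates: sex, birth-year 1991/92
indicator, ten genetic principal components (independent standard normals by
default, with an optional structure-confounded mode).  Child/mother/father
PGIs come either from the SNP-level family simulation or from a Gaussian
midparent model (child = midparent average + segregation noise), which agrees
in distribution for a polygenic score and scales to cohorts of 10⁵+.

Test scores for five stages (school-entry assessment + four in-school Key
Stages) are generated either *reduced-form* — per-stage linear coefficients on
treatment, PGI, their interaction, running-variable trends and parental PGIs,
with defaults set to the published preferred-specification values of the
school-entry application this package emulates (entry: treatment 1.151,
interaction +0.126; KS2: 0.379, −0.093; and analogously for KS1/KS3/KS4) — or
*structurally* from the skill-formation model of §5.  Stage noise SDs
(0.65–0.95) were chosen once so generated scores have variance near one under
the default coefficients.  Missingness is missing-completely-at-random with
default rates (entry 75%, Key Stages 17–29%, paternal PGI 32%) scaled to the
cohort being emulated; the entry test is deliberately the sparsest stage.
Selection into test-taking is not modelled.

## 3. Imputation, GWAS designs, PGIs, ORIV

**Duo imputation.**  The missing father's expected allele count is
`E[G_f | G_m, G_c, p] = P(transmitted paternal allele = 1 | ·) + p`, with the
posterior from enumerating maternal segregation and a Hardy–Weinberg father.
A brute-force enumeration over phased configurations is kept as an independent
oracle; the two agree to machine precision over all nine duo genotypes × a
frequency grid.  Impossible duos — (G_m, G_c) ∈ {(0,2), (2,0)} — are masked
per SNP and reported, never imputed.  The closed form assumes random mating
and a matched reference panel; under assortative mating the induced bias is
measured (trio regressions with imputed fathers remain unbiased within
Monte-Carlo error at `r_am = 0.4` in the tests) rather than corrected.

**GWAS stage.**  Three designs, each a series of per-SNP regressions with
HC1-robust SEs, vectorized across SNPs (batched normal equations) so
Monte-Carlo studies can re-run the stage hundreds of times: naive univariate
OLS; trio OLS on (child, mother, father/imputed-father) genotypes whose child
coefficient is the direct effect; and within-family demeaned OLS for sibling
pairs.  Genotypes are not standardized here — weights stay on the allele-count
scale — and monomorphic, collinear, or within-family-invariant SNPs are
dropped with recorded reasons.

**PGI + ORIV.**  Scores are weighted allele-count sums standardized in a
declared sample.  Split-sample PGIs run the GWAS on disjoint random halves,
giving two scores with independent estimation noise.  ORIV stacks the two
just-identified IV equations (each score instrumenting the other), shares all
control coefficients across the stack, and clusters SEs on the individual,
who appears twice.  With equal-noise splits, OLS on either score converges to
`λ·β` (λ = reliability = corr of the two scores) and ORIV to `β`; both facts
are verified at λ = 0.5, and a first-stage F floor (default 10) guards weak
instruments.  Scores enter ORIV on the caller's scale; G×E attenuation is
measured but not corrected (no established correction exists for the
interacted, within-family case).

## 4. Estimators and the bias grid

`fit_gxe` estimates the fully-interacted linear model with optional quadratic
(`G²`, `E²`) blocks and full control × G, control × E interaction blocks; the
specification descriptor records exactly which blocks were included, and
column order is deterministic so identical inputs give bit-identical
covariance matrices.  `fit_rdd` builds the school-entry design — main effects,
trend × treatment × PGI blocks, controls demeaned in the estimation sample
before interacting (so main effects are at-average-characteristics effects),
optional parental-PGI controls with their PGI and treatment interactions, the
missing-father dummy, and optional entry-score controls for the mediation
probe.

**Inference with six clusters.**  The default covariance is cluster-robust by
month of birth with t(G−1) critical values, mirroring the empirical design
being emulated.  With only six clusters in the bandwidth this estimator is
known to be unreliable, and we measure it badly understating the true
sampling error under the iid generating model (cluster SE ~0.001 vs empirical
sampling SD ~0.018 for the treatment effect at n = 10⁵).  The validation
experiments therefore use HC-robust inference, which is the correctly
specified choice under the MCAR/iid-noise null: the interaction test's
empirical size is ~5% over 2,000 replications and CI coverage is within
binomial bounds.  Conclusions about clustered inference with few clusters
should not be drawn from this package's defaults; the robust option is
exposed and flagged in every estimate descriptor.

**Bias grid.**  Nine cells cross three G designs (well-powered family-GWAS
weights + parental controls; finite regular-GWAS weights + parental controls;
finite regular-GWAS weights, no controls) with the three environment regimes.
The "well-powered family GWAS" row uses the probability-limit weights (the
true direct effects): a finite trio GWAS would re-introduce exactly the
sampling-noise channel that distinguishes row 2, confounding the design
contrast.  Rows 2–3 re-estimate a regular GWAS on a fresh discovery sample of
1,500 each replication; at that size the weight noise gives PGI reliability
≈ 0.8, large enough for the attenuation of both the PGI coefficient and the
interaction to clear the 3-MC-SE classification threshold at 200 replications
of n = 4,000 families.  The benchmark "truth" is the oracle-weights /
parental-controls / exogenous-E estimate at the same n, because
standardization makes the estimand scale-dependent; bias is classified
unbiased iff |mean bias| < 3 MC-SE, else by sign.  Cells whose direction is
not universal (E under endogenous regimes; the interaction without parental
controls) are verified only against the direction implied by this package's
positive default loadings, and the narrative labels them as such.

## 5. Structural skill-formation model

Entry skill at age 4 is affine in the endowment, `θ₄(G) = μ₀ + μ_G G`.  An
extra home year adds autonomous maturation plus invested skill,
`θ₅ = θ₄ + m₅ + (a₀ + a_G G)·x^α` with α ∈ (0,1), where parents choose x to
maximize the test outcome net of a convex cost
`C = c₀ x^{1+η}/(1+η)·(1 + c_G G)` (bounded scalar maximization; interior
optima satisfy the first-order condition to < 10⁻⁴ and the power technology's
Inada condition means corners arise only asymptotically).  In-school
production is an inhomogeneous CES,

    θ_τ(θ_e, G, a) = m(a, G) · [ω_e θ_e^r + ω_G (g₀ + g_G G)^r]^{ρ/r},

with r < 1 and ρ ∈ (0,1), age multiplier `m(5,G) = 1 + φ + ageG·G`.  The
affine positive map of G (not a softplus) is deliberate: softplus is convex
and would not guarantee the concavity-in-G shape restriction; positivity and
the shape restrictions (increasing, concave in both continuous inputs) are
enforced on the admissible domain G ∈ [−3, 3] at construction and asserted on
a grid in the tests.  The sign of the skill–gene cross partial is
`sign(ρ − r)` — a homogeneous CES cannot produce substitutability, which the
decomposition's mechanism-3 dial requires.  One parameter per interaction
mechanism: (μ_G, a_G) → differential pre-entry accumulation; φ → productivity
of entry skills; ρ vs r → skill–gene complementarity; ageG → age–gene
coupling.  A separable linear family (`θ_τ = κa + ω_e θ_e + ω_G(g₀+g_G G)`)
is the benchmark in which mechanisms 2–4 vanish identically.

All decomposition derivatives are central finite differences (default
h = 10⁻⁴ on the standardized-G scale; h > 0.1 triggers a warning), with the
investment policy re-solved at perturbed G so the parental behavioural
response is part of the total derivative (a toggle freezes it).  Terms 1+2
equal the exact product-rule first-plus-third terms algebraically; terms 3+4
carry a first-order Taylor remainder, so the four-term sum differs from the
exact numerical gradient by a residual that shrinks quadratically as the
entry-skill gap is scaled down (measured shrink factor ≈ 3.7–3.9 per halving;
the deviation from 4 is the higher-order remainder).  The welfare gradient
subtracts the cost terms and is checked against a direct central difference
of the value function.  Calibration fits (μ_G, a₀, a_G, φ, ρ, ageG) by
bounded least squares to stage-wise (treatment effect, interaction) targets
computed on a normal-weighted G grid in pooled-SD units, with interaction
residuals weighted ×4 because the targets are an order of magnitude smaller
than the main effects; calibrated to the published values it reproduces the
positive-entry / negative-Key-Stage interaction sign flip, both in implied
moments and in a simulated cohort run through the RDD estimator.

The ambiguity about whether mechanism 1's marginal product is evaluated at
entry age 4 or 5 is resolved by evaluating it at (θ₄, G, 4) — the printed
form of the four-term decomposition — while the two-part treatment-effect
split evaluates at (θ₄, G, 5); sensitivity to the evaluation point is
O(gap²) and absorbed in the reported residual.

## 6. Reference validation conditions

The acceptance battery (tests/test_acceptance.py, recomputed from scratch by
`scripts/acceptance.py`) runs at these fixed conditions, chosen once:

| study | conditions |
|---|---|
| worked examples | published coefficients only (KS2 0.379/−0.093; KS4 0.281/−0.050 and 0.274/−0.042) |
| imputation oracle | 9 duos × p ∈ {0.05,…,0.95} |
| trio recovery | 200 reps × 2,000 trios × 100 SNPs, nurture 0.3/0.3 |
| bias grid | 9 cells × 200 reps, n = 4,000 families, 200 SNPs, discovery n = 1,500 |
| ORIV | λ = 0.5, n = 10⁴, 60 reps, β = 0.4 |
| RDD size | 2,000 reps × n = 2,000 children, all-zero coefficients |
| RDD recovery | mean of 12 cohorts × n = 10⁵, unstandardized scores |
| decomposition | default CES and separable-linear parameter sets |
| mediation | 60 reps, β_G² = 0.15, active loading 0.7, zero true interaction |

Recovery runs leave scores unstandardized so the published generating
coefficients are the estimands exactly; standardizing would rescale them by
1/sd(Y), a 2–5% distortion that is large relative to the recovery tolerance.

## 7. What the synthetic cohort does and does not show

The generator reproduces the *design* of a school-entry cohort — the cutoff,
the bandwidth sample, the covariate and missingness structure, the PGI
correlations within families — and the estimators' behaviour under known
truths.  It does not reproduce: linkage disequilibrium (so no claim about
LD-aware scoring), selection into test-taking (missingness is MCAR),
population structure (PCs are noise by default), per-SNP nurture
heterogeneity, school-level clustering or peer composition, or non-normal
score distributions.  Passing tests therefore establish that the estimators
are correct under the stated generative assumptions, not that those
assumptions hold in any real cohort.  The few-cluster caveat of §4 applies to
any real month-of-birth design emulated with these defaults.
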