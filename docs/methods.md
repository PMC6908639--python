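# Methods

This note documents the statistical models implemented in `telodyn`, the
choices made where the design was genuinely open, and what the synthetic
study generator does and does not emulate.

## The measurement model: qPCR T/S ratios

Relative leukocyte telomere length (LTL) is measured as a T/S ratio: the
telomere-repeat signal (T) divided by a single-copy-gene signal (S), each
interpolated against its own per-plate standard curve. A standard curve
is an ordinary least-squares fit

    Ct = slope · log10(quantity in ng) + intercept

over a serial dilution of a reference DNA (the default design uses five
3-fold steps from 2.22 to 180 ng, an 81-fold range). Amplification
efficiency is `10^(−1/slope) − 1`; a perfectly doubling reaction has slope
−1/log10(2) ≈ −3.3219 and efficiency 1.0. Unknown wells are inverted
through the curve, `quantity = 10^((Ct − intercept)/slope)`, and the T/S
ratio is the quantity ratio of the two targets.

Open choices, and what we chose:

* **Replicate aggregation.** Reactions run in triplicate; no published
  aggregation rule exists for this assay. We take the mean Ct after
  dropping replicates more than 0.5 cycles from the replicate median
  (threshold configurable). Dropping below two survivors raises a
  low-replication flag; quantities outside the standard range (±5%
  relative slack) raise an extrapolation flag.
* **Reference normalization.** Dividing all T/S values by a designated
  reference sample's T/S is supported but off by default: the quantity
  ratio is already on the standard-DNA scale, and both conventions order
  samples identically.
* **Scope.** Input begins at Ct values. Fluorescence baselining,
  thresholding and melt-curve analysis are instrument concerns.

Error model: with per-well Ct noise of sd 0.05 cycles, triplicate
aggregation leaves ~2–3% noise per sample T/S and ~1.5% shared
plate-level (curve-fit) noise; the procedure is unbiased to ~1%.

## Kinship

The kinship coefficient φ(i,j) is the probability that two alleles, one
sampled from each individual, are identical by descent. It is computed by
the standard tabular recursion in topological order:

    φ(i,i) = ½(1 + φ(f_i, m_i)),   φ(i,j) = ½(φ(f_i, j) + φ(m_i, j))

with founders non-inbred and mutually unrelated, and a missing single
parent treated as a unique phantom founder. The additive (numerator)
relationship matrix is A = 2Φ; it is kept dense (cohorts here are a few
hundred animals). The recursion is verified in tests against
gene-dropping Monte Carlo (simulated transmission of founder alleles).

## Variance decomposition

The phenotype vector of n related animals is modelled as

    y ~ N(Xβ, σ²g·2Φ + σ²e·I),    h² = σ²g / (σ²g + σ²e).

Fitting eigendecomposes A = 2Φ once, rotates y and X into the eigenbasis
where the covariance is diagonal, profiles β and the total variance
analytically, and maximizes the one-dimensional profile over h² ∈ [0,1]
by a 21-point grid scan followed by bounded scalar refinement (tolerance
1e−8). Boundary solutions are returned as-is with a `boundary` flag; a
profile flat to 1e−7 across the grid (e.g. 2Φ = I, where σ²g and σ²e are
not separately identified) resolves to h² = 0 with an `unidentifiable`
flag. Standard errors come from the curvature of the profiled objective
(h²) and the GLS covariance (β).

**Estimation criterion.** The default is REML. Plain ML variance
components are biased downward by the fixed-effect degrees of freedom,
and at these cohort sizes (~200 related animals, 3–4 covariates, mean
kinship ~0.14) that bias is material: in simulation at true h² = 0.27,
ML averages ≈ 0.22 while REML averages ≈ 0.27. The intercept in
particular overlaps the leading eigenvectors of a high-mean-kinship A,
so the loss is far larger than p/n. ML remains available
(`method="ml"`) and is what the dense multivariate-normal oracle tests
exercise.

**Hypothesis tests.**

* Covariate effects: likelihood-ratio test of the model against the same
  model with that coefficient constrained to zero, referred to χ²(1).
  These always compare ordinary-ML log-likelihoods on identical rows
  (listwise deletion first) — restricted likelihoods are not comparable
  across different fixed-effect designs. A covariate that is identically
  zero (or otherwise adds nothing to the design) yields statistic 0 and
  p = 1 by construction.
* Heritability: h² = 0 lies on the boundary of the parameter space, so
  the LRT statistic is referred to the mixture ½χ²(0) + ½χ²(1); a zero
  statistic gives p = 0.5. Full and null share the fixed effects, so the
  ratio is formed on the estimation criterion (REML by default), which
  is valid here and markedly more powerful than the ML ratio (simulated
  power 0.75 vs 0.54 at h² = 0.27, n = 211; type-I error 0.023 vs 0.007
  at α = 0.05 — both conservative).

**Associations.** A predictor's association with a trait is estimated
inside the kinship model: the predictor enters as one more covariate, and
the effect size is reported as R² = β̂²·Var(x)/Var(y), r = sign(β̂)·√R²,
with the ML LRT p-value. This makes R² = r² an exact identity of the
report. A naive Pearson route that ignores kinship is provided for
comparison only. Note two properties of this estimator visible in the
recovery studies: (i) when the predictor carries genetically structured
variance, the GLS discounts covariance that travels through 2Φ, mildly
attenuating r̂ (~0.01–0.02 here); (ii) the *mean* of R̂² across replicate
studies exceeds the square of the mean correlation by Var(r̂) ≈ 1/n —
about one percentage point at n ≈ 106 — which matters when comparing
mean variance fractions against single-study published values of 4–6%.

## Rank-based transforms and the median test

* **Inverse-normal (i-normal) scores:** value = Φ⁻¹((rank − ½)/n) with
  midranks for ties; missing values stay missing and consume no ranks.
  The (r − ½)/n offset is the default; Blom ((r − 3/8)/(n + ¼)) is an
  option. Scores are symmetric about zero by construction.
* **Residualization:** OLS residuals on intercept + covariates (sex,
  age, optionally age×sex); zero-variance covariates are dropped,
  rank-deficient designs raise.
* **ΔLTL (attrition):** baseline minus follow-up, so shortening is
  positive. Two modes reflect the two analyses: per-cohort attrition is
  the difference of plain i-normal scores; combined-cohort attrition is
  the difference of sex/age-adjusted i-normal residuals. (Adjusting for
  age *before* differencing would erase any age effect on attrition,
  which is exactly the effect studied in the control cohort.)
* **Median comparisons:** a permutation Wilcoxon–Mann–Whitney test on
  raw T/S values. The statistic is the midrank sum of the first group;
  the null distribution is enumerated exactly when C(n, n_a) ≤ 2×10⁶,
  otherwise sampled with ≥10⁵ seeded label permutations and the add-one
  estimate (k+1)/(B+1). The two-sided p doubles the smaller tail, capped
  at 1. The rank-sum orders assignments identically to the Mann–Whitney
  U; a Mood-style median dichotomy was considered and rejected as less
  standard.

## The synthetic study generator

No pedigree or phenotype data are deposited for the study this package
models, so every analysis stage is exercised against a generator that
reproduces the *statistical structure the analysis assumes*, with
published effect sizes as generating truth.

**Pedigree.** A closed breeding colony with six discrete, non-overlapping
generations and polygynous mating: every female of a generation is mated
to sires drawn from a pool of 4 males (as in a harem-structured colony),
litter sizes Poisson(2.8), generation sizes clamped to 150–190 animals
(short generations topped up with offspring of random pairs, long ones
thinned) so the sampling pool is stable across seeds. 36 founders. Study
cohorts are sampled from the youngest two generations with a 0.44 female
fraction. Under these defaults the mean pairwise kinship of the cohort
pool is 0.139 (range 0.117–0.163 over 40 seeds), matching the
"between half and full siblings" regime of a real pedigreed colony. Only
the kinship structure enters the likelihood, so the mating system itself
is a free choice.

**Phenotypes.** On the latent (analysis) scale,

    y_it = β_sex·female_i + β_age·(age_i − mean age)
         + β_diet·diet_i·[t = t2] − γ·std(age_i)·[t = t2]
         + g_i + u_i + e_it

with g ~ N(0, h²·2Φ) shared across time points, u an animal-level
environmental effect sized so the within-animal test–retest correlation
is 0.6 (a free choice; no published value exists), and e_it independent
noise scaled so the residual variance is exactly σ²g + σ²e = 1 at each
time point. γ generates age-dependent attrition: γ² = R²_age·2(σ²e − c)
makes age explain a target fraction R²_age of ΔLTL variance. Ages are
uniform on [6, 17] years; sexes Bernoulli. Observed T/S ratios are a
fixed log-linear monotone map of the latent scale (median anchors 0.92
at baseline, 0.90 at follow-up, log-scale spread 0.12), so the analysis
chain must undo the map via ranks rather than being handed the latent
values. Secondary traits (lesion extents, biomarkers) are drawn as
r·z + √(1−r²)·noise against the standardized residual of endpoint LTL
(or of ΔLTL for traits whose association target is attrition), giving
exact target population correlations.

**Scenario library** (generating values from the published tables):
`baseline_combined` (n = 211, h² = 0.27, β_sex = 0.516, β_age = −0.089),
`combined_2yr` (n = 211, h² = 0.46, β_sex = 0.218, β_age = −0.048,
β_diet = −0.486), `lesion_assoc` (n = 106; r = −0.247 descending aorta
vs LTL, r = −0.202 common iliac vs ΔLTL), `biomarker_7wk` (n = 106;
r = −0.241, −0.214, +0.212, +0.224 for V+LDLC, apoE, PON1, TAS) and
`control_delta_age` (n = 105; age explains 20% of ΔLTL variance).
Scenarios where the source tables state no sex/age effects default to
zero fixed effects and h² = 0.27; association recovery is insensitive to
that choice because the predictors are sex/age-adjusted. Identical
(scenario, seed) pairs reproduce byte-identical output; the pedigree,
phenotype and plate streams are seeded independently.

**What the generator does not emulate** — and hence what passing
recovery tests do not show about real data: assay batch/plate effects and
DNA-quality artefacts; age structure tied to pedigree depth (cohort ages
are drawn independently of generation); selection or non-random cohort
assignment; longitudinal attrition of animals; non-Gaussian tails beyond
what the monotone ratio map induces; shared-environment (household/cage)
variance, which would inflate h² estimates in real colonies.

## Numerical and reporting choices

* Within-cohort *sample* variance of the latent trait is below
  σ²g + σ²e = 1 in expectation, by h²·(mean offdiag(2Φ) − (mean diag − 1))
  (≈ 0.06 at h² = 0.27, kinship 0.14): relatives share genetic values.
  Calibration tests check against this analytic expectation.
* Inverse-normal transformation of a two-cohort mixture whose means are
  shifted by a diet effect mildly compresses within-group spacing; at
  the published endpoint effect sizes this attenuates recovered h² by
  ≈ 0.04 (still within the ±0.05 recovery tolerance) and β̂ by ≈ 1–4%.
* Report tables are written with `%.6g` float formatting, and all
  randomness (including Monte-Carlo permutation tests) derives from the
  run seed, so a pipeline run is byte-reproducible.
* Replicate recovery studies use 200 replicates; type-I-error
  simulations use 1000 draws on a fixed 211-animal cohort. These sizes
  put Monte-Carlo error comfortably inside the stated tolerances (e.g.
  SE of the mean ĥ² ≈ 0.012).
* No multiple-testing adjustment is applied anywhere; the report
  records the number of hypothesis tests performed.

## Known limitations

* REML/ML assume multivariate normality on the transformed scale; the
  inverse-normal transform enforces marginal, not joint, normality.
* Standard errors at boundary estimates (h² ∈ {0, 1}) are undefined and
  reported as NaN with a flag.
* The h² standard error is a curvature-based approximation to the
  observed information; for near-boundary estimates it understates the
  asymmetry of the profile.
* Dominance, epistasis, shared-environment components, X-linkage and
  marker-based relationships are out of scope; so are paired/signed-rank
  tests and absolute telomere length in kilobases.
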