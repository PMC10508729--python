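# Methods

This note documents the models, estimators, numerical choices, and
known limitations of `rfa`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The reference-free decomposition

A genotype space is the product of per-site alphabets (`n` sites, `q_i`
states at site `i`, `N = Π q_i` genotypes; alphabets may differ across
sites). The reference-free effects are the factorial (ANOVA-style)
decomposition of the phenotype function: `e0` is the grand mean, an
order-k term is the mean phenotype of the variants sharing a k-state
combination minus the expectation from all lower-order terms. Two
consequences drive everything else:

- **Zero-sum canonical form.** Summing any term group over the states
  of one involved site gives zero. `EffectSet` stores one dense tensor
  per site subset in this form; `zero_sum_violation()` audits it
  (tolerance 1e-9).
- **Variance partition.** The phenotypic variance attributable to a
  term with sites `S` is `e² · Π_{i∈S} 1/q_i`; on a complete full-order
  decomposition the contributions sum exactly to the empirical variance
  of the mean phenotypes (tested at 1e-10).

The exact path (`rfa_exact.exact_effects`) accepts only complete
tables — every genotype measured at least once, duplicates averaged —
and refuses anything less rather than imputing; incomplete data belong
to the regression path. Exactness (full-order model reproduces every
mean phenotype), the minimality of the truncated model's SSE against
reference-based models under every choice of wild type, and agreement
with a literal nested-averaging oracle are all exercised in the suite.

Noise propagation: with iid measurement noise of variance ω, an exactly
computed order-k effect has sampling variance `(q−1)^k ω / q^n` for
uniform alphabets. The mixed-alphabet analogue is taken as
`Π_{i∈S}(q_i−1) · ω / N`; this product form is not stated in the
source formalism for unequal alphabets, so the Monte-Carlo oracle in
the tests is the arbiter.

## Nonspecific epistasis

The link `y = L + (U−L)/(1+e^{−s})` maps genetic score to measured
phenotype. Parameters and defaults:

- `L`, `U` (measurement units): bounds of the measurable phenotype,
  fitted jointly; initialized at the observed range expanded by 5%, and
  parameterized as `(L, log(U−L))` so `U > L` is structural.
- Inverse-link clipping ε = 1e-6 of the range: phenotypes at or beyond
  the bounds have no finite preimage, and inverting near the bounds
  amplifies noise — which is exactly why the package fits the link
  jointly and uses the inverse only for initialization, the
  reference-based grid procedure, and diagnostics.
- Thermodynamic layer: occupancy `e^s/(1+e^s)`, fold change `e^{Δs}`,
  and `ΔΔG = −Δs·kB·T` with T defaulting to 310.15 K (37 °C) and
  `kB = 1.9872 × 10⁻³ kcal/(mol·K)`.

## Joint L1-regularized estimation

Objective: `Σ_{g∈G*} (y_g − link(s(g)))² + λ Σ|terms|`, intercept and
link parameters unpenalized.

**Parameterization.** The default regression encoding is an
*overcomplete one-hot* basis: one coefficient per state and per state
combination, so the penalty acts on the effects themselves and an
unsampled variant's prediction involves only the terms for its own
states. This locality is what makes the reference-free fit robust to
missing genotypes; penalizing an orthogonal contrast basis instead
(also available, `basis="zero_sum"`) demonstrably forfeits it. The
fitted coefficients are decoded to canonical zero-sum form by exactly
re-decomposing the represented function, so all encodings agree
wherever they represent the same function.

**Optimizer.** Proximal-gradient (FISTA) steps on the coefficients —
soft-thresholding handles the L1 term exactly, with backtracking line
search and momentum restarts — alternating with analytic-gradient
L-BFGS-B steps on `(L, log(U−L))`. Convergence is declared when the
relative objective change falls below `grad_tol` (default 1e-8);
non-convergence flags the result and logs a warning, never raises. The
sigmoid makes the joint problem non-convex, so standalone fits run 3
random restarts by default (jittered link initialization); inner
cross-validation fits use 1, because the range-based initialization is
stable and the restart cost across the λ-by-fold grid is not repaid.
Without a link and λ = 0 the solver is a minimum-norm least squares;
with λ > 0 it matches an independent coordinate-descent implementation
to 1e-6 in the tests.

**Regularization path.** The automatic grid has 20 log-spaced values
spanning six decades below `λ_max = 2·max|Xᵀ(y−ȳ)|` — the smallest
strength that zeroes every penalized coefficient in the linear problem
— plus 0. The ceiling is data-driven because the objective's SSE is
unnormalized; a variance-scaled ceiling would leave the strongest grid
point ineffective and the selection rule unable to reach the
intercept-only model.

**Selection rule.** For each λ, out-of-sample R² is recorded per CV
replicate (random k-fold, default 10 folds × 3 repeats; or
leave-one-measurement-replicate-out when the table has fewer than 50
rows and ≥2 replicates). The chosen λ is the strongest whose per-fold
R² does not significantly differ from the maximum in a paired two-sided
t-test at p = 0.1; identical fold vectors count as not different. The
final model is refit on all rows at that λ. The cross-validation table
reports both the per-fold mean ± SE (what the selection rule consumes)
and a pooled predict-the-held-out-rest R² per repeat. The pooled form
matters for near-null models: the per-fold average of a constant
predictor is biased by about `−(1+n_test/n_train)/(n_test−1)`, large
enough to mask a true zero on small spaces, while the pooled estimator's
bias is `−(1/n_train + 1/N)`.

Note the selected estimator shrinks magnitudes: refitting at the chosen
λ biases each surviving coefficient toward zero by roughly
`λ/(2‖x_j‖²)`. Signs and support are reliable; users needing unbiased
magnitudes should refit the selected support at λ = 0.

For all-binary spaces `fit_binary_fourier` runs the identical machinery
on the ±1 Fourier encoding (fewer coefficients) and converts back;
at λ = 0 on complete data it reproduces the exact decomposition.

## Comparator formalisms

All four formalisms parameterize the same function space via per-site
bases, which is how the package implements them:

- **Reference-based (RBA):** terms defined by inclusion–exclusion so the
  order-k model is exact for the wild type and all ≤k-mutants. The
  link-aware variant grid-searches `(L, U)` over the observed range
  expanded by 50% (25 × 25, refined once around the best cell), computes
  the low-order terms from inverse-linked phenotypes, and scores each
  candidate by R² on the higher-order mutants. Regression least squares
  does *not* estimate true RBA terms from incomplete data — the package
  demonstrates this as a regression test rather than hiding it.
- **Fourier (FA):** deterministic Helmert orthonormal contrasts per site
  (the Walsh–Hadamard basis for binary sites up to √2-per-site scaling).
  Any orthonormal choice gives identical predictions and per-order
  variance, which is what the tests assert.
- **Background-averaged (BA):** the term for a mutation combination is
  the finite difference over the focal sites (mutant versus per-site
  reference states, default: first alphabet token) averaged over all
  backgrounds. Averaging cancels every reference-free term not
  involving all focal sites, so the BA order-k terms are signed
  combinations of the order-k reference-free tensors — the
  implementation, verified against a literal averaged-finite-difference
  oracle for binary and 3-state spaces and against the classical
  Hadamard form for binary sites.

`convert` evaluates the source model's scores on the complete space and
exactly re-decomposes in the target formalism; a truncated model of
order k spans only interactions up to order k in every parameterization,
so conversion is prediction-identical (machine precision) and requires
an enumerable space.

## Synthetic data

`simulate_architecture` draws effects from a standard normal in a
chosen formalism. Drawing reference-free gives exact control over the
populated orders (tensors are drawn, zero-sum-projected per axis, then
rescaled by `Π √(q_i/(q_i−1))` so the marginal SD of drawn terms is the
requested `effect_sd`); drawing reference-based and converting induces
nonzero lower-order reference-free terms, as the benchmark experiments
require. `simulate_phenotypes` applies the optional link and adds
iid Gaussian noise per replicate. All generators thread one master
seed through `numpy.random.SeedSequence`, so every experiment table is
bit-reproducible.

What the generator emulates: the shapes of published combinatorial
datasets (2–20 states, 3–16 sites), bounded dynamic range, replicate
noise, random incompleteness. What it does not: non-random missingness
(read-count filters), heteroscedastic noise, multi-phenotype
correlations, or any sequence-level structure — so a green simulation
test establishes correctness of the estimators under the stated
sampling model, not robustness to every artifact of real assays.

Experiment runners and their stated worlds:

- *Noise*: 3-state, 5-site space, ω = 1. Both exact estimators are
  linear in the data, so error distributions are computed by applying
  them to pure noise draws; the reference-free error SD tracks the
  analytic law (10% relative at the tested draw counts) while the
  reference-based error is `√(2^k ω)` and grows with order.
- *Missing genotypes*: third-order reference-based architectures on
  4-state/6-site and 16-state/3-site spaces; models fit on a sampled
  fraction at a single weak penalty (`1e-3 · var(y)` — the comparison
  is between encodings, not regularization schedules) and scored on the
  rest. At 5% sampling the reference-free and background-averaged
  encodings tie on the 4-state space and separate decisively on the
  16-state space, so the directional test lives there.
- *Truncation*: third-order-only truth through a sigmoid on 3^5.
  First- and second-order fits should explain ~0 variance; the
  complete-data tolerance is |R²| ≤ 0.02, and the half-sampled variant
  uses 0.04 because a correct (intercept-only) model scored on 121 rows
  cannot beat the pooled-CV bias floor of about −0.019.

## Diagnostics

- `rank_terms`: descending variance contribution, deterministic
  tie-break by (order, sites, states).
- `t90_curve`: the ranking is frozen from the fitted model; each prefix
  refits its term values (indicator features, plus intercept and link,
  unpenalized) and is scored by k-fold CV. T90 is reported two ways —
  prefix reaching R² ≥ 0.9 (an overestimate under noise) and prefix
  reaching 90% of the full model's R² — plus their average; NaN marks
  "not attained".
- `n90_curve`: per sample size, without-replacement samples are fitted
  with CV-chosen λ and scored on all unsampled rows; N90 interpolates
  the 0.9 crossing linearly on log sample size.
- `detect_outliers`: residual of the second-order model against the
  *observed* phenotype range (max − min of replicate means, not the
  fitted `U − L`, which can saturate far beyond data); flagged on
  strict inequality at 20% of the range.
- `bound_fraction`: mean phenotype within 2% of the link range of
  either bound.
- `specificity_scores`: per-term score differences between two fits on
  the same space; `exp` of a difference is the fold preference in
  relative occupancy.
- `fit_power_law`: plain least squares on log–log scale; no outlier
  robustness promised.

## Known limitations

- Exact constructors, `convert`, and the one-hot decoding enumerate the
  genotype space, so they require `N` below the enumeration cap
  (default 2 × 10⁶); regression on larger spaces would need a
  streaming decoder that is out of scope.
- The sigmoid is the only shipped link; the interface (transform,
  inverse, parameter count) is pluggable but alternatives are not
  implemented.
- Weighted averaging under non-uniform genotype distributions is out of
  scope; all means are uniform over the space.
- The p = 0.1 selection rule has low power with few CV replicates and
  then chooses aggressive penalties; with very sparse samples this can
  collapse the model to the intercept. This mirrors the rule as
  specified rather than a defect of the optimizer.
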