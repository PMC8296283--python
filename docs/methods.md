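# Methods

## The problem and the models

`anemiamap` estimates the prevalence of a binary health outcome — its
motivating application is anemia (hemoglobin < 110 g/L) in children under
five across Guinea's eight administrative regions — and maps how that risk
varies over areal units after adjusting for individual-level covariates.
Child *i* in region *j* has outcome
Y_ij ~ Bernoulli(p_ij), and four nested logit models are available:

| kind | linear predictor                  | region effect                       |
|------|-----------------------------------|-------------------------------------|
| M1   | x' β                              | none                                |
| M2   | x' β + v_j                        | exchangeable, v_j ~ N(0, σ²)        |
| M3   | x' β + u_j                        | spatially structured (intrinsic CAR)|
| M4   | x' β + u_j + v_j                  | both (the BYM convolution)          |

x is an intercept plus treatment-coded dummies for declared categorical
covariates (for the bundled Guinea covariate set: residence, child age
group, wealth quintile, mother's education, household-head ethnicity and
religion, TV ownership, electricity — k = 22 columns).

The ICAR prior conditions each u_j on its graph neighbours:
u_j | u_-j ~ N(mean of neighbours, τ²/m_j), with m_j the neighbour count.
The joint density is improper (constant shifts are unpenalised) with rank
J − 1 on a connected graph; identifiability is restored by recentring u to
sum to zero after every sweep.  The exchangeable effect v captures
unstructured heterogeneity between regions.

Priors: every coefficient (intercept included) is N(0, 1/10⁻³); the
precisions 1/σ² and 1/τ² carry Gamma(10⁻³, 10⁻³) hyperpriors.  With both
gamma constants equal, the shape/rate and shape/scale readings coincide;
the API names them shape and rate.  A notational caveat: some disease-
mapping literature writes the ICAR spread as a "standard deviation" where
the formula uses a variance; here `tau2` is always the conditional variance
scale (the τ² dividing by m_j).

## Sampler

Metropolis-within-Gibbs.  Per sweep: each coefficient gets a scalar
symmetric random-walk Metropolis move, then each v_j, then each u_j (whose
prior term uses the ICAR full conditional), then the two precisions are
drawn from their conjugate gamma full conditionals — for v,
Gamma(a + J/2, b + Σv²/2); for u the intrinsic rank J − 1 and the
pairwise-difference sum of squares replace the dimension and Σu².  Because
every design column is 0/1, a scalar move shifts the linear predictor by a
constant on that column's active rows only, which is what the compiled
(numba) sweep exploits; the per-row log-normaliser log(1 + e^η) is
maintained incrementally and the per-draw deviance is recorded during
sampling.

Numerical and design choices:

* **Initialisation**: β = 0 except over-dispersed intercepts per chain
  (0, +1, −1, …); u = v = 0; precisions 1.  At least two chains are required
  so the Gelman–Rubin diagnostic is defined.
* **Adaptation**: random-walk scales (initial 0.2) are tuned only during
  burn-in, in windows of 50 sweeps toward a 0.44 acceptance target; the
  post-adaptation contract band is 0.2–0.7 — wider than the target because
  acceptance for the random-effect blocks drifts as the hierarchical
  variances settle after adaptation freezes.  Freezing after burn-in keeps
  the retained chain a valid fixed-kernel Markov chain.
* **Recentring**: after each u sweep the mean of u is subtracted and added
  to the intercept, leaving the linear predictor — hence the likelihood —
  unchanged mid-chain.
* **Divergence**: a non-finite deviance at a kept iteration aborts the
  chain with a diagnostic.
* **Defaults**: 100,000 iterations with 5,000 burn-in (the motivating
  analysis's settings), 2 chains, no thinning.  Chains are reproducible
  bit-for-bit from the seed.

## Diagnostics and reporting

* **Gelman–Rubin**: classic form, R̂ = sqrt(((n−1)/n·W + B/n)/W); no rank
  normalisation, matching the diagnostic as originally defined.  Undefined
  (NaN) when W = 0.
* **DIC**: D̄ is the mean of the per-draw deviances; D̂ plugs in the
  posterior means of all quantities in the linear predictor (β, u, v);
  p_D = D̄ − D̂; DIC = D̄ + p_D.  Differences ≤ 3 are labelled
  indistinguishable (the boundary counts as indistinguishable), 3–7 weak,
  > 7 clear.
* **Odds ratios**: exp(posterior mean of β) with exp of the equal-tailed
  2.5/97.5% quantiles — exp-of-mean is used rather than mean-of-exp for
  stability under heavy right tails.  Reference levels print as 1.
* **Predicted region prevalence**: posterior mean of the region-average
  probability (averaging inverse-logits within each draw), not the
  probability at the posterior means — the two differ by Jensen's
  inequality and the former is the honest posterior summary of prevalence.
* **Crude odds ratios** (descriptive stage): (a/b)/(c/d) from 2×2 tables
  with Woolf CIs exp(ln OR ± z·sqrt(1/a+1/b+1/c+1/d)); no continuity
  correction; a zero cell leaves the CI undefined rather than corrected.
  Woolf was chosen because it reproduces the published crude region CIs for
  the Guinea survey to two printed decimals.  Display rounding is half-up
  to two decimals; full precision is kept internally.
* **Effect maps**: region-effect posterior means are binned low (≤ 0),
  moderate (0, 0.1], high (> 0.1) for choropleth-style export.

## Bundled reference data and the adjacency fixture

The published summary tables of the Guinea MICS5 2016 survey are embedded
(`anemiamap.guinea`): covariate margins, per-region prevalence, crude OR
tables, and DIC values.  Per-region positive counts are reconstructed as
round(N × prevalence/100); the reconstruction is exact — it recovers the
published national total of 2009 anemic children.

The survey's analysis never printed its region adjacency.  The bundled
fixture is first-order contiguity read off the national map (Boke–Kindia,
Boke–Labe, Conakry–Kindia, Kindia–Mamou, Mamou–Labe, Mamou–Faranah,
Labe–Faranah, Faranah–Kankan, Faranah–Nzerekore, Kankan–Nzerekore) and is
user-overridable via a neighbours-list file or adjacency-matrix CSV, so no
result silently depends on an unstated graph.

## Synthetic-data generator

The generator emulates the survey's structure: n = 2609 children allocated
to regions with the published shares, covariates drawn independently from
the published margins, v ~ N(0, σ²) per region, u from the
sum-to-zero-constrained ICAR (sampled by spectral decomposition of the
graph Laplacian), and outcomes through the logistic link.  Default truth:
intercept logit(0.77) — the national prevalence — with the three published
adjusted effects (OR 0.47 for ages 48–59 months, 0.67 for secondary-or-
above maternal education, 0.48 for Kissi household heads) and all other
coefficients zero; σ² = τ² = 0.01, i.e. sd 0.1 on the logit scale, matching
the magnitude of the published posterior region effects (≈ 0.0–0.11).

What the generator does **not** emulate: covariate dependence (real wealth,
education, residence and ethnicity are strongly associated), household/
cluster sampling stages, survey weights, and missing-data mechanisms.
Passing recovery tests therefore demonstrate the estimator's correctness
under the declared model, not robustness to the design features of a real
complex survey.

## Validation strategy and problem sizes

The descriptive stage is validated exactly against the published tables.
The modelling stage, whose published adjusted estimates require restricted
microdata, is validated by simulation:

* parameter recovery — 20 replicates of the default generator fitted with
  the convolution model at 20,000 iterations / 2,000 burn-in / 2 chains;
  each nonzero true coefficient must be covered by its 95% credible
  interval in at least 17 of 20 replicates;
* the ICAR full conditional derived numerically from the joint density
  matches the neighbour-mean normal law;
* Gibbs precision draws pass a Kolmogorov–Smirnov check against the
  closed-form gamma posterior;
* the chain marginal on a two-child intercept-only toy matches a
  grid-enumerated posterior;
* DIC obeys its algebraic identity to 10⁻¹⁰ and p_D approximates the
  coefficient count (±20%) for the fixed-effects model at full survey size;
* R̂ reproduces hand-computed values and stays below 1.1 on well-mixed
  fits.

Shorter chains than the 100,000-iteration default are used throughout the
test and validation runs (2,000–60,000 iterations depending on the check);
these lengths were chosen as the smallest at which Monte Carlo error is
comfortably below each check's tolerance.

## Known limitations

* Complete-case analysis only; no imputation or survey weights.
* Categorical covariates only (the design matrix must be 0/1; this is also
  what the compiled sweep exploits).
* The adjacency fixture is an assumption, not a published artifact.
* Coordinate-wise random-walk moves mix slowly for strongly correlated
  coefficients; the intercept is the slowest-mixing parameter.  The
  defaults leave ample effective sample size, but heavily reduced runs
  should be checked with `rhat_table`.
* DIC is reported in its plug-in form; it is known to under-penalise when
  posteriors are far from normal (e.g., variance parameters near zero).
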