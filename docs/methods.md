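# Methods

## The model

Association mapping between N samples' covariates and their count-based
expression readouts is cast as a multivariate Poisson regression whose
P×Q coefficient matrix **B** is constrained to rank R ≪ min(P, Q) through
the factorization **B** = **U V**ᵀ, with **U** ∈ ℝ^{P×R} (covariate
factors) and **V** ∈ ℝ^{Q×R} (gene factors). The low-rank constraint
encodes the assumption that covariates act on expression through a small
number of shared transcriptional programs rather than gene by gene, which
both regularizes the fit in the common Q ≫ N regime and reduces the
number of association hypotheses from P·Q to R·(P+Q).

Two likelihoods are implemented:

**Log-link PRRR** (`PoissonRRR`):

    y_nq | U, V, x_n  ~  Poisson( exp(x_n U v_q^T) )

with independent Gaussian priors on the factor entries,
u_pr ~ N(0, σ₁²), v_qr ~ N(0, σ₂²). Covariates may be any real
numbers: genotype dosages, one-hot cell-type indicators, spatial
coordinates, clinical measurements.

**Identity-link nonnegative PRRR** (`NonnegativePoissonRRR`):

    y_nq | U, V, x_n  ~  Poisson( s_n · x_n U v_q^T )

with Gamma(α, β) priors on the strictly positive factor entries and
per-sample size factors s_n fixed to the sample's total count
s_n = Σ_q y_nq, absorbing sequencing depth. Requiring x, U, V ≥ 0 yields
a parts-based, purely additive decomposition (in the spirit of
nonnegative matrix factorization) at the cost of requiring nonnegative
covariates. Defaults α = 2, β = 1.

Only **B** = **U V**ᵀ is identified: (U G, V G⁻ᵀ) gives the same
likelihood for any invertible R×R matrix G (any c > 0 in the rank-1
rescaling (Uc, V/c) for the nonnegative model). All coefficient analyses
therefore report **B** or per-factor outer products u_r v_rᵀ, never raw
factors compared across fits.

## Inference

Gradients of both log joints are closed form, so all fitting runs on
numpy with an in-package Adam optimizer (learning rate 0.01 by default).

**MAP** (`fit(method="map")`) ascends
log p(U, V) + Σ_n log p(y_n | x_n, U, V). The nonnegative model is
optimized in log-parameters (log U, log V) — a smooth, unconstrained
reparameterization that guarantees positivity and matches the geometry of
the log-normal variational family. Initialization draws factor entries
(log-factor entries for the nonnegative model) from N(0, 0.1²): small
enough not to saturate the exp link, random enough to break the
rotational symmetry of the factorization.

**Stochastic variational inference** (`fit(method="vi")`) posits a
mean-field family — independent N(μ, σ²) per factor entry for the
log-link model, LogNormal(μ, σ²) for the nonnegative one — and maximizes
the evidence lower bound

    ELBO = E_q[ log p(Y, U, V | X) − log q(U, V) ] ≤ log p(Y | X).

Training gradients use the reparameterization trick with
`mc_samples_train` draws (default 1) for the likelihood term; the
expected log prior and the entropy are closed form for both
family/prior pairs and enter analytically, which keeps gradient variance
low at no cost. Variational locations initialize like MAP; log σ starts
at −2. Point estimates are the variational means mapped through the
family: μ for the normal family, exp(μ + σ²/2) for the log-normal.

The *reported* ELBO of a VI fit is the plain Monte-Carlo estimator
(averaging log p − log q over `mc_samples_eval` = 64 reparameterized
draws) at a fixed evaluation seed shared by all fits, so ELBOs are
comparable across ranks and restarts: every fit is scored against the
same Monte-Carlo noise. The `elbo()` function is deterministic given its
seed.

**Rank selection** (`select_rank`) fits VI at each candidate rank with
`restarts` independent initializations (seeds `seed + restart index`,
shared across ranks so restarts are paired), and picks the rank with the
largest mean evaluated ELBO, ties toward the smaller rank. Underfitting
(R < R*) costs likelihood sharply; overfitting (R > R*) costs KL mass for
the extra factor columns slowly — so the ELBO curve rises steeply to R*
and drifts down beyond it, and held-out prediction degrades much faster
below R* than above it. Misspecifying the rank upward is the safer error.

### Numerical choices

- The log-link linear predictor is clipped to [−30, 30] before
  exponentiation (exp(30) ≈ 10¹³ counts, far beyond data; exp(700)
  overflows float64). The gradient passes straight through so a saturated
  predictor is pulled back rather than stalling.
- Identity-link rates get a floor of 10⁻⁸ so logs stay finite when a
  covariate row is all zeros.
- Poisson log-pmf constants (log y!) are retained, so objectives and
  ELBOs are comparable across models and ranks.
- Convergence: stop when the relative change between successive
  50-iteration moving averages of the objective falls below `rel_tol`
  (10⁻⁶), or at `max_iter` (default 3000). The moving average makes the
  rule usable on the noisy single-sample ELBO trace.
- Step budgets: Adam at a constant 0.01 learning rate needs iterations
  roughly proportional to the largest coefficient magnitude. Generative
  draws occasionally place a linear predictor near 10–15 (counts of
  10⁵–10⁶), and such fits need ~10⁴ steps to converge; the bundled
  rank-selection and rank-robustness experiments therefore run with
  `max_iter = 12000`. Comparing ELBOs or held-out R² across ranks is
  meaningful only between converged fits.
- Gaussian reduced-rank regression (`fit_gaussian_rrr`) adds a small
  ridge (10⁻⁶) to XᵀX by default; the reduced-rank projection uses the
  leading right singular vectors of the fitted values X·B̂_OLS, making
  X·B̂_RRR the Eckart–Young-optimal rank-R approximation of the OLS
  fitted values (verified against a multi-start alternating-least-squares
  oracle in the tests).
- No intercept is fitted; request a constant covariate column at encoding
  time if needed.

### Defaults and the prior scales

The Gaussian prior variances default to σ₁² = σ₂² = 1 and are exposed in
`PriorConfig`; with standardized covariates this is a weakly informative
choice under the log link (coefficient ±2 means a ±e² fold change). MAP
and VI are both first-class: MAP is faster and is the default for
prediction experiments; VI supplies the ELBO for rank selection and
uncertainty summaries.

## Synthetic data

`simulate_dataset` draws from the models' own generative processes:

- factor entries: N(0, factor_scale²) (log-link) or
  factor_scale·Gamma(2, 1) (nonnegative). `factor_scale` defaults to
  0.5, which with P = 10, R = 3 Gaussian covariates keeps median counts
  in a realistic single-cell range (≈ 1–50) while still producing the
  occasional highly expressed gene.
- covariate schemes: `gaussian` (standard normal), `genotype`
  (i.i.d. Binomial(2, maf) minor-allele counts, default maf 0.3),
  `one_hot` (balanced random group labels), `spatial` (uniform 2-D
  coordinates in [0,1]², naturally paired with a rank-1 fit for a single
  spatial expression gradient).
- the `grouped` scheme emulates grouped single-cell counts (e.g. 10 cell
  populations with population-specific expression profiles) as a
  low-rank log-link draw over one-hot group indicators. It reproduces the
  shape of such data — group-structured means with Poisson noise — but
  not dropout, library-size dispersion, or batch effects, so conclusions
  drawn from it concern group-mean structure only.
- nonnegative-scheme size factors are drawn uniformly in [500, 2000] and
  then treated as fixed truths; an all-zero sample row (possible at tiny
  rates) receives one pseudo-count so its size factor is defined.

What passing these simulations shows — and does not. The generators match
the fitted models' assumptions exactly (aside from the grouped scheme's
excess of structure over a rank-5 fit), so recovery and rank-selection
results certify the inference machinery, not robustness to the
overdispersion, zero inflation, or confounding of real sequencing data.

## Evaluation and downstream analyses

- `split(n, fraction=0.8, seed)`: uniform train/test split,
  ⌊fraction·n⌋ training rows.
- `predict`: held-out Poisson rates exp(X_new Û V̂ᵀ) (log link) or
  ŝ·(X_new Û V̂ᵀ); new-sample size factors default to the training mean,
  because held-out totals are part of the outcome being predicted — pass
  observed totals explicitly for pure goodness-of-fit use.
- `goodness_of_fit_r2`: R² = 1 − SSE/SST between predicted rates and
  observed counts, jointly over all entries against the grand mean; may
  be negative. A per-gene variant exists but is not the default.
- `full_coefficients` / `factor_association` / `top_markers`: B = U Vᵀ
  with labels; the top-k |entries| of u_r v_rᵀ per factor (ties broken
  lexicographically); and the k genes with the largest signed coefficient
  in a covariate's row of B (k = 10 default) as that covariate's marker
  genes.

## Known limitations

- Linear associations only; no gene–gene covariance beyond the low-rank
  mean structure; Poisson (equidispersed) noise — no negative-binomial or
  zero-inflated variants.
- Mean-field VI underestimates posterior correlations between U and V;
  its ELBO remains a valid lower bound and a usable model-comparison
  score.
- The rank must be supplied or scanned; there is no nonparametric rank
  inference.
- MAP point estimates of B are identified only up to the factor
  ambiguity; per-factor analyses (u_r v_rᵀ) depend on the particular
  factorization the optimizer reached and should be read as exploratory.
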