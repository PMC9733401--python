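# prrr — Poisson reduced-rank regression for count-based association mapping

Tools for mapping associations between high-dimensional covariates and
count-based gene expression. Given covariates **X** (N samples × P
features — genotype dosages, one-hot cell types, spatial coordinates,
…) and transcript counts **Y** (N × Q genes), the package fits a
multivariate Poisson regression whose coefficient matrix is constrained
to low rank,

    y_nq ~ Poisson( exp(x_n U v_q^T) ),        B = U V^T,  rank R << min(P, Q),

with Gaussian priors on the factors **U** (P×R) and **V** (Q×R)
(`PoissonRRR`), or the nonnegative identity-link variant

    y_nq ~ Poisson( s_n · x_n U v_q^T ),       x, U, V >= 0,

with Gamma priors and per-sample size factors s_n = Σ_q y_nq
(`NonnegativePoissonRRR`), which yields a parts-based additive
decomposition. The low-rank constraint shares statistical strength across
correlated genes and replaces P·Q univariate association tests with
R·(P+Q) interpretable factor loadings — the regime of eQTL studies,
cell-type marker analysis, and spatial expression profiling, where
outcomes are counts and Gaussian methods fit poorly.

Fitting is by MAP gradient ascent or stochastic variational inference
(mean-field normal / log-normal families); the evidence lower bound
(ELBO) doubles as a model-comparison score for selecting the rank.
Gaussian reduced-rank regression (closed form) and full-rank Poisson
regression are included as baselines. Audience: statistical-genetics and
single-cell people who want multivariate count-aware association maps
without writing inference code.

## Worked example

Simulate from the generative model with a true rank of 2, fit on 80% of
samples, score held-out predictions:

```python
import numpy as np
from prrr import (PoissonRRR, SimulationSpec, simulate_dataset, split,
                  goodness_of_fit_r2, top_markers)

data = simulate_dataset(SimulationSpec(n_samples=300, n_covariates=8,
                                       n_genes=40, true_rank=2, seed=7))
sp = split(300, 0.8, seed=0)
Ytr, Yte = data.Y.values[sp.train_rows], data.Y.values[sp.test_rows]
Xtr, Xte = data.X.values[sp.train_rows], data.X.values[sp.test_rows]

model = PoissonRRR(Ytr, Xtr)
res = model.fit(rank=2, method="map", seed=0)
print(res.summary())
```

```
Poisson RRR (log link)
==========================================================
  samples:          240
  covariates:       8
  genes:            40
  rank:             2
  method:           MAP
  iterations:       1700 (converged)
  final objective:  -12678.9701
  largest |coefficients| (covariate, gene, value):
    covariate5       gene0            -0.7509
    covariate5       gene2            +0.7137
    covariate5       gene20           -0.7033
    covariate5       gene15           +0.6759
    covariate5       gene16           +0.6424
==========================================================
```

The final objective is the log joint (log prior + Poisson log
likelihood) at the optimum; the coefficient list shows the strongest
covariate–gene associations in B = U Vᵀ.

```python
r2 = goodness_of_fit_r2(Yte, res.predict(Xte))
err = np.linalg.norm(res.coefficients - data.true_B) / np.linalg.norm(data.true_B)
print(f"held-out R^2: {r2:.3f}")                 # held-out R^2: 0.400
print(f"relative coefficient error: {err:.3f}")  # relative coefficient error: 0.148
print(top_markers(res.coefficients_frame, "covariate0", k=3))
# ['gene18', 'gene21', 'gene0']
```

Held-out R² compares predicted Poisson rates with unseen counts (1 is
perfect, 0 is the grand-mean predictor); the 0.148 relative Frobenius
error says the fitted coefficient matrix is close to the generating one;
`top_markers` lists the genes most strongly driven by a covariate.

To choose the rank, sweep VI fits and compare ELBOs:

```python
sel = model.select_rank(range(1, 6), restarts=5, seed=0, max_iter=12000)
print(sel.best_rank)        # 2
print(sel.summary())        # per-rank mean ELBO, standard error, restarts
```

The same workflow is available from the shell:

```bash
prrr simulate --n-samples 300 --true-rank 2 --seed 7 --out sim/
prrr fit --counts sim/Y.csv --covariates sim/X.csv --rank 2 --out fit/
prrr predict --factors fit/ --covariates sim/X.csv --out pred/
prrr score --counts sim/Y.csv --predictions pred/predicted_rates.csv
prrr select-rank --counts sim/Y.csv --covariates sim/X.csv --ranks 1:5 --restarts 5 --out sel/
prrr markers --factors fit/ --covariate covariate0 --top-k 10 --out mk/
```

Counts are read as labeled CSV/TSV or MatrixMarket MTX (with
`samples.txt`/`genes.txt` sidecars, genes-as-rows auto-detected);
categorical covariates can be one-hot encoded on read
(`--encoding one_hot`), genotype files are validated to {0,1,2}.

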