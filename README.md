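# esis

Model-free gene screening for high-dimensional right-censored survival data.

## The problem

In cancer genomics a cohort of a few hundred patients comes with tens of
thousands of gene-expression measurements and a right-censored survival
endpoint: the observed time is `Y = min(T, C)` with event indicator
`δ = I(T ≤ C)`, where `T` is the time to event and `C` an independent
censoring time.  Only a small subset 𝒜 of genes is believed to influence
`P(T > t | X)`, and fitting any joint model with p ≫ n is hopeless.  *Sure
independence screening* sidesteps this: rank every gene by a marginal
dependence measure with the outcome and keep the top `d` (typically
`⌊n/log n⌋` … `n − 1`), so that 𝒜 is retained with high probability and
classical low-dimensional tools can take over.

Screens built on the Pearson correlation or on Cox-model fits miss genes
whose effect on the hazard is nonlinear or non-monotone.  This package
implements a fully model-free screen built on a kernel dependence measure,
together with a synthetic-cohort generator and the downstream
risk-stratification stage, so the whole
screening → selection → evaluation workflow runs end to end.

## The screening index

For random variables `U`, `V` and a characteristic positive-definite kernel
`K` (Gaussian or Laplacian here), the ECCFIC dependence measure is

    H²_K(U|V) = E_V E_{U|V, U'|V} K(U, U') − E_{U,U'} K(U, U'),

and its normalization

    ρ_K(U|V) = H²_K(U|V) / H²_K(U|U)  ∈ [0, 1]

is 0 iff `U ⫫ V` and 1 iff `U` is a function of `V` — an R²-style
coefficient that sees arbitrary nonlinear dependence.  `H²_K(U|V)` is
estimated by a Nadaraya–Watson plug-in with Gaussian smoothing weights and
the rule-of-thumb bandwidth `h = 1.06 · sd(V) · n^{−1/5}`; the package
carries both the literal O(n⁵) sum (as a correctness oracle) and an
algebraically equivalent O(n³) form used everywhere.

Screening proceeds per gene `j`:

1. transform the outcome, `U_T = F̂_T(Y)`, with `F̂_T` the Kaplan–Meier CDF
   estimate, and the gene, `U_Xj = F̂_Xj(X_j)`, with its empirical CDF;
2. score `ŵ_j = ρ̂_K(U_T | U_Xj)`;
3. keep the genes with the `d` largest scores.

Both transforms are rank-based, so scores are invariant under monotone
rescaling of genes and robust to heavy-tailed expression values.  After
screening, a LASSO-penalized proportional-hazards model (delegated to
scikit-survival) turns the retained genes into a risk score; patients are
split into high/low-risk groups at the training-cohort median score and the
groups compared with the log-rank test.

## Worked example

Library use, on a synthetic cohort whose hazard depends on 4 of 1000 genes
through x², sin(x) and |x| effects with ~30% censoring:

```python
from esis import generate, screen, minimum_model_size

ds = generate(n=200, p=1000, model="cox_nonlinear", censor_frac=0.3, seed=7)
res = screen(ds.X, ds.samples)          # d defaults to floor(n / log n) = 37
print(res.d, list(res.selected_ids[:6]))
print(minimum_model_size(res.scores, ds.active))
```

prints `d = 37`, top genes `['g1', 'g2', 'g3', 'g0', 'g643', 'g415']` with
scores `0.131, 0.094, 0.068, 0.047, 0.040, 0.037`, and a minimum model size
of `4`: all four truly active genes (g0–g3) rank ahead of all 996 noise
genes, even though none of them acts linearly on the hazard.

The same workflow from the shell:

```sh
esis simulate --n 80 --p 40 --seed 2 --censor-frac 0.3 --out sim
# wrote synthetic cohort (n=80, p=40, censored 36.3%) to sim
esis screen --expression sim/expression.tsv --survival sim/survival.csv --out scr
# screened 40 genes, kept d=18; results in scr   (ranking.tsv: g2, g1, g0, ...)
esis evaluate --expression sim/expression.tsv --survival sim/survival.csv \
    --cv-folds 5 --out ev
# test log-rank p = 0.0002329; results in ev
```

`ev/summary.json` reports 4 nonzero coefficients — exactly the simulated
active genes g0–g3 — and the high/low-risk split of the held-out fifth of
the cohort separates with log-rank p ≈ 2.3e−4.

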