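# Methods

## Estimand and estimator

For a characteristic positive-definite kernel `K`, the dependence of `U` on
`V` is measured by `H²_K(U|V) = E_V E_{U|V,U'|V} K(U,U') − E_{U,U'} K(U,U')`
and normalized by the self term `H²_K(U|U) = E_U K(U,U) − E_{U,U'} K(U,U')`
to give `ρ_K(U|V) ∈ [0,1]`, zero iff independence, one iff `U` is a function
of `V`.

The plug-in estimator of `H²_K(U|V)` replaces the conditional expectations
with Nadaraya–Watson smoothers built from a Gaussian kernel `G` with
bandwidth `h`.  Written with the row-stochastic weight matrix
`A[t,s] = G_h(V_t−V_s) / Σ_l G_h(V_t−V_l)`, kernel row sums `R` and grand
sum `Q`, the estimate is

    (1/n) Σ_t [ (A K Aᵀ)_tt − (2/n)(A R)_t + Q/n² ],

which is exactly the printed quintuple sum with its per-`t1` denominator,
after the two free summation indices are summed analytically; each summand
is the squared RKHS distance between the smoothed conditional mean embedding
at `V_t` and the marginal mean embedding, so this form is nonnegative by
construction.  `eccfic.h2_cond_naive` transcribes the quintuple sum
literally (cost O(n⁵), capped at n ≤ 12) and serves as the oracle: the test
suite requires agreement within 1e−10 over 100+ random instances for both
Gaussian and Laplacian `K`.  Any constant factor on `G` (the `h^{−q}`
normalizer) cancels between numerator and denominator; both code paths use
the same `G` values so the equivalence check is exact.

Estimated correlations are reported raw.  The normalized estimate can
exceed [0,1] slightly in finite samples; since the only downstream use is
ranking, clamping would hide estimator defects without changing any result.

## Transforms

* Outcome: `U_T = F̂_T(Y)` with `F̂_T` the Kaplan–Meier CDF estimate.  Tied
  event times are handled with the grouped factor `(1 − d_k/r_k)` per
  distinct event time; censored observations tied with an event count toward
  its risk set; censored observations are evaluated through the same step
  function as events, with no imputation.  The survival product is
  accumulated in exact rational arithmetic (a one-off O(n) cost per
  dataset), which makes the no-censoring case coincide bit-for-bit with the
  empirical CDF, ties included.
* Genes: `U_Xj = F̂_Xj(X_j)`, the empirical CDF `#{x_l ≤ x_i}/n`, computed by
  sorted-rank lookup.  Both transforms are invariant under strictly
  increasing maps of their input, giving the screen its robustness to heavy
  tails; tests assert bit-identical scores under such maps.

Constant (zero-IQR) gene columns cannot be rank-transformed meaningfully:
the readers drop them with a logged count, and the screen flags any that
survive with a `-inf` sentinel score rather than dropping them silently.

## Tunable parameters

| parameter | default | notes |
| --- | --- | --- |
| characteristic kernel | Gaussian | Laplacian available; both unit-diagonal on the unit interval |
| kernel scale σ_K | median heuristic | median of nonzero pairwise |ΔU_T|; scale-adaptive on (0,1]; override with a fixed value |
| smoothing kernel G | Gaussian | normalization cancels |
| bandwidth h | 1.06·sd(V)·n^(−1/5) | sample sd with denominator n−1, resolved per gene from the transformed column (near-constant across genes after the ECDF transform); fixed override available |
| screening size d | ⌊n/log n⌋ | also 2×, 3× that, or n−1; natural log |
| ties in ranking | ascending column index | determinism |

σ_K is resolved once per dataset from the outcome transform, so the kernel
Gram matrix is shared across genes; per gene only the smoothing weights are
rebuilt, making a p = 1000, n = 200 screen take under a second.

## Synthetic cohorts

`synthetic.generate` emulates the structure of expression–survival cohorts:
`X` has mean-zero, unit-variance Gaussian genes with equicorrelation `rho_x`
(default 0.0; positive values stress marginal screening by correlating noise
genes with active ones), the first `active_size` columns drive the outcome,
and censoring is independent exponential with its rate calibrated by root
finding on a pilot sample so the expected censored fraction hits
`censor_frac` (default 0.4, matching the 40–60% typical of lung-cancer
cohorts).  Hazard models:

* `cox_linear` — hazard `0.05 · exp(β Σ X_j)` per month;
* `cox_nonlinear` — effects cycle through x², sin(x), |x|, each component
  standardized to mean zero/unit variance under N(0,1) so equal `β` means
  equal per-gene signal (otherwise the x² terms, with raw variance 2,
  dominate and the sin/|x| genes become undetectable at realistic n);
* `non_ph` — log-normal accelerated times, monotone in the standardized
  gene score plus noise, violating proportional hazards.

The default effect size is β = 3.0 on the standardized components, a strong
signal typical of sure-screening simulation designs; at n = 200 it yields
roughly 95% coverage of a 4-gene active set within the top ⌊n/log n⌋ of
p = 1000 genes.  One seed drives design, event, censoring and
pilot sub-streams separately, so growing `p` leaves the leading columns
unchanged and results are bit-reproducible.

What the generator does **not** emulate: RNA-seq count marginals (negative
binomial skew), batch effects, missingness, or realistic gene–gene
correlation structure beyond equicorrelation.  Passing tests therefore
demonstrate the statistical mechanics of the screen, not performance on any
particular real cohort.

## Downstream evaluation

The application stage mirrors standard practice: a 4:1 train/test split
stratified by censoring status (per-stratum floor for the test set, so 207
events + 266 censored split to exactly 379/94), a LASSO-penalized
proportional-hazards fit on the screened genes (scikit-survival coordinate
descent; the penalty is chosen glmnet-style by 10-fold cross-validation over
the fitted alpha path, scored by held-out concordance, ties to the heavier
penalty), risk scores from the linear predictor, dichotomization at the
training median (strictly greater → high; ties low), and a two-sample
log-rank test.  The log-rank statistic is implemented natively — summed
observed-minus-expected events with hypergeometric variance
`d_k·(n1_k/n_k)(1−n1_k/n_k)(n_k−d_k)/(n_k−1)` at each distinct event time,
referred to χ²(1) — and is cross-checked against lifelines to 1e−8 and
calibrated to a 3–7% rejection band at the 5% level over 1000 null
replicates.

## Problem sizes used in the statistical tests

Sure-screening coverage: n = 200, p = 1000, 4 active genes, 30% censoring,
50 replicates.  Nonlinear-advantage comparison: p = 500, 30 replicates.
End-to-end stratification: n = 300, p = 500, 25 replicates.  These sizes
reproduce the qualitative regime (n in the hundreds, p ≫ n) while keeping
the whole suite around a minute on one core.

## Numerical choices and degenerate inputs

* Double precision throughout; kernel matrices computed once per dataset.
* Constant `u` gives `H²_K(U|U) = 0`: the unnormalized terms return 0 and
  the correlation raises a degeneracy error rather than dividing by zero.
* Zero-variance smoothing input (constant gene) is rejected by the
  bandwidth rule; the screen converts this to the `-inf` sentinel.
* With a Gaussian `G` and h > 0, smoothing rows cannot all underflow (the
  diagonal is 1/h); a zero row — possible only for a future
  compactly-supported `G` — raises rather than silently substituting
  uniform weights.
* At very small h, off-diagonal weights may underflow to exactly 0; this is
  benign (the limit is the identity smoother).

## Known limitations

* Scalar conditioning only (q = 1): the screen is marginal by design;
  conditional/iterative screening is out of scope.
* No permutation p-values: the index ranks genes, it does not test them.
* The Kaplan–Meier transform treats censored observations as observations
  of `F_T` at their censoring time; heavy censoring concentrated in one
  region of a gene's range dilutes the detectable dependence there.
* The kernel scale for any given real dataset is a genuine tuning choice;
  the median heuristic is a sensible default, not an optimum, and gene
  rankings on real cohorts can shift with it.
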