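# Methods

This note documents the statistical model implemented by `diriclust`, the
algorithms and their numerical realization, the default parameters and why
they are set as they are, the scope of the simulation generators, and known
limitations.

## 1. Compositional data and preprocessing

A compositional observation is a vector of p non-negative parts carrying
only relative information. All model code operates on the open simplex:
every row is strictly positive and sums to one.

**Closure.** `closure` divides each row by its row sum. Rows with a
non-positive sum or negative entries are rejected.

**Zero replacement.** Dirichlet densities are undefined at the boundary, so
zeros must be imputed before fitting. `multiplicative_replacement` uses the
standard multiplicative strategy: each zero cell is set to a small value δ
and the nonzero cells of that row are scaled by (1 − z·δ), where z is the
number of zeros in the row, so the row still sums to one. The default
δ = (1/p)² is deliberately far below the uniform part 1/p; it perturbs the
nonzero parts by at most z/p² in relative terms. The transformation is
idempotent (rows without zeros are untouched) and is cross-checked in the
tests against scikit-bio's implementation when that package is available.

## 2. The Dirichlet distribution

For x on the open (p−1)-simplex and α ∈ (0, ∞)ᵖ,

log f(x; α) = log Γ(Σₘ αₘ) − Σₘ log Γ(αₘ) + Σₘ (αₘ − 1) log xₘ.

`log_density` evaluates this with `scipy.special.gammaln`; boundary points
and non-positive α are rejected. `sample` draws with numpy's Generator and
clips to the smallest positive float before renormalizing, so sampled rows
are always strictly interior.

### 2.1 Maximum-likelihood estimation (`fit_mle`)

The MLE has no closed form. The implemented estimator is the classical
digamma fixed point: given the sufficient statistics
s̄ₘ = (1/n) Σᵢ log xᵢₘ, iterate

ψ(αₘ⁽ᵗ⁺¹⁾) = ψ(Σₖ αₖ⁽ᵗ⁾) + s̄ₘ,

which increases the likelihood at every sweep and converges to the unique
maximizer for interior data.

**Inverse digamma.** Each sweep needs ψ⁻¹. `inverse_digamma` starts from
the two-branch initialization x₀ = exp(y) + 1/2 for y ≥ −2.22 and
x₀ = −1/(y + γ) otherwise (γ the Euler–Mascheroni constant), then runs
Newton steps with the trigamma derivative to a residual of 1e−12. The tests
verify the round trip ψ⁻¹(ψ(x)) over x ∈ [1e−3, 1e3] to rtol 1e−8.

**Aitken acceleration.** The plain fixed point converges linearly, and its
rate degrades badly as the total concentration Σαₘ grows: at Σα ≈ 10³–10⁴
(routine for the benchmark generators, whose parameters reach 500) it can
need thousands of sweeps to reach tol = 1e−7. `fit_mle` therefore applies a
safeguarded Aitken Δ² extrapolation every second sweep: the extrapolated
point is accepted only if it is finite, strictly positive, and does not
decrease the average log likelihood; otherwise the plain sweep result is
kept. This changes nothing about the fixed point being sought — it only
accelerates approach to it — and cuts the sweep count by roughly two orders
of magnitude in the hard cases. Convergence is declared when the maximum
absolute change in α across a sweep falls below `tol` (default 1e−7);
`DirichletParams.converged` records whether that happened within
`max_iter`.

Initialization defaults to the column means scaled to a total concentration
matching a method-of-moments estimate; an explicit `init` overrides it.
A single observation is rejected (the MLE is degenerate there).

### 2.2 Bayesian estimation (`fit_bayes`)

With independent Gamma(a, b) priors on each αₘ and an approximation that
treats the coordinates through their Beta marginals, the posterior mean has
the closed form

α̂ₘ = (a + n) / (b − Σᵢ log xᵢₘ),

implemented exactly as written (defaults a = b = 1). Two properties are
worth recording:

- It is well defined for any n ≥ 1, including a single observation, which
  is precisely why the mixture's small-cluster variant uses it.
- It is an approximation with visible bias at moderate concentrations: its
  large-n limit is 1/(ψ(Σα) − ψ(αₘ)) + o(1), which for Dirichlet(5, 5) data
  equals 1/(ψ(10) − ψ(5)) ≈ 1.37, not 5. The tests assert the closed form
  and this limit rather than recovery of the generating value. For small
  concentrations (αₘ ≪ 1, where ψ(Σα) − ψ(αₘ) ≈ 1/αₘ) the estimator is
  close to consistent, which matches its intended use on small, possibly
  diffuse clusters.

## 3. The hard-EM Dirichlet mixture (`mixture.fit`)

The model is a k-component mixture of Dirichlets with weights π and
parameter vectors α₁..α_k. Fitting is by hard (classification) EM:

1. **Initialization.** k-means (scikit-learn, `n_init=10`,
   `random_state=seed`) on the compositions; the initial αⱼ⁰ is c times the
   j-th centroid (default c = 60, centroid entries floored at 1e−6), and π⁰
   is the empirical cluster proportions. The centroid is a mean on the
   simplex, so c plays the role of an assumed total concentration.
2. **E-step.** Responsibilities γᵢⱼ ∝ πⱼ f(xᵢ; αⱼ), computed with
   log-sum-exp.
3. **Hard assignment.** Each row goes to argmaxⱼ γᵢⱼ (ties to the lowest
   index).
4. **M-step.** Per cluster, refit αⱼ on its assigned rows, warm-started
   from the previous αⱼ. πⱼ is updated from the soft counts Σᵢ γᵢⱼ / N.
   A cluster that is empty or has fewer than two rows is reset to its
   initial αⱼ⁰ (counted in `FitResult.empty_cluster_events`); an M-step
   whose inner MLE fails to converge keeps the previous αⱼ (counted in
   `mle_failures`).
5. **Stopping.** Iterate until the absolute change in the observed-data log
   likelihood falls below ε (default 1e−4) or `max_iter` (default 500) is
   reached. The likelihood trace is returned in `FitResult.loglik_trace`.

**Variants.** `variant="hard_dmm_1"` always uses the MLE in the M-step.
`variant="hard_dmm_2"` uses the Bayesian closed form for clusters with
fewer than `small_cluster_threshold` = 30 members (the MLE is unreliable or
undefined there) and the MLE otherwise. The published algorithm listing
prints the condition with the opposite orientation (≥ 30 → Bayes); since
that contradicts the stated motivation, the default follows the motivation
(`threshold_direction="small_gets_bayes"`), and
`threshold_direction="as_printed"` reproduces the literal listing. On data
where no small clusters arise the two variants coincide exactly, which the
tests assert.

**Defaults and rationale.**

| parameter | default | rationale |
|---|---|---|
| `epsilon` | 1e−4 | published stopping tolerance on the log-likelihood change |
| `init_scale_c` | 60.0 | published initialization scale; see limitations below |
| `small_cluster_threshold` | 30 | published cutoff for the Bayesian branch |
| `prior` | Gamma(1, 1) | published diffuse prior |
| `mle_tol` | 1e−7 | inner fixed-point tolerance |
| `mle_max_iter` | 50 000 | sweep budget; with Aitken acceleration this is never near-binding, but a large cap prevents silent parameter freezing at high concentrations |

## 4. Simulation generators (`simulate`)

The generators exist to reproduce the published benchmark comparisons; they
are not general-purpose simulators.

- **`scheme1`** (k = 3, p = 3, n = 900): 500 rows from Dirichlet(30, 20, 10),
  100 from (10, 20, 30), 300 from (15, 15, 15).
- **`scheme2`** (k = 4, p = 3, n = 1300): 500 from (10, 10, 3), 100 from
  (10, 20, 50), 300 from (15, 15, 15), 400 from (0.2, 0.5, 3) — the last
  component concentrates near the simplex boundary.
- **`performance_scheme(k, p, seed)`** for k = 2..6 at arbitrary p, with the
  published cluster sizes (e.g. k = 3: 500/400/300). Component parameter
  vectors are drawn per replicate: sorted Uniform(1, 110) ascending and
  Uniform(110, 500) descending for the first two components; Uniform(1, 100)
  for the fourth (k ≥ 4); constant 50 for the fifth (k ≥ 5); and for k = 6 a
  "spike" component whose top l coordinates equal 110 (l from a published
  lookup by p, e.g. l = 5 at p = 20) over an ascending Uniform(1, 5) base.
- **`replicate_grid(k, p, n_reps, seed)`** yields independent replicates
  with per-replicate seeds `seed + r`, so any replicate can be regenerated
  in isolation.

All generators return the data, the true labels, and the drawn parameter
vectors, and are deterministic given the seed.

## 5. Evaluation (`evaluate`)

Cluster labels are arbitrary, so predicted clusters are first matched to
true classes by maximizing the total diagonal of the confusion matrix via
the Hungarian algorithm (`scipy.optimize.linear_sum_assignment` on a padded
square matrix; surplus clusters remain unmatched and all their rows count
as errors). After matching: accuracy is the fraction of rows in matched
diagonal cells; precision and recall are macro-averaged one-vs-rest over
true classes (`average="micro"` reduces both to accuracy). The matching is
cross-checked in the tests against brute-force permutation enumeration.

## 6. Known limitations and discrepancies

- **The k = 6, p = 20 benchmark cell is not reproduced.** The published
  comparison reports ≈ 0.70 mean accuracy there; this implementation
  measures ≈ 0.98. Under the documented generator the six components are
  separable at p = 20 — classification under the *true* parameters achieves
  accuracy 1.0 — so the published degradation cannot be a property of the
  data-generating process as stated. The degradation mechanism the original
  work describes does reproduce here, but at higher dimension: at p = 100
  the initial concentration c = 60 spread over 100 coordinates (~0.6 each)
  is so diffuse that the first hard assignments destroy an initially
  perfect k-means partition, clusters empty out, and their diffuse resets
  never recover; measured accuracy there is ≈ 0.69, matching the published
  p = 100 value (≈ 0.68). The onset dimension of the collapse evidently
  depends on implementation details that the publication does not specify.
- **c = 60 is a p ≈ 3–20 heuristic.** As above, a fixed total concentration
  becomes a poor (over-diffuse) initialization as p grows. For
  high-dimensional data consider scaling c with p or passing explicit
  initial parameters.
- **Hard EM is not full EM.** Classification EM maximizes a classification
  likelihood; its parameter estimates are inconsistent in the overlap
  regions and the log-likelihood trace need not be monotone (the stopping
  rule uses the absolute change). This is by design — it is the published
  algorithm — not a defect of the implementation.
- **The Bayesian closed form is an approximation** (Section 2.2): accurate
  for small concentrations, visibly biased for moderate ones. It is used
  only where the MLE is unreliable.
- **Zeros are imputed, not modeled.** Multiplicative replacement with a
  fixed δ is simple and order-preserving but ignores the count mechanism
  that produced the zeros; results for very sparse tables will be sensitive
  to δ.
- **Model selection is out of scope.** k must be supplied; the package does
  not implement information-criterion or stability-based selection of the
  number of components.
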