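# diriclust

Hard-EM Dirichlet mixture model clustering for compositional data.

Compositional data are vectors of non-negative parts carrying only relative
information — each row lives on the probability simplex (parts sum to one).
Microbiome relative abundances, chemical compositions, and budget shares are
typical examples. Distance-based clustering treats such rows as points in
unconstrained Euclidean space and ignores the simplex geometry; `diriclust`
instead clusters rows with a finite mixture of Dirichlet distributions, the
natural parametric family on the simplex, fitted by a hard (classification)
EM algorithm.

The package provides:

- **`diriclust.compdata`** — closure (normalization to the simplex) and
  multiplicative zero replacement, plus CSV/TSV reading and writing.
- **`diriclust.dirichlet`** — Dirichlet log density, sampling, a fixed-point
  maximum-likelihood estimator built on an inverse-digamma Newton solver, and
  a closed-form Bayesian estimator under independent Gamma priors.
- **`diriclust.mixture`** — the hard-EM mixture fitter, with two variants:
  the base algorithm (every cluster refit by maximum likelihood each
  iteration) and a small-cluster variant that switches to the Bayesian
  estimator when a cluster has fewer than 30 members.
- **`diriclust.simulate`** — the benchmark simulation schemes used for the
  published comparisons (two fixed three/four-component schemes and a family
  of performance schemes for k = 2..6 clusters at arbitrary dimension).
- **`diriclust.evaluate`** — optimal cluster-to-class matching (Hungarian
  assignment) and matched accuracy / macro precision / macro recall.
- **`diriclust.cli`** — a `diriclust` command with `simulate`, `fit`, and
  `evaluate` subcommands.

## Quick start (Python API)

```python
import numpy as np
from diriclust import FitConfig, fit, scheme1, score

data = scheme1(seed=0)                 # 900 rows: 500/100/300 from 3 Dirichlets
result = fit(data.data, 3, FitConfig(seed=0))
report = score(data.labels, result.labels)

print(result.n_iter, result.converged)      # 12 True
print(result.params.pi.round(3))            # [0.349 0.111 0.54 ]
for a in result.params.alphas:
    print(np.round(a, 2))
# [16.97 17.22 16.85]   <- recovers (15, 15, 15)
# [ 9.82 20.64 31.45]   <- recovers (10, 20, 30)
# [34.76 23.28 11.08]   <- recovers (30, 20, 10)
print(round(report.accuracy, 4))            # 0.92
```

Fitting your own table:

```python
from diriclust import closure, fit, multiplicative_replacement, read_table

table, _ = read_table("counts.csv")          # rows = samples, columns = parts
comp = multiplicative_replacement(closure(table))   # simplex + zero handling
result = fit(comp, k=4)
labels = result.labels
```

## Quick start (command line)

```sh
diriclust simulate --scheme scheme1 --seed 7 --out sim/
diriclust fit --input sim/data.csv --k 3 --seed 7 --out fit/
diriclust evaluate --truth sim/labels.csv --pred fit/labels.csv --out eval/
cat eval/metrics.json
```

Every subcommand writes a `config.json` echo sufficient to re-run it.
Defaults can also be supplied through `--config file.yaml`; explicit flags
take precedence over the YAML file, which takes precedence over built-in
defaults. Exit codes: 0 success, 1 user error, 2 internal error.

## Testing

```sh
python -m pytest -q tests/
```

The suite covers worked-by-hand examples, cross-checks against independent
oracles (direct numerical likelihood maximization, brute-force permutation
matching, scikit-bio's zero replacement when available), statistical
recovery checks, and `tests/test_acceptance.py`, which re-derives the
published comparison numbers. One acceptance assertion (the `t7` cell
above) fails by design and is documented rather than weakened.

## Documentation

- `docs/methods.md` — the statistical model, algorithms, parameter defaults
  and their rationale, numerical choices, and known limitations.
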