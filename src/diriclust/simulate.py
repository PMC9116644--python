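"""Seeded generators for the benchmark simulation schemes.

Two fixed three-part schemes exercise the comparison study:

* scheme 1 — three components on the 2-simplex: 500 draws from
  Dirichlet(30, 20, 10), 100 from Dirichlet(10, 20, 30), 300 from
  Dirichlet(15, 15, 15).
* scheme 2 — four components, adding the boundary-hugging
  Dirichlet(0.2, 0.5, 3): sizes 500 / 100 / 300 / 400.

The performance schemes sweep cluster count k = 2..6 at dimension p,
drawing fresh concentration vectors per dataset from stated uniform ranges
with stated sorting; the k = 4 and k = 6 schemes include a "spike"
component with l coordinates fixed at 110 and the rest drawn from
Uniform(1, 5), which creates overlap that grows with p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compdata import Composition

__all__ = [
    "LabeledSample",
    "scheme1",
    "scheme2",
    "performance_scheme",
    "replicate_grid",
    "SPIKE_L_BY_P",
]

# number of spiked coordinates l per dimension p for the overlap components
SPIKE_L_BY_P = {5: 2, 10: 3, 20: 5, 35: 8, 50: 12, 70: 15, 100: 18}

_PERF_SIZES = {
    2: (800, 500),
    3: (500, 400, 300),
    4: (400, 300, 800, 500),
    5: (500, 100, 300, 400, 300),
    6: (500, 100, 300, 400, 300, 500),
}


@dataclass
class LabeledSample:
    """Simulated compositional data with its ground-truth component labels."""

    data: Composition
    labels: np.ndarray
    alphas: list  # generating concentration vectors, one per component

    def __post_init__(self) -> None:
        if self.data.values.shape[0] != self.labels.size:
            raise ValueError("label count must match row count")


def _draw(rng: np.random.Generator, alphas, sizes, shuffle: bool) -> LabeledSample:
    blocks, labels = [], []
    for j, (a, n) in enumerate(zip(alphas, sizes)):
        x = rng.dirichlet(np.asarray(a, dtype=float), size=n)
        tiny = np.finfo(float).tiny
        np.clip(x, tiny, None, out=x)
        x /= x.sum(axis=1, keepdims=True)
        blocks.append(x)
        labels.append(np.full(n, j, dtype=int))
    data = np.vstack(blocks)
    labels = np.concatenate(labels)
    if shuffle:
        order = rng.permutation(data.shape[0])
        data, labels = data[order], labels[order]
    return LabeledSample(Composition(data), labels, [np.asarray(a, float) for a in alphas])


def scheme1(seed, shuffle: bool = False) -> LabeledSample:
    """900 x 3 mixture: 500 Dir(30,20,10) + 100 Dir(10,20,30) + 300 Dir(15,15,15)."""
    rng = np.random.default_rng(seed)
    return _draw(
        rng,
        [(30, 20, 10), (10, 20, 30), (15, 15, 15)],
        (500, 100, 300),
        shuffle,
    )


def scheme2(seed, shuffle: bool = False) -> LabeledSample:
    """1300 x 3 mixture with a boundary-hugging fourth component."""
    rng = np.random.default_rng(seed)
    return _draw(
        rng,
        [(10, 10, 3), (10, 20, 50), (15, 15, 15), (0.2, 0.5, 3)],
        (500, 100, 300, 400),
        shuffle,
    )


def _spike_alpha(rng: np.random.Generator, p: int, integer: bool) -> np.ndarray:
    """l coordinates at 110, the remaining p - l from Uniform(1, 5), ascending."""
    if p in SPIKE_L_BY_P:
        l = SPIKE_L_BY_P[p]
    else:
        ps = np.array(sorted(SPIKE_L_BY_P))
        l = int(round(np.interp(p, ps, [SPIKE_L_BY_P[q] for q in ps])))
    low = rng.uniform(1, 5, size=p - l)
    if integer:
        low = np.floor(low)
        low = np.maximum(low, 1.0)
    return np.concatenate([np.sort(low), np.full(l, 110.0)])


def _range_alpha(
    rng: np.random.Generator, p: int, lo: float, hi: float,
    order: str, integer: bool,
) -> np.ndarray:
    a = rng.uniform(lo, hi, size=p)
    if integer:
        a = np.rint(a)
        a = np.clip(a, max(lo, 1.0), hi)
    a = np.sort(a)
    return a if order == "asc" else a[::-1].copy()


def performance_scheme(
    k: int, p: int, seed, shuffle: bool = False, integer_params: bool = False
) -> LabeledSample:
    """One dataset of the k-cluster benchmark at dimension p.

    Concentration vectors are drawn fresh on every call:

    * k=2 — Uniform(1, 110) ascending (n=800); same range descending (n=500).
    * k=3 — Uniform(110, 500) asc (500); Uniform(1, 110) desc (400);
      constant 50 (300).
    * k=4 — Uniform(1, 100) asc (400) and desc (300); constant 50 (800);
      spike component (500).
    * k=5 — Uniform(110, 500) asc (500) / desc (100); Uniform(1, 110)
      asc (300) / desc (400); constant 50 (300).
    * k=6 — the k=5 components plus the spike component (500).
    """
    if k not in _PERF_SIZES:
        raise ValueError(f"unknown performance scheme k={k}")
    rng = np.random.default_rng(seed)
    const50 = np.full(p, 50.0)
    if k == 2:
        alphas = [
            _range_alpha(rng, p, 1, 110, "asc", integer_params),
            _range_alpha(rng, p, 1, 110, "desc", integer_params),
        ]
    elif k == 3:
        alphas = [
            _range_alpha(rng, p, 110, 500, "asc", integer_params),
            _range_alpha(rng, p, 1, 110, "desc", integer_params),
            const50,
        ]
    elif k == 4:
        alphas = [
            _range_alpha(rng, p, 1, 100, "asc", integer_params),
            _range_alpha(rng, p, 1, 100, "desc", integer_params),
            const50,
            _spike_alpha(rng, p, integer_params),
        ]
    else:  # k in (5, 6)
        alphas = [
            _range_alpha(rng, p, 110, 500, "asc", integer_params),
            _range_alpha(rng, p, 110, 500, "desc", integer_params),
            _range_alpha(rng, p, 1, 110, "asc", integer_params),
            _range_alpha(rng, p, 1, 110, "desc", integer_params),
            const50,
        ]
        if k == 6:
            alphas.append(_spike_alpha(rng, p, integer_params))
    return _draw(rng, alphas, _PERF_SIZES[k], shuffle)


def replicate_grid(
    k: int, p: int, n_reps: int, seed: int, **kwargs
) -> list[LabeledSample]:
    """n_reps independent datasets with per-replicate seeds seed + index.

    Concentration vectors are redrawn for every replicate, so replicate
    means reflect both sampling and parameter-draw variability.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    return [performance_scheme(k, p, seed + r, **kwargs) for r in range(n_reps)]
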