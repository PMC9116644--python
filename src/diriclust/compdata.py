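"""Compositional data handling: closure onto the simplex and zero replacement.

Compositional data carry relative information only: a row of non-negative
parts is meaningful up to its total, so each row is divided by its sum
(closure, or L1 normalization) to live on the unit simplex.  Rounded zeros —
values below a detection threshold — must be replaced before any
Dirichlet-likelihood work, because the density involves log x.  The
multiplicative replacement rule substitutes each zero cell by a small delta
and shrinks the non-zero cells of the same row multiplicatively so the row
sum is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RawTable",
    "Composition",
    "closure",
    "multiplicative_replacement",
    "read_table",
    "write_composition",
]


@dataclass
class RawTable:
    """A table of finite non-negative values prior to closure.

    Rows that sum to zero cannot be closed and are rejected at validation.
    """

    values: np.ndarray
    row_ids: list | None = None
    col_ids: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("RawTable values must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("RawTable contains non-finite entries")
        neg = np.argwhere(self.values < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(f"negative entry at row {i}, column {j}")
        zero_rows = np.flatnonzero(self.values.sum(axis=1) == 0)
        if zero_rows.size:
            raise ValueError(
                f"row(s) {zero_rows.tolist()} sum to 0 and cannot be closed"
            )


@dataclass
class Composition:
    """An N x p matrix whose rows sum to a constant (default 1).

    After zero replacement every entry is strictly positive; immediately
    after closure zeros may still be present (``allow_zeros=True``).
    """

    values: np.ndarray
    sum_constraint: float | np.ndarray = 1.0
    allow_zeros: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Composition values must be a 2-D matrix")
        c = np.broadcast_to(
            np.asarray(self.sum_constraint, dtype=float), (self.values.shape[0],)
        )
        if np.any(c <= 0):
            raise ValueError("sum constraints must be positive")
        if np.max(np.abs(self.values.sum(axis=1) - c)) > 1e-9:
            raise ValueError("rows do not sum to their sum constraint")
        if self.allow_zeros:
            if np.any(self.values < 0):
                raise ValueError("negative entries are not allowed")
        elif np.any(self.values <= 0):
            raise ValueError(
                "Composition requires strictly positive entries; "
                "apply multiplicative_replacement first"
            )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_parts(self) -> int:
        return self.values.shape[1]


def closure(raw: RawTable | np.ndarray) -> Composition:
    """Divide each row by its sum so rows sum to 1.

    Zeros are preserved as zeros: replacement is a separate, explicit step.
    """
    if not isinstance(raw, RawTable):
        raw = RawTable(np.asarray(raw, dtype=float))
    sums = raw.values.sum(axis=1, keepdims=True)
    return Composition(raw.values / sums, 1.0, allow_zeros=True)


def multiplicative_replacement(
    x: Composition | np.ndarray, delta: float | np.ndarray | None = None
) -> Composition:
    """Replace zero cells by ``delta`` and rescale non-zero cells per row.

    For row i with sum constraint c_i, each zero cell becomes delta and each
    non-zero cell x_ij is multiplied by ``1 - sum(deltas over zero cells)/c_i``
    so the row still sums to c_i.  Rows without zeros are returned unchanged.

    Parameters
    ----------
    x : Composition or array
        Closed data, possibly containing zeros.
    delta : float or length-p vector, optional
        Replacement value per cell.  Default ``(1/p)**2`` times the row's sum
        constraint — the conventional squared-inverse-dimension choice.
    """
    if not isinstance(x, Composition):
        x = Composition(np.asarray(x, dtype=float), allow_zeros=True)
    vals = x.values
    n, p = vals.shape
    c = np.broadcast_to(np.asarray(x.sum_constraint, dtype=float), (n,))

    if delta is None:
        delta_row = np.tile(c[:, None] * (1.0 / p) ** 2, (1, p))
    else:
        d = np.asarray(delta, dtype=float)
        if np.any(d <= 0):
            raise ValueError("delta must be strictly positive")
        delta_row = np.broadcast_to(d, (n, p)).copy()

    zero_mask = vals == 0
    if not zero_mask.any():
        return Composition(vals.copy(), x.sum_constraint)

    delta_sum = np.where(zero_mask, delta_row, 0.0).sum(axis=1)
    multiplier = 1.0 - delta_sum / c
    bad = np.flatnonzero(multiplier <= 0)
    if bad.size:
        raise ValueError(
            f"delta too large: adjusted non-zero entries would be <= 0 "
            f"in row(s) {bad.tolist()}"
        )
    out = np.where(zero_mask, delta_row, vals * multiplier[:, None])
    return Composition(out, x.sum_constraint)


def read_table(
    path,
    sep: str | None = None,
    id_column: str | None = None,
    label_column: str | None = None,
):
    """Read a CSV/TSV with a header row into a :class:`RawTable`.

    Non-numeric columns must be named explicitly as ``id_column`` or
    ``label_column``; an unexpected non-numeric column raises instead of
    being silently dropped.

    Returns
    -------
    (RawTable, labels) : labels is a pandas Series or None.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    labels = None
    if label_column is not None:
        labels = df.pop(label_column)
    row_ids = None
    if id_column is not None:
        row_ids = df.pop(id_column).tolist()
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValueError(
            f"non-numeric column(s) {non_numeric}; declare them via "
            "id_column/label_column"
        )
    table = RawTable(df.to_numpy(dtype=float), row_ids=row_ids, col_ids=list(df.columns))
    return table, labels


def write_composition(x: Composition, path, col_ids: list | None = None) -> None:
    """Write a composition as CSV with repr-round-trip-safe float precision."""
    p = x.values.shape[1]
    cols = col_ids if col_ids is not None else [f"part_{m}" for m in range(p)]
    pd.DataFrame(x.values, columns=cols).to_csv(path, index=False, float_format="%.17g")
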