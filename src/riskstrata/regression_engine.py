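"""Design matrices and least-squares calibration of expected utilization.

The model is the standard actuarial one: a binary design matrix X with one
row per beneficiary -- mutually exclusive demographic-cell columns followed
by condition-category columns -- and performance-year admission counts y.
Training solves the heavily overdetermined system X_t b ~= y_t by least
squares (normal equations X_t'X_t b = X_t'y_t, with minimum-norm
pseudoinverse semantics when the Gram matrix is singular); prediction on the
held-out study arm is the plain matrix-vector product X_s b_t.  Because the
demographic cells partition every row, they act as a composite intercept:
training-arm fitted values preserve the observed mean exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse

from .hcc_mapper import demographic_cell_ids

logger = logging.getLogger(__name__)

#: max allowed ||X'(y - Xb)||_inf relative to ||X'y||_inf
RESIDUAL_ORTHOGONALITY_RTOL = 1e-6


@dataclass(frozen=True)
class DesignMatrix:
    """Sparse 0/1 design matrix with aligned row and column identifiers.

    Columns are the lexicographically sorted demographic cells followed by
    the lexicographically sorted category ids; rows are sorted by
    beneficiary id.  Every row has exactly one 1 in the demographic block.
    """

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    values: scipy.sparse.csr_matrix

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def toarray(self) -> np.ndarray:
        return self.values.toarray()


def design_columns(category_ids) -> list[str]:
    """Fixed column order shared by training and study arms."""
    return demographic_cell_ids() + sorted(category_ids)


def build_design_matrix(profiles: pd.DataFrame, category_ids) -> DesignMatrix:
    """Binary design matrix from condition profiles.

    ``profiles`` needs columns ``beneficiary_id``, ``demographic_cell`` and
    ``hcc_flags`` (semicolon-joined).  Profiles carrying a category absent
    from ``category_ids`` are an error.
    """
    cols = design_columns(category_ids)
    col_pos = {c: j for j, c in enumerate(cols)}
    prof = profiles.sort_values("beneficiary_id", kind="stable")
    row_ids = tuple(prof["beneficiary_id"])
    n = len(row_ids)

    rows: list[int] = []
    col_ix: list[int] = []
    cells = prof["demographic_cell"].to_numpy()
    for i, cell in enumerate(cells):
        if cell not in col_pos:
            raise ValueError(f"unknown demographic cell {cell!r}")
        rows.append(i)
        col_ix.append(col_pos[cell])
    for i, flags in enumerate(prof["hcc_flags"].fillna("")):
        if not flags:
            continue
        for cat in flags.split(";"):
            j = col_pos.get(cat)
            if j is None:
                raise ValueError(f"profile references unknown category id {cat!r}")
            rows.append(i)
            col_ix.append(j)
    values = scipy.sparse.csr_matrix(
        (np.ones(len(rows)), (rows, col_ix)), shape=(n, len(cols))
    )
    return DesignMatrix(row_ids=row_ids, col_ids=tuple(cols), values=values)


def fit_least_squares(X, y) -> np.ndarray:
    """Minimum-norm least-squares coefficients for X b ~= y.

    Accepts a :class:`DesignMatrix`, a sparse matrix or a dense array.
    Solves via the (small) Gram system with a symmetric-eigenvalue
    pseudoinverse fallback when X'X is numerically singular, and verifies
    the normal-equation residual orthogonality contract
    ``||X'(y - Xb)||_inf <= 1e-6 ||X'y||_inf``.
    """
    A = X.values if isinstance(X, DesignMatrix) else X
    y = np.asarray(y, dtype=float).ravel()
    if A.shape[0] != y.size:
        raise ValueError(f"X has {A.shape[0]} rows but y has {y.size} entries")

    if scipy.sparse.issparse(A):
        gram = np.asarray((A.T @ A).todense())
        xty = np.asarray(A.T @ y).ravel()
    else:
        A = np.asarray(A, dtype=float)
        gram = A.T @ A
        xty = A.T @ y

    zero_cols = np.flatnonzero(np.diag(gram) == 0)
    if zero_cols.size:
        logger.warning(
            "%d all-zero design column(s) at indices %s: coefficient 0 under "
            "the minimum-norm convention",
            zero_cols.size,
            zero_cols.tolist(),
        )

    try:
        c, low = scipy.linalg.cho_factor(gram)
        b = scipy.linalg.cho_solve((c, low), xty)
    except scipy.linalg.LinAlgError:
        b = None
    if b is None or not _orthogonal(A, y, b, xty):
        # (X'X)^+ X'y equals the minimum-norm pseudoinverse solution X^+ y
        b = scipy.linalg.pinvh(gram) @ xty
    if not _orthogonal(A, y, b, xty):
        raise RuntimeError("least-squares solve failed the orthogonality contract")
    return b


def _orthogonal(A, y, b, xty) -> bool:
    resid_grad = np.asarray(A.T @ (y - A @ b)).ravel()
    scale = np.max(np.abs(xty))
    if scale == 0:
        return bool(np.max(np.abs(resid_grad)) <= RESIDUAL_ORTHOGONALITY_RTOL)
    return bool(np.max(np.abs(resid_grad)) <= RESIDUAL_ORTHOGONALITY_RTOL * scale)


def predict(X: DesignMatrix, coefficients: np.ndarray, col_ids=None) -> np.ndarray:
    """Expected performance-year counts X_s b_t; no clipping.

    Negative expectations are retained -- only the ranking matters
    downstream.  When ``col_ids`` is given (the training column order) it is
    compared against the study matrix's columns rather than assumed equal.
    """
    coefficients = np.asarray(coefficients, dtype=float).ravel()
    if isinstance(X, DesignMatrix):
        if col_ids is not None and tuple(col_ids) != X.col_ids:
            raise ValueError("design-matrix column order differs from training order")
        A = X.values
    else:
        A = X
    if A.shape[1] != coefficients.size:
        raise ValueError(
            f"X has {A.shape[1]} columns but coefficient vector has "
            f"{coefficients.size} entries"
        )
    return np.asarray(A @ coefficients).ravel()
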