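"""Sequential (fit-in-order) sums of squares and expected-mean-square
coefficients via orthonormal column bases.

Shared by the ANOVA engines. Terms are added to the model one at a time;
the reduction in residual SS attributable to a term is computed from the
orthonormal basis of the growing design matrix, which is exact for
arbitrarily unbalanced layouts (cells may be missing entirely). Expected
values of the same quadratic forms give design-derived coefficients for
method-of-moments variance-component estimation (generalised Henderson
Method III).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg


def dummies(labels: pd.Series | np.ndarray) -> np.ndarray:
    """Full indicator matrix (one column per level, no reference level)."""
    return pd.get_dummies(pd.Series(np.asarray(labels, dtype=object)), dtype=float).to_numpy()


def orth_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing)."""
    return linalg.orth(X)


def sequential_ss(
    y: np.ndarray, term_blocks: list[tuple[str, np.ndarray]]
) -> tuple[pd.DataFrame, list[np.ndarray]]:
    """Sequential SS for terms fitted in the given order.

    ``term_blocks`` is a list of (name, columns) starting with the intercept.
    Returns a table of (source, df, ss) including a final ``Error`` row, and
    the list of cumulative orthonormal bases (one per term) for EMS use.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    bases: list[np.ndarray] = []
    rows = []
    X = np.empty((n, 0))
    prev_fit = 0.0
    prev_rank = 0
    for name, cols in term_blocks:
        X = np.hstack([X, cols])
        Q = orth_basis(X)
        bases.append(Q)
        fit = float(np.sum((Q.T @ y) ** 2))
        rank = Q.shape[1]
        rows.append({"source": name, "df": rank - prev_rank, "ss": fit - prev_fit})
        prev_fit, prev_rank = fit, rank
    rows.append({"source": "Error", "df": n - prev_rank, "ss": float(y @ y) - prev_fit})
    return pd.DataFrame(rows), bases


def trace_coefficient(Q_prev: np.ndarray | None, Q_curr: np.ndarray, Z: np.ndarray) -> float:
    """tr((P_curr - P_prev) Z Z') where P = Q Q'.

    This is the coefficient of a random term with incidence matrix ``Z`` in
    the expectation of the sequential SS captured between the two bases.
    """
    val = float(np.sum((Z.T @ Q_curr) ** 2))
    if Q_prev is not None:
        val -= float(np.sum((Z.T @ Q_prev) ** 2))
    return val
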