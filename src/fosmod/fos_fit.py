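"""Pointwise ordinary least squares for function-on-scalar regression.

At every grid time t_k the model  Y_i(t_k) = x_i' beta(t_k) + eps_i(t_k),
eps_i(t_k) ~ N(0, sigma^2(t_k)) iid across observations, is fitted by OLS.
Because the design is shared across times, a single QR factorization serves
all K fits; the per-time residual variance uses the unbiased divisor n - p.
Ordinary t-statistics are beta_hat / (s * sqrt(v_jj)) with d = n - p
residual degrees of freedom, v_jj the j-th diagonal of (X'X)^{-1}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.linalg import solve_triangular

from .curves_io import CovariateTable, CurveSet, TimeGrid

DEFAULT_PREDICTORS = ("ndi", "age", "neck_length", "sex")
INTERCEPT = "intercept"


@dataclass
class DesignMatrix:
    """Shared n x p design with intercept, plus derived fit constants.

    ``v_diag`` is the diagonal of (X'X)^{-1} (identical at every time
    because the design is common to all fits) and ``residual_df`` is
    d = n - p.
    """

    X: np.ndarray
    coefficient_names: Sequence[str]
    v_diag: np.ndarray
    residual_df: int

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class PointwiseFitSet:
    """Per-time OLS results: beta_hat (p x K), s2 (K,), ordinary se/t/p."""

    design: DesignMatrix
    grid: TimeGrid
    beta_hat: np.ndarray
    s2: np.ndarray
    se_ordinary: np.ndarray
    t_ordinary: np.ndarray
    p_ordinary: np.ndarray
    response_label: str = "angle"

    def coefficient_index(self, name: str) -> int:
        names = list(self.design.coefficient_names)
        if name not in names:
            raise KeyError(f"unknown coefficient {name!r}; design has {names}")
        return names.index(name)


def build_design(
    cov: CovariateTable,
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    center: bool = False,
) -> DesignMatrix:
    """Assemble X = [1 | predictors in order] and its fit constants.

    ``center=True`` subtracts each covariate's sample mean (numerical
    hygiene only; it provably changes neither t nor p of the predictors).
    Rank deficiency is a hard error naming the offending column.
    """
    cols = [np.ones(cov.n)]
    names = [INTERCEPT]
    for name in predictors:
        col = cov.column(name).astype(float)
        if center:
            col = col - col.mean()
        cols.append(col)
        names.append(name)
    X = np.column_stack(cols)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations than coefficients (n={n}, p={p})")
    r = np.linalg.qr(X, mode="r")
    rdiag = np.abs(np.diag(r))
    tol = max(n, p) * np.finfo(float).eps * rdiag.max()
    deficient = np.nonzero(rdiag <= tol)[0]
    if deficient.size:
        raise ValueError(
            f"design matrix is rank deficient at column {names[deficient[0]]!r} "
            "(constant or collinear with earlier columns)"
        )
    rinv = solve_triangular(r, np.eye(p))
    v_diag = np.sum(rinv**2, axis=1)
    return DesignMatrix(X=X, coefficient_names=names, v_diag=v_diag, residual_df=n - p)


def fit_pointwise(cs: CurveSet, design: DesignMatrix) -> PointwiseFitSet:
    """OLS at every grid time via one QR factorization of the shared design."""
    if cs.n != design.n:
        raise ValueError(f"curve set has n={cs.n} but design has n={design.n}")
    d = design.residual_df
    if d < 1:
        raise ValueError("residual degrees of freedom must be at least 1")
    Y = cs.values  # (n, K): one column of responses per time
    q, r = np.linalg.qr(design.X)
    beta = solve_triangular(r, q.T @ Y)
    resid = Y - design.X @ beta
    s2 = np.sum(resid**2, axis=0) / d
    se = np.sqrt(np.outer(design.v_diag, s2))
    t, p = _t_and_p(beta, se, d)
    return PointwiseFitSet(
        design=design,
        grid=cs.grid,
        beta_hat=beta,
        s2=s2,
        se_ordinary=se,
        t_ordinary=t,
        p_ordinary=p,
        response_label=cs.response_label,
    )


def _t_and_p(beta: np.ndarray, se: np.ndarray, df: float) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided t inference, handling the degenerate se = 0 cases.

    se = 0 with beta = 0 gives t = 0, p = 1; se = 0 with beta != 0 gives
    p = 0 (a perfect fit contradicting the null) with a warning.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.where(beta == 0, 0.0, np.inf * np.sign(beta)))
    if np.any(np.isinf(t)):
        warnings.warn("zero residual variance with nonzero coefficient: p set to 0", stacklevel=3)
    if np.isinf(df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    return t, p


def ordinary_inference(
    fit: PointwiseFitSet, coefficient: str, allow_intercept: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-time (t, p) sequences of the ordinary t-test for one coefficient.

    The intercept is excluded by default (only the scalar predictors carry
    p-value functions); pass ``allow_intercept=True`` to override.
    """
    if coefficient == INTERCEPT and not allow_intercept:
        raise ValueError("intercept inference requires allow_intercept=True")
    j = fit.coefficient_index(coefficient)
    return fit.t_ordinary[j].copy(), fit.p_ordinary[j].copy()
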