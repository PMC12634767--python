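"""FDR adjustment of p-value functions and significance-region extraction.

Each coefficient's raw p-value function over the K grid times is adjusted
with the Benjamini-Hochberg step-up procedure (valid under independence /
positive regression dependence) and the more conservative
Benjamini-Yekutieli variant (valid under arbitrary dependence, relevant
because p-values at nearby times are strongly positively correlated).
Adjustment is always per coefficient, per method, per response - the K
times of one p-value function only, never pooled across coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .curves_io import ResultTable, TimeGrid
from .eb_moderation import ModeratedStats
from .fos_fit import INTERCEPT, PointwiseFitSet


@dataclass
class PValueFunction:
    """Raw and FDR-adjusted p-values over the grid for one coefficient/method."""

    grid: TimeGrid
    coefficient_name: str
    method: str  # "ols" | "moderated"
    p_raw: np.ndarray
    p_bh: np.ndarray
    p_by: np.ndarray

    def __post_init__(self) -> None:
        for name in ("p_raw", "p_bh", "p_by"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (self.grid.k,):
                raise ValueError(f"{name} must have one value per grid point")
            setattr(self, name, v)
        if np.any(self.p_bh < self.p_raw - 1e-15) or np.any(self.p_by < self.p_bh - 1e-15):
            raise ValueError("adjusted p-values must satisfy p_by >= p_bh >= p_raw")

    def adjusted(self, which: str) -> np.ndarray:
        if which not in ("bh", "by"):
            raise ValueError("which must be 'bh' or 'by'")
        return self.p_bh if which == "bh" else self.p_by


@dataclass
class SignificanceRegions:
    """Maximal grid-time intervals where the adjusted p-value is <= alpha."""

    alpha: float
    intervals: list[tuple[float, float]]


def _validate_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if not np.all(np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and within [0, 1]")
    return p


def _step_up(p: np.ndarray, scale: float) -> np.ndarray:
    """Shared BH/BY machinery: sort, scale by K/i (times ``scale``),
    enforce monotonicity by cumulative minimum from the top rank, cap at 1."""
    k = p.size
    order = np.argsort(p, kind="mergesort")
    q = p[order] * (scale * k / np.arange(1, k + 1))
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, FDR under independence)."""
    return _step_up(_validate_p(p), 1.0)


def adjust_by(p: np.ndarray) -> np.ndarray:
    """Benjamini-Yekutieli adjusted p-values.

    BH scaled by c(K) = sum_{i=1..K} 1/i before the monotonicity and
    capping steps; valid under arbitrary dependence, hence elementwise at
    least as large as BH.
    """
    p = _validate_p(p)
    c_k = float(np.sum(1.0 / np.arange(1, p.size + 1)))
    return _step_up(p, c_k)


def assemble_pvalue_functions(
    fit: PointwiseFitSet,
    mod: ModeratedStats | None = None,
    include_intercept: bool = False,
) -> list[PValueFunction]:
    """Build the per-coefficient p-value functions for the ordinary and (if
    given) moderated statistics, each adjusted across its own K times only."""
    functions: list[PValueFunction] = []
    for j, name in enumerate(fit.design.coefficient_names):
        if name == INTERCEPT and not include_intercept:
            continue
        sources = [("ols", fit.p_ordinary[j])]
        if mod is not None:
            if mod.p_mod.shape != fit.p_ordinary.shape:
                raise ValueError("moderated statistics do not match the fit's shape")
            sources.append(("moderated", mod.p_mod[j]))
        for method, raw in sources:
            functions.append(
                PValueFunction(
                    grid=fit.grid,
                    coefficient_name=name,
                    method=method,
                    p_raw=np.asarray(raw, dtype=float),
                    p_bh=adjust_bh(raw),
                    p_by=adjust_by(raw),
                )
            )
    return functions


def significant_regions(
    pf: PValueFunction, which: str = "bh", alpha: float = 0.05
) -> SignificanceRegions:
    """Extract maximal runs of grid times with adjusted p <= alpha.

    Intervals snap to grid points ([t_first, t_last] of each run); no
    sub-grid interpolation of the alpha crossing.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    mask = pf.adjusted(which) <= alpha
    t = pf.grid.points
    intervals: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((float(t[start]), float(t[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(t[start]), float(t[mask.size - 1])))
    return SignificanceRegions(alpha=alpha, intervals=intervals)


def build_result_table(
    fit: PointwiseFitSet,
    mod: ModeratedStats | None = None,
    pfuncs: Sequence[PValueFunction] | None = None,
) -> ResultTable:
    """Assemble the long-format :class:`ResultTable` for one response model."""
    if pfuncs is None:
        pfuncs = assemble_pvalue_functions(fit, mod)
    se = {"ols": fit.se_ordinary}
    tstat = {"ols": fit.t_ordinary}
    if mod is not None:
        se["moderated"] = np.sqrt(np.outer(fit.design.v_diag, mod.s2_tilde))
        tstat["moderated"] = mod.t_mod
    rows = []
    for pf in pfuncs:
        j = fit.coefficient_index(pf.coefficient_name)
        rows.append(
            pd.DataFrame(
                {
                    "response": fit.response_label,
                    "coefficient": pf.coefficient_name,
                    "time": fit.grid.points,
                    "method": pf.method,
                    "beta": fit.beta_hat[j],
                    "se": se[pf.method][j],
                    "t": tstat[pf.method][j],
                    "p_raw": pf.p_raw,
                    "p_bh": pf.p_bh,
                    "p_by": pf.p_by,
                }
            )
        )
    return ResultTable(pd.concat(rows, ignore_index=True))
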