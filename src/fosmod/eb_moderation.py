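"""Empirical-Bayes variance moderation across time points (limma method).

The K per-time residual variances s^2(t_k) are modeled as draws from a
scaled inverse chi-square prior, 1/sigma^2 ~ chi^2_{d0} / (d0 * s0^2).
Moment matching on log s^2 estimates the hyperparameters (d0, s0^2); the
posterior-mean ("squeezed") variance is the precision-weighted compromise

    s~^2(t_k) = (d0 * s0^2 + d * s^2(t_k)) / (d0 + d),

and the moderated t-statistic beta_hat_j / (s~ * sqrt(v_jj)) is
t-distributed with d + d0 degrees of freedom under the null, gaining d0
degrees of freedom by borrowing variance information across times.  With
d0 = 0 everything reduces to the ordinary t; with d0 = +inf the squeezed
variance is s0^2 everywhere and the null law is standard normal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import digamma, polygamma

from .fos_fit import PointwiseFitSet, _t_and_p


@dataclass(frozen=True)
class ModerationParams:
    """Prior degrees of freedom d0 (possibly +inf) and variance scale s0^2."""

    d0: float
    s02: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):  # d0 = 0 is the no-moderation limit, allowed explicitly
            raise ValueError("d0 must be non-negative (or +inf)")
        if not (self.s02 > 0):
            raise ValueError("s02 must be positive")


@dataclass
class ModeratedStats:
    """Squeezed variances and moderated inference for every coefficient/time."""

    params: ModerationParams
    s2_tilde: np.ndarray  # (K,)
    df_total: float  # d + d0, possibly +inf
    t_mod: np.ndarray  # (p, K)
    p_mod: np.ndarray  # (p, K)


def trigamma_inverse(y: float | np.ndarray) -> float | np.ndarray:
    """Solve psi'(x) = y for x > 0 (psi' is the trigamma function).

    Newton iteration on the near-linear reciprocal 1/psi'(x), started at
    x = 0.5 + 1/y, at most 50 steps, to relative tolerance 1e-8.  psi' is
    strictly decreasing, so the root is unique.
    """
    arr = np.asarray(y, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("trigamma_inverse requires positive finite input")
    x = 0.5 + 1.0 / arr
    # asymptotic starting points for extreme arguments
    x = np.where(arr > 1e7, 1.0 / np.sqrt(arr), x)
    x = np.where(arr < 1e-6, 1.0 / arr, x)
    for _ in range(50):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / arr) / polygamma(2, x)
        x = x + step
        if np.all(np.abs(step) < 1e-10 * x):
            break
    if np.any(np.abs(polygamma(1, x) - arr) > 1e-8 * arr):
        warnings.warn("trigamma_inverse did not reach requested tolerance", stacklevel=2)
    return float(x[0]) if scalar else x


def estimate_hyperparameters(s2: np.ndarray, d: float) -> ModerationParams:
    """Estimate (d0, s0^2) by moment matching on z = log s^2.

    Under the model, z_k = log sigma^2_k + log(chi^2_d / d) with
    log sigma^2_k itself a log-inverse-chi-square draw, so

        E z  = log s0^2 - psi(d0/2) + log(d0/2) + psi(d/2) - log(d/2)
        Var z = psi'(d0/2) + psi'(d/2).

    Matching the sample mean e and variance v of z gives
    d0 = 2 * trigamma_inverse(v - psi'(d/2)) and the s0^2 displayed below.
    When v <= psi'(d/2) the prior spread is indistinguishable from zero:
    d0 = +inf and s0^2 = exp(e - psi(d/2) + log(d/2)).

    Non-positive s^2 entries (possible with degenerate data) are excluded
    with a warning; at least two positive values are required.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 2:
        raise ValueError("hyperparameter estimation needs at least 2 variances")
    positive = s2 > 0
    if np.count_nonzero(positive) < 2:
        raise ValueError("hyperparameter estimation needs at least 2 positive variances")
    if not np.all(positive):
        warnings.warn(
            f"excluding {np.count_nonzero(~positive)} non-positive variances "
            "from hyperparameter estimation",
            stacklevel=2,
        )
    z = np.log(s2[positive])
    e = float(z.mean())
    v = float(z.var(ddof=1))
    gap = v - float(polygamma(1, d / 2.0))
    if gap <= 0:
        return ModerationParams(d0=math.inf, s02=math.exp(e - digamma(d / 2.0) + math.log(d / 2.0)))
    d0 = 2.0 * trigamma_inverse(gap)
    s02 = math.exp(
        e - digamma(d / 2.0) + math.log(d / 2.0) + digamma(d0 / 2.0) - math.log(d0 / 2.0)
    )
    return ModerationParams(d0=d0, s02=s02)


def squeeze_variances(s2: np.ndarray, d: float, params: ModerationParams) -> np.ndarray:
    """Posterior-mean variances: (d0 s0^2 + d s^2) / (d0 + d).

    d0 = 0 returns s^2 unchanged; d0 = +inf returns s0^2 everywhere.
    """
    s2 = np.asarray(s2, dtype=float)
    if math.isinf(params.d0):
        return np.full_like(s2, params.s02)
    if params.d0 == 0.0:
        return s2.copy()
    return (params.d0 * params.s02 + d * s2) / (params.d0 + d)


def moderated_inference(
    fit: PointwiseFitSet, params: ModerationParams | None = None
) -> ModeratedStats:
    """Moderated t and p for every coefficient and time of a pointwise fit.

    If ``params`` is omitted the hyperparameters are estimated from the
    fit's own K residual variances (never pooled across responses).  The
    null distribution is Student t with d + d0 degrees of freedom, or
    standard normal when d0 = +inf.  Coefficients are left untouched.
    """
    if params is None:
        params = estimate_hyperparameters(fit.s2, fit.design.residual_df)
    d = fit.design.residual_df
    s2_tilde = squeeze_variances(fit.s2, d, params)
    se = np.sqrt(np.outer(fit.design.v_diag, s2_tilde))
    df_total = d + params.d0
    t, p = _t_and_p(fit.beta_hat, se, df_total)
    return ModeratedStats(params=params, s2_tilde=s2_tilde, df_total=df_total, t_mod=t, p_mod=p)
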