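"""Effect curves: model-predicted mean responses at fixed covariate profiles.

An effect plot varies one covariate over a set of levels while the others
are held at their sample means; the predicted curve at level v is
x(v)' beta_hat(t), a linear function of the profile, so two levels differ
by exactly (v1 - v2) * beta_hat_varied(t).  A significance mask from a
chosen adjusted p-value function marks the movement phases where the
varied covariate's effect is significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .curves_io import CovariateTable, TimeGrid
from .fos_fit import INTERCEPT, PointwiseFitSet
from .multiple_testing import PValueFunction


@dataclass(frozen=True)
class CovariateProfile:
    """One value per scalar predictor (the intercept is implicit)."""

    ndi: float
    age: float
    neck_length: float
    sex: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ndi <= 50.0):
            raise ValueError("ndi must lie in [0, 50]")
        if self.age <= 0 or self.neck_length <= 0:
            raise ValueError("age and neck_length must be positive")
        if not (0.0 <= self.sex <= 1.0):
            raise ValueError("sex must lie in [0, 1] (proportion coded 1 allowed)")

    def value(self, name: str) -> float:
        if name not in ("ndi", "age", "neck_length", "sex"):
            raise KeyError(f"unknown covariate {name!r}")
        return float(getattr(self, name))

    def replace(self, name: str, value: float) -> "CovariateProfile":
        kwargs = {k: getattr(self, k) for k in ("ndi", "age", "neck_length", "sex")}
        kwargs[name] = value
        return CovariateProfile(**kwargs)


@dataclass
class EffectCurve:
    """Predicted mean curve at one covariate profile, with significance mask."""

    grid: TimeGrid
    predicted: np.ndarray
    profile: CovariateProfile
    level: float
    significance_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.predicted.shape != (self.grid.k,):
            raise ValueError("predicted must have one value per grid point")
        if self.significance_mask is None:
            self.significance_mask = np.zeros(self.grid.k, dtype=bool)
        self.significance_mask = np.asarray(self.significance_mask, dtype=bool)


def mean_profile(cov: CovariateTable) -> CovariateProfile:
    """Sample-mean profile (sex becomes the proportion coded 1)."""
    return CovariateProfile(
        ndi=float(cov.ndi.mean()),
        age=float(cov.age.mean()),
        neck_length=float(cov.neck_length.mean()),
        sex=float(cov.sex.mean()),
    )


def _profile_vector(fit: PointwiseFitSet, profile: CovariateProfile) -> np.ndarray:
    x = np.empty(fit.design.p)
    for j, name in enumerate(fit.design.coefficient_names):
        x[j] = 1.0 if name == INTERCEPT else profile.value(name)
    return x


def predict_profile(fit: PointwiseFitSet, profile: CovariateProfile) -> np.ndarray:
    """Predicted mean curve x' beta_hat(t) at one profile."""
    return _profile_vector(fit, profile) @ fit.beta_hat


def predict_effect_curves(
    fit: PointwiseFitSet,
    varied: str,
    levels: Sequence[float],
    base: CovariateProfile,
    pfunc: PValueFunction | None = None,
    which: str = "bh",
    alpha: float = 0.05,
) -> list[EffectCurve]:
    """Effect curves for ``varied`` at each level, other covariates at ``base``.

    If ``pfunc`` (normally the varied coefficient's moderated, BH-adjusted
    p-value function) is given, the mask flags times with adjusted
    p <= alpha.  The choice of correction cannot change the curves
    themselves - they depend only on beta_hat.
    """
    if varied not in fit.design.coefficient_names or varied == INTERCEPT:
        raise KeyError(f"varied coefficient {varied!r} is not a predictor in the design")
    if len(levels) == 0:
        raise ValueError("need at least one level")
    mask = None
    if pfunc is not None:
        mask = pfunc.adjusted(which) <= alpha
    curves = []
    for v in levels:
        profile = base.replace(varied, float(v))
        curves.append(
            EffectCurve(
                grid=fit.grid,
                predicted=predict_profile(fit, profile),
                profile=profile,
                level=float(v),
                significance_mask=mask,
            )
        )
    return curves


def effect_curves_frame(curves: Sequence[EffectCurve]) -> pd.DataFrame:
    """Long-format export: level, time, predicted, significant."""
    frames = [
        pd.DataFrame(
            {
                "level": c.level,
                "time": c.grid.points,
                "predicted": c.predicted,
                "significant": c.significance_mask,
            }
        )
        for c in curves
    ]
    return pd.concat(frames, ignore_index=True)
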