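"""Optional matplotlib figures: p-value functions and effect plots.

Isolated from the fitting pipeline so a headless or font-less environment
can never break a fit run; matplotlib is imported lazily.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .effects import EffectCurve
from .multiple_testing import PValueFunction


def plot_pvalue_functions(
    raw: PValueFunction,
    moderated: PValueFunction | None = None,
    which: str = "bh",
    alpha: float = 0.05,
    ax=None,
):
    """One predictor's p-value functions over normalized time.

    Grey: raw ordinary p; black: its adjusted version; red: the moderated
    adjusted version; dashed horizontal line at ``alpha``.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = raw.grid.points
    ax.plot(t, raw.p_raw, color="0.6", label="raw")
    ax.plot(t, raw.adjusted(which), color="black", label=f"{which.upper()} adjusted")
    if moderated is not None:
        ax.plot(t, moderated.adjusted(which), color="red", label=f"moderated {which.upper()}")
    ax.axhline(alpha, linestyle="--", color="black", linewidth=0.8)
    ax.set_xlabel("normalized time")
    ax.set_ylabel("p-value")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(raw.coefficient_name)
    ax.legend(fontsize="small")
    return ax


def plot_effect_curves(curves: Sequence[EffectCurve], ylabel: str = "", ax=None):
    """Effect curves for several levels with the significant phases shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for curve in curves:
        ax.plot(curve.grid.points, curve.predicted, label=f"{curve.level:g}")
    mask = curves[0].significance_mask
    if mask.any():
        t = curves[0].grid.points
        ax.fill_between(
            t,
            *ax.get_ylim(),
            where=mask,
            color="tab:blue",
            alpha=0.15,
            linewidth=0,
        )
    ax.set_xlabel("normalized time")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize="small")
    return ax
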