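#!/usr/bin/env python
"""Fit the three function-on-scalar models (angle, velocity, acceleration).

Each response gets its own synthetic study emulating the published pattern:
NDI and age carry effects on velocity and acceleration, nothing is
significant on the angle after adjustment.  For every model the pointwise
OLS fit, the moderated inference and both FDR corrections are computed;
full result tables go to scratch/, a compact summary (estimated d0/s02 and
the BH-significant regions per predictor) to results/.
"""

from pathlib import Path

import pandas as pd

import fosmod as fm
from fosmod.synthetic_data import EffectSpec

ROOT = Path(__file__).resolve().parents[1]
SEED = 1

# effect amplitudes are in response units per covariate unit; noise scales
# (s02, in squared response units) keep the error SD at roughly 5% of each
# response's amplitude
SCENARIOS = {
    "angle": dict(
        effect_spec={name: EffectSpec("null") for name in fm.DEFAULT_PREDICTORS},
        s02_true=25.0,
    ),
    "velocity": dict(
        effect_spec={
            "ndi": EffectSpec("bump", amplitude=-2.0, center=0.25, width=0.3),
            "age": EffectSpec("bump", amplitude=-0.8, center=0.7, width=0.4),
            "neck_length": EffectSpec("null"),
            "sex": EffectSpec("null"),
        },
        s02_true=64.0,
    ),
    "acceleration": dict(
        effect_spec={
            "ndi": EffectSpec("bump", amplitude=-6.0, center=0.5, width=0.25),
            "age": EffectSpec("bump", amplitude=-2.5, center=0.1, width=0.2),
            "neck_length": EffectSpec("null"),
            "sex": EffectSpec("null"),
        },
        s02_true=625.0,
    ),
}


def main() -> None:
    (ROOT / "scratch" / "fits").mkdir(parents=True, exist_ok=True)
    summary_rows = []
    for response, scenario in SCENARIOS.items():
        cfg = fm.GeneratorConfig(seed=SEED, response=response, **scenario)
        study = fm.simulate_study(cfg)
        fit = fm.fit_pointwise(study.curves, fm.build_design(study.covariates))
        mod = fm.moderated_inference(fit)
        pfuncs = fm.assemble_pvalue_functions(fit, mod)
        table = fm.build_result_table(fit, mod, pfuncs)
        fm.write_result_table(table, ROOT / "scratch" / "fits" / f"results_{response}.csv")

        print(f"{response}: d0={mod.params.d0:.3g}, s02={mod.params.s02:.4g}")
        for pf in pfuncs:
            if pf.method != "moderated":
                continue
            regions = fm.significant_regions(pf, "bh", 0.05)
            for lo, hi in regions.intervals:
                summary_rows.append(
                    dict(response=response, coefficient=pf.coefficient_name,
                         d0=mod.params.d0, s02=mod.params.s02, t_start=lo, t_end=hi)
                )
            if regions.intervals:
                spans = ", ".join(f"[{lo:.2f}, {hi:.2f}]" for lo, hi in regions.intervals)
                print(f"  {pf.coefficient_name}: BH-significant on {spans}")
        if not any(r["response"] == response for r in summary_rows):
            print("  no predictor significant after adjustment")

    dest = ROOT / "results" / "significant_regions.csv"
    pd.DataFrame(
        summary_rows,
        columns=["response", "coefficient", "d0", "s02", "t_start", "t_end"],
    ).to_csv(dest, index=False)
    print(f"\nregion summary written to {dest}")
    print(
        "finding: after BH adjustment of the moderated p-value functions, NDI "
        "and age show significant windows on velocity and acceleration while "
        "the angle model shows none - the pattern the generator encodes."
    )


if __name__ == "__main__":
    main()
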