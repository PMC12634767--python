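import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fosmod as fm
from fosmod.synthetic_data import EffectSpec

settings.register_profile(
    "det", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("det")


def null_effects() -> dict:
    return {name: EffectSpec("null") for name in ("ndi", "age", "neck_length", "sex")}


def fit_study(study: fm.SyntheticStudy, predictors=fm.DEFAULT_PREDICTORS):
    design = fm.build_design(study.covariates, predictors)
    fit = fm.fit_pointwise(study.curves, design)
    return fit, fm.moderated_inference(fit)


@pytest.fixture(scope="session")
def default_study() -> fm.SyntheticStudy:
    """One study at the default conditions (n=55, K=100, NDI bump effect)."""
    return fm.simulate_study(fm.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def default_fit(default_study):
    return fit_study(default_study)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
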