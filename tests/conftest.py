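import numpy as np
import pandas as pd
import pytest

from itrboost.synthetic_trial import (
    ConstantEffect,
    EffectSpec,
    LinearEffect,
    simulate_trial,
)
from itrboost.trial_data import BINARY, CONTINUOUS, SURVIVAL, Endpoint

ENDPOINTS = [CONTINUOUS, BINARY, SURVIVAL]


def make_trial(kind: str, n: int = 100, seed: int = 0, z_coef: float = 1.0):
    """Small seeded trial with a linear contrast on x1 and a main effect on x2."""
    spec = EffectSpec(
        n=n,
        p=3,
        h=LinearEffect({"x2": 0.5}),
        z=LinearEffect({"x1": z_coef}),
        endpoint=Endpoint(kind),
        censoring_rate=0.25 if kind == "survival" else 0.0,
        seed=seed,
    )
    return simulate_trial(spec)


@pytest.fixture(params=["continuous", "binary", "survival"])
def any_trial(request):
    ds, z, grp = make_trial(request.param, n=80, seed=5)
    return ds


@pytest.fixture
def continuous_trial():
    return make_trial("continuous", n=100, seed=1)[0]


@pytest.fixture
def survival_trial():
    return make_trial("survival", n=100, seed=2)[0]
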