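import numpy as np
import pytest

from blswitch.model_core import ModelParams


@pytest.fixture
def baseline() -> ModelParams:
    """Baseline parameter set at the critical CheR concentration, ell=20."""
    return ModelParams(A0=13.6, R0=0.224, L=2.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260213)


def random_stable_params(rng: np.random.Generator) -> ModelParams:
    """Random but physically sensible parameter draw."""
    return ModelParams(
        A0=float(rng.uniform(2.0, 30.0)),
        R0=float(rng.uniform(0.02, 1.0)),
        B0=float(rng.uniform(0.05, 1.0)),
        Kr=float(rng.uniform(0.1, 2.0)),
        Kb=float(rng.uniform(0.1, 2.0)),
        KL=float(rng.uniform(0.05, 1.0)),
        nu_r=float(rng.uniform(0.1, 2.0)),
        nu_b=float(rng.uniform(0.1, 2.0)),
        L=float(rng.uniform(0.0, 20.0)),
    )
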