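import numpy as np
import pytest

from warconj.core import ModelParams, SystemState


@pytest.fixture
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def standard_init() -> SystemState:
    """1:1:0 attacker:target:transconjugant at total biomass 0.02."""
    return SystemState(C1=0.01, C2=0.01, C3=0.0, N1=1.0, N2=0.0, N3=0.0, T=0.0)


def random_state(rng: np.random.Generator) -> SystemState:
    c = rng.uniform(0.0, 2.0, size=3)
    n = rng.uniform(0.0, 3.0, size=3)
    t = rng.uniform(0.0, 1.0)
    return SystemState(C1=c[0], C2=c[1], C3=c[2], N1=n[0], N2=n[1], N3=n[2], T=t)


def random_params(rng: np.random.Generator) -> ModelParams:
    """Parameter draw over a physiologically plausible range around defaults."""
    return ModelParams(
        rC1=rng.uniform(0.5, 1.5),
        rC2=rng.uniform(0.5, 1.5),
        rC3=rng.uniform(0.5, 1.5),
        KN1=rng.uniform(2.0, 8.0),
        KN2=rng.uniform(2.0, 8.0),
        KN3=rng.uniform(2.0, 8.0),
        E=rng.uniform(0.5, 20.0),
        b=rng.uniform(0.0, 0.5),
        gamma=rng.uniform(0.0, 0.3),
        KC2T=rng.uniform(0.5, 2.0),
    )
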