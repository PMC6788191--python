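import warnings

import numpy as np
import pytest

from precautiongame import GameParams


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


def draw_params(rng: np.random.Generator, rule: str = "parametric") -> GameParams:
    """One random valid parameter set; cost-ordering warnings suppressed."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return GameParams(
            cc=float(rng.uniform(0.2, 20.0)),
            cs=float(rng.uniform(0.2, 20.0)),
            p=float(rng.uniform(0.2, 20.0)),
            a=float(rng.uniform(0.0, 1.0)),
            b=float(rng.uniform(0.0, 1.0)),
            rule=rule,
        )


def draw_state(rng: np.random.Generator) -> tuple[float, float]:
    return (float(rng.uniform(0.0, 1.0)), float(rng.uniform(0.0, 1.0)))


def make_params(cc, cs, p, a, b, rule="parametric") -> GameParams:
    """GameParams without the cs >= cc ordering warning (used all over the tests)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return GameParams(cc=cc, cs=cs, p=p, a=a, b=b, rule=rule)
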