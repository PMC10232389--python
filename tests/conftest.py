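import numpy as np
import pytest

from webpatch import FoodWeb, ParamSet


def basal_web(n_P: int) -> FoodWeb:
    """A web with only basal species (no consumers)."""
    return FoodWeb(
        tuple(f"P{i + 1}" for i in range(n_P)),
        (),
        np.zeros((n_P, 0)),
        np.zeros((0, 0)),
    )


def basal_params(c, e=0.2, U=0.0) -> ParamSet:
    c = np.atleast_1d(np.asarray(c, dtype=float))
    return ParamSet(cP=c, eP=np.full(c.size, e), U=U)


@pytest.fixture
def chain3():
    """Linear chain P1 -> A1 -> A2."""
    return FoodWeb(("P1",), ("A1", "A2"),
                   np.array([[1, 0]]), np.array([[0, 1], [0, 0]]))


@pytest.fixture
def diamond():
    """P1 -> A1, P1 -> A2, A1 -> A3, A2 -> A3."""
    return FoodWeb(
        ("P1",),
        ("A1", "A2", "A3"),
        np.array([[1, 1, 0]]),
        np.array([[0, 0, 1], [0, 0, 1], [0, 0, 0]]),
    )


@pytest.fixture
def pair_web():
    """One basal species and one consumer feeding on it."""
    return FoodWeb(("P1",), ("A1",), np.array([[1]]), np.array([[0]]))
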