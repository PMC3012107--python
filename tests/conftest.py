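import math

import numpy as np
import pytest

from sgof.core import PValueSet


def binomial_tail_oracle(S: int, gamma: float, K: int) -> float:
    """Brute-force P(Binomial(S, gamma) >= K) by direct pmf summation."""
    return sum(
        math.comb(S, k) * gamma**k * (1.0 - gamma) ** (S - k) for k in range(K, S + 1)
    )


def critical_value_oracle(S: int, gamma: float, alpha: float) -> int:
    """Smallest b with P(Binomial(S, gamma) >= b) <= alpha, by enumeration."""
    for b in range(S + 2):
        if binomial_tail_oracle(S, gamma, b) <= alpha:
            return b
    raise AssertionError("unreachable: tail at S+1 is 0")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20101229)


@pytest.fixture
def bimodal_pset():
    """20 tests: ten clear effects at p=0.01, ten clear nulls at p=0.9."""
    return PValueSet(
        ids=[f"g{i}" for i in range(20)],
        pvalues=[0.01] * 10 + [0.9] * 10,
    )


@pytest.fixture
def uniform_pset(rng):
    """1000 complete-null tests with Uniform(0,1) p-values."""
    p = rng.uniform(size=1000)
    return PValueSet(ids=[str(i) for i in range(1000)], pvalues=p)
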