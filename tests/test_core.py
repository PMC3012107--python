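"""Unit and property tests for the single-gamma SGoF statistic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sgof.core import (
    PValueSet,
    SGoFParams,
    binomial_critical_value,
    count_rejections,
    efdr,
    meta_test_pvalue,
    n_effects,
    pi0_estimate,
    sgof,
    sgof_sequential,
    threshold_for_n,
)

from .conftest import binomial_tail_oracle, critical_value_oracle


@pytest.mark.parametrize(
    "pvalues, gamma, expected",
    [
        ([0.01, 0.04, 0.2], 0.05, 2),
        ([], 0.05, 0),
        ([0.05, 0.05, 0.6], 0.05, 2),  # boundary p == gamma is counted
    ],
)
def test_count_rejections(pvalues, gamma, expected):
    assert count_rejections(pvalues, gamma) == expected


def test_count_rejections_rejects_out_of_range():
    with pytest.raises(ValueError, match="index 1"):
        count_rejections([0.2, 1.5], 0.05)


@pytest.mark.parametrize(
    "S, gamma, alpha, expected",
    [
        (10, 0.5, 0.05, 9),  # P(X>=9)=11/1024<=0.05 < P(X>=8)=56/1024
        (1, 0.5, 0.05, 2),  # only the empty tail is <= 0.05
        (10, 0.5, 0.999, 2),  # P(X>=1)=1-1/1024 > 0.999 >= P(X>=2)
    ],
)
def test_binomial_critical_value_frozen_oracle_values(S, gamma, alpha, expected):
    assert critical_value_oracle(S, gamma, alpha) == expected
    assert binomial_critical_value(S, gamma, alpha) == expected


@pytest.mark.parametrize(
    "S, gamma, K, expected",
    [
        (37, 0.2, 0, 1.0),
        (10, 0.5, 10, 1 / 1024),
        (10, 0.5, 9, 11 / 1024),
    ],
)
def test_meta_test_pvalue_frozen_values(S, gamma, K, expected):
    assert meta_test_pvalue(S, gamma, K) == pytest.approx(expected, rel=1e-12)


def test_meta_test_pvalue_rejects_K_above_S():
    with pytest.raises(ValueError):
        meta_test_pvalue(5, 0.5, 6)


@pytest.mark.parametrize("S", range(61))
@pytest.mark.parametrize("gamma", [0.01, 0.05, 0.26, 0.5, 0.9])
def test_binomial_tail_matches_bruteforce_oracle(S, gamma):
    """Exact tail and critical count agree with direct pmf summation."""
    for K in range(S + 1):
        oracle = binomial_tail_oracle(S, gamma, K)
        got = meta_test_pvalue(S, gamma, K)
        assert got == pytest.approx(oracle, rel=1e-12)
    for alpha in (0.01, 0.05, 0.15):
        assert binomial_critical_value(S, gamma, alpha) == critical_value_oracle(
            S, gamma, alpha
        )


@pytest.mark.parametrize(
    "K, b, K_at_alpha, capped, expected",
    [
        (50, 40, 0, False, 11),
        (10, 20, 0, False, 0),
        (50, 40, 5, True, 5),
    ],
)
def test_n_effects_formula(K, b, K_at_alpha, capped, expected):
    assert n_effects(K, b, K_at_alpha, capped) == expected


@pytest.mark.parametrize(
    "pvalues, N, expected",
    [
        ([0.01, 0.02, 0.03, 0.9], 2, (0.02, 2)),
        ([0.5, 0.6], 0, (None, 0)),
        ([0.01, 0.02, 0.02, 0.9], 2, (0.02, 3)),  # tie at the cut
    ],
)
def test_threshold_for_n(pvalues, N, expected):
    assert threshold_for_n(pvalues, N) == expected


def test_threshold_for_n_rejects_N_above_S():
    with pytest.raises(ValueError):
        threshold_for_n([0.1], 2)


def test_pi0_point_values():
    assert pi0_estimate([1 - math.exp(-1)]) == pytest.approx(1.0, rel=1e-12)
    assert pi0_estimate([0.0, 0.0]) == 0.0


def test_pi0_uniform_calibration(rng):
    """E[-log(1-U)] = 1 for U ~ Uniform(0,1)."""
    draws = rng.uniform(size=10_000)
    assert pi0_estimate(draws) == pytest.approx(1.0, abs=0.03)


def test_pi0_clamps_p_equal_one():
    with pytest.warns(RuntimeWarning, match="clamped"):
        val = pi0_estimate([1.0, 0.0])
    assert np.isfinite(val)


@pytest.mark.parametrize(
    "S, threshold, pi0, N, expected",
    [
        (1000, 0.05, 0.9, 100, 0.45),
        (1000, 0.0, 0.9, 10, 0.0),
        (1000, 0.5, 1.0, 100, 1.0),  # raw 5 clipped to 1
    ],
)
def test_efdr_formula(S, threshold, pi0, N, expected):
    assert efdr(S, threshold, pi0, N) == pytest.approx(expected)


def test_efdr_absent_without_declarations():
    assert efdr(1000, None, 0.9, 0) is None


class TestSgofComposition:
    def test_bimodal_example(self, bimodal_pset):
        """Ten p=0.01 among twenty: K=10, b=4 from Binomial(20,0.05), N=7."""
        r = sgof(bimodal_pset, SGoFParams(gamma=0.05, alpha=0.05))
        assert (r.K, r.b, r.n_effects) == (10, 4, 7)
        assert r.threshold == 0.01
        assert r.achieved_count == 10  # ties: all ten 0.01s sit at the cut
        assert len(r.declared_ids) == 7
        assert all(i.startswith("g") and int(i[1:]) < 10 for i in r.declared_ids)

    def test_nothing_below_gamma(self):
        pset = PValueSet(["a", "b", "c"], [0.99, 0.99, 0.99])
        r = sgof(pset, SGoFParams(gamma=0.05))
        assert r.K == 0
        assert r.meta_pvalue == 1.0
        assert r.n_effects == 0
        assert r.threshold is None and r.efdr is None
        assert r.declared_ids == ()

    def test_single_pvalue_boundary_rejection(self):
        """S=1, p=0.01: P(Bin(1,0.05)>=1)=0.05<=alpha, so the effect is declared."""
        r = sgof(PValueSet(["only"], [0.01]), SGoFParams(gamma=0.05, alpha=0.05))
        assert (r.K, r.b, r.n_effects) == (1, 1, 1)
        assert r.declared_ids == ("only",)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            sgof(PValueSet([], []), SGoFParams(gamma=0.05))

    def test_declaration_iff_meta_significant(self, rng):
        """n_effects >= 1 exactly when the meta p-value is <= alpha (uncapped)."""
        for _ in range(50):
            S = int(rng.integers(1, 80))
            p = rng.uniform(size=S) ** rng.uniform(0.3, 1.0)
            pset = PValueSet([str(i) for i in range(S)], p)
            r = sgof(pset, SGoFParams(gamma=0.05, alpha=0.05))
            assert (r.n_effects >= 1) == (r.meta_pvalue <= 0.05)

    def test_cap_dominance(self, rng):
        """Capped declarations never exceed uncapped ones nor p > alpha."""
        for _ in range(30):
            S = int(rng.integers(5, 100))
            p = rng.uniform(size=S) ** 0.4
            pset = PValueSet([str(i) for i in range(S)], p)
            params = SGoFParams(gamma=0.4, alpha=0.05)
            r_free = sgof(pset, params)
            r_cap = sgof(pset, SGoFParams(gamma=0.4, alpha=0.05, capped=True))
            assert r_cap.n_effects <= r_free.n_effects
            declared_p = [p[int(i)] for i in r_cap.declared_ids]
            assert all(x <= 0.05 for x in declared_p)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    pvals=st.lists(
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=100
    ),
    gamma=st.sampled_from([0.01, 0.05, 0.1, 0.26, 0.5, 0.9]),
    alpha=st.sampled_from([0.01, 0.05, 0.15]),
)
def test_sequential_equals_closed_form(pvals, gamma, alpha):
    """The step-wise algorithm equals max(K - b + 1, 0) on random instances."""
    pset = PValueSet([str(i) for i in range(len(pvals))], pvals)
    params = SGoFParams(gamma=gamma, alpha=alpha)
    closed = sgof(pset, params).n_effects
    assert sgof_sequential(pset, params) == closed


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    pvals=st.lists(
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=60
    ),
    alpha=st.sampled_from([0.01, 0.05, 0.15]),
)
def test_K_and_b_monotone_in_gamma(pvals, alpha):
    """K(gamma) and b_alpha(gamma) are non-decreasing in gamma."""
    grid = [0.05, 0.1, 0.3, 0.5, 0.7, 0.9]
    S = len(pvals)
    Ks = [count_rejections(pvals, g) for g in grid]
    bs = [binomial_critical_value(S, g, alpha) for g in grid]
    assert Ks == sorted(Ks)
    assert bs == sorted(bs)
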