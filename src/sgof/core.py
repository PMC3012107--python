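"""Core SGoF statistic for a single working threshold gamma.

SGoF (Sequential Goodness-of-Fit) tests the intersection null — "all S
individual null hypotheses are true" — by comparing the observed number of
p-values at or below a working threshold gamma, K(gamma), with its null
distribution Binomial(S, gamma).  If the one-sided exact binomial test
rejects at level alpha, the method declares the N = K(gamma) - b_alpha(gamma) + 1
smallest p-values as true effects, where b_alpha(gamma) is the binomial
critical count.  This controls the family-wise error rate at alpha in the
weak sense (under the complete null).

The module also provides the plug-in quantities that accompany a run: the
p-value threshold q_alpha(gamma) realising N declared effects, the
proportion-of-true-nulls estimate pi0 (mean of -log(1 - p_i)), and the
estimated false discovery rate eFDR = S * q * pi0 / N.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import binom

__all__ = [
    "PValueSet",
    "SGoFParams",
    "SGoFResult",
    "count_rejections",
    "binomial_critical_value",
    "meta_test_pvalue",
    "n_effects",
    "threshold_for_n",
    "pi0_estimate",
    "efdr",
    "sgof",
    "sgof_sequential",
]

#: Floor applied to exact binomial tail probabilities so that log-scale
#: plots of the meta p-value never hit -inf on extreme data.
META_PVALUE_FLOOR = 1e-300

#: p = 1 is clamped to this value inside pi0_estimate so -log(1-p) stays
#: finite without silently dropping tests.
_ONE_MINUS_EPS = 1.0 - 1e-15


def _validate_pvalues(pvalues: np.ndarray) -> None:
    bad = np.flatnonzero((pvalues < 0.0) | (pvalues > 1.0) | ~np.isfinite(pvalues))
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"p-value at index {i} is {pvalues[i]!r}, outside the interval [0, 1]"
        )


@dataclass(frozen=True)
class PValueSet:
    """A collection of S tests: identifiers, p-values and optional truth labels.

    ``truth`` (True = genuine effect, i.e. a non-true null) is only available
    for simulated data; it is None for real data sets.  Duplicated
    identifiers are preserved verbatim.
    """

    ids: tuple[str, ...]
    pvalues: np.ndarray
    truth: Optional[np.ndarray] = None

    def __init__(
        self,
        ids: Sequence[str],
        pvalues: Sequence[float],
        truth: Optional[Sequence[bool]] = None,
    ):
        p = np.asarray(pvalues, dtype=float)
        _validate_pvalues(p)
        id_tuple = tuple(str(i) for i in ids)
        if len(id_tuple) != p.size:
            raise ValueError(
                f"ids (length {len(id_tuple)}) and pvalues (length {p.size}) differ"
            )
        t = None
        if truth is not None:
            t = np.asarray(truth, dtype=bool)
            if t.size != p.size:
                raise ValueError(
                    f"truth (length {t.size}) and pvalues (length {p.size}) differ"
                )
            t.setflags(write=False)
        p.setflags(write=False)
        object.__setattr__(self, "ids", id_tuple)
        object.__setattr__(self, "pvalues", p)
        object.__setattr__(self, "truth", t)

    def __len__(self) -> int:
        return self.pvalues.size

    @property
    def S(self) -> int:
        return self.pvalues.size


@dataclass(frozen=True)
class SGoFParams:
    """Tuning parameters of one SGoF run.

    gamma   working threshold in (0, 1) defining K(gamma)
    alpha   weak-FWER level of the exact binomial meta-test, default 0.05
    capped  if True, cap the declared count at K(alpha) so that no p-value
            above alpha is ever declared an effect
    """

    gamma: float
    alpha: float = 0.05
    capped: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ValueError(f"gamma must lie in (0, 1); got {self.gamma}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1); got {self.alpha}")


@dataclass(frozen=True)
class SGoFResult:
    """All per-gamma quantities of a single SGoF evaluation."""

    S: int
    gamma: float
    alpha: float
    capped: bool
    K: int
    b: int
    meta_pvalue: float
    n_effects: int
    threshold: Optional[float]
    achieved_count: int
    declared_ids: tuple[str, ...] = field(repr=False)
    pi0: float = float("nan")
    efdr: Optional[float] = None


def count_rejections(pvalues: Sequence[float], gamma: float) -> int:
    """Number of individual rejections K(gamma) = #{p_i <= gamma}.

    The boundary p = gamma is counted (non-strict inequality).
    """
    p = np.asarray(pvalues, dtype=float)
    _validate_pvalues(p)
    return int(np.count_nonzero(p <= gamma))


def binomial_critical_value(S: int, gamma: float, alpha: float) -> int:
    """Critical count b_alpha(gamma) of the one-sided exact binomial test.

    Returns the smallest integer b such that P(Binomial(S, gamma) >= b) <= alpha,
    so that rejecting the intersection null whenever K >= b keeps the weak
    FWER at or below alpha.  The result can be S + 1 when even observing all
    S p-values below gamma would not be significant (then P(X >= S+1) = 0).
    """
    if S < 0:
        raise ValueError(f"S must be >= 0; got {S}")
    if not 0.0 < gamma < 1.0:
        raise ValueError(f"gamma must lie in (0, 1); got {gamma}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1); got {alpha}")
    # isf gives the smallest k with sf(k) <= alpha, i.e. P(X >= k+1) <= alpha;
    # step locally to guard against discreteness/rounding at the boundary.
    b = int(binom.isf(alpha, S, gamma)) + 1
    while b > 0 and binom.sf(b - 2, S, gamma) <= alpha:
        b -= 1
    while b <= S and binom.sf(b - 1, S, gamma) > alpha:
        b += 1
    return b


def meta_test_pvalue(S: int, gamma: float, K: int) -> float:
    """Exact upper binomial tail P(Binomial(S, gamma) >= K).

    This is the p-value of the SGoF meta-test of the intersection null.
    Computed from the exact survival function (no normal approximation);
    underflow is floored at 1e-300 so the value stays in (0, 1].
    """
    if K > S:
        raise ValueError(f"K ({K}) cannot exceed S ({S})")
    if K < 0:
        raise ValueError(f"K must be >= 0; got {K}")
    if K == 0:
        return 1.0
    p = float(binom.sf(K - 1, S, gamma))
    return max(p, META_PVALUE_FLOOR)


def n_effects(K: int, b: int, K_at_alpha: int = 0, capped: bool = False) -> int:
    """Number of declared effects N_alpha(gamma).

    K - b + 1 upon rejection (K >= b), else 0.  When ``capped`` the count is
    additionally bounded by K_at_alpha = #{p_i <= alpha}, so no p-value above
    alpha is declared.
    """
    if K < b:
        return 0
    n = K - b + 1
    if capped:
        n = min(n, K_at_alpha)
    return n


def threshold_for_n(
    pvalues: Sequence[float], N: int
) -> tuple[Optional[float], int]:
    """p-value threshold q realising N declared effects.

    Returns ``(threshold, achieved_count)`` where threshold is the N-th
    smallest p-value and achieved_count = #{p_i <= threshold}.  Under ties at
    the cut the achieved count can exceed N; both are reported so the
    discrepancy is visible.  N = 0 yields ``(None, 0)``.
    """
    p = np.asarray(pvalues, dtype=float)
    if N > p.size:
        raise ValueError(f"N ({N}) exceeds the number of p-values ({p.size})")
    if N < 0:
        raise ValueError(f"N must be >= 0; got {N}")
    if N == 0:
        return None, 0
    q = float(np.partition(p, N - 1)[N - 1])
    achieved = int(np.count_nonzero(p <= q))
    return q, achieved


def pi0_estimate(pvalues: Sequence[float]) -> float:
    """Estimate the proportion of true nulls as mean(-log(1 - p_i)).

    Under the complete null the p-values are Uniform(0, 1) and
    E[-log(1-U)] = 1; an excess of small p-values pulls the mean below 1.
    p = 1 is clamped to 1 - 1e-15 (with a warning) rather than dropped, so S
    is unchanged.  The raw value can exceed 1; it is truncated to 1 only
    inside :func:`efdr`.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("pi0_estimate requires a non-empty p-value list")
    _validate_pvalues(p)
    if np.any(p >= 1.0):
        warnings.warn(
            "p-values equal to 1 clamped to 1 - 1e-15 in pi0 estimation",
            RuntimeWarning,
            stacklevel=2,
        )
        p = np.minimum(p, _ONE_MINUS_EPS)
    return float(np.mean(-np.log1p(-p)))


def efdr(S: int, threshold: Optional[float], pi0: float, N: int) -> Optional[float]:
    """Plug-in estimated FDR of the SGoF declaration set.

    eFDR = S * q * min(pi0, 1) / N, clipped into [0, 1]; None when N = 0
    (no declarations, hence no FDR to estimate).
    """
    if N == 0:
        return None
    if threshold is None:
        raise ValueError("threshold must be given when N > 0")
    raw = S * threshold * min(pi0, 1.0) / N
    return float(min(max(raw, 0.0), 1.0))


def sgof(pset: PValueSet, params: SGoFParams) -> SGoFResult:
    """Run SGoF at a single gamma and assemble every per-run quantity.

    Declared effects are the N smallest p-values; ties at the cut are broken
    by input order (stable sort), so reruns are deterministic.
    """
    if len(pset) == 0:
        raise ValueError("sgof requires a non-empty p-value set")
    S = pset.S
    p = pset.pvalues
    K = count_rejections(p, params.gamma)
    b = binomial_critical_value(S, params.gamma, params.alpha)
    meta_p = meta_test_pvalue(S, params.gamma, K)
    K_at_alpha = count_rejections(p, params.alpha) if params.capped else 0
    N = n_effects(K, b, K_at_alpha, params.capped)
    q, achieved = threshold_for_n(p, N)
    pi0 = pi0_estimate(p)
    e = efdr(S, q, pi0, N)
    order = np.argsort(p, kind="stable")
    declared = tuple(pset.ids[i] for i in order[:N])
    return SGoFResult(
        S=S,
        gamma=params.gamma,
        alpha=params.alpha,
        capped=params.capped,
        K=K,
        b=b,
        meta_pvalue=meta_p,
        n_effects=N,
        threshold=q,
        achieved_count=achieved,
        declared_ids=declared,
        pi0=pi0,
        efdr=e,
    )


def sgof_sequential(pset: PValueSet, params: SGoFParams) -> int:
    """Step-wise form of SGoF: count successive significant tail tests.

    Starting from k = K(gamma), test P(Binomial(S, gamma) >= k) <= alpha,
    decrement k while significance holds, and return the number of
    significant steps.  Provided for cross-validation: it equals the closed
    form max(K - b + 1, 0) of the uncapped method.
    """
    if len(pset) == 0:
        raise ValueError("sgof_sequential requires a non-empty p-value set")
    S = pset.S
    k = count_rejections(pset.pvalues, params.gamma)
    n = 0
    while k >= 1 and meta_test_pvalue(S, params.gamma, k) <= params.alpha:
        n += 1
        k -= 1
    return n
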