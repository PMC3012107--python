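"""Monte-Carlo power/FDR study of SGoF against a Benjamini-Hochberg baseline.

Each trial simulates S simultaneous tests: a fraction of them are genuine
effects whose p-values are drawn as p = 1 - Phi(Z + w) with Z ~ N(0, 1)
(one-sided normal test shifted by w standard errors), the rest are true
nulls with Uniform(0, 1) p-values.  SGoF is applied at every gamma of a
grid, BH at a nominal FDR level, on the same sample, and per-test power and
realised false-discovery proportion (FDP) are averaged over trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import PValueSet, binomial_critical_value

__all__ = [
    "SimulationConfig",
    "TrialOutcome",
    "SimulationSummary",
    "generate_pvalues",
    "bh_procedure",
    "evaluate_trial",
    "run_simulation",
    "write_summary_tsv",
]


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation scenario.

    S                  total number of tests per trial
    effect_proportion  fraction of genuine effects in [0, 1); the effect
                       count round(S * effect_proportion) is fixed per trial
    w                  effect size in units of standard errors
    n_trials           number of Monte-Carlo trials
    alpha              weak-FWER level of SGoF
    gammas             SGoF working thresholds evaluated on every trial
    bh_fdr             nominal FDR level of the BH baseline
    seed               master RNG seed; per-trial substreams are derived
                       deterministically so any trial is reproducible alone
    capped             cap SGoF declarations at K(alpha)
    """

    S: int = 1000
    effect_proportion: float = 0.10
    w: float = 2.0
    n_trials: int = 1000
    alpha: float = 0.05
    gammas: tuple[float, ...] = (0.01, 0.05, 0.09, 0.13, 0.17)
    bh_fdr: float = 0.05
    seed: int = 0
    capped: bool = False

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError(f"S must be >= 1; got {self.S}")
        if not 0.0 <= self.effect_proportion < 1.0:
            raise ValueError(
                f"effect_proportion must lie in [0, 1); got {self.effect_proportion}"
            )
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1; got {self.n_trials}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1); got {self.alpha}")
        if not 0.0 < self.bh_fdr < 1.0:
            raise ValueError(f"bh_fdr must lie in (0, 1); got {self.bh_fdr}")
        object.__setattr__(self, "gammas", tuple(float(g) for g in self.gammas))
        for g in self.gammas:
            if not 0.0 < g < 1.0:
                raise ValueError(f"gamma must lie in (0, 1); got {g}")

    @property
    def n_effects_true(self) -> int:
        return int(round(self.S * self.effect_proportion))


@dataclass(frozen=True)
class TrialOutcome:
    """Power and realised FDP of one method on one trial."""

    method: str
    declared: tuple[int, ...] = field(repr=False)
    power: Optional[float]
    fdp: float


@dataclass(frozen=True)
class SimulationSummary:
    """Averaged power/FDP (with MC standard errors) per method."""

    config: SimulationConfig
    table: pd.DataFrame  # columns: method, gamma, power, power_se, fdr, fdr_se,
    #                                rejection_rate, n_trials


def generate_pvalues(
    S: int, effect_proportion: float, w: float, rng: np.random.Generator
) -> PValueSet:
    """Draw one trial's p-values from the null/effect mixture.

    The first round(S * effect_proportion) entries are effects with
    p = 1 - Phi(Z + w); the remainder are Uniform(0, 1) nulls.  Truth labels
    and unique synthetic identifiers are attached.
    """
    if S < 1:
        raise ValueError(f"S must be >= 1; got {S}")
    if not 0.0 <= effect_proportion < 1.0:
        raise ValueError(f"effect_proportion must lie in [0, 1); got {effect_proportion}")
    m = int(round(S * effect_proportion))
    z = rng.standard_normal(m)
    p_eff = norm.sf(z + w)  # 1 - Phi(Z + w)
    p_null = rng.uniform(size=S - m)
    pvalues = np.concatenate([p_eff, p_null])
    truth = np.concatenate([np.ones(m, bool), np.zeros(S - m, bool)])
    ids = [f"t{i + 1}" for i in range(S)]
    return PValueSet(ids=ids, pvalues=pvalues, truth=truth)


def bh_procedure(pvalues: Sequence[float], fdr_level: float = 0.05) -> set[int]:
    """Benjamini-Hochberg step-up rule; returns the declared indices.

    Find the largest i with p_(i) <= (i / S) * fdr_level and declare the i
    smallest p-values; the empty set when no such i exists.
    """
    if not 0.0 < fdr_level < 1.0:
        raise ValueError(f"fdr_level must lie in (0, 1); got {fdr_level}")
    p = np.asarray(pvalues, dtype=float)
    S = p.size
    if S == 0:
        return set()
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, S + 1)
    ok = np.flatnonzero(p[order] <= ranks / S * fdr_level)
    if ok.size == 0:
        return set()
    cut = int(ok[-1]) + 1
    return set(int(i) for i in order[:cut])


def evaluate_trial(truth: Sequence[bool], declared: set[int]) -> TrialOutcome:
    """Power and FDP of one declaration set against known truth.

    power = TP / #effects (None when the trial has no true effects);
    fdp = FP / max(R, 1) so a trial with zero rejections contributes 0.
    """
    t = np.asarray(truth, dtype=bool)
    idx = np.fromiter(declared, dtype=int, count=len(declared))
    if idx.size and (idx.min() < 0 or idx.max() >= t.size):
        raise ValueError("declared indices outside 0..S-1")
    n_eff = int(t.sum())
    tp = int(t[idx].sum()) if idx.size else 0
    fp = idx.size - tp
    power = None if n_eff == 0 else tp / n_eff
    fdp = fp / max(idx.size, 1)
    return TrialOutcome(method="", declared=tuple(int(i) for i in idx), power=power, fdp=fdp)


def _trial_metrics(
    pvalues: np.ndarray,
    truth: np.ndarray,
    gammas: Sequence[float],
    b_crit: Sequence[int],
    alpha: float,
    capped: bool,
    bh_fdr: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float, int]:
    """Per-trial SGoF (each gamma) and BH power/FDP on one shared sample.

    Uses the sorted order once: K(gamma) by bisection and the true-positive
    count among the N smallest p-values by a cumulative sum.  Algebraically
    identical to calling :func:`sgof.core.sgof` per gamma.
    """
    S = pvalues.size
    order = np.argsort(pvalues, kind="stable")
    p_sorted = pvalues[order]
    truth_sorted = truth[order]
    cum_tp = np.cumsum(truth_sorted)
    m = int(truth.sum())

    K_at_alpha = int(np.searchsorted(p_sorted, alpha, side="right")) if capped else 0
    n_g = len(gammas)
    powers = np.zeros(n_g)
    fdps = np.zeros(n_g)
    n_decl = np.zeros(n_g, dtype=int)
    for j, (g, b) in enumerate(zip(gammas, b_crit)):
        K = int(np.searchsorted(p_sorted, g, side="right"))
        N = 0 if K < b else K - b + 1
        if capped:
            N = min(N, K_at_alpha)
        n_decl[j] = N
        if N > 0:
            tp = int(cum_tp[N - 1])
            powers[j] = tp / m if m else 0.0
            fdps[j] = (N - tp) / N

    ok = np.flatnonzero(p_sorted <= np.arange(1, S + 1) / S * bh_fdr)
    R = int(ok[-1]) + 1 if ok.size else 0
    if R > 0:
        tp = int(cum_tp[R - 1])
        bh_power = tp / m if m else 0.0
        bh_fdp = (R - tp) / R
    else:
        bh_power = 0.0
        bh_fdp = 0.0
    return powers, fdps, n_decl, bh_power, bh_fdp, R


def run_simulation(config: SimulationConfig) -> SimulationSummary:
    """Run the full Monte-Carlo study for one scenario.

    Every trial draws one p-value sample shared by SGoF (at each gamma) and
    BH, so the methods are compared on identical data.  Deterministic given
    ``config.seed``.
    """
    gammas = config.gammas
    b_crit = [binomial_critical_value(config.S, g, config.alpha) for g in gammas]
    streams = np.random.SeedSequence(config.seed).spawn(config.n_trials)

    n_g = len(gammas)
    pow_acc = np.zeros((config.n_trials, n_g))
    fdp_acc = np.zeros((config.n_trials, n_g))
    rej_acc = np.zeros((config.n_trials, n_g), dtype=bool)
    bh_pow = np.zeros(config.n_trials)
    bh_fdp = np.zeros(config.n_trials)
    bh_rej = np.zeros(config.n_trials, dtype=bool)

    for t, ss in enumerate(streams):
        rng = np.random.Generator(np.random.PCG64(ss))
        pset = generate_pvalues(config.S, config.effect_proportion, config.w, rng)
        powers, fdps, n_decl, bp, bf, bR = _trial_metrics(
            pset.pvalues,
            pset.truth,
            gammas,
            b_crit,
            config.alpha,
            config.capped,
            config.bh_fdr,
        )
        pow_acc[t] = powers
        fdp_acc[t] = fdps
        rej_acc[t] = n_decl > 0
        bh_pow[t] = bp
        bh_fdp[t] = bf
        bh_rej[t] = bR > 0

    has_effects = config.n_effects_true > 0
    n = config.n_trials

    def se(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")

    rows = []
    for j, g in enumerate(gammas):
        rows.append(
            {
                "method": f"SGoF({g:g})",
                "gamma": g,
                "power": float(pow_acc[:, j].mean()) if has_effects else np.nan,
                "power_se": se(pow_acc[:, j]) if has_effects else np.nan,
                "fdr": float(fdp_acc[:, j].mean()),
                "fdr_se": se(fdp_acc[:, j]),
                "rejection_rate": float(rej_acc[:, j].mean()),
                "n_trials": n,
            }
        )
    rows.append(
        {
            "method": "BH",
            "gamma": np.nan,
            "power": float(bh_pow.mean()) if has_effects else np.nan,
            "power_se": se(bh_pow) if has_effects else np.nan,
            "fdr": float(bh_fdp.mean()),
            "fdr_se": se(bh_fdp),
            "rejection_rate": float(bh_rej.mean()),
            "n_trials": n,
        }
    )
    return SimulationSummary(config=config, table=pd.DataFrame(rows))


def write_summary_tsv(summary: SimulationSummary, path) -> None:
    """Write a two-row (Power / FDR) table with one column per method."""
    tab = summary.table
    cfg = summary.config
    label = f"{cfg.effect_proportion:.0%} w={cfg.w:g}"
    wide = pd.DataFrame(
        {row["method"]: [row["power"], row["fdr"]] for _, row in tab.iterrows()},
        index=pd.MultiIndex.from_product([[label], ["Power", "FDR"]]),
    )
    wide.to_csv(path, sep="\t", na_rep="NA")
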