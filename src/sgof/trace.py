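"""Significance trace of SGoF over a grid of gamma values.

Sweeping the working threshold gamma over (0, 1) turns a single SGoF run
into a trace of four per-gamma quantities: the exact binomial meta p-value
p(gamma) (shown on the log scale), the declared-effect count N_alpha(gamma),
the plug-in estimated FDR, and the realised p-value threshold q_alpha(gamma).
Plotted together these four panels summarise how much significance the data
carry against the complete null at every gamma, and what each choice of
gamma would cost in false discoveries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import META_PVALUE_FLOOR, PValueSet, SGoFParams, SGoFResult, pi0_estimate, sgof

__all__ = [
    "TracePoint",
    "Trace",
    "TraceSummary",
    "default_gamma_grid",
    "compute_trace",
    "trace_table",
    "write_trace_tsv",
    "render_trace",
]


@dataclass(frozen=True)
class TracePoint:
    """Per-gamma quartet of the trace, plus the achieved count under ties."""

    gamma: float
    meta_pvalue: float
    log_meta_pvalue: float
    n_effects: int
    efdr: Optional[float]
    threshold: Optional[float]
    achieved_count: int


@dataclass(frozen=True)
class TraceSummary:
    """Grid point with the largest declared-effect count.

    On ties the smallest gamma attaining the maximum is reported: a smaller
    gamma gives a stricter p-value threshold at equal power.
    """

    gamma_at_max_n: float
    max_n: int
    efdr_at_max_n: Optional[float]
    threshold_at_max_n: Optional[float]


@dataclass(frozen=True)
class Trace:
    points: tuple[TracePoint, ...]
    pi0: float
    alpha: float
    summary: TraceSummary


def default_gamma_grid() -> np.ndarray:
    """The default grid 0.01, 0.02, ..., 0.99 (99 values)."""
    return np.round(np.arange(1, 100) / 100.0, 2)


def compute_trace(
    pset: PValueSet,
    gamma_grid: Optional[Sequence[float]] = None,
    alpha: float = 0.05,
    capped: bool = False,
) -> Trace:
    """Evaluate SGoF at every gamma of the grid.

    Each point is exactly the output of a standalone :func:`sgof.core.sgof`
    call at that gamma; pi0 is estimated once from the full p-value set.
    The grid must be strictly increasing inside (0, 1).
    """
    if len(pset) == 0:
        raise ValueError("compute_trace requires a non-empty p-value set")
    grid = default_gamma_grid() if gamma_grid is None else np.asarray(gamma_grid, float)
    if grid.size == 0:
        raise ValueError("gamma grid must be non-empty")
    if np.any((grid <= 0.0) | (grid >= 1.0)):
        raise ValueError("every grid gamma must lie strictly inside (0, 1)")
    if np.any(np.diff(grid) <= 0.0):
        raise ValueError("gamma grid must be strictly increasing")

    pi0 = pi0_estimate(pset.pvalues)
    points = []
    for g in grid:
        r: SGoFResult = sgof(pset, SGoFParams(gamma=float(g), alpha=alpha, capped=capped))
        points.append(
            TracePoint(
                gamma=float(g),
                meta_pvalue=r.meta_pvalue,
                log_meta_pvalue=math.log(max(r.meta_pvalue, META_PVALUE_FLOOR)),
                n_effects=r.n_effects,
                efdr=r.efdr,
                threshold=r.threshold,
                achieved_count=r.achieved_count,
            )
        )

    best = max(range(len(points)), key=lambda i: (points[i].n_effects, -i))
    summary = TraceSummary(
        gamma_at_max_n=points[best].gamma,
        max_n=points[best].n_effects,
        efdr_at_max_n=points[best].efdr,
        threshold_at_max_n=points[best].threshold,
    )
    return Trace(points=tuple(points), pi0=pi0, alpha=alpha, summary=summary)


def trace_table(trace: Trace) -> pd.DataFrame:
    """Trace as a DataFrame (one row per gamma); None rendered as NaN."""
    return pd.DataFrame(
        {
            "gamma": [p.gamma for p in trace.points],
            "meta_pvalue": [p.meta_pvalue for p in trace.points],
            "log_meta_pvalue": [p.log_meta_pvalue for p in trace.points],
            "n_effects": [p.n_effects for p in trace.points],
            "efdr": [np.nan if p.efdr is None else p.efdr for p in trace.points],
            "threshold": [
                np.nan if p.threshold is None else p.threshold for p in trace.points
            ],
            "achieved_count": [p.achieved_count for p in trace.points],
        }
    )


def write_trace_tsv(trace: Trace, path) -> None:
    """Write the trace table as TSV; missing values encoded as ``NA``."""
    trace_table(trace).to_csv(path, sep="\t", index=False, na_rep="NA")


def render_trace(trace: Trace, output_path) -> None:
    """Render the four-panel trace figure to ``output_path``.

    (A) log meta p-value vs gamma with a horizontal dashed line at log(alpha);
    (B) declared effects vs gamma; (C) estimated FDR vs gamma; (D) p-value
    threshold vs gamma.  The file format follows the path extension.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not trace.points:
        raise ValueError("cannot render an empty trace")

    tab = trace_table(trace)
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    (ax_a, ax_b), (ax_c, ax_d) = axes

    ax_a.plot(tab["gamma"], tab["log_meta_pvalue"], color="C0")
    ax_a.axhline(math.log(trace.alpha), linestyle="--", color="black", linewidth=1)
    ax_a.set_ylabel("log p(γ)")
    ax_a.set_title("A")

    ax_b.plot(tab["gamma"], tab["n_effects"], color="C1")
    ax_b.set_ylabel("declared effects N(γ)")
    ax_b.set_title("B")

    ax_c.plot(tab["gamma"], tab["efdr"], color="C2")
    ax_c.set_ylabel("estimated FDR")
    ax_c.set_title("C")

    ax_d.plot(tab["gamma"], tab["threshold"], color="C3")
    ax_d.set_ylabel("threshold q(γ)")
    ax_d.set_title("D")

    for ax in (ax_a, ax_b, ax_c, ax_d):
        ax.set_xlabel("γ")
    fig.tight_layout()
    fig.savefig(output_path)
    plt.close(fig)
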