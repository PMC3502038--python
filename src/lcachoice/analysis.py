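"""Within-trial preference reversals, condition summaries, curve comparison.

A within-trial preference reversal occurs when each response unit dominates
the other by more than a small margin at some point of the same trial --
the network's "change of mind".  Reversal counts per participant, together
with the hyperbolic discount rates, are summarised per cell of the 2x2
threshold-by-framing design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import Condition, ModelParameters, TrialResult, default_reversal_epsilon
from .paradigm import CELLS, ConditionAssignment
from .psychfit import DiscountFit, IndifferenceCurve

__all__ = [
    "ConditionSummary",
    "is_reversal_trial",
    "count_reversal_trials",
    "summarize_conditions",
    "summary_frame",
    "curve_frame",
    "correlate_curves",
]


@dataclass
class ConditionSummary:
    """Mean/SD of k and reversal counts for one cell of the 2x2 design."""

    cell: Condition
    n_participants: int
    mean_k: float
    sd_k: float
    mean_reversals: float
    sd_reversals: float
    #: interval -> mean indifference ratio over the cell's participants
    mean_curve: dict[int, float] = field(default_factory=dict)
    #: interval -> standard error of that mean
    curve_se: dict[int, float] = field(default_factory=dict)
    #: True when n == 1 and the sample SD is undefined (reported as 0)
    sd_undefined: bool = False


def is_reversal_trial(trace: np.ndarray, epsilon: float) -> bool:
    """Both response units dominant by more than ``epsilon`` at some step.

    ``trace`` has shape (2, n_steps): row 0 the sooner unit, row 1 the later
    unit.  The trial counts iff there are steps s1, s2 with
    x_sooner(s1) - x_later(s1) > eps and x_later(s2) - x_sooner(s2) > eps.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[0] != 2 or trace.shape[1] == 0:
        raise ValueError(f"trace must have shape (2, n_steps), got {trace.shape}")
    diff = trace[0] - trace[1]
    return bool((diff > epsilon).any() and (diff < -epsilon).any())


def count_reversal_trials(
    results: list[TrialResult],
    epsilon: float | None = None,
    p: ModelParameters | None = None,
) -> int:
    """Number of trials of one participant showing a dominance reversal.

    ``epsilon`` defaults to 1% of the low response threshold, suppressing
    numerical jitter around zero; pass it explicitly to override.
    """
    if epsilon is None:
        if p is None:
            raise ValueError("provide epsilon or a ModelParameters to derive it from")
        epsilon = default_reversal_epsilon(p)
    for i, r in enumerate(results):
        if r.trace is None or np.asarray(r.trace).size == 0:
            raise ValueError(f"trial {i} has no activation trace")
    return sum(is_reversal_trial(r.trace, epsilon) for r in results)


def _sample_sd(x: np.ndarray) -> tuple[float, bool]:
    if len(x) < 2:
        return 0.0, True
    return float(np.std(x, ddof=1)), False


def summarize_conditions(
    fits: list[DiscountFit],
    reversal_counts: dict[object, int],
    assignments: list[ConditionAssignment],
    curves: list[IndifferenceCurve] | None = None,
) -> list[ConditionSummary]:
    """Per-cell sample mean and SD (n-1) of k and of reversal counts.

    Every participant in ``fits`` must appear in ``assignments`` and
    ``reversal_counts``.  Participants whose discount fit is invalid are
    excluded from the k statistics but still counted for reversals.  When
    ``curves`` are given, the cell's mean indifference ratio per interval is
    attached.
    """
    cond_of = {a.participant_id: a.condition for a in assignments}
    missing = [f.participant_id for f in fits if f.participant_id not in cond_of]
    if missing:
        raise ValueError(f"participants without a condition assignment: {missing}")
    missing = [f.participant_id for f in fits if f.participant_id not in reversal_counts]
    if missing:
        raise ValueError(f"participants without a reversal count: {missing}")
    curve_of = {c.participant_id: c for c in (curves or [])}

    summaries = []
    for cell in CELLS:
        members = [f for f in fits if cond_of[f.participant_id] == cell]
        if not members:
            continue
        ks = np.array([f.k for f in members if f.valid and np.isfinite(f.k)])
        revs = np.array([reversal_counts[f.participant_id] for f in members], dtype=float)
        sd_k, und_k = _sample_sd(ks)
        sd_r, und_r = _sample_sd(revs)
        mean_curve: dict[int, float] = {}
        curve_se: dict[int, float] = {}
        cell_curves = [curve_of[f.participant_id] for f in members if f.participant_id in curve_of]
        if cell_curves:
            intervals = sorted({d for c in cell_curves for d in c.points})
            for d in intervals:
                vals = [c.points[d] for c in cell_curves if d in c.points and np.isfinite(c.points[d])]
                if vals:
                    mean_curve[d] = float(np.mean(vals))
                    curve_se[d] = (
                        float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                        if len(vals) > 1 else 0.0
                    )
        summaries.append(
            ConditionSummary(
                cell=cell,
                n_participants=len(members),
                mean_k=float(np.mean(ks)) if len(ks) else np.nan,
                sd_k=sd_k,
                mean_reversals=float(np.mean(revs)),
                sd_reversals=sd_r,
                mean_curve=mean_curve,
                curve_se=curve_se,
                sd_undefined=und_k or und_r,
            )
        )
    return summaries


def summary_frame(summaries: list[ConditionSummary]) -> pd.DataFrame:
    """CSV-ready table: one row per design cell."""
    return pd.DataFrame(
        {
            "cell": [s.cell.label for s in summaries],
            "threshold_condition": [s.cell.threshold for s in summaries],
            "framing_condition": [s.cell.framing for s in summaries],
            "n": [s.n_participants for s in summaries],
            "mean_k": [s.mean_k for s in summaries],
            "sd_k": [s.sd_k for s in summaries],
            "mean_reversals": [s.mean_reversals for s in summaries],
            "sd_reversals": [s.sd_reversals for s in summaries],
        }
    )


def curve_frame(summaries: list[ConditionSummary]) -> pd.DataFrame:
    """Long-format mean indifference curves: cell x interval."""
    rows = []
    for s in summaries:
        for d, v in sorted(s.mean_curve.items()):
            rows.append({
                "cell": s.cell.label,
                "interval": d,
                "mean_indifference_ratio": v,
                "se": s.curve_se.get(d, np.nan),
            })
    return pd.DataFrame(rows)


def correlate_curves(curve_a, curve_b) -> float:
    """Squared Pearson correlation between two (concatenated) mean curves.

    Both inputs must live on the same grid and contain >= 3 points; zero
    variance in either makes the correlation undefined and raises.
    """
    a = np.asarray(curve_a, dtype=float).ravel()
    b = np.asarray(curve_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"curves differ in length: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("need at least 3 points to correlate curves")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("curve with zero variance: correlation undefined")
    r = stats.pearsonr(a, b).statistic
    return float(r * r)
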