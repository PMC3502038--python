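"""Two-step temporal-discounting analysis.

Step 1: for every participant and inter-option interval, estimate the
indifference point -- the sooner/later value ratio at which the participant
chooses either option with probability one half -- as the inflection of a
logistic psychometric function fitted by maximum likelihood to the binary
choices over value ratios.

Step 2: fit the single-parameter hyperbola V(D) = 1 / (1 + k*D) to each
participant's indifference ratios over intervals D (days) by bounded least
squares and report the discount rate k (1/days).  Larger k means steeper
discounting.

Both steps work on any choice table with the standard schema, whether it
came from the network simulation, from the fixture generator, or from a
behavioural experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

__all__ = [
    "CHOICE_TABLE_COLUMNS",
    "IndifferencePoint",
    "IndifferenceCurve",
    "DiscountFit",
    "ChoiceTableError",
    "validate_choice_table",
    "fit_indifference_point",
    "fit_hyperbolic_k",
    "indifference_curves",
    "pool_and_fit",
    "hyperbola",
]

CHOICE_TABLE_COLUMNS = [
    "participant_id",
    "threshold_condition",
    "framing_condition",
    "sooner_delay_days",
    "later_delay_days",
    "sooner_value",
    "later_value",
    "choice",
]

#: estimated indifference ratios are clipped into this half-open interval
RATIO_CLIP = (1e-6, 1.05)

#: slope value reported for perfectly separated (step-function) choice data
SEPARATED_SLOPE = np.inf


class ChoiceTableError(ValueError):
    """Raised when a choice table violates the schema; lists offending rows."""


@dataclass(frozen=True)
class IndifferencePoint:
    """Logistic inflection estimate for one interval."""

    ratio: float          # r0, the sooner/later ratio at P(later) = 1/2
    slope: float          # logistic steepness s in P(later) = expit(-s*(r - r0))
    converged: bool
    boundary: bool        # all choices one-sided; ratio pinned to the data edge

    @property
    def valid(self) -> bool:
        return self.converged and not self.boundary


@dataclass
class IndifferenceCurve:
    """Per-participant indifference ratio per inter-option interval."""

    participant_id: object
    points: dict[int, float]
    diagnostics: dict[int, IndifferencePoint] = field(default_factory=dict)

    def valid_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Intervals and ratios of the usable points, sorted by interval."""
        items = sorted(
            (d, r) for d, r in self.points.items() if np.isfinite(r)
        )
        if not items:
            return np.array([]), np.array([])
        d, r = zip(*items)
        return np.asarray(d, dtype=float), np.asarray(r, dtype=float)


@dataclass(frozen=True)
class DiscountFit:
    """Hyperbolic discount rate for one participant."""

    participant_id: object
    k: float              # 1/days, >= 0; NaN when the fit was impossible
    sse: float
    n_points: int
    valid: bool = True
    warn_nondecreasing: bool = False


def hyperbola(D, k: float):
    """Single-parameter hyperbolic discounting curve V(D) = 1 / (1 + k*D)."""
    return 1.0 / (1.0 + k * np.asarray(D, dtype=float))


def validate_choice_table(table: pd.DataFrame) -> None:
    """Check the choice-table schema; raise listing every offending row."""
    missing = [c for c in CHOICE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ChoiceTableError(f"missing columns: {missing}")
    if len(table) == 0:
        raise ChoiceTableError("choice table is empty")
    bad: dict[str, list] = {}

    def record(mask, reason):
        idx = table.index[np.asarray(mask)].tolist()
        if idx:
            bad[reason] = idx

    record(~table["choice"].isin(["sooner", "later"]),
           "choice must be 'sooner' or 'later' (timeouts are excluded upstream)")
    record(table["sooner_delay_days"] < 0, "negative sooner delay")
    record(table["later_delay_days"] <= table["sooner_delay_days"],
           "later delay must exceed sooner delay")
    record(table["sooner_value"] <= 0, "non-positive sooner value")
    record(table["later_value"] < table["sooner_value"],
           "later value must be >= sooner value")
    if bad:
        lines = [f"  {reason}: rows {idx[:20]}" for reason, idx in bad.items()]
        raise ChoiceTableError("invalid choice table:\n" + "\n".join(lines))


def _logistic_nll(params: np.ndarray, r: np.ndarray, y: np.ndarray) -> float:
    r0, log_s = params
    s = np.exp(min(log_s, 13.0))
    eta = -s * (r - r0)          # log-odds of choosing later
    # -sum[y*log p + (1-y)*log(1-p)] with p = expit(eta)
    return float(np.sum(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1 - y)))


def fit_indifference_point(
    ratios: np.ndarray,
    chose_later: np.ndarray,
) -> IndifferencePoint:
    """Maximum-likelihood logistic inflection over sooner/later value ratios.

    Fits P(choose later) = 1 / (1 + exp(s*(r - r0))) to the binary choices
    ``chose_later`` observed at value ratios ``ratios`` and returns r0.

    Degenerate data are handled without exceptions: perfectly one-sided
    choices give a boundary estimate at the observed edge ratio; perfectly
    separated (step-like) data give the midpoint of the separating gap with
    an infinite slope.
    """
    r = np.asarray(ratios, dtype=float)
    y = np.asarray(chose_later, dtype=bool)
    if r.shape != y.shape or r.ndim != 1 or len(r) == 0:
        raise ValueError("ratios and chose_later must be equal-length 1-d arrays")
    if len(np.unique(r)) < 2:
        raise ValueError("need choices at >= 2 distinct value ratios")

    def clip(x: float) -> float:
        return float(min(max(x, RATIO_CLIP[0]), RATIO_CLIP[1]))

    if y.all():
        return IndifferencePoint(clip(r.max()), SEPARATED_SLOPE, True, True)
    if not y.any():
        return IndifferencePoint(clip(r.min()), SEPARATED_SLOPE, True, True)

    hi_later = r[y].max()        # largest ratio at which "later" was chosen
    lo_sooner = r[~y].min()      # smallest ratio at which "sooner" was chosen
    if hi_later < lo_sooner:
        # perfect separation: any r0 in the gap maximises the likelihood
        return IndifferencePoint(
            clip(0.5 * (hi_later + lo_sooner)), SEPARATED_SLOPE, True, False
        )

    best = None
    starts = [
        (r0, np.log(s0))
        for r0 in (np.median(r), hi_later, lo_sooner, 0.5 * (hi_later + lo_sooner))
        for s0 in (5.0, 25.0)
    ]
    for x0 in starts:
        res = optimize.minimize(
            _logistic_nll, x0=np.asarray(x0), args=(r, y), method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    converged = bool(best.success) and np.isfinite(best.fun)
    r0 = clip(best.x[0])
    slope = float(np.exp(min(best.x[1], 13.0)))
    return IndifferencePoint(r0, slope, converged, False)


#: log-spaced multistart grid for the hyperbolic k fit
_K_STARTS = np.array([1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0])


def fit_hyperbolic_k(
    curve: IndifferenceCurve | tuple[np.ndarray, np.ndarray],
    participant_id: object | None = None,
) -> DiscountFit:
    """Bounded least-squares fit of V(D) = 1/(1+k*D) to indifference points.

    Accepts an :class:`IndifferenceCurve` or a bare ``(intervals, ratios)``
    pair.  k is constrained non-negative; a multistart over log-spaced
    initial values guards against the flat likelihood at small k, ties
    resolved by lowest SSE then smallest k.  Indifference ratios that do not
    decrease with the interval yield k = 0 with a warning flag.
    """
    if isinstance(curve, IndifferenceCurve):
        D, V = curve.valid_points()
        pid = curve.participant_id if participant_id is None else participant_id
    else:
        D, V = np.asarray(curve[0], dtype=float), np.asarray(curve[1], dtype=float)
        pid = participant_id
    if len(D) < 3:
        raise ValueError(
            f"participant {pid!r}: need >= 3 indifference points, got {len(D)}"
        )

    # boundary candidate first: exact k = 0 (no discounting)
    best_k, best_sse = 0.0, float(np.sum((V - 1.0) ** 2))
    for k0 in _K_STARTS:
        res = optimize.least_squares(
            lambda k: hyperbola(D, k[0]) - V,
            x0=[k0], bounds=([0.0], [np.inf]), method="trf", xtol=1e-14, ftol=1e-14,
        )
        sse = float(np.sum(res.fun**2))
        k = float(res.x[0])
        if sse < best_sse - 1e-15 or (abs(sse - best_sse) <= 1e-15 and (best_k is None or k < best_k)):
            best_k, best_sse = k, sse

    slope = np.polyfit(D, V, 1)[0] if len(np.unique(D)) > 1 else 0.0
    nondecreasing = bool(slope > 1e-12)
    if nondecreasing:
        best_k = 0.0
        best_sse = float(np.sum((V - 1.0) ** 2))
        warnings.warn(
            f"participant {pid!r}: indifference ratios do not decrease with "
            "the interval; reporting k = 0", stacklevel=2,
        )
    return DiscountFit(
        participant_id=pid, k=best_k, sse=best_sse, n_points=len(D),
        valid=True, warn_nondecreasing=nondecreasing,
    )


def indifference_curves(table: pd.DataFrame) -> list[IndifferenceCurve]:
    """Step 1 for every participant: logistic inflection per interval.

    Intervals are ``later_delay_days - sooner_delay_days``; the two
    sooner-onset levels contribute to the same interval (choices pooled over
    onset).  Non-convergent fits become explicit missing points (NaN).
    """
    validate_choice_table(table)
    df = table.copy()
    df["interval"] = df["later_delay_days"] - df["sooner_delay_days"]
    df["ratio"] = df["sooner_value"] / df["later_value"]
    df["chose_later"] = df["choice"] == "later"
    curves = []
    for pid, grp in df.groupby("participant_id", sort=True):
        points: dict[int, float] = {}
        diags: dict[int, IndifferencePoint] = {}
        for interval, sub in grp.groupby("interval", sort=True):
            pt = fit_indifference_point(sub["ratio"].to_numpy(), sub["chose_later"].to_numpy())
            diags[int(interval)] = pt
            points[int(interval)] = pt.ratio if pt.converged else np.nan
        curves.append(IndifferenceCurve(pid, points, diags))
    return curves


def pool_and_fit(table: pd.DataFrame) -> list[DiscountFit]:
    """Full two-step pipeline: per-participant indifference points, then k.

    Participants with fewer than three usable indifference points receive an
    invalid :class:`DiscountFit` (k = NaN) rather than being dropped.
    """
    fits = []
    for curve in indifference_curves(table):
        D, _ = curve.valid_points()
        if len(D) < 3:
            fits.append(
                DiscountFit(curve.participant_id, np.nan, np.nan, len(D), valid=False)
            )
        else:
            fits.append(fit_hyperbolic_k(curve))
    return fits
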