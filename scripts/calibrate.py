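"""Calibrate the network's default parameters to the reference condition means.

The model's qualitative predictions (threshold-by-framing interaction,
within-trial preference reversals) hold over a wide region of parameter
space, but the shipped defaults are additionally required to reproduce the
reference simulation statistics of the 2x2 paradigm:

    mean hyperbolic k per cell   : fast/low 0.077, fast/high 0.047,
                                   slow/low 0.026, slow/high 0.027  (1/days)
    mean reversal trials per cell: fast/high 26.31, fast/low 22,
                                   slow/low 4.62, slow/high 2.92    (of 72)

with near-equal k in the two slow cells.  This script measures a parameter
set against those statistics and, with --optimize, refines it by a simple
stochastic hill-climb (random multiplicative perturbations, accept on
improvement).  The error for each statistic is normalised by twice the
reference between-participant SD; timeout trials are penalised.

Usage:
    python scripts/calibrate.py --params src/lcachoice/data/default_params.yaml
    python scripts/calibrate.py --optimize 200 --seed 7 --out calibrated.yaml
"""

from __future__ import annotations

import argparse
import json
import warnings
from pathlib import Path

import numpy as np

import lcachoice as lc
from lcachoice import analysis, psychfit
from lcachoice.cli_io import run_simulation

#: reference condition means and between-participant SDs (13 per cell)
REFERENCE = {
    "k": {
        "fast/low": (0.077, 0.006), "fast/high": (0.047, 0.004),
        "slow/low": (0.026, 0.003), "slow/high": (0.027, 0.004),
    },
    "reversals": {
        "fast/high": (26.31, 1.49), "fast/low": (22.0, 1.0),
        "slow/low": (4.62, 1.55), "slow/high": (2.92, 1.5),
    },
}

#: search box for the hill-climb
BOUNDS = {
    "time_compression": (0.12, 0.5), "tau_time_fast": (0.25, 1.6),
    "tau_value": (1.5, 4.0), "tau_time_slow": (1.8, 5.0),
    "tau_response": (0.8, 3.2), "threshold_low": (0.6, 1.3),
    "threshold_high": (0.75, 1.6), "self_excitation": (0.15, 0.9),
    "lateral_inhibition": (0.4, 1.3), "w_time": (0.55, 1.1),
    "w_value": (0.8, 1.3), "noise_sd": (0.001, 0.009),
    "sigmoid_gain": (3.0, 6.0), "sigmoid_center": (0.4, 0.75),
}


def measure(p: lc.ModelParameters, seed: int = 1, n: int = 20):
    """Cell means of k and reversal counts for an n-participant batch."""
    sim = run_simulation(p, "simulation", n, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fits = psychfit.pool_and_fit(sim.table)
    summaries = analysis.summarize_conditions(
        fits, sim.reversal_counts, sim.assignments
    )
    out = {}
    for s in summaries:
        out[s.cell.label] = {"k": s.mean_k, "reversals": s.mean_reversals}
    return out, sum(sim.timeout_counts.values())


def score(cells: dict, n_timeouts: int, n: int) -> float:
    s = 0.0
    for stat in ("k", "reversals"):
        for cell, (target, sd) in REFERENCE[stat].items():
            s += ((cells[cell][stat] - target) / (2.0 * sd)) ** 2
    # the slow cells should not differ appreciably in k
    gap = abs(cells["slow/low"]["k"] - cells["slow/high"]["k"])
    s += (max(0.0, gap - 0.004) / 0.002) ** 2
    return s + 2.0 * n_timeouts / n


def report(p: lc.ModelParameters, seed: int, n: int) -> float:
    cells, nto = measure(p, seed, n)
    print(f"{'cell':10s} {'mean k':>8s} {'target':>8s} {'mean rev':>9s} {'target':>7s}")
    for cell in ("fast/low", "fast/high", "slow/low", "slow/high"):
        print(
            f"{cell:10s} {cells[cell]['k']:8.4f} {REFERENCE['k'][cell][0]:8.3f}"
            f" {cells[cell]['reversals']:9.2f} {REFERENCE['reversals'][cell][0]:7.2f}"
        )
    s = score(cells, nto, n)
    print(f"timeout trials: {nto};  score: {s:.2f}")
    return s


def optimize(p: lc.ModelParameters, iters: int, seed: int, n: int) -> lc.ModelParameters:
    rng = np.random.default_rng(seed)
    cur = {k: getattr(p, k) for k in BOUNDS}
    cells, nto = measure(p.replace(**cur), 1, n)
    best = score(cells, nto, n)
    print(f"start score {best:.2f}")
    for it in range(iters):
        cand = dict(cur)
        for key in rng.choice(list(BOUNDS), size=rng.integers(1, 4), replace=False):
            lo, hi = BOUNDS[key]
            cand[key] = float(np.clip(cand[key] * np.exp(rng.normal(0, 0.06)), lo, hi))
        if cand["threshold_low"] >= cand["threshold_high"] - 0.05:
            continue
        try:
            cells, nto = measure(p.replace(**cand), 1, n)
        except (ValueError, FloatingPointError):
            continue
        s = score(cells, nto, n)
        if s < best:
            cur, best = cand, s
            print(f"[{it}] score {s:.2f}  " + json.dumps(
                {k: round(v, 4) for k, v in cur.items()}))
    return p.replace(**cur)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--params", type=Path, default=None,
                    help="YAML parameter file to evaluate (default: shipped set)")
    ap.add_argument("--optimize", type=int, default=0, metavar="ITERS",
                    help="run a hill-climb for ITERS iterations")
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n-participants", type=int, default=20)
    ap.add_argument("--out", type=Path, default=None,
                    help="write the (refined) parameter set to this YAML file")
    args = ap.parse_args()

    p = (lc.ModelParameters.from_yaml(args.params) if args.params
         else lc.default_parameters())
    if args.optimize:
        p = optimize(p, args.optimize, args.seed, args.n_participants)
    report(p, seed=1, n=max(args.n_participants, 20))
    if args.out:
        p.to_yaml(args.out)
        print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
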