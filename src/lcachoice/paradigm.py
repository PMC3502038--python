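"""Factorial choice designs and the 2x2 between-participant simulation batch.

The simulation paradigm crosses 6 inter-option intervals with 6 sooner/later
value ratios and 2 sooner-option onsets (72 trials per participant).  The
behavioural-experiment grid is larger (7 intervals x 8 ratios x 2 onsets x
2 later amounts, 224 trials).  Between participants, response threshold
(low/high) and time-framing (fast/slow accumulation) are crossed with equal
cell sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .model_core import (
    Condition,
    ModelParameters,
    Option,
    TrialResult,
    TrialSpec,
    simulate_trials,
)

__all__ = [
    "DesignPreset",
    "ConditionAssignment",
    "SIMULATION_PRESET",
    "EXPERIMENT_PRESET",
    "get_preset",
    "build_design",
    "assign_conditions",
    "simulate_participant",
    "design_frame",
]


@dataclass(frozen=True)
class DesignPreset:
    """Factor levels of a fully crossed intertemporal-choice design."""

    intervals: tuple[int, ...]
    ratios: tuple[float, ...]          # sooner value as % of the later value
    onsets: tuple[int, ...]            # delay of the sooner option, days
    later_values: tuple[float, ...]    # amount of the later option
    label: str = "custom"

    def __post_init__(self) -> None:
        for name in ("intervals", "ratios", "onsets", "later_values"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"design preset {self.label!r}: {name} is empty")
        if any(i <= 0 for i in self.intervals):
            raise ValueError("intervals must be strictly positive")
        if any(not (0 < r <= 100) for r in self.ratios):
            raise ValueError("ratios must lie in (0, 100]")

    @property
    def n_trials(self) -> int:
        return (
            len(self.intervals) * len(self.ratios)
            * len(self.onsets) * len(self.later_values)
        )


SIMULATION_PRESET = DesignPreset(
    intervals=(1, 3, 5, 8, 11, 14),
    ratios=(20, 50, 70, 85, 95, 99),
    onsets=(0, 7),
    later_values=(20.0,),
    label="simulation",
)

EXPERIMENT_PRESET = DesignPreset(
    intervals=(1, 2, 3, 5, 7, 10, 14),
    ratios=(20, 50, 70, 80, 88, 93, 97, 99),
    onsets=(0, 7),
    later_values=(19.68, 20.32),
    label="experiment",
)

_PRESETS = {"simulation": SIMULATION_PRESET, "experiment": EXPERIMENT_PRESET}

# fixed cell order used for round-robin condition assignment
CELLS: tuple[Condition, ...] = (
    Condition("low", "fast"),
    Condition("high", "fast"),
    Condition("low", "slow"),
    Condition("high", "slow"),
)


def get_preset(label: str) -> DesignPreset:
    try:
        return _PRESETS[label]
    except KeyError:
        raise ValueError(
            f"unknown preset {label!r}; available: {sorted(_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class ConditionAssignment:
    """One simulated participant's cell of the 2x2 design plus their RNG seed."""

    participant_id: int
    condition: Condition
    seed: int


def build_design(preset: DesignPreset) -> list[TrialSpec]:
    """Expand a preset into the full Cartesian product of trial specs.

    sooner.delay = onset, later.delay = onset + interval and
    sooner.value = ratio% of the later amount.  Order is deterministic:
    later_value (outer) x onset x interval x ratio (inner).
    """
    specs: list[TrialSpec] = []
    for trial_id, (lv, onset, interval, ratio) in enumerate(
        product(preset.later_values, preset.onsets, preset.intervals, preset.ratios)
    ):
        specs.append(
            TrialSpec(
                sooner=Option(delay_days=onset, value=ratio / 100.0 * lv),
                later=Option(delay_days=onset + interval, value=lv),
                meta={
                    "trial_id": trial_id,
                    "interval": interval,
                    "ratio_pct": ratio,
                    "onset": onset,
                    "later_value": lv,
                    "preset": preset.label,
                },
            )
        )
    return specs


def design_frame(design: list[TrialSpec]) -> pd.DataFrame:
    """Tabular view of a design, matching the export CSV schema."""
    return pd.DataFrame(
        {
            "trial_id": [t.meta["trial_id"] for t in design],
            "sooner_delay_days": [t.sooner.delay_days for t in design],
            "later_delay_days": [t.later.delay_days for t in design],
            "sooner_value": [t.sooner.value for t in design],
            "later_value": [t.later.value for t in design],
            "interval": [t.meta["interval"] for t in design],
            "ratio_pct": [t.meta["ratio_pct"] for t in design],
            "onset": [t.meta["onset"] for t in design],
        }
    )


def assign_conditions(n_participants: int, master_seed: int = 0) -> list[ConditionAssignment]:
    """Round-robin balanced 2x2 assignment with per-participant derived seeds.

    Participant ``i`` lands in cell ``i % 4`` and gets noise stream seed
    ``master_seed + i``, so cells share no stream and every cell holds
    exactly ``n_participants / 4`` members.
    """
    if n_participants % 4 != 0:
        raise ValueError(
            f"n_participants must be divisible by 4, got {n_participants}"
        )
    return [
        ConditionAssignment(
            participant_id=i,
            condition=CELLS[i % 4],
            seed=int(master_seed) + i,
        )
        for i in range(n_participants)
    ]


def simulate_participant(
    assignment: ConditionAssignment,
    design: list[TrialSpec],
    p: ModelParameters,
) -> list[TrialResult]:
    """Run one simulated participant through a (shuffled) design.

    Trial order is shuffled by the participant's own seeded generator, which
    also supplies the within-trial noise; the whole run is reproducible from
    the assignment.  Trials are dynamically independent (each starts at
    rest), so the shuffle only affects the mapping of noise to trials.
    """
    rng = np.random.default_rng(assignment.seed)
    order = rng.permutation(len(design))
    shuffled = [design[i] for i in order]
    return simulate_trials(shuffled, p, assignment.condition, rng)
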