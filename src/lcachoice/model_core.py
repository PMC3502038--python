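"""Three-layer leaky competing accumulator (LCA) network for intertemporal choice.

The network has two input layers -- one coding the delivery times of the two
options, one coding their monetary values -- and a response layer whose two
units race toward a decision threshold.  Within every layer the two units
excite themselves and inhibit each other laterally through a sigmoid
activation function, which yields competitive attractor dynamics.  Time is
rate-coded with logarithmic compression (longer delays -> less drive), value
is rate-coded linearly (larger amounts -> more drive), and each response unit
sums the sigmoid outputs of its time and value units.

Two experimental manipulations enter as parameters: the response threshold
(low = impulsive / little self-control, high = self-controlled) and the
timescale of the time layer (fast = delay framing, slow = calendar-date
framing).  A trial ends when a raw response-unit activation reaches the
threshold; the crossing unit is the choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "Option",
    "TrialSpec",
    "NetworkState",
    "TrialResult",
    "Condition",
    "sigmoid",
    "encode_time",
    "encode_value",
    "step_network",
    "run_trial",
    "simulate_trials",
    "default_reversal_epsilon",
]

ThresholdCondition = Literal["low", "high"]
FramingCondition = Literal["fast", "slow"]


@dataclass(frozen=True)
class Condition:
    """One cell of the 2x2 between-participant design.

    ``threshold``: "low" (impulsive) or "high" (self-controlled) response
    threshold.  ``framing``: "fast" (delay framing, quickly accumulating time
    information) or "slow" (date framing, slowly accumulating time
    information).
    """

    threshold: ThresholdCondition
    framing: FramingCondition

    def __post_init__(self) -> None:
        if self.threshold not in ("low", "high"):
            raise ValueError(f"threshold must be 'low' or 'high', got {self.threshold!r}")
        if self.framing not in ("fast", "slow"):
            raise ValueError(f"framing must be 'fast' or 'slow', got {self.framing!r}")

    @property
    def label(self) -> str:
        return f"{self.framing}/{self.threshold}"


@dataclass
class ModelParameters:
    """All network constants plus the 2x2 condition knobs.

    Time is dimensionless; one Euler step advances the network by ``dt`` time
    units.  The defaults are the package's calibrated reference set (see
    ``scripts/calibrate.py`` and docs/methods.md): they were chosen so that
    the simulated 2x2 paradigm reproduces the published condition means of
    the hyperbolic discount rate k and of the within-trial reversal counts.
    """

    dt: float = 0.05
    #: timescale of the value input layer
    tau_value: float = 3.093
    #: timescale of the response layer
    tau_response: float = 1.709
    #: time-layer timescale under delay framing (fast accumulation)
    tau_time_fast: float = 0.3
    #: time-layer timescale under date framing (slow accumulation)
    tau_time_slow: float = 2.7849
    #: per-unit decay coefficient
    leak: float = 1.0
    #: recurrent self-excitation gain (alpha)
    self_excitation: float = 0.52
    #: within-layer lateral inhibition gain (beta)
    lateral_inhibition: float = 0.75
    #: feed-forward weight, time unit -> response unit
    w_time: float = 0.714
    #: feed-forward weight, value unit -> response unit
    w_value: float = 1.0
    #: sigmoid slope (shared by every unit)
    sigmoid_gain: float = 4.2
    #: sigmoid midpoint (shared by every unit)
    sigmoid_center: float = 0.4
    #: SD of the per-step Gaussian input noise (scaled by sqrt(dt))
    noise_sd: float = 0.003
    #: response threshold, impulsive condition (raw activation)
    threshold_low: float = 1.03
    #: response threshold, self-controlled condition (raw activation)
    threshold_high: float = 1.14
    #: coefficient of the logarithmic delay compression
    time_compression: float = 0.2314
    #: trial timeout, in Euler steps
    max_steps: int = 1200
    #: drive of a zero-delay or reference-value input
    drive_max: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "dt", "tau_value", "tau_response", "tau_time_fast", "tau_time_slow",
            "leak", "time_compression", "drive_max", "sigmoid_gain",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.lateral_inhibition < 0:
            raise ValueError("lateral_inhibition must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.threshold_low < self.threshold_high:
            raise ValueError("threshold_low must be < threshold_high")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")

    def tau_time(self, framing: FramingCondition) -> float:
        return self.tau_time_fast if framing == "fast" else self.tau_time_slow

    def threshold(self, condition: ThresholdCondition) -> float:
        return self.threshold_low if condition == "low" else self.threshold_high

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValueError(f"{path}: expected a flat key/value mapping")
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def replace(self, **kw) -> "ModelParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class Option:
    """One dated, valued option: ``value`` currency units after ``delay_days``."""

    delay_days: int
    value: float

    def __post_init__(self) -> None:
        if self.delay_days < 0:
            raise ValueError(f"delay_days must be >= 0, got {self.delay_days}")
        if self.value < 0:
            raise ValueError(f"value must be >= 0, got {self.value}")


@dataclass(frozen=True)
class TrialSpec:
    """A sooner/smaller vs later/larger choice problem."""

    sooner: Option
    later: Option
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sooner.delay_days < self.later.delay_days:
            raise ValueError("sooner option must have the shorter delay")
        if not self.sooner.value <= self.later.value:
            raise ValueError("sooner option must not exceed the later value")


@dataclass
class NetworkState:
    """Unit activations of the three layers at one step (index 0 = sooner)."""

    x_time: np.ndarray
    x_value: np.ndarray
    x_response: np.ndarray
    step: int = 0

    @classmethod
    def zeros(cls) -> "NetworkState":
        return cls(np.zeros(2), np.zeros(2), np.zeros(2), 0)


@dataclass
class TrialResult:
    """Outcome of one simulated trial.

    ``trace`` holds the raw response-layer activations, shape (2, n_steps),
    row 0 = sooner unit, row 1 = later unit, including the crossing step.
    ``reversal`` flags whether each response unit dominated the other by at
    least the default epsilon margin at some step of the trial.
    """

    choice: Literal["sooner", "later", "timeout"]
    decision_steps: int
    trace: np.ndarray
    reversal: bool
    spec: TrialSpec | None = None


def default_reversal_epsilon(p: ModelParameters) -> float:
    """Dominance margin used when flagging within-trial preference reversals."""
    return 0.01 * p.threshold_low


def sigmoid(x, gain: float, center: float):
    """Logistic activation function 1 / (1 + exp(-gain * (x - center))).

    Strictly increasing, bounded in (0, 1), value 0.5 at ``x == center``.
    Accepts scalars or arrays.
    """
    if gain <= 0:
        raise ValueError(f"gain must be > 0, got {gain}")
    return 1.0 / (1.0 + np.exp(-gain * (np.asarray(x, dtype=float) - center)))


def encode_time(delay_days, p: ModelParameters):
    """Rate-code a delay as input drive with logarithmic compression.

    drive(d) = drive_max / (1 + c * ln(1 + d)), c = ``time_compression``.
    Zero delay maps to the full drive; the marginal drop shrinks with delay,
    mirroring the compressed subjective perception of long waits.
    """
    d = np.asarray(delay_days, dtype=float)
    if np.any(d < 0):
        raise ValueError("delay_days must be >= 0")
    return p.drive_max / (1.0 + p.time_compression * np.log1p(d))


def encode_value(value, reference: float, p: ModelParameters | None = None, *, drive_max: float | None = None):
    """Rate-code a monetary amount linearly relative to ``reference``.

    drive = drive_max * value / reference.  ``reference`` is the larger
    (later) amount of the trial, so the later unit receives the full drive.
    """
    if drive_max is None:
        drive_max = p.drive_max if p is not None else 1.0
    if reference <= 0:
        raise ValueError(f"reference must be > 0, got {reference}")
    v = np.asarray(value, dtype=float)
    if np.any(v < 0) or np.any(v > reference * (1 + 1e-12)):
        raise ValueError("value must satisfy 0 <= value <= reference")
    return drive_max * v / reference


def _layer_update(x: np.ndarray, drive: np.ndarray, tau: float, p: ModelParameters) -> np.ndarray:
    """Euler increment (without noise) for one two-unit layer.

    dx_i = (dt/tau) * (-leak*x_i + I_i + alpha*sig(x_i) - beta*sig(x_j))
    where j is the within-layer competitor of i.
    """
    s = sigmoid(x, p.sigmoid_gain, p.sigmoid_center)
    s_comp = s[..., ::-1]
    return (p.dt / tau) * (
        -p.leak * x + drive + p.self_excitation * s - p.lateral_inhibition * s_comp
    )


def trial_drives(trial: TrialSpec, p: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """Input drives (time_drives[2], value_drives[2]) for one trial, sooner first."""
    time_drives = encode_time(
        np.array([trial.sooner.delay_days, trial.later.delay_days]), p
    )
    ref = trial.later.value
    value_drives = encode_value(
        np.array([trial.sooner.value, trial.later.value]), ref, p
    )
    return time_drives, value_drives


def step_network(
    state: NetworkState,
    time_drives: np.ndarray,
    value_drives: np.ndarray,
    p: ModelParameters,
    condition: Condition,
    rng: np.random.Generator | None = None,
) -> NetworkState:
    """Advance the whole network by one Euler step.

    The time layer integrates with the framing condition's timescale; every
    response unit receives w_time*sig(x_time_i) + w_value*sig(x_value_i).
    With a ``rng``, each of the six units gets independent Gaussian input
    noise with SD ``noise_sd * sqrt(dt)``.
    """
    for arr in (state.x_time, state.x_value, state.x_response):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(
                f"non-finite activation at step {state.step}"
            )
    tau_t = p.tau_time(condition.framing)
    resp_drive = (
        p.w_time * sigmoid(state.x_time, p.sigmoid_gain, p.sigmoid_center)
        + p.w_value * sigmoid(state.x_value, p.sigmoid_gain, p.sigmoid_center)
    )
    new_time = state.x_time + _layer_update(state.x_time, time_drives, tau_t, p)
    new_value = state.x_value + _layer_update(state.x_value, value_drives, p.tau_value, p)
    new_resp = state.x_response + _layer_update(state.x_response, resp_drive, p.tau_response, p)
    if rng is not None and p.noise_sd > 0:
        noise = rng.normal(0.0, p.noise_sd * math.sqrt(p.dt), size=(1, 6))[0]
        new_time = new_time + noise[0:2]
        new_value = new_value + noise[2:4]
        new_resp = new_resp + noise[4:6]
    out = NetworkState(new_time, new_value, new_resp, state.step + 1)
    for arr in (out.x_time, out.x_value, out.x_response):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite activation produced at step {out.step}")
    return out


def simulate_trials(
    trials: list[TrialSpec],
    p: ModelParameters,
    condition: Condition,
    rng: np.random.Generator | None = None,
) -> list[TrialResult]:
    """Simulate a batch of trials with a shared noise stream (vectorized).

    All trials start from rest (zero activations) and run until their first
    raw response-layer threshold crossing, or until ``max_steps`` (timeout).
    Noise is drawn for every trial and step up front so that trial outcomes
    do not depend on when *other* trials of the batch finish, and so that
    the same seed yields the identical trajectory under a different
    threshold.  For a single trial the noise sequence matches a plain
    ``step_network`` loop with the same generator.
    """
    n = len(trials)
    if n == 0:
        return []
    tau_t = p.tau_time(condition.framing)
    threshold = p.threshold(condition.threshold)

    time_drives = np.empty((n, 2))
    value_drives = np.empty((n, 2))
    for i, t in enumerate(trials):
        time_drives[i], value_drives[i] = trial_drives(t, p)

    x_t = np.zeros((n, 2))
    x_v = np.zeros((n, 2))
    x_r = np.zeros((n, 2))
    sqrt_dt = math.sqrt(p.dt)

    traces = np.empty((p.max_steps, n, 2))
    crossed_at = np.full(n, -1, dtype=int)
    choice_idx = np.full(n, -1, dtype=int)
    active = np.ones(n, dtype=bool)

    def sig(x):
        return sigmoid(x, p.sigmoid_gain, p.sigmoid_center)

    for step in range(p.max_steps):
        if rng is not None and p.noise_sd > 0:
            noise = rng.normal(0.0, p.noise_sd * sqrt_dt, size=(n, 6))
        else:
            noise = None
        s_t, s_v, s_r = sig(x_t), sig(x_v), sig(x_r)
        resp_drive = p.w_time * s_t + p.w_value * s_v
        x_t = x_t + (p.dt / tau_t) * (
            -p.leak * x_t + time_drives + p.self_excitation * s_t
            - p.lateral_inhibition * s_t[:, ::-1]
        )
        x_v = x_v + (p.dt / p.tau_value) * (
            -p.leak * x_v + value_drives + p.self_excitation * s_v
            - p.lateral_inhibition * s_v[:, ::-1]
        )
        x_r = x_r + (p.dt / p.tau_response) * (
            -p.leak * x_r + resp_drive + p.self_excitation * s_r
            - p.lateral_inhibition * s_r[:, ::-1]
        )
        if noise is not None:
            x_t = x_t + noise[:, 0:2]
            x_v = x_v + noise[:, 2:4]
            x_r = x_r + noise[:, 4:6]
        if not (np.all(np.isfinite(x_t)) and np.all(np.isfinite(x_v)) and np.all(np.isfinite(x_r))):
            raise FloatingPointError(f"non-finite activation produced at step {step + 1}")
        traces[step] = x_r
        newly = active & (x_r >= threshold).any(axis=1)
        if newly.any():
            for i in np.flatnonzero(newly):
                over = x_r[i] >= threshold
                if over.all():
                    # simultaneous crossing: larger activation wins;
                    # an exact tie is resolved by a seeded coin flip
                    if x_r[i, 0] > x_r[i, 1]:
                        choice_idx[i] = 0
                    elif x_r[i, 1] > x_r[i, 0]:
                        choice_idx[i] = 1
                    else:
                        coin_rng = rng if rng is not None else np.random.default_rng(0)
                        choice_idx[i] = int(coin_rng.integers(0, 2))
                else:
                    choice_idx[i] = int(np.argmax(over))
                crossed_at[i] = step + 1
            active &= ~newly
        if not active.any():
            break

    eps = default_reversal_epsilon(p)
    results: list[TrialResult] = []
    labels = {0: "sooner", 1: "later", -1: "timeout"}
    for i, t in enumerate(trials):
        n_steps = crossed_at[i] if crossed_at[i] > 0 else p.max_steps
        trace = traces[:n_steps, i, :].T.copy()
        diff = trace[0] - trace[1]
        reversal = bool((diff > eps).any() and (-diff > eps).any())
        results.append(
            TrialResult(
                choice=labels[int(choice_idx[i])],
                decision_steps=int(n_steps),
                trace=trace,
                reversal=reversal,
                spec=t,
            )
        )
    return results


def run_trial(
    trial: TrialSpec,
    p: ModelParameters,
    condition: Condition,
    rng: np.random.Generator | None = None,
) -> TrialResult:
    """Simulate one trial from rest to threshold crossing (or timeout)."""
    return simulate_trials([trial], p, condition, rng)[0]
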