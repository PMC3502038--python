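"""Unit and property tests for the accumulator network."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lcachoice as lc
from lcachoice.model_core import (
    NetworkState,
    step_network,
    simulate_trials,
    trial_drives,
)


# ---------------------------------------------------------------------------
# activation function
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "x, gain, center, expected",
    [
        (0.5, 4.0, 0.5, 0.5),                        # value at the midpoint
        (0.75, 4.0, 0.5, 1.0 / (1.0 + math.exp(-1.0))),  # closed form
        (0.0, 2.0, 0.0, 0.5),
    ],
)
def test_sigmoid_closed_forms(x, gain, center, expected):
    assert lc.sigmoid(x, gain, center) == pytest.approx(expected, abs=1e-12)


def test_sigmoid_saturates():
    gain, center = 4.0, 0.5
    assert lc.sigmoid(center + 100.0 / gain, gain, center) > 0.999
    assert lc.sigmoid(center - 100.0 / gain, gain, center) < 0.001


@settings(derandomize=True, max_examples=200)
@given(
    x1=st.floats(-2, 2),
    dx=st.floats(1e-4, 1.0),
    gain=st.floats(0.1, 8),
    center=st.floats(-1, 1),
)
def test_sigmoid_monotone_bounded_symmetric(x1, dx, gain, center):
    # ranges keep gain*(x - center) away from float saturation
    lo, hi = lc.sigmoid(x1, gain, center), lc.sigmoid(x1 + dx, gain, center)
    assert 0.0 < lo < 1.0 and 0.0 < hi < 1.0
    assert hi > lo
    # point symmetry about (center, 1/2)
    s_plus = lc.sigmoid(center + dx, gain, center)
    s_minus = lc.sigmoid(center - dx, gain, center)
    assert s_plus + s_minus == pytest.approx(1.0, abs=1e-9)


def test_sigmoid_rejects_nonpositive_gain():
    with pytest.raises(ValueError):
        lc.sigmoid(0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# input encoding
# ---------------------------------------------------------------------------

def test_encode_time_anchor_and_monotone(params):
    assert lc.encode_time(0, params) == pytest.approx(params.drive_max)
    delays = [0, 1, 3, 5, 7, 8, 11, 14, 21]
    drives = [float(lc.encode_time(d, params)) for d in delays]
    assert all(a > b for a, b in zip(drives, drives[1:]))
    # logarithmic compression: marginal decrease shrinks with delay
    diffs = [a - b for a, b in zip(drives, drives[1:])]
    assert diffs[0] > diffs[-1]


def test_encode_time_closed_form():
    # drive = drive_max / (1 + c*ln(1+d)); c = 1, d = e-1 halves the drive
    p = lc.ModelParameters(time_compression=1.0, drive_max=1.0)
    assert lc.encode_time(math.e - 1.0, p) == pytest.approx(0.5, rel=1e-12)


def test_encode_time_rejects_negative(params):
    with pytest.raises(ValueError):
        lc.encode_time(-1, params)


def test_encode_value_linear(params):
    dm = params.drive_max
    assert lc.encode_value(20.0, 20.0, params) == pytest.approx(dm)
    assert lc.encode_value(0.0, 20.0, params) == 0.0
    assert lc.encode_value(17.0, 20.0, params) == pytest.approx(0.85 * dm)
    with pytest.raises(ValueError):
        lc.encode_value(1.0, 0.0, params)


# ---------------------------------------------------------------------------
# parameters and trial types
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kw",
    [
        dict(dt=0.0),
        dict(leak=-1.0),
        dict(lateral_inhibition=-0.1),
        dict(threshold_low=2.0, threshold_high=1.0),
        dict(noise_sd=-0.01),
        dict(max_steps=0),
        dict(time_compression=0.0),
    ],
)
def test_parameter_validation(kw):
    with pytest.raises(ValueError):
        lc.ModelParameters(**kw)


def test_parameters_yaml_roundtrip(tmp_path, params):
    path = tmp_path / "p.yaml"
    params.to_yaml(path)
    assert lc.ModelParameters.from_yaml(path) == params


def test_trial_spec_invariants():
    with pytest.raises(ValueError):
        lc.TrialSpec(lc.Option(5, 10.0), lc.Option(3, 20.0))  # delays reversed
    with pytest.raises(ValueError):
        lc.TrialSpec(lc.Option(0, 30.0), lc.Option(3, 20.0))  # values reversed
    with pytest.raises(ValueError):
        lc.Option(-1, 10.0)


# ---------------------------------------------------------------------------
# single Euler step
# ---------------------------------------------------------------------------

def _hand_step_from_zero():
    """Independent arithmetic of one update from rest, plain-float math.

    Parameters and drives are hand-picked; every term is written out from
    the update rule x_i += (dt/tau)*(-leak*x_i + I_i + a*sig(x_i) - b*sig(x_j)).
    """
    dt, leak, a, b = 0.1, 0.9, 0.6, 1.1
    tau_t, tau_v, tau_r = 0.5, 2.0, 1.0
    w_t, w_v = 0.8, 1.2
    g, c = 3.0, 0.4
    t_drv = (0.7, 0.3)
    v_drv = (0.5, 1.0)
    s0 = 1.0 / (1.0 + math.exp(-g * (0.0 - c)))     # sigmoid of every unit at rest
    # from x=0: dx = (dt/tau)*(I + a*s0 - b*s0)
    x_t = [(dt / tau_t) * (t_drv[i] + a * s0 - b * s0) for i in range(2)]
    x_v = [(dt / tau_v) * (v_drv[i] + a * s0 - b * s0) for i in range(2)]
    resp_in = w_t * s0 + w_v * s0                    # same for both units at rest
    x_r = [(dt / tau_r) * (resp_in + a * s0 - b * s0) for _ in range(2)]
    return (dt, leak, a, b, tau_t, tau_v, tau_r, w_t, w_v, g, c, t_drv, v_drv), (x_t, x_v, x_r)


def test_step_network_matches_hand_arithmetic():
    (dt, leak, a, b, tau_t, tau_v, tau_r, w_t, w_v, g, c, t_drv, v_drv), exp = _hand_step_from_zero()
    p = lc.ModelParameters(
        dt=dt, leak=leak, self_excitation=a, lateral_inhibition=b,
        tau_time_fast=tau_t, tau_value=tau_v, tau_response=tau_r,
        w_time=w_t, w_value=w_v, sigmoid_gain=g, sigmoid_center=c,
        noise_sd=0.0,
    )
    out = step_network(
        NetworkState.zeros(), np.array(t_drv), np.array(v_drv), p,
        lc.Condition("low", "fast"),
    )
    np.testing.assert_allclose(out.x_time, exp[0], atol=1e-12)
    np.testing.assert_allclose(out.x_value, exp[1], atol=1e-12)
    np.testing.assert_allclose(out.x_response, exp[2], atol=1e-12)
    assert out.step == 1


def test_step_network_fixed_point_persistence(params):
    """At a numerically relaxed rest point, one more step barely moves."""
    p = params.replace(noise_sd=0.0)
    cond = lc.Condition("low", "fast")
    drives = np.zeros(2)
    state = NetworkState.zeros()
    for _ in range(20000):
        state = step_network(state, drives, drives, p, cond)
    before = np.concatenate([state.x_time, state.x_value, state.x_response])
    after_state = step_network(state, drives, drives, p, cond)
    after = np.concatenate(
        [after_state.x_time, after_state.x_value, after_state.x_response]
    )
    assert np.max(np.abs(after - before)) < p.dt * 1e-6


def test_step_network_symmetric_drives_stay_symmetric(params):
    """Equal times and equal values: unit pairs identical at every step."""
    p = params.replace(noise_sd=0.0)
    cond = lc.Condition("high", "slow")
    t_drv = np.array([0.6, 0.6])
    v_drv = np.array([0.9, 0.9])
    state = NetworkState.zeros()
    for _ in range(500):
        state = step_network(state, t_drv, v_drv, p, cond)
        assert state.x_time[0] == state.x_time[1]
        assert state.x_value[0] == state.x_value[1]
        assert state.x_response[0] == state.x_response[1]


def test_step_network_rejects_nonfinite(params):
    state = NetworkState(np.array([np.inf, 0.0]), np.zeros(2), np.zeros(2), 7)
    with pytest.raises(FloatingPointError, match="step 7"):
        step_network(state, np.zeros(2), np.zeros(2), params, lc.Condition("low", "fast"))


def test_boundedness_noise_free(params):
    """Without noise, activations stay below the leak/input bound."""
    p = params.replace(noise_sd=0.0)
    cond = lc.Condition("high", "fast")
    bound = (p.w_time + p.w_value + p.self_excitation) / p.leak + 1.0
    for t_drv, v_drv in [((p.drive_max, 0.2), (0.2, p.drive_max)),
                         ((p.drive_max, p.drive_max), (p.drive_max, p.drive_max))]:
        state = NetworkState.zeros()
        for _ in range(5000):
            state = step_network(state, np.array(t_drv), np.array(v_drv), p, cond)
        big = max(np.max(np.abs(state.x_time)), np.max(np.abs(state.x_value)),
                  np.max(np.abs(state.x_response)))
        assert np.isfinite(big) and big < bound


def test_mirrored_drives_give_mirrored_dynamics(params):
    """Swapping both drive pairs swaps the unit trajectories exactly."""
    p = params.replace(noise_sd=0.0)
    cond = lc.Condition("low", "fast")
    t_drv = np.array([0.9, 0.4])
    v_drv = np.array([0.5, 1.0])
    s1 = NetworkState.zeros()
    s2 = NetworkState.zeros()
    for _ in range(300):
        s1 = step_network(s1, t_drv, v_drv, p, cond)
        s2 = step_network(s2, t_drv[::-1], v_drv[::-1], p, cond)
    np.testing.assert_allclose(s1.x_response, s2.x_response[::-1], atol=1e-12)
    np.testing.assert_allclose(s1.x_time, s2.x_time[::-1], atol=1e-12)


# ---------------------------------------------------------------------------
# whole trials
# ---------------------------------------------------------------------------

def test_run_trial_fast_low_prefers_sooner_on_tiny_value_gap(params):
    """Near-equal values, 14-day gap: early time dominance picks the sooner
    option in the impulsive fast-accumulation condition."""
    p = params.replace(noise_sd=0.0)
    trial = lc.TrialSpec(lc.Option(0, 20.0), lc.Option(14, 20.32))
    res = lc.run_trial(trial, p, lc.Condition("low", "fast"))
    assert res.choice == "sooner"
    assert 1 <= res.decision_steps <= p.max_steps
    assert res.trace.shape == (2, res.decision_steps)


def test_run_trial_timeout_is_explicit(params):
    p = params.replace(noise_sd=0.0, threshold_low=50.0, threshold_high=60.0,
                       max_steps=50)
    trial = lc.TrialSpec(lc.Option(0, 10.0), lc.Option(5, 20.0))
    res = lc.run_trial(trial, p, lc.Condition("low", "fast"))
    assert res.choice == "timeout"
    assert res.decision_steps == p.max_steps


def test_engine_matches_reference_step_loop(params):
    """The vectorized trial runner reproduces a plain step_network loop,
    including the noise stream, for a single trial."""
    p = params.replace(max_steps=400)
    cond = lc.Condition("high", "fast")
    trial = lc.TrialSpec(lc.Option(0, 17.0), lc.Option(8, 20.0))
    res = lc.run_trial(trial, p, cond, np.random.default_rng(99))

    t_drv, v_drv = trial_drives(trial, p)
    rng = np.random.default_rng(99)
    state = NetworkState.zeros()
    threshold = p.threshold(cond.threshold)
    ref = []
    for _ in range(p.max_steps):
        state = step_network(state, t_drv, v_drv, p, cond, rng)
        ref.append(state.x_response.copy())
        if (state.x_response >= threshold).any():
            break
    ref = np.array(ref).T
    assert res.decision_steps == ref.shape[1]
    np.testing.assert_allclose(res.trace, ref, atol=1e-12)


def test_threshold_raises_decision_time_under_matched_seeds(params, sim_design):
    """Same noise stream: a higher threshold never decides earlier."""
    trials = sim_design[:25]
    lo = simulate_trials(trials, params, lc.Condition("low", "fast"),
                         np.random.default_rng(7))
    hi = simulate_trials(trials, params, lc.Condition("high", "fast"),
                         np.random.default_rng(7))
    assert all(h.decision_steps >= l.decision_steps for l, h in zip(lo, hi))
    assert np.mean([h.decision_steps for h in hi]) > np.mean(
        [l.decision_steps for l in lo]
    )


def test_stochastic_choice_monotonicity(params):
    """P(sooner) rises with the sooner option's relative value and falls
    as the sooner option itself is delayed."""
    cond = lc.Condition("low", "fast")
    rng = np.random.default_rng(11)

    def p_sooner(onset, ratio, n=120):
        trials = [
            lc.TrialSpec(lc.Option(onset, ratio * 20.0), lc.Option(onset + 8, 20.0))
            for _ in range(n)
        ]
        res = simulate_trials(trials, params, cond, rng)
        return np.mean([r.choice == "sooner" for r in res])

    by_ratio = [p_sooner(0, r) for r in (0.2, 0.7, 0.99)]
    assert by_ratio[2] >= by_ratio[1] - 0.05
    assert by_ratio[1] >= by_ratio[0] - 0.05
    assert by_ratio[2] > by_ratio[0]
    # delaying the sooner option shrinks its time advantage
    assert p_sooner(7, 0.7) <= p_sooner(0, 0.7) + 0.05
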