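# Methods

## The model

`lcachoice` implements a three-layer leaky competing accumulator (LCA)
network for binary intertemporal choice. Two options are on offer: a
*sooner/smaller* reward (value `v_s` after `d_s` days) and a *later/larger*
reward (`v_l > v_s` after `d_l > d_s` days). Two input layers rate-code the
option attributes — one layer for delivery times, one for monetary values —
and project feed-forward onto a two-unit response layer. The unit whose raw
response activation first reaches the decision threshold determines the
choice.

Every unit `i` (competitor `j` in the same layer) follows the Euler-discretised
stochastic dynamics

    x_i <- x_i + (dt/tau_L) * [ -leak*x_i + I_i
                                + alpha*sig(x_i) - beta*sig(x_j) ]
                + Normal(0, noise_sd * sqrt(dt))

with the logistic activation function
`sig(x) = 1/(1 + exp(-gain*(x - center)))`. `alpha` is recurrent
self-excitation, `beta` within-layer lateral inhibition; both are shared by
all three layers, as is the sigmoid shape. Each trial starts from rest
(all activations zero).

Inputs:

* **Time coding** — longer delays yield weaker drive, with logarithmic
  compression: `I_time(d) = drive_max / (1 + c*ln(1+d))`, `c` the
  `time_compression` coefficient. This is the standard compressed
  subjective-time assumption; it is what bends the choice boundary into an
  approximately hyperbolic discounting curve.
* **Value coding** — linear in the amount, normalised by the trial's larger
  (later) amount: `I_value(v) = drive_max * v / v_l`, so the later unit
  always receives the full value drive and the sooner unit a fraction equal
  to the value ratio.
* **Response drive** — `I_resp,i = w_time*sig(x_time,i) + w_value*sig(x_value,i)`.

Two experimental factors enter as parameters, crossed between simulated
participants:

* **Response threshold** (`threshold_low` vs `threshold_high`, on the raw
  response activation): a low threshold models impulsive, low-self-control
  responding; a high threshold prolongs accumulation.
* **Time-layer timescale** (`tau_time_fast` vs `tau_time_slow`): delay
  framing lets time information accumulate quickly; calendar-date framing
  slows it down.

### Why the interaction emerges

With fast time accumulation the time layer settles well before the value
layer (`tau_time_fast << tau_value`), so early in a trial the response unit
of the sooner option — favoured by time — leads. A low threshold is often
reached during this time-dominated phase, producing steep discounting. A
high threshold leaves time for the later option's larger value signal to
catch up and, via lateral inhibition, to reverse the response-layer
dominance within the trial; discounting is weaker and within-trial
preference reversals are frequent. With slow time accumulation the time
advantage never dominates the early trial, both thresholds sample the same
(value-balanced) competition, and the threshold manipulation loses its
effect — reversals become rare and discounting shallow. This
threshold-by-framing interaction is the model's headline prediction.

## Simulated paradigm

The default design crosses 6 inter-option intervals (1, 3, 5, 8, 11, 14
days) with 6 sooner/later value ratios (20, 50, 70, 85, 95, 99% of the
later amount) and 2 sooner-option onsets (0 and 7 days): 72 trials per
participant, each presented once in per-participant shuffled order. A
second preset mirrors the larger behavioural-experiment grid (7 intervals x
8 ratios x 2 onsets x 2 later amounts of 19.68 and 20.32 currency units,
224 trials). 52 simulated participants are assigned round-robin to the four
threshold-by-framing cells (13 per cell). Participants differ *only* by
their noise stream (seed = master seed + participant index); there is no
parameter jitter, so all between-participant variance is accumulation
noise.

## Analysis pipeline

1. **Indifference points.** Per participant and interval (pooling the two
   onsets), P(choose later) is modelled as a logistic function of the value
   ratio r, `P = 1/(1+exp(s*(r - r0)))`, fitted by maximum likelihood on
   the binary choices; `r0` is the indifference point. One choice per
   design cell makes proportion-based least squares ill-posed, hence ML on
   binaries. Perfectly separated (step-like) data are handled analytically:
   the midpoint of the separating gap, flagged with an infinite slope;
   one-sided data yield a boundary estimate at the observed edge ratio,
   flagged. Estimates are clipped to (0, 1.05].
2. **Discount rate.** The single-parameter hyperbola `V(D) = 1/(1+kD)`
   (V the indifference ratio, D the interval in days) is fitted per
   participant by bounded least squares (k >= 0) with a log-spaced
   multistart (1e-4 … 10) plus the exact k = 0 boundary candidate; ties go
   to the lower SSE, then the smaller k. Non-decreasing indifference
   curves report k = 0 with a warning flag. At least 3 valid indifference
   points are required; participants below that are reported as invalid
   fits, never silently dropped.
3. **Reversals.** A trial counts as a within-trial preference reversal iff
   each response unit leads the other by more than a dominance margin
   epsilon at some step of its trace. The margin defaults to 1% of the low
   threshold, suppressing numerical jitter around zero; it is configurable.
4. **Summaries.** Per design cell: sample mean and SD (denominator n-1) of
   k and of the per-participant reversal counts, plus the cell-mean
   indifference curve. Curve-level agreement between two datasets is the
   squared Pearson correlation of their concatenated mean curves.

Timeout trials (no unit reached threshold within `max_steps`) contribute to
neither statistic: they are excluded from the fitting pipeline and from the
per-participant reversal counts (a trial that never reaches a decision is
not a completed choice, and its sub-threshold drift is not a
decision-relevant change of mind), and are reported as a per-participant
timeout count. With the default parameters about 2–3% of trials time out,
almost all of them near-indifference trials in the slow/high cell whose
winning unit equilibrates just below the high threshold.

## Default parameters and calibration

The defaults in `src/lcachoice/data/default_params.yaml` were produced by
`scripts/calibrate.py`, which scores a parameter set against the reference
condition statistics of the simulated paradigm (mean k of 0.077, 0.047,
0.026, 0.027 and mean reversal counts of 26.31, 22, 4.62, 2.92 in the
fast/low, fast/high, slow/low, slow/high cells, each normalised by twice
its between-participant SD, near-equality of the two slow-cell k means, and
a timeout penalty) and refines it by a stochastic hill-climb. The
qualitative interaction is robust over a wide parameter region; the
calibration pins the quantitative scale. Key scales of the shipped set: the
fast time layer is roughly an order of magnitude faster than the value
layer, while the slow time layer is of the same order as the value layer,
so that neither attribute dominates the early trial under date framing;
lateral
inhibition moderately exceeds self-excitation so that a leading unit
suppresses its competitor without locking the race against late-arriving
value evidence; the two thresholds bracket the activation range where the
time-led early phase hands over to the value-led late phase.

## Numerical choices and edge cases

* Integration step `dt = 0.05` dimensionless time units; all timescales are
  expressed in the same units, thresholds on raw (not sigmoid-transformed)
  activations so that threshold and sigmoid parameters stay independently
  interpretable.
* Noise is drawn for every unit, trial and step up front in the vectorised
  runner, so a trial's outcome does not depend on when other trials of the
  batch finish, and matched seeds give identical trajectories under both
  thresholds (used by the decision-time monotonicity test).
* Simultaneous threshold crossing: the unit with the larger activation
  wins; an exact tie falls to a seeded coin flip.
* Non-finite activations raise immediately with the offending step index.
* The logistic ML fit uses Nelder-Mead with multistart and a slope cap of
  e^13 to avoid overflow on quasi-separated data.

## What the synthetic fixture generator does and does not emulate

`generate_fixture` produces choice tables from ideal hyperbolic discounters
with logistic decision noise: P(later) = logistic(s * (1/(1+kD) - r)). It
shares the design grid and table schema with the simulation and provides
ground-truth k for end-to-end recovery tests of the fitting pipeline. It
does not emulate accumulation dynamics, decision times, reversals, or any
within-trial structure — passing recovery tests therefore validates the
*analysis* pipeline, not the network model; and neither fixture nor
simulation captures attributes of real data such as lapses, sequential
effects, or heterogeneous discounting styles across participants.

## Problem sizes

The shipped tests and the acceptance script use the reference scale
(52 participants x 72 trials) for the numeric checks and 20 participants
per master seed for the multi-seed interaction checks; a full
simulate-fit-summarise run at reference scale completes in well under a
minute on one CPU.

## Known limitations

* The simulated mean indifference curves are flatter than the hyperbolas
  implied by the fitted k values (curve-level r² against those hyperbolas
  is about 0.8 rather than above 0.95, although the fitted k values
  themselves match the reference cell means). Two causes: the logarithmic
  delay encoding makes the 0-to-1-day drive drop large relative to the
  7-to-21-day tail, so pooling the two onsets compresses the curve range;
  and at the low noise level the reversal-count calibration requires,
  choices are nearly deterministic, so per-interval logistic inflections
  quantize to midpoints of the ratio grid. Saturating the encoding (larger
  `drive_max`) steepens the curves but destroys the reversal-count pattern;
  the two constraints could not be met simultaneously with this encoding.

* The two slow-cell k means agree only approximately (the calibration
  enforces |difference| below the 0.005 used by the interaction check).
* The original network's exact parameter values were not available; the
  shipped defaults are a calibration that reproduces the reference
  condition statistics, not a transcription. All parameters live
  in one YAML file so a reference set can be dropped in verbatim.
* A small fraction of near-tie trials can deadlock below threshold and time
  out; they are excluded from fitting and reported, mirroring how empty
  cells are handled in behavioural pipelines.
* The model makes no claims about neural implementation; there is no
  learning, no inter-attribute inhibition, and no trial-order dependence
  (each trial starts from rest).
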