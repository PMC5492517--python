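# Methods

## Problem and signal model

Driver fatigue alters steering behaviour in a characteristic way: an alert
driver makes frequent, small, quick corrections around straight-ahead; a
drowsy driver corrects rarely but with larger amplitude and higher angular
velocity; a severely drowsy driver holds the wheel still for seconds at a
time and then swings it abruptly. The vehicle's yaw angle follows the
steering input through the (much slower) lateral dynamics. Both channels
are treated as uniformly sampled scalar time series in degrees at 100 Hz,
segmented into one-minute samples — the unit at which human experts can
assign a fatigue level from synchronized facial video.

Fatigue is a three-level ordinal label: 0 = awake, 1 = drowsy,
2 = very drowsy. Expert scores for a sample are resolved by unanimity;
a disagreement falls back to a negotiated level if one was recorded and is
otherwise discarded. Samples flagged as involving a curved road or a lane
shift are discarded too, since road curvature injects steering activity
unrelated to fatigue. Flags and scores arrive in a metadata CSV; detecting
curves from video is outside this package's scope.

## Approximate entropy

ApEn(m, r, N) measures the (ir)regularity of a window u(1)..u(N) as the
log-likelihood drop of pattern matches when the embedding dimension grows
from m to m+1:

    ApEn = (1/(N−m+1)) Σ_{i=1}^{N−m+1} ln C_i^m(r)
         − (1/(N−m))   Σ_{i=1}^{N−m}   ln C_i^{m+1}(r)

with C_i^k(r) = B_i/(N−k+1), B_i the number of embedded vectors within
Chebyshev distance r of X(i). Numerical conventions, each switchable where
noted:

* **Self-matches are counted** (the original formulation), so every
  C_i > 0 and the logs are finite even at r = 0; a constant series gives
  exactly 0.
* **Chebyshev metric** (max coordinate difference) between embedded
  vectors; comparisons use ≤ r, ties count as matches.
* **Natural logarithm**; values are in nats.
* The denominator of C_i^k uses the k-dimensional vector count N−k+1,
  which keeps both sums in the defining equation dimensionally consistent.
* **Parameters m = 2, r = 0.2 × SD** of the analysed window, the standard
  choice for short physiological windows. SD uses the n−1 (sample)
  denominator (`ddof` configurable). r is recomputed per window by
  default; `ApEnParams(global_r=True)` uses the whole signal's SD instead.
* **Windows**: 2 s (N = 200 points at 100 Hz), non-overlapping by default;
  `step_s` allows overlap. A 60-s sample yields 30 windows.

ApEn with SD-relative r is exactly invariant under affine transforms
u → a·u + b (a ≠ 0): all distance/tolerance comparisons scale together.
This is verified as a test property, as is equality (within 1e-10) with a
naive triple-loop reference implementation across N ∈ {50, 200},
m ∈ {1, 2, 3}.

The implementation builds the N×N matrix |u(i)−u(j)| once; the
k-dimensional Chebyshev match matrix is the AND of k shifted submatrices
of the thresholded scalar matrix, so the whole computation is a handful of
vectorised boolean reductions, O(N²·m) work with small constants.

## Synthetic driving-data generator

Real labelled road recordings for this problem are not publicly available,
so the package ships a seeded generator that emulates the three regimes'
qualitative signatures:

* Steering is a piecewise-linear correction process. Event times follow a
  Poisson process with rate `correction_rate`; each event ramps the wheel
  from its current angle toward a fresh target at slew rate
  `slew_deg_per_s` (jittered ±25 %). Targets are `amplitude_deg` times a
  standard normal truncated at ±3, which makes the process mean-reverting
  and keeps the noiseless trajectory within ±3 × amplitude of
  straight-ahead.
* The very-drowsy regime adds an exponential hold of mean `plateau_s`
  to every inter-event gap: flat, zero-derivative plateaus between bursts.
* Yaw is a causal first-order low-pass (time constant `ya_smooth_s`) of
  `ya_gain` × the clean steering trajectory.
* Both channels get additive Gaussian sensor noise: SD `noise_deg` on the
  steering encoder and `ya_gain × noise_deg` on the yaw channel — a yaw
  gyro is a much cleaner sensor than a wheel-angle encoder, and its noise
  floor is taken to scale with the channel gain. With equal noise on both
  channels the yaw trace would be noise-dominated at the default gain and
  carry no usable information, which does not match how informative the
  yaw channel is reported to be in road data.

Default regime parameters (all overridable): awake — 1.5 events/s,
1.5°, 10°/s; drowsy — 0.4/s, 6°, 30°/s; very drowsy — 0.2/s, 10°, 60°/s
with 4-s plateaus; noise 0.1°, ya_gain 0.1, ya_smooth 0.5 s. These are
tuned stand-ins reproducing the qualitative contrasts between regimes,
not measurements of real driving.

What the generator does **not** emulate: road curvature and lane-change
manoeuvres, speed-dependent steering, driver-to-driver variability,
non-stationary drift between fatigue states within a sample, and realistic
vehicle dynamics (a first-order lag stands in for the full lateral model).
Passing the end-to-end test therefore shows that the feature/classifier
chain recovers regime structure of this generative family — it is
evidence about the method's mechanics, not a performance claim about real
road data.

## Network and training

The classifier is a fully connected 2-6-6-3 tanh network: input
(ApEn_SWA, ApEn_YA), two hidden layers of six units, three outputs, every
non-input layer computing A = tanh(W·A_prev + B). Design choices:

* **Targets ±0.9**, not ±1: tanh reaches ±1 only at infinite weights.
  Decoding is argmax over the three outputs (ties toward the lower
  level), so the coding constant never affects predictions.
* **Feature standardisation** (training-set mean/SD) is applied to the
  inputs and stored in the model; tanh units need unit-scale inputs.
* **Initialisation** U(−0.5, 0.5), seed-controlled.
* **Full-batch gradient descent** on MSE with momentum 0.95 and the
  growth/decay adaptive learning rate: initial rate 0.082; after each
  epoch, if the MSE grew by more than 4 % the step is rolled back, the
  momentum memory cleared and the rate multiplied by 0.7; otherwise the
  step stands and, on an improvement, the rate is multiplied by 1.05.
  Training stops at MSE ≤ 10⁻⁴ (on the ±0.9-coded targets) or 20 000
  epochs. With the growth allowance set to 0 the accepted-epoch MSE trace
  is exactly non-increasing; at the default 1.04 it can grow by at most
  4 % per accepted epoch.
* Gradients are analytic backpropagation, tested against central finite
  differences at 10⁻⁶ relative tolerance; mini-batching is available via
  `batch_size` but full batch is the default at these data sizes.

Models serialise to JSON (config, standardisation constants, weights,
biases) and reload bit-exactly.

## Pipeline and evaluation

The network's input is two-dimensional, so classification is necessarily
per window; a sample-level decision aggregates its 30 window labels by
majority vote with ties broken toward the **higher** fatigue level — when
the evidence is balanced the safety-conservative call is the drowsier one.
An alternative aggregation (classify the sample's mean feature vector) is
available via `aggregation="mean"`.

Evaluation uses a 3×3 confusion matrix indexed (expert level, predicted
level); overall accuracy is trace/total, and per-class rates are
row-normalised (each expert class sums to 100 %), a convention this
package fixes explicitly. The train/test split is stratified by label at
the **sample** level (70/30 by default), so windows from one sample never
straddle the split.

The default end-to-end configuration — 20 one-minute samples per level at
100 Hz, 2-s windows, the 2-6-6-3 network, seed 42 — runs in about ten
seconds on one core and is the problem size used throughout the tests and
the acceptance script; the only deliberately small sizes are the XOR and
gradient-check fixtures, where tiny networks make the oracles exact.

## Known limitations

* ApEn is biased at short N and not comparable across very different
  window lengths; the fixed 2-s window sidesteps this but the absolute
  values should not be compared to other windowings.
* The three-level label is treated as nominal by the classifier; the
  ordinal structure only enters through the tie-break rule.
* No validation-based early stopping: training runs to the MSE goal or
  the epoch cap, which can overfit small, noisy feature sets.
* Real-data accuracy cannot be established here; see the generator
  section for what the synthetic results do and do not show.
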