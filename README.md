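# drivefatigue

Detection of driver fatigue from non-intrusive vehicle telemetry: the
steering-wheel angle (SWA) and the vehicle yaw angle (YA), both in degrees
at 100 Hz. Fatigued drivers correct the wheel less often but with larger
amplitude and higher velocity, and eventually hold it still for long
stretches before abrupt swings; these changes in the *irregularity* of the
two signals are captured by approximate entropy and classified into three
fatigue levels — awake (0), drowsy (1), very drowsy (2) — by a small
backpropagation neural network. The package is aimed at researchers in
driver-state monitoring who need a complete, reproducible reference
implementation of this feature/classifier chain, including a simulator of
labelled driving data for testing.

## Method

For a window u(1)..u(N), approximate entropy with embedding dimension m
and tolerance r is

    ApEn(m, r, N) = (1/(N−m+1)) Σᵢ log Cᵢᵐ(r) − (1/(N−m)) Σᵢ log Cᵢᵐ⁺¹(r)

where Cᵢᵏ(r) is the fraction of delay vectors X(j) = [u(j), ..., u(j+k−1)]
within Chebyshev distance r of X(i), self-match included. The package uses
m = 2 and r = 0.2 × SD of each 2-second window, computed over an N×N
scalar distance matrix rather than a triple loop.

Each one-minute sample yields 30 feature pairs (ApEn_SWA, ApEn_YA). A
fully connected 2-6-6-3 network with tangent-sigmoid units — A = f(WP + B)
at every layer — is trained by full-batch backpropagation with momentum
0.95, initial learning rate 0.082, an adaptive growth/decay rate schedule
and MSE goal 10⁻⁴. Windows are classified individually; a sample's level
is the majority vote of its windows, ties broken toward the higher fatigue
level. Expert labels are resolved by unanimity, negotiation, or discard,
and samples flagged for curved roads or lane shifts are dropped before
training.

## Worked example

```sh
python examples/04_full_pipeline.py
```

simulates 20 labelled one-minute samples per level, trains on a stratified
70 % and prints the held-out evaluation:

```
train samples: 42   test samples: 18
test accuracy: 94.44%
confusion matrix (rows = expert, cols = predicted):
predicted    awake  drowsy  very drowsy
expert
awake            6       0            0
drowsy           0       5            1
very drowsy      0       0            6
per-class rates (% within expert class):
         awake: 100.00    0.00    0.00
        drowsy:   0.00   83.33   16.67
   very drowsy:   0.00    0.00  100.00
```

Rows are the generating (true) fatigue levels of the 18 held-out samples,
columns the detected levels; accuracy is the diagonal fraction. One drowsy
sample is mistaken for very drowsy — the adjacent, safety-conservative
error. `examples/01_apen_basics.py` shows the feature itself: ApEn is
0 for a constant window, ≈0.27 for a sinusoid and ≈0.89 for white noise.

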