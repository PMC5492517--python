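"""The backpropagation network learns a non-linear boundary.

Trains the from-scratch tanh MLP on XOR — the classic test a linear model
fails — using the fatigue classifier's hyperparameters (initial learning
rate 0.082, momentum 0.95, adaptive rate). Prints the MSE trajectory and
the final predictions.
"""

import numpy as np

from drivefatigue import MLPConfig, init_model, train
from drivefatigue.bpnn import forward

X = np.array([[-1, -1], [-1, 1], [1, -1], [1, 1]], dtype=float)
Y = np.array([[-0.9], [0.9], [0.9], [-0.9]])  # XOR, coded for tanh outputs

cfg = MLPConfig(layer_sizes=(2, 2, 1), mse_goal=1e-3, max_epochs=5000, seed=3)
model, trace = train(init_model(cfg), X, Y, standardize=False)

print(f"converged to MSE {model.final_mse:.2e} in {model.trained_epochs} epochs")
for k in (0, len(trace) // 4, len(trace) // 2, len(trace) - 1):
    print(f"  accepted epoch {k:4d}: MSE {trace[k]:.5f}")
_, out = forward(model, X)
for x, y, o in zip(X, Y, out):
    print(f"  input {x} -> {o[0]:+.3f} (target {y[0]:+.1f})")
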