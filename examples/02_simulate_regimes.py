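"""The three simulated fatigue regimes and their ApEn signatures.

Generates one one-minute steering/yaw sample per fatigue level and prints
summary statistics of the steering trace plus the mean windowed ApEn of
both channels. Awake driving shows frequent small corrections; drowsy
driving sparse, large, fast ones; very drowsy driving long flat holds
punctuated by abrupt swings.
"""

import numpy as np

from drivefatigue import ApEnParams, FatigueLabel, extract_features, generate_sample

params = ApEnParams()  # 2-s windows, m=2, r=0.2*SD
print(f"{'level':>12} {'SWA range':>10} {'SWA SD':>8} {'ApEn SWA':>9} {'ApEn YA':>8}")
for level in FatigueLabel:
    sample = generate_sample(level, duration_s=60, fs=100, seed=7)
    swa = sample.swa.values
    F = extract_features(sample, params)  # 30 windows x (ApEn_SWA, ApEn_YA)
    print(f"{level.display_name:>12} {np.ptp(swa):10.2f} {swa.std():8.2f} "
          f"{F[:, 0].mean():9.3f} {F[:, 1].mean():8.3f}")

print("\nRange/SD grow with fatigue (larger, sparser corrections); the")
print("windowed ApEn pair is the 2-D feature the classifier works from.")
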