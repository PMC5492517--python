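"""End-to-end fatigue detection on simulated driving data.

Simulates 20 labelled one-minute samples per fatigue level at 100 Hz,
extracts 30 windowed (ApEn_SWA, ApEn_YA) feature pairs per sample, trains
the 2-6-6-3 network on a stratified 70% of the samples and classifies the
held-out 30% by majority vote over window predictions. Prints the
confusion matrix and accuracy; the run takes a few seconds.
"""

from drivefatigue import run_end_to_end

report = run_end_to_end({"seed": 42})
print(report.summary())
print("\nRows are the true (generating) fatigue levels, columns the")
print("detected ones; accuracy is the diagonal fraction of held-out samples.")
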