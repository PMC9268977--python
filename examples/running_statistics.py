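"""Summarise a stream one value at a time without ever storing it.

The accumulator keeps six numbers (count, min, max, mean and two
central-moment auxiliaries); every incoming sample updates them and is
then gone.  The final summary matches a conventional full-array
computation to floating-point accuracy.
"""

import numpy as np

import dndmotion as dm

rng = np.random.default_rng(0)
heart_rates = rng.normal(72.0, 8.0, 5000)  # a day of spot measurements

state = dm.RunningState()
for x in heart_rates:
    state.push(float(x))  # x is disposable after this line

recursive = state.summary()
batch = dm.batch_oracle(heart_rates)

print("recursive (never stored the stream):")
print(" ", recursive.as_dict())
print("batch oracle (saw the whole array):")
print(" ", batch.as_dict())
print(
    "largest relative difference:",
    max(
        abs(getattr(recursive, f) - getattr(batch, f)) / max(1e-12, abs(getattr(batch, f)))
        for f in ("mean", "sample_sd", "sample_skewness")
    ),
)
# The two rows agree to ~1e-15: the one-pass recursion loses nothing,
# while the raw series never had to exist anywhere after ingestion.
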