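"""Mixture vs streaming vs idealized TRF models on one simulated listener.

Generates pooled 0.125-s and 0.25-s echoic sessions whose response encodes
the direct sound and the echo as separate streams, fits the three encoding
models by ridge regression, and prints their 10-fold cross-validated
predictive power.
"""

import numpy as np

from echostream import EchoSpec, SynthConfig, model_streams, trf_predictive_power
from echostream.synth import _native_envelope, synth_recording

cfg = SynthConfig(duration_s=90.0, n_channels=60, regime="streaming",
                  snr_db=-10.0, seed=42)
rng = np.random.default_rng(42)
sessions = [
    synth_recording(_native_envelope(np.random.default_rng(rng.integers(2**31)), cfg),
                    EchoSpec.fixed(delay, 1.0), cfg)
    for delay in (0.125, 0.25)
]

print("cross-validated predictive power (mean over channels and folds):")
for kind in ("mixture", "streaming", "idealized"):
    streams = [model_streams(s, kind) for s in sessions]
    resps = [s.recording.data for s in sessions]
    power = trf_predictive_power(streams, resps, n_lags=100)
    print(f"  {kind:10s}: r = {power.mean:.3f}")

print()
print("The generating (streaming) model predicts held-out responses best:")
print("separate kernels for direct sound and echo beat a single mixture")
print("kernel once the two delays are pooled and the streams are separable.")
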