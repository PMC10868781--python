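"""Phase coherence between a simulated neural response and the direct sound.

Simulates five minutes of a multichannel response that faithfully tracks the
envelope of 0-dB echoic speech (mixture regime, realistic 1/f + sensor noise)
and prints the stimulus-response phase coherence at the echo-related
frequency and its flanks, plus the shuffle-based chance level.
"""

import numpy as np

from echostream import EchoSpec, SynthConfig, chance_null
from echostream.synth import _native_envelope, synth_recording

cfg = SynthConfig(duration_s=300.0, seed=17, n_channels=24,
                  regime="mixture", snr_db=-10.0)
env = _native_envelope(np.random.default_rng(17), cfg)
session = synth_recording(env, EchoSpec.fixed(0.125, 1.0), cfg)

res = chance_null(session.direct, session.recording,
                  n_shuffles=500, seed=1, f_max=8.0)

print("coherence with the DIRECT envelope (channel average):")
for f0 in (3.0, 3.5, 4.0, 4.5, 5.0):
    b = int(np.argmin(np.abs(res.frequencies - f0)))
    print(f"  {f0:3.1f} Hz: C = {res.observed[b]:.3f}"
          f"  (chance {res.chance_level[b]:.3f}, p = {res.p_values[b]:.4g})")

print()
print("A response that encodes the echoic mixture as a whole carries no")
print("4 Hz information about the direct sound: the coherence collapses to")
print("chance exactly at the echo-related frequency.")
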