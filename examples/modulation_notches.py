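"""Modulation spectrum of echoic speech: where the echo notches it.

Passes anechoic and echoic versions of the same synthetic narration through
the 128-band auditory front end and prints the modulation amplitude around
the first echo-related frequency (4 Hz for a 0.125-s echo).
"""

from echostream import EchoSpec, SynthConfig, make_echoic, modulation_spectrum
from echostream.synth import speech_like_audio

audio = speech_like_audio(SynthConfig(duration_s=60.0, seed=13))
anechoic = modulation_spectrum(audio, audio)

print("modulation amplitude (re. anechoic peak) at 3 / 4 / 5 Hz:")
print(f"  anechoic : {anechoic.at(3):.3f} / {anechoic.at(4):.3f} / {anechoic.at(5):.3f}")
for amp, label in ((1.0, "0-dB echo"), (0.5, "6-dB echo")):
    ms = modulation_spectrum(make_echoic(audio, EchoSpec.fixed(0.125, amp)), audio)
    print(f"  {label:9s}: {ms.at(3):.3f} / {ms.at(4):.3f} / {ms.at(5):.3f}")

print()
print("The 0-dB echo cuts the 4 Hz modulation to near zero (deep notch);")
print("the 6-dB echo only attenuates it, since the copies no longer cancel.")
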