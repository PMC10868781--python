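# Methods

`echostream` implements, end to end, the analyses used to ask whether
cortical activity tracking speech survives a long-delay echo: how the echo
reshapes the stimulus, how stimulus–response phase locking is quantified,
what a synaptic-depression account predicts, and how competing encoding
hypotheses are compared with temporal response function (TRF) models. All
analyses run on synthetic data with known ground truth; this note records
the models, the conventions, and the design decisions that were genuinely
open.

## Echoic stimuli

An echoic mixture is `A·s(t) + s(t − τ)`: the direct (leading) sound with
gain `A` plus a unit-gain delayed copy. `A = 1` is the 0-dB echo (equal
amplitudes), `A = 0.5` the 6-dB echo (echo twice the direct sound). For the
envelope, the echo acts as a comb filter `H(f) = A + e^{−i2πfτ}`, which for
`A = 1` has exact zeros at the echo-related frequencies `(2k−1)/(2τ)` —
4, 12, … Hz for τ = 0.125 s and 2, 6, 10, 14 … Hz for τ = 0.25 s. Because a
decorrelated signal and its delayed copy add in power, the 0-dB mixture is
`10·log10(2) = 3.01` dB stronger than the direct sound and the `A = 0.5`
mixture `10·log10(1.25) = 0.97` dB stronger.

Delays are realized as integer sample shifts so the antiphase cancellation
is exact. At the 100 Hz analysis rate a 0.125-s delay is 12.5 samples, so
envelope-domain synthesis runs at a 200 Hz native rate (where 0.125 s and
0.25 s are 25 and 50 samples) and is decimated to 100 Hz afterwards; audio
runs at 16 kHz, where both delays are integral. Variable-delay stimuli
redraw the delay uniformly from the 5-ms grid spanning 0.125–0.25 s at every
pause longer than 500 ms, switching at pause midpoints where the direct
sound is silent, so the splice is inaudible by construction. Mixtures keep
the echo tail (output longer by the maximum delay); downstream alignment
truncates to the common support.

One-channel noise vocoding removes the spectro-temporal fine structure that
serves as the stream-segregation cue: each stream's Hilbert envelope
(low-passed below 160 Hz, 4th-order Butterworth) modulates Gaussian noise
low-passed below 4 kHz; the streams are vocoded separately, then mixed, and
the result is rescaled to the RMS of the non-vocoded mixture.

Pause segmentation thresholds the envelope at 5% of its median over voiced
frames — a gain-invariant criterion; the paper-style analyses only need
pauses to place delay switches.

## Auditory front end

The auditory spectrogram is 128 narrowband envelopes between 180 Hz and
4 kHz at 200 Hz frames, computed as an STFT magnitude (40-ms Hann window)
re-binned through triangular filters on a log-frequency axis. Triangles
narrower than one FFT bin (the lowest bands) are widened to one bin, and
each row is normalized to unit sum, so a band reports the average magnitude
over its bins. This deliberately replaces the cochlear model the analyses
were originally built on: everything downstream depends only on having 128
narrowband envelopes at 200 Hz, not on the cochlear nonlinearity. The
modulation spectrum is the DFT amplitude of each band's envelope (single
full-length window, per-band mean removed so DC does not swamp the
modulations), summed over bands and normalized by the maximum of the
anechoic reference.

## Synthetic data generator

The generator emulates only the statistics the analyses rely on.

*Envelope.* Voiced stretches alternate with pauses: voiced durations are
gamma-distributed (shape 2, mean 3.4 s) truncated to 0.4–11.2 s; pauses are
uniform on 0.65–1.2 s, so every pause exceeds the 500-ms criterion and the
detected inter-pause interval averages ≈ 3.1 s. Within voiced stretches,
Hann-shaped syllable pulses (120 ms wide) arrive with gamma-jittered
inter-onset intervals (mean 0.2 s, CV 0.55, capped at 0.45 s so no
within-voiced gap registers as a pause) and lognormal amplitudes (σ = 0.6).
The jitter makes the envelope's autocorrelation negligible (|ρ| < 0.05)
beyond 100 ms within voiced stretches while keeping the modulation spectrum
peaked in the 2–8 Hz syllabic range. What this deliberately does **not**
emulate: linguistic rhythm and phrasal structure, amplitude co-modulation
across cochlear bands, pitch, or any spectral detail of real speech — so
passing tests certify the analysis machinery, not robustness to real
recordings.

*Audio.* The envelope modulates Gaussian noise low-passed below 4 kHz, so
the waveform is exactly decorrelated at the echo lags regardless of the
envelope's autocorrelation — this alone guarantees the 3.01 dB property.

*Responses.* Per channel, `response = g_c · Σ_streams(kernel ⊛ stream
envelope) + noise`, with lags 1–100 at 100 Hz. Ground-truth kernels are
biphasic gamma-shaped curves (positive peak near 50 ms, trough near 100 ms;
the echo stream's kernel, used by the streaming regime, peaks later and
weaker so the two streams are identifiable). The per-channel gains `g_c`
(random sign, lognormal magnitude, σ = 0.3) play the role of a sensor
topography. Noise is 80% 1/f-power ("spontaneous activity", flattened below
0.1 Hz) plus 20% white sensor noise, scaled per channel so the ratio of
driven to noise variance equals the configured SNR (default −10 dB, 204
gradiometer-like channels). Three regimes define which streams drive the
response: `mixture` (the echoic-mixture envelope, one kernel), `streaming`
(direct and echo envelopes, two kernels), `idealized` (direct only). All
randomness derives from a single seed.

## Phase coherence

Stimulus envelope and each response channel are cut into non-overlapping
2-s epochs (0.5 Hz bins), DFT-transformed with a rectangular window (no
taper — the statistic is defined on the plain per-epoch DFT), and the phase
difference `θ_ft = α_ft − β_ft` is summarized by its mean resultant length
`C(f) = |mean_t e^{iθ_ft}|`. `C = 1` for a constant phase lag (any pure
delay); for independent signals `E[C] ≈ 0.886/√T`. The epoch grid is
anchored at the stimulus onset after delay compensation, making `T`
reproducible. Chance level comes from shuffling the stimulus epoch order
(uniform permutations, identity included) with the response fixed,
recomputing `C`, and averaging across channels — and participants, when
several sessions are given with the same shuffle — before comparison; the
one-sided p-value is `(M+1)/(n_shuffles+1)` with `M` the number of null
values strictly above the observed one.

A subtlety this package documents explicitly: for a *noiseless* response
equal to the continuous mixture envelope, the coherence at the notch
frequencies does not fall to chance. The per-epoch DFT of a delayed signal
differs from the shift-theorem prediction by epoch-boundary terms, and their
covariance with the direct envelope's bin content leaves an irreducible
coherence floor of about `(π/4)·√(τ/2E)` (≈ 0.14 for τ = 0.125 s, 0.20 for
τ = 0.25 s at E = 2 s) for any envelope that decorrelates faster than the
epoch length. The constant-phase-lag premise of the statistic holds only up
to these boundary terms. In a simulated *neural* response the premise is
rescued by background activity: at the notch bins the driven signal is
essentially zero, the correlated boundary leakage sinks below the noise
floor, and the coherence collapses to chance (measured 0.046–0.065 at
−10 dB SNR, flanking bins ≈ 0.16). The ideal-tracking check therefore uses
the mixture-regime simulation with its noise model, which is also the
physiologically meaningful reading of "a neural response that faithfully
tracks the echoic envelope".

## Adaptation model

Each spectrogram channel passes through

    r(t,c) = max(s(t,c) − D(t,c), 0) · G(t,c)
    D(t,c) = V · (1 + Σ_{n=0}^{N_sd−1} s(t−n,c) W_sd(n))
    G(t,c) = 1 / (1 + Σ_{n=1}^{N_gc}   r(t−n,c) W_gc(n))

with raw (unnormalized) Hann weights over windows of width `τ_sd` and
`τ_gc`. Conventions that the defining equations leave open, fixed here: the
gain sum runs over strictly past outputs (a lower bound of 0 would make
`r(t)` depend on itself); the depression sum keeps the current input;
windows are whole numbers of 200 Hz frames; spectrograms are normalized so
their 95th percentile is 1 before adaptation, making the threshold `V`
scale-free. The implementation accumulates window taps in ascending lag
order so it matches a naive direct-summation reference bit for bit; a pure
`O(T·W)` reference implementation ships alongside for that cross-check.
Parameters are fitted by exhaustive grid search maximizing the Pearson
correlation between the channel-summed adapted response (resampled to
100 Hz) and the direct-sound envelope, averaged over the echoic conditions;
ties break toward the smallest `(V, τ_sd, τ_gc)`. The full published grid
(step 0.05 / 50 ms / 50 ms) is supported but the shipped checks use coarser
grids and shorter sessions — the fitted optimum is broad and the
0-dB-helps / 6-dB-hurts sign flip holds across the whole explored region.

## TRF models

The three encoding models differ only in their predictor streams: mixture —
the echoic-mixture envelope; streaming — direct and echo envelopes with
separate kernels; idealized — the direct envelope alone. Kernels span lags
1–100 samples (10 ms–1 s) per the defining sums, are estimated per channel
by closed-form ridge regression with mean-centering (no intercept column),
and are scored by the Pearson correlation between held-out response and
prediction under 10-fold cross-validation with contiguous time folds
(shuffled folds would leak autocorrelated samples). The ridge strength is
chosen per held-out fold by an inner leave-one-fold-out loop over the
remaining nine folds — never on the held-out fold — from the grid
`10^{0..6} ×` mean design-column variance. Cross-validation runs on
per-fold sufficient statistics (Gram matrices), so nested selection over
the λ grid costs little more than a single fit.

With a single fixed delay the echo stream is the direct stream shifted, the
two-stream design is rank-deficient up to that shift, and streaming is not
identifiable; `LaggedDesign.condition_number()` exposes the diagnostic, and
pooling sessions with different delays (or using variable-delay stimuli)
restores identifiability. Pooled sessions are concatenated with the first
`D` samples of each session dropped, so no lag window crosses a boundary.

Adapted TRFs pass each predictor stream's own spectrogram through the
adaptation cascade (the mixture model uses the mixture's spectrogram) and
grid-search the adaptation parameters to maximize CV predictive power; the
identity corner (`V = 0`, zero-width windows) reduces exactly to the plain
TRF on the channel-summed spectrogram. Band-limited TRFs filter predictors
and responses with the same delay-compensated linear-phase FIR before the
standard pipeline.

## Preprocessing

Responses are resampled to 100 Hz (polyphase with anti-aliasing) and
band-passed 0.8–10 Hz with a linear-phase FIR designed from a 6-s Hamming
window (601 taps at 100 Hz, −6 dB at the cutoffs, the window-method
convention); the constant 3-s group delay is compensated by dropping the
first 3 s of output, which realigns the response to the stimulus within one
sample.

## Inference

Paired condition contrasts use the exact sign-flip permutation test: all
`2^N` sign patterns of the per-participant differences are enumerated
(meet-in-the-middle, refused above N = 22 with an explicit instruction to
use the Monte-Carlo variant), and `p = (M+1)/(2^N+1)` with `M` the patterns
whose mean strictly exceeds the observed mean. Ties — including the
identity pattern — count as not exceeding, which is anti-conservative
exactly at the margin and caps p at `2^N/(2^N+1)` rather than 1; a
float-rounding tolerance keeps the count invariant to participant
relabeling. The cross-experiment comparison resamples one group 10,000
times with replacement and counts resampled means strictly below the other
group's mean, `p = (M+1)/(n_boot+1)`. This one-sample procedure is
calibrated against its own null (the reference mean treated as fixed);
when the comparison group's own sampling variability is substantial it is
anti-conservative (measured type-I ≈ 0.13 at α = 0.05 for groups of 15 vs
12), which users comparing two small cohorts should keep in mind. A BCa
interval utility for the mean is provided separately. Multiple comparisons
are Benjamini–Hochberg adjusted (via statsmodels) within each comparison
family.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use desk-scale sessions chosen
as the package's own defaults: 60–120 s of audio for stimulus-level
quantities, 90-s sessions per delay condition for TRF analyses (the
two-delay pooled design then has ~17,800 rows), 12 simulated participants
and 204 channels for model-selection recovery, and full ~13-minute sessions
(390 epochs) only where the epoch count matters — the ideal-tracking
coherence check, averaged over 10 seeds. Filters are zero-phase
(`sosfiltfilt`) for envelope extraction and linear-phase FIR with delay
compensation wherever stimulus–response alignment matters. Envelopes are
clipped at zero after any filtering step that can undershoot. Degenerate
inputs fail loudly: silent tracks in RMS comparisons, non-integer sample
delays, inverted bands, unknown regimes.

## Known limitations

The generator's syllable process has no linguistic structure, so effects
that depend on real speech statistics (e.g., exact modulation-spectrum
shapes, phrasal rhythms) are outside what the tests certify. The front end
is an STFT filterbank, not a cochlear model; absolute modulation-spectrum
shapes differ from cochlear-model outputs even though the notch structure
does not. Sensor geometry is abstract (random gains, no forward model), so
topographic claims cannot be reproduced, only per-channel tables. The
one-sample bootstrap inherits the anti-conservativeness described above.
Streaming-model identifiability near the single-delay degenerate case
depends on the ridge penalty; condition numbers should be checked before
interpreting per-stream kernels.
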