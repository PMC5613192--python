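# Methods

`somnevent` detects six kinds of sleep microstructure events in
polysomnographic (PSG) recordings — sleep spindles, K-complexes, slow
waves, rapid eye movements (REMs), muscle twitches and signal peaks —
and provides the surrounding machinery: EDF and hypnogram I/O, a signal
toolbox, sleep statistics, an event-level validation loop, and a
synthetic PSG generator with ground truth. This note records the models,
the parameter choices that matter, and the limits of what the synthetic
benchmarks demonstrate.

## Signal model and conventions

All signals are microvolt time series at a uniform sampling rate
(100 Hz is the customary working rate; detectors run at the native rate
of their input, with `downsample` available as an explicit pre-step).
Event intervals are half-open `[start, end)` in seconds from the
recording start, with a 0-based sample origin. Every processing function
returns new arrays: the input is never modified, so the original signal
is always recoverable.

## Morlet decomposition

Time-resolved amplitude, power and phase come from convolution with a
complex Morlet wavelet: a Gaussian-windowed complex exponential with
temporal width `sigma_t = cycles / (2*pi*f0)`. The kernel is normalized
by half the sum of its Gaussian envelope so that a unit-amplitude
sinusoid at the center frequency yields a unit-amplitude envelope —
amplitudes read directly in microvolts. Edges use reflective padding.
The default width is 7 cycles, a standard compromise between frequency
selectivity and the temporal resolution (~0.17 s FWHM at 13 Hz) needed
for sub-second duration criteria.

## Normalized band powers

Relative power in the four classical bands (delta 0.5–4, theta 4–8,
alpha 8–12, sigma 12–16 Hz) is computed per sample: absolute power is
the squared Morlet amplitude at each band's center frequency, with the
wavelet width chosen so its spectral FWHM equals the band width
(`cycles = 2*sqrt(2 ln 2) * fc / bw`, i.e. ~1.5 cycles for delta up to
~8 for sigma). The four powers are divided by their sum, so each
sample's four values sum to exactly 1. Two numerical details:

- The band-matched delta wavelet is short enough that a DC offset would
  leak into the delta estimate, so the series is demeaned first.
- An identically zero signal has no defined ratio; such samples are
  assigned the uniform 0.25 sentinel so downstream thresholding remains
  total. This sentinel is the one deliberate departure from a pure
  ratio.

A width floor (e.g. 3 cycles) for the delta wavelet was considered and
rejected: it makes the delta estimator nearly blind to 1 Hz slow waves
(response ~0.25), which defeats the slow-wave detector.

## Thresholding and event formation

"k standard deviations" thresholds are `mean + k*SD` of the nonnegative
amplitude/energy series over the whole analyzed signal (population SD).
Suprathreshold masks become events by run-length extraction, merging of
neighboring runs separated by strictly less than the gap limit
(default 0.5 s), then suppression of events outside the duration bounds.
Note that the baseline statistics include the events themselves; on
event-dense signals the threshold is therefore slightly conservative.

## Detectors

**Spindles** (12–14 Hz bursts, 0.5–2 s). Two indices are intersected:
(1) the 7-cycle Morlet amplitude at the band center exceeding
`mean + 2.4 SD`, and (2) the normalized sigma power exceeding 0.25 —
chance level for four bands, so sigma must dominate relative to a 1/f
background. The intersection is what rejects broadband amplitude
excursions, which raise index 1 but not index 2. Gap filling (<0.5 s)
and the 0.5–2 s duration window follow.

**K-complexes**. Delta (0.5–4 Hz) bandpass, Teager-Kaiser energy
operator (TKEO, `psi[n] = x[n]^2 - x[n-1]x[n+1]`), smoothed with a
0.2 s moving average — raw TKEO is too spiky for a duration criterion
to act on — then `mean + 1.0 SD` thresholding. Each candidate interval
is scored by the unweighted mean of three binary morphological
criteria: duration within 0.5–2 s, peak-to-peak amplitude >= 75 uV, and
a detected spindle within 2 s. Candidates scoring >= 0.5 (two of three)
are accepted and carry the score. A lone large biphasic transient thus
passes on duration + amplitude; the spindle-vicinity term rewards the
classic K-complex/spindle association.

**Slow waves** (>75 uV, <3 Hz, N3 hallmark). The normalized delta power
must reach 0.8 for at least 0.5 s; surviving intervals must show a
peak-to-peak amplitude >= 75 uV *measured on the signal lowpassed at
3 Hz*. Measuring the slow component (the field's convention for the
75 uV rule) prevents broadband background from pushing a small wave
over the bar.

**REMs**. The published algorithm for this detector lives in an
external reference; the implementation here is an intent-preserving
substitute, not a formula-exact port: 0.5–5 Hz bandpass, absolute first
difference, `mean + 3.5 SD` threshold, events of 0.1–1.5 s with 0.3 s
gap merging. The 0.1 s minimum reflects that a genuine eye-movement
deflection sustains a high derivative for at least its rise time;
shorter crossings are single-sample noise.

**Muscle twitches**. Morlet amplitude at 25 Hz (7 cycles) on the EMG,
`mean + 2 SD` threshold, duration 0.1–0.8 s. Against REM atonia the
burst-to-background contrast is large, so the threshold is undemanding.

**Peaks**. Sample `n` is a peak iff it is strictly higher than every
other sample within ±lookaround; among equal maxima in one window the
earliest sample wins; windows truncated at the edges compare against
available samples only (so a series-final local maximum is eligible).
Verified exhaustively against an O(N·w) brute-force oracle.

## Filtering

Butterworth or Bessel IIR designs (lowpass/highpass/bandpass/bandstop),
applied forward-backward (`sosfiltfilt`): zero phase, so detected event
boundaries are not shifted against the raw signal, at the cost of
doubling the effective order. Cutoffs must lie strictly inside
(0, Nyquist).

## Hypnogram and statistics

The native hypnogram is one integer stage code per second with the
vocabulary Art=-1, Wake=0, N1=1, N2=2, N3=3, REM=4 (overridable via a
description sidecar file, which also carries the file's values-per-
second density; conversion expands by repetition or decimates by taking
the value at each whole second). Statistics follow the standard
definitions: TIB = recording length; TST = N1+N2+N3+REM seconds;
efficiency = 100·TST/TIB; per-stage latency = time to the stage's first
second (absent if never reached, measured from recording start — no
lights-off marker is modeled); WASO = Wake after the first sleep
second. Artefact seconds count in TIB but are excluded from TST and
WASO. Events are staged by the code at their onset second.

## Evaluation

Matching is greedy one-to-one temporal overlap in time order, which for
internally disjoint interval tables attains the maximum bipartite
matching (checked against an exhaustive oracle in tests). Sensitivity =
TP/(TP+FN), FDR = FP/(FP+TP); a zero denominator is reported as an
explicitly absent value, never a silent zero — only inside the sweep's
objective is an absent FDR replaced by 1 (no detections are maximally
unhelpful). The threshold grid is half-open (`0:5:0.2` → 25 values,
0 through 4.8) and the optimum maximizes sensitivity − FDR, earliest
grid value on ties.

## Synthetic nights: what they do and do not show

The generator produces Gaussian 1/f background (unit SD, scaled to
10 uV for EEG/EOG; white 3 uV for EMG — low-voltage
inter-graphoelement background) with additive archetypal templates:

| kind     | template                                   | default            |
|----------|--------------------------------------------|--------------------|
| spindle  | Hann-windowed 13 Hz burst                  | 1.0 s, 25 uV peak  |
| kcomplex | smoothed biphasic negative-then-positive   | 0.8 s, 120 uV p-p  |
| slowwave | Hann-windowed 1 Hz oscillation epoch       | 4 s, 100 uV p-p    |
| rem      | sharp deflection, 0.1 s rise               | 0.5 s, 150 uV      |
| twitch   | Hann-windowed 25 Hz burst                  | 0.3 s, 60 uV peak  |

`make_psg` tiles a night from stage blocks (default
Wake/N1/N2/N3/REM = 60/60/300/180/120 s, repeated), injects events into
their home stages (spindles and K-complexes in N2, slow waves in N3,
REMs and twitches in REM) at configured per-minute densities on their
home channels, and returns the recording, hypnogram and ledger. All
randomness flows from one seed; output is bitwise reproducible.

The benchmark suite uses 10-minute single-channel nights with 20
injected events, 10 seeds, TP/FP/FN pooled across seeds. At default
parameters the detectors recover spindles at sensitivity >= 0.9 with
FDR <= 0.2, and K-complexes, slow waves and twitches at >= 0.8 / <= 0.3
(measured values are essentially 1.0 / 0.0).

These numbers certify the pipeline logic — the indices, thresholds,
gap/duration criteria and the evaluation loop — under a favorable,
known-truth regime. They do not certify performance on real
polysomnography: real EEG has non-Gaussian, nonstationary background,
ambiguous expert scoring, artifacts, and graphoelements far more
variable than one template each. Published expert-vs-detector figures
on real nights (e.g. spindle sensitivities near 0.7–0.8 with FDR near
0.4) are the realistic expectation, not the synthetic ceiling. Numeric
parity with any specific prior implementation is not claimed.

## Problem sizes

Default test and benchmark sizes (10-minute nights, 100 Hz, 30-minute
full-night simulation) were chosen so the whole suite exercises every
pipeline end-to-end in a few seconds on one core while keeping >= 20
events per night for stable ratio estimates.

## Known limitations

- EDF writer: plain EDF, 16-bit, 1 s records; integer sampling rates
  only; a final partial second is padded by repeating the last sample;
  the start date is a fixed dummy (clock time is carried).
- Hypnogram decimation from finer-than-1 Hz files keeps the value at
  each whole second; sub-second scoring detail is discarded.
- The REM detector is a substitute scheme (see above).
- No artifact simulation, no machine-learning staging, no multi-channel
  consensus detection.
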