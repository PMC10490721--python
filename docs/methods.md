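# Methods

This package estimates dyspnea severity on the 4-level mMRC scale
(0 = healthy … 3 = most severe, levels 3/4 merged) from three
controlled vocalizations — a sustained /ae-ae/, a sustained /sa-sa/
and counting 1-to-30 as fast as possible — captured by a 4-microphone
linear array on a robot head in a reverberant, noisy room.  Because
the clinical corpus that motivates the design is private, the package
ships a synthetic-corpus generator whose class structure is known by
construction; every downstream component (scene simulation,
beamforming, features, classifiers, fusion, evaluation protocol) is
real and is exercised end-to-end on that synthetic corpus.

## Synthetic vocalization corpus

The generator emulates the statistical structure that encodes dyspnea
severity in controlled phonetizations, not the acoustics of any
particular patient:

* **Roster.** 100 subjects by default: 34 healthy (mMRC 0) and 66
  patients. The per-class split of the patients is not derivable from
  the diagnosis mix, so the default is an even 22/22/22 over classes
  1–3 (configurable). Diagnosis labels (COPD / pulmonary fibrosis /
  post-COVID) are carried as metadata only and never alter synthesis.
* **Waveforms.** Vowel segments are jittered glottal pulse trains
  through a fixed three-resonator (700/1220/2600 Hz) vocal-tract
  filter; /sa/ prepends a high-passed fricative burst; counting is 30
  short vowel bursts with articulation gaps.  Severity acts only on
  timing and F0 statistics: content duration shrinks, per-gap pause
  probability and pause length grow, per-period F0 jitter grows, and
  band-limited (300–2000 Hz) breath bursts appear more often and
  louder.  Class profile defaults: pause probability
  0.05/0.15/0.30/0.45, breath probability 0.0/0.1/0.25/0.4, relative
  F0 jitter SD 0.010/0.020/0.040/0.060 for classes 0–3.
* **Duration calibration.** Per-class content-duration means are
  (13.25, 12.6, 11.2, 9.85) s with SD 15% of the mean, plus 0.4 s of
  near-silence at each edge (which also provides the non-speech
  intervals the SNR estimator needs).  At the default class mix this
  gives a corpus grand-mean duration of ≈12.7 s.  Pauses and breaths
  are carved out of the drawn content budget (capped at half of it),
  so inserting them does not inflate the calibrated duration.
* **Event log.** Every vocalization carries syllable/pause/breath
  timestamps so structural tests assert construction properties
  without audio analysis.
* **What it does not model.** Coughing as a separate symptom,
  speaker identity beyond the per-file random draws, linguistic
  content, channel effects of a real telephone network, or any
  clinically validated acoustics.  Passing tests therefore demonstrate
  that the pipeline recovers planted class structure under the modeled
  acoustics — not clinical performance.

## Acoustic scene model

* **Room.** Shoebox 6.5 × 5.35 × 3.0 m (≈104 m³), RT60 = 0.5 s.  RIRs
  come from a self-contained image-source method: mirror sources on
  the reflection lattice, amplitude β^r/(4πd), nearest-sample
  injection at 16 kHz.  Wall reflectivity starts from the Eyring
  formula; because a shoebox image model decays slower than the
  diffuse-field prediction (near-axial image chains hit fewer walls
  per meter), the per-reflection log-attenuation is calibrated once
  per room against the Schroeder estimate so that the simulated decay
  matches the configured RT60.  Each image source receives a random
  sign (direct path positive) so late arrivals add incoherently;
  Schroeder/T20 estimates on the default room come out at 0.5 ± 0.02 s.
* **Array.** 4-microphone non-uniform linear layout at offsets
  (0, 0.04, 0.08, 0.12) m (the reference array is only shown
  pictorially, so the layout is a documented default), speed of sound
  343 m/s.  Nearest-sample injection keeps direct-path inter-microphone
  delays within one sample of the far-field steering delays
  τ_l = (d_l/v)·sin φ.
* **Training grid.** 3 distances (1, 2, 3 m) × 11 head angles (−50°…50°
  in 10° steps) = 33 conditions.  Each utterance draws a condition, an
  SNR uniform in [5, 15] dB, a robot-to-environment noise ratio uniform
  in [−5, 5] dB and one of six environmental-noise surrogate classes;
  every draw is logged in a provenance record, and the capture keeps
  the clean and noise components at the reference microphone so the
  logged SNR can be re-derived exactly.
* **Noise.** Robot-ego noise is band-limited pink noise plus a
  50/100 Hz hum; the six environmental classes are generated
  spectral/temporal surrogates of public-space noise (street, station,
  car, babble, restaurant, airport).  The noise loudspeaker sits at a
  fixed 1.5 m from the array, 45° away from the speech source.
* **Dynamic capture.** The head angle follows a triangular wave
  between ±50° at 0.42 rad/s (period ≈ 8.3 s, so a mean-length
  utterance contains at least one full sweep).  Channels are built
  block-wise (20 ms) with the direct-path fractional delays frozen
  within each block; the capture is direct-path plus the directional
  noise, without per-block re-reverberation — adequate at this angular
  rate and much cheaper than re-convolving per block.  The per-sample
  DOA track is returned with the audio, mirroring a robot that logs
  its own head azimuth.

## Beamforming

* **Delay-and-sum:** y(t) = Σ_l x_l(t − τ_l) with no 1/L
  normalization; fractional delays use an 8-tap Hann-windowed sinc.
* **MVDR:** per frame m and bin ω,
  w = Σ_N⁻¹v / (vᴴΣ_N⁻¹v), Y = wᴴX, where v encodes the
  inter-microphone phase shifts of the look direction and Σ_N is the
  sample covariance of noise-only frames plus diagonal loading
  δ·trace/L with δ = 10⁻³.  Noise frames default to the 0.3 s edge
  intervals (the same voice-activity convention as the SNR estimator);
  an oracle mask can be supplied.  For dynamic captures the steering
  vector is rebuilt per frame from the DOA track.
* **STFT:** 32 ms frames, 50% hop, square-root-Hann analysis and
  synthesis windows (COLA); 512-point DFT at 16 kHz gives 257 bins.
  These beamforming frame parameters are package choices — the
  reference system specifies frames only for features.
* **SNR metric:** noise power from the first and last 0.3 s of each
  file; SNR = 10·log₁₀((P_interior − P_noise)/P_noise), floored for
  all-noise inputs.

## Features (8 kHz telephone front-end)

Audio is analyzed at 8 kHz (resampled from the 16 kHz capture rate),
honoring the telephone provenance of the feature design; a 50 ms
window is then 400 samples, zero-padded to the 512-point FFT.

* **Time-independent 3-vector:** SD of the mean-normalized F0 curve
  over voiced frames; mean of the per-voiced-pair normalized slope
  (ΔF0/Δt)/mean(F0) — the "normalized slope" definition is stated here
  explicitly because it admits alternatives; and the utterance
  duration in seconds.  F0 comes from normalized autocorrelation peak
  picking in 60–400 Hz (voiced when the peak exceeds 0.45), with the
  smallest lag within 90% of the best peak chosen to suppress
  octave-down errors, and parabolic peak interpolation.
* **Time-dependent matrices:** 14 triangular log-mel energies
  (0–4 kHz) per frame for /ae-ae/ and /sa-sa/; for counting, the
  lowest ⌈0.75·257⌉ = 193 log-power bins concatenated with their
  first-difference deltas (zero-prepended), i.e. 386 dims/frame — 193
  is the reading that makes static+delta equal the documented total.
* **MVN:** per-dimension mean/variance fitted over the whole database
  by default (the leakage-safe train-only variant is available);
  variance floored at 10⁻⁸ with flagged constant dimensions zeroed.
* **Padding:** zero rows up to the longest training utterance of the
  same phonetization; longer test utterances are truncated.

## Classifiers and training protocol

Six classifiers: one per (phonetization, feature kind).
Time-independent 3-vectors feed MLPs with hidden layouts (40, 40) for
/ae-ae/, (20, 20) for /sa-sa/ and (10,)×5 for counting, learning rates
0.01/0.01/0.001.  Time-dependent matrices feed temporal-pooling MLPs:
per-dimension mean and SD over the valid (non-padded) frames, then
dense layers — (64, 32) for /ae-ae/ and /sa-sa/ (lr 0.0005) and
(128, 64) for counting (lr 0.0001).  The pooling front-end is this
package's stand-in for convolutional/recurrent encoders: it preserves
the learning rates, the 4-way softmax head, ReLU activations, Adam and
cross-entropy of the reference design while remaining dependency-free
and fast on CPU.  All networks are trained with minibatch size 16.

The protocol is speaker-disjoint 9-fold cross-validation with double
validation: test sets partition the subjects (sizes 11×8 + 12 for 100
subjects, class-stratified), and the remaining subjects of each
partition split 70/15/15 into train / validation-1 / validation-2.
Each classifier trains from several independent initializations;
validation-1 accuracy drives early stopping (patience 20 epochs,
best-validation-1 weights restored), and the run with the highest mean
validation-1/validation-2 accuracy wins (ties: lower validation-1
loss, then lower run index).  "Iteration" in the early-stopping rule
is read as "epoch".  The outer protocol repeats with fresh fold plans
and training seeds; the corpus itself is generated and simulated once,
matching a fixed recorded database.

## Fusion and metrics

Per subject, 12 leaf softmax vectors (3 phonetizations × 2 feature
kinds × 2 repetitions) are fused bottom-up: five rules (element-wise
mean, median, min, max, product, each renormalized to the simplex —
min/max/product are not norm-preserving, and renormalization is stated
explicitly because the reference description calls the outputs softmax
values) averaged across repetitions; plain averaging across feature
kinds; the five rules again across phonetizations.  Argmax of the
final vector is the predicted class, ties resolved toward the
healthier class.  Fusion over the two repetitions uses the five-rule
scheme for symmetry with the phonetization level; the reference
description implies but never states this.

Metrics: pooled 4-class accuracy over all subjects (each subject is
tested exactly once per outer repeat) and the binary
healthy-vs-dyspnea AUC via the rank-sum formulation with midrank tie
handling, scoring each subject by 1 − P(class 0) (identical to
P(1)+P(2)+P(3) on the simplex).

## Problem sizes and numerical choices

* Default end-to-end evaluation: 100 subjects / 600 utterances, the
  full 33-condition augmentation, delay-and-sum enhancement, 9 folds,
  2 training runs per classifier per fold, 5 outer repeats, up to 300
  epochs with patience 20.  This configuration runs in minutes on one
  CPU; the classifiers reach early stopping well before the epoch cap.
* Monte-Carlo generator self-checks use shortened-duration profiles
  (the checks compare the generator against its own configured
  parameters, so the time scale is free) and 3-standard-error bounds.
* Diagonal loading 10⁻³, log floor 10⁻¹⁰ on spectral energies, MVN
  variance floor 10⁻⁸, voicing threshold 0.45.
* RIR tails are simulated to 1.05·RT60; tests that only exercise grid
  indexing use short tails.

## Known limitations

* The synthetic corpus plants the class structure it later recovers;
  end-to-end accuracies quantify pipeline integrity, not clinical
  performance, and are not comparable to results on the private
  clinical database.
* The image-source model uses nearest-sample injection and
  frequency-independent walls; it reproduces decay time and direct-path
  geometry but not wall-material coloration.
* Dynamic captures omit per-block re-reverberation.
* The temporal-pooling classifiers discard frame ordering beyond the
  delta features; sequence encoders would be needed to exploit
  longer-range dynamics.
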