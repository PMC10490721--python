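"""Extract both feature families from one vocalization.

Time-independent: [F0 spread, mean normalized F0 slope, duration].
Time-dependent: 14 log-mel energies per frame for /ae-ae/ and /sa-sa/,
386 log-spectral + delta dims per frame for the counting task
(50 ms windows, 50% overlap, 512-point FFT at the 8 kHz front-end).
"""

from dyspnea_hri import features
from dyspnea_hri.synthetic_corpus import generate_subjects, synthesize_vocalization

subjects = generate_subjects(4, (1, 1, 1, 1), seed=0)

for cls, subject in enumerate(subjects):
    voc = synthesize_vocalization(subject, "ae", 1, seed=20 + cls)
    ti = features.time_independent_features(voc.audio, voc.rate)
    print(f"mMRC {cls}: f0_spread={ti.f0_spread:.4f}  "
          f"slope={ti.f0_norm_slope_mean:+.4f}  duration={ti.duration:6.2f} s")

voc = synthesize_vocalization(subjects[0], "ae", 1, seed=20)
mel = features.mel_features(voc.audio, voc.rate)
count_voc = synthesize_vocalization(subjects[0], "count", 1, seed=30)
spec = features.counting_spectral_features(count_voc.audio, count_voc.rate)
print(f"\n/ae-ae/ time-dependent matrix: {mel.shape[0]} frames x {mel.shape[1]} dims")
print(f"counting time-dependent matrix: {spec.shape[0]} frames x {spec.shape[1]} dims")
# F0 spread grows and duration shrinks with severity by construction.
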