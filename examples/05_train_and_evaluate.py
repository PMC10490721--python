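"""Small end-to-end run: corpus -> simulation -> D&S -> features ->
9-fold double-validation training -> softmax fusion -> metrics.

Uses a reduced corpus (24 subjects) and 3 folds so it finishes in
about a minute; the full protocol (100 subjects, 9 folds, 5 repeats)
is what tests/test_acceptance.py runs.
"""

from dyspnea_hri import pipeline

result = pipeline.run_default_experiment(
    seed=0,
    n_subjects=24,
    n_per_class=(6, 6, 6, 6),
    folds=3,
    runs=2,
    repeats=1,
    max_epochs=60,
)

r = result.repeats[0]
print(f"pooled 4-class accuracy: {r.accuracy:.1f} %  (chance = 25 %)")
print(f"binary healthy-vs-dyspnea AUC: {r.auc:.3f}")
print("single-phonetization accuracies:",
      {k: round(v, 1) for k, v in r.per_phonetization_accuracy.items()})
# The fused system combines 12 softmax outputs per subject
# (3 phonetizations x 2 feature kinds x 2 repetitions).
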