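"""End-to-end experiment runner: corpus -> scene simulation -> beamforming
-> features -> double-validation training -> fusion -> metrics.

This stitches the modules into the full evaluation protocol: generate
the synthetic corpus, augment every vocalization through the 33-condition
RIR/noise model, beamform, extract both feature families, apply
whole-database MVN, run speaker-disjoint 9-fold training with double
validation, fuse the softmax hierarchy per subject and report pooled
4-class accuracy and binary AUC over several outer repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import array_sim, beamform, classify, features, fusion_eval
from .config import (
    DEFAULT_CLASS_COUNTS,
    PHONETIZATIONS,
    FeatureConfig,
    GeneratorProfile,
    RoomSpec,
)
from .synthetic_corpus import SubjectRecord, generate_subjects, iter_corpus_specs, synthesize_vocalization


@dataclass
class UtteranceFeatures:
    subject_id: str
    mmrc_class: int
    phonetization: str
    repetition: int
    ti: np.ndarray  # (3,)
    td: np.ndarray  # (n_frames, dims) float32, pre-MVN
    n_frames: int


@dataclass
class RepeatResult:
    accuracy: float
    auc: float
    per_phonetization_accuracy: dict[str, float]
    predictions: list


@dataclass
class ExperimentResult:
    repeats: list[RepeatResult] = field(default_factory=list)

    @property
    def accuracies(self) -> list[float]:
        return [r.accuracy for r in self.repeats]

    @property
    def aucs(self) -> list[float]:
        return [r.auc for r in self.repeats]


# --------------------------------------------------------------------------
# feature extraction over the simulated corpus
# --------------------------------------------------------------------------


def extract_corpus_features(
    subjects: list[SubjectRecord],
    profile: GeneratorProfile | None = None,
    seed: int = 0,
    beamformer: str = "das",
    simulate: bool = True,
    room: RoomSpec | None = None,
    feature_cfg: FeatureConfig | None = None,
    rir_t_max: float | None = None,
) -> list[UtteranceFeatures]:
    """Synthesize, simulate and featurize the corpus, streaming one
    utterance at a time so audio never accumulates in memory.

    ``beamformer`` is 'das', 'mvdr' or 'none' (reference channel).
    With ``simulate=False`` the clean vocalizations are featurized
    directly (the telephone-condition analog).
    """
    profile = profile or GeneratorProfile()
    room = room or RoomSpec()
    feature_cfg = feature_cfg or FeatureConfig()
    rng = np.random.default_rng(seed)

    rir_grid = None
    if simulate:
        rir_grid = array_sim.build_rir_grid(room, rate=profile.rate, t_max=rir_t_max)

    out: list[UtteranceFeatures] = []
    specs = list(iter_corpus_specs(subjects, seed))
    sim_seed = int(rng.integers(2**31))

    def clean_vocs():
        for subject, phon, rep, file_seed in specs:
            yield synthesize_vocalization(subject, phon, rep, profile, file_seed)

    if simulate:
        stream = array_sim.simulate_training_corpus(
            clean_vocs(), rir_grid, room=room, seed=sim_seed
        )
        items = ((cap.provenance, _beamform(cap, beamformer)) for cap in stream)
    else:
        items = (
            (
                dict(
                    subject_id=v.subject_id, mmrc_class=v.mmrc_class,
                    phonetization=v.phonetization, repetition=v.repetition,
                ),
                (v.audio, v.rate),
            )
            for v in clean_vocs()
        )

    for prov, (mono, rate) in items:
        ti = features.time_independent_features(mono, rate, feature_cfg)
        if prov["phonetization"] == "count":
            td = features.counting_spectral_features(mono, rate, feature_cfg)
        else:
            td = features.mel_features(mono, rate, feature_cfg)
        out.append(
            UtteranceFeatures(
                prov["subject_id"], prov["mmrc_class"], prov["phonetization"],
                prov["repetition"], ti.as_array(), td.astype(np.float32), td.shape[0],
            )
        )
    return out


def _beamform(capture, method: str) -> tuple[np.ndarray, int]:
    if method == "none":
        return capture.channels[0], capture.rate
    if method == "das":
        return beamform.delay_and_sum(capture), capture.rate
    if method == "mvdr":
        return beamform.mvdr_filter(capture), capture.rate
    raise ValueError(f"unknown beamformer {method!r}")


# --------------------------------------------------------------------------
# MVN over the whole database
# --------------------------------------------------------------------------


def apply_database_mvn(
    feats: list[UtteranceFeatures], fit_subject_ids: set[str] | None = None
) -> list[UtteranceFeatures]:
    """Mean/variance normalization per phonetization, separately for the
    3-vector and the frame-level dimensions.

    Statistics are fitted over the whole database by default; passing
    ``fit_subject_ids`` restricts fitting to those subjects (the
    leakage-safe train-only alternative) while still normalizing
    everything.
    """
    out = list(feats)
    for phon in PHONETIZATIONS:
        sel = [f for f in out if f.phonetization == phon]
        if not sel:
            continue
        fit = (
            sel
            if fit_subject_ids is None
            else [f for f in sel if f.subject_id in fit_subject_ids]
        ) or sel
        ti_stats = features.fit_mvn(np.stack([f.ti for f in fit]))
        dims = sel[0].td.shape[1]
        n = 0
        s = np.zeros(dims)
        s2 = np.zeros(dims)
        for f in fit:
            n += f.n_frames
            s += f.td.sum(axis=0, dtype=np.float64)
            s2 += (f.td.astype(np.float64) ** 2).sum(axis=0)
        mean = s / n
        var = np.maximum(s2 / n - mean**2, features.VAR_FLOOR)
        td_stats = features.MVNStats(mean, var, var <= features.VAR_FLOOR)
        for f in sel:
            f.ti = features.apply_mvn(f.ti, ti_stats)
            f.td = features.apply_mvn(f.td.astype(np.float64), td_stats).astype(np.float32)
    return out


# --------------------------------------------------------------------------
# protocol
# --------------------------------------------------------------------------


def _subset_matrix(
    feats_by_subject: dict[str, list[UtteranceFeatures]],
    ids: list[str],
    phon: str,
    kind: str,
    pad_len: int,
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for sid in ids:
        for f in feats_by_subject[sid]:
            if f.phonetization != phon:
                continue
            if kind == classify.TIME_INDEP:
                xs.append(f.ti)
            else:
                padded = features.pad_to_length(f.td.astype(np.float64), pad_len)
                xs.append(classify.pool_features(padded, min(f.n_frames, pad_len)))
            ys.append(f.mmrc_class)
    if not xs:
        from .config import ConfigurationError

        raise ConfigurationError(
            f"no utterances for phonetization {phon!r} in subset; "
            "too few subjects per class for this fold count"
        )
    return np.stack(xs), np.asarray(ys)


def run_protocol(
    feats: list[UtteranceFeatures],
    subjects: list[SubjectRecord],
    kinds: tuple[str, ...] = classify.FEATURE_KINDS,
    folds: int = 9,
    runs: int = 2,
    repeats: int = 5,
    max_epochs: int = 120,
    patience: int = 20,
    seed: int = 0,
) -> ExperimentResult:
    """Run the outer-repeated k-fold double-validation protocol on
    pre-extracted (MVN-applied) features and fuse per-subject scores."""
    feats_by_subject: dict[str, list[UtteranceFeatures]] = {}
    for f in feats:
        feats_by_subject.setdefault(f.subject_id, []).append(f)
    cls_of = {s.subject_id: s.mmrc_class for s in subjects}
    specs = classify.default_model_specs()
    result = ExperimentResult()
    for rep in range(repeats):
        plan = classify.make_fold_plan(subjects, k=folds, seed=seed + 1000 * (rep + 1))
        classify.validate_fold_plan(plan, subjects)
        leaves_by_subject: dict[str, dict[tuple[str, str], list[np.ndarray]]] = {}
        for fold_idx, part in enumerate(plan.partitions):
            for phon in PHONETIZATIONS:
                pad_len = max(
                    f.n_frames
                    for sid in part.train
                    for f in feats_by_subject[sid]
                    if f.phonetization == phon
                )
                for kind in kinds:
                    data = {
                        name: _subset_matrix(feats_by_subject, ids, phon, kind, pad_len)
                        for name, ids in (
                            ("train", part.train), ("val1", part.val1), ("val2", part.val2)
                        )
                    }
                    trained = classify.train_with_double_validation(
                        specs[(phon, kind)], data, runs=runs, patience=patience,
                        max_epochs=max_epochs,
                        seed=seed + 7919 * rep + 101 * fold_idx
                        + 17 * PHONETIZATIONS.index(phon)
                        + 5 * classify.FEATURE_KINDS.index(kind),
                    )
                    for sid in part.test:
                        for f in feats_by_subject[sid]:
                            if f.phonetization != phon:
                                continue
                            if kind == classify.TIME_INDEP:
                                x = f.ti
                            else:
                                padded = features.pad_to_length(
                                    f.td.astype(np.float64), pad_len
                                )
                                x = classify.pool_features(
                                    padded, min(f.n_frames, pad_len)
                                )
                            sm = classify.predict_softmax(trained.model, x)
                            leaves_by_subject.setdefault(sid, {}).setdefault(
                                (phon, kind), []
                            ).append(sm)
        preds = [
            fusion_eval.subject_score(leaves, sid, cls_of[sid])
            for sid, leaves in sorted(leaves_by_subject.items())
        ]
        per_phon_acc = {}
        for phon in PHONETIZATIONS:
            phon_preds = [
                fusion_eval.subject_score(
                    {k: v for k, v in leaves.items() if k[0] == phon}, sid, cls_of[sid]
                )
                for sid, leaves in sorted(leaves_by_subject.items())
            ]
            per_phon_acc[phon] = fusion_eval.accuracy(phon_preds)
        result.repeats.append(
            RepeatResult(
                accuracy=fusion_eval.accuracy(preds),
                auc=fusion_eval.binary_auc(
                    [p.final_softmax for p in preds], [p.true_class for p in preds]
                ),
                per_phonetization_accuracy=per_phon_acc,
                predictions=preds,
            )
        )
    return result


def run_default_experiment(
    seed: int = 0,
    n_subjects: int = 100,
    n_per_class: tuple[int, int, int, int] = DEFAULT_CLASS_COUNTS,
    beamformer: str = "das",
    kinds: tuple[str, ...] = classify.FEATURE_KINDS,
    folds: int = 9,
    runs: int = 2,
    repeats: int = 5,
    max_epochs: int = 120,
    simulate: bool = True,
    profile: GeneratorProfile | None = None,
) -> ExperimentResult:
    """Convenience wrapper: default corpus through the full protocol."""
    subjects = generate_subjects(n_subjects, n_per_class, seed)
    feats = extract_corpus_features(
        subjects, profile=profile, seed=seed, beamformer=beamformer, simulate=simulate
    )
    feats = apply_database_mvn(feats)
    return run_protocol(
        feats, subjects, kinds=kinds, folds=folds, runs=runs,
        repeats=repeats, max_epochs=max_epochs, seed=seed,
    )
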