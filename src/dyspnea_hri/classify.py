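"""Per-phonetization classifiers and the k-fold double-validation protocol.

One classifier is trained per (phonetization, feature kind) pair — six
in total — each ending in a 4-way softmax over mMRC classes 0-3.
Time-independent 3-vectors feed small MLPs whose layouts follow the
reference system (/ae-ae/: two hidden layers of 40; /sa-sa/: two of
20; counting: five of 10).  Time-dependent frame matrices feed
temporal-pooling MLPs: per-dimension mean and SD over the valid
(non-padded) frames, then dense layers — a compact stand-in for the
convolutional/recurrent front-ends of the reference system that keeps
its learning rates and training protocol.

The training protocol is speaker-disjoint 9-fold cross-validation with
double validation: per partition the non-test subjects are split
70/15/15 into train/validation-1/validation-2; each classifier is
trained several times from independent initializations, validation-1
drives early stopping, and the run with the highest mean
validation-1/validation-2 accuracy is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import N_CLASSES, PHONETIZATIONS, ConfigurationError
from .nets import MLP, Adam, train_epoch
from .synthetic_corpus import SubjectRecord

TIME_DEP = "time_dep"
TIME_INDEP = "time_indep"
FEATURE_KINDS = (TIME_DEP, TIME_INDEP)


# --------------------------------------------------------------------------
# model specs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    phonetization: str
    feature_kind: str
    hidden: tuple[int, ...]
    learning_rate: float
    pooled_input: bool = False  # temporal mean+SD pooling of a frame matrix

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigurationError("learning rate must be positive")
        if self.phonetization not in PHONETIZATIONS or self.feature_kind not in FEATURE_KINDS:
            raise ConfigurationError(
                f"unknown (phonetization, feature_kind) = "
                f"({self.phonetization!r}, {self.feature_kind!r})"
            )


def default_model_specs() -> dict[tuple[str, str], ModelSpec]:
    """The six default classifier specs keyed by (phonetization, kind)."""
    return {
        ("ae", TIME_INDEP): ModelSpec("ae", TIME_INDEP, (40, 40), 0.01),
        ("sa", TIME_INDEP): ModelSpec("sa", TIME_INDEP, (20, 20), 0.01),
        ("count", TIME_INDEP): ModelSpec("count", TIME_INDEP, (10, 10, 10, 10, 10), 0.001),
        ("ae", TIME_DEP): ModelSpec("ae", TIME_DEP, (64, 32), 0.0005, pooled_input=True),
        ("sa", TIME_DEP): ModelSpec("sa", TIME_DEP, (64, 32), 0.0005, pooled_input=True),
        ("count", TIME_DEP): ModelSpec("count", TIME_DEP, (128, 64), 0.0001, pooled_input=True),
    }


def build_model(spec: ModelSpec, input_dim: int, seed: int = 0) -> MLP:
    """Instantiate an untrained network for a spec; ReLU hidden layers,
    4-way softmax head, He initialization."""
    return MLP(input_dim, spec.hidden, out_dim=N_CLASSES, seed=seed)


def pool_features(padded: np.ndarray, n_frames: int) -> np.ndarray:
    """Temporal pooling of a (pad_length x dims) matrix: concatenated
    per-dimension mean and SD over the first ``n_frames`` valid rows."""
    valid = padded[: max(n_frames, 1)]
    return np.concatenate([valid.mean(axis=0), valid.std(axis=0)])


def predict_softmax(model: MLP, features: np.ndarray) -> np.ndarray:
    """Class-probability vector(s): 4 non-negative entries summing to 1."""
    return model.predict_proba(features)


# --------------------------------------------------------------------------
# fold plan
# --------------------------------------------------------------------------


@dataclass
class Partition:
    test: list[str]
    train: list[str]
    val1: list[str]
    val2: list[str]


@dataclass
class FoldPlan:
    partitions: list[Partition]
    seed: int


def _stratified_split(
    ids_by_class: dict[int, list[str]], fractions=(0.70, 0.15, 0.15)
) -> tuple[list[str], list[str], list[str]]:
    train: list[str] = []
    val1: list[str] = []
    val2: list[str] = []
    for ids in ids_by_class.values():
        n = len(ids)
        n_v1 = max(int(round(fractions[1] * n)), 1 if n >= 3 else 0)
        n_v2 = max(int(round(fractions[2] * n)), 1 if n >= 3 else 0)
        n_tr = n - n_v1 - n_v2
        train.extend(ids[:n_tr])
        val1.extend(ids[n_tr: n_tr + n_v1])
        val2.extend(ids[n_tr + n_v1:])
    return train, val1, val2


def make_fold_plan(subjects: list[SubjectRecord], k: int = 9, seed: int = 0) -> FoldPlan:
    """Speaker-disjoint k-fold plan with double validation.

    Test sets partition the subjects as evenly as possible (for 100
    subjects and k=9: one fold of 12 and eight of 11), stratified by
    class; the remaining subjects of each partition are split 70/15/15
    into train / validation-1 / validation-2, also stratified.
    """
    if len(subjects) < k:
        raise ConfigurationError("need at least k subjects")
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[str]] = {}
    for s in subjects:
        by_class.setdefault(s.mmrc_class, []).append(s.subject_id)
    fold_test: list[list[str]] = [[] for _ in range(k)]
    offset = 0
    for cls in sorted(by_class):
        ids = list(by_class[cls])
        rng.shuffle(ids)
        for i, sid in enumerate(ids):
            fold_test[(i + offset) % k].append(sid)
        offset += len(ids)  # rotate so remainders spread across folds
    cls_of = {s.subject_id: s.mmrc_class for s in subjects}
    partitions = []
    for test in fold_test:
        rest = [s.subject_id for s in subjects if s.subject_id not in set(test)]
        rest_by_class: dict[int, list[str]] = {}
        for sid in rest:
            rest_by_class.setdefault(cls_of[sid], []).append(sid)
        for ids in rest_by_class.values():
            rng.shuffle(ids)
        train, val1, val2 = _stratified_split(rest_by_class)
        partitions.append(Partition(test, train, val1, val2))
    return FoldPlan(partitions, seed)


def validate_fold_plan(plan: FoldPlan, subjects: list[SubjectRecord]) -> None:
    """Assert subject-disjointness and coverage; raises on violation."""
    all_ids = {s.subject_id for s in subjects}
    seen: set[str] = set()
    for p in plan.partitions:
        groups = [set(p.test), set(p.train), set(p.val1), set(p.val2)]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if groups[i] & groups[j]:
                    raise AssertionError("subsets within a partition overlap")
        if set().union(*groups) != all_ids:
            raise AssertionError("partition does not cover all subjects")
        if seen & set(p.test):
            raise AssertionError("test sets overlap across partitions")
        seen |= set(p.test)
    if seen != all_ids:
        raise AssertionError("test sets do not cover all subjects")


# --------------------------------------------------------------------------
# double-validation training
# --------------------------------------------------------------------------


@dataclass
class RunLog:
    run: int
    epochs: int
    val1_accuracy: float
    val2_accuracy: float
    val1_loss: float


@dataclass
class TrainedModel:
    model: MLP
    spec: ModelSpec
    runs: list[RunLog] = field(default_factory=list)
    selected_run: int = -1


def _accuracy(model: MLP, x: np.ndarray, y: np.ndarray) -> float:
    pred = np.argmax(model.logits(x), axis=1)
    return float(np.mean(pred == y))


def _loss(model: MLP, x: np.ndarray, y: np.ndarray) -> float:
    from .nets import softmax

    p = softmax(model.logits(x))
    return float(-np.mean(np.log(np.maximum(p[np.arange(len(y)), y], 1e-12))))


def train_with_double_validation(
    spec: ModelSpec,
    data: dict[str, tuple[np.ndarray, np.ndarray]],
    runs: int = 8,
    patience: int = 20,
    max_epochs: int = 500,
    batch_size: int = 16,
    seed: int = 0,
) -> TrainedModel:
    """Train ``runs`` independently initialized networks and select one.

    ``data`` maps subset names ('train', 'val1', 'val2') to (X, y).
    Each run's epoch loop stops when validation-1 accuracy has not
    improved for ``patience`` epochs (best-val1 weights kept); the
    winner maximizes mean(val1, val2) accuracy, ties broken by lower
    validation-1 loss.  Fully deterministic for a fixed seed.
    """
    for name in ("train", "val1", "val2"):
        if name not in data or len(data[name][1]) == 0:
            raise ConfigurationError(f"subset {name!r} is empty")
    x_tr, y_tr = data["train"]
    x_v1, y_v1 = data["val1"]
    x_v2, y_v2 = data["val2"]
    logs: list[RunLog] = []
    snapshots = []
    ss = np.random.SeedSequence(seed)
    run_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(runs)]
    for r in range(runs):
        model = build_model(spec, x_tr.shape[1], seed=run_seeds[r])
        opt = Adam(model, spec.learning_rate)
        rng = np.random.default_rng(run_seeds[r] + 1)
        best_acc = -1.0
        best_snap = model.snapshot()
        since_best = 0
        epoch = 0
        for epoch in range(1, max_epochs + 1):
            train_epoch(model, opt, x_tr, y_tr, batch_size, rng)
            acc = _accuracy(model, x_v1, y_v1)
            if acc > best_acc:
                best_acc = acc
                best_snap = model.snapshot()
                since_best = 0
            else:
                since_best += 1
            if since_best > patience:
                break
        model.restore(best_snap)
        logs.append(
            RunLog(
                run=r,
                epochs=epoch,
                val1_accuracy=_accuracy(model, x_v1, y_v1),
                val2_accuracy=_accuracy(model, x_v2, y_v2),
                val1_loss=_loss(model, x_v1, y_v1),
            )
        )
        snapshots.append((model, best_snap))
    scores = [
        (0.5 * (lg.val1_accuracy + lg.val2_accuracy), -lg.val1_loss, -lg.run)
        for lg in logs
    ]
    # lexicographic: best mean val accuracy, then lower val1 loss, then lower run index
    winner = max(range(runs), key=lambda r: scores[r])
    return TrainedModel(snapshots[winner][0], spec, logs, winner)
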