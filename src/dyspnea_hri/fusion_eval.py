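"""Softmax fusion hierarchy and evaluation metrics.

Each subject yields 12 leaf softmax vectors (3 phonetizations x 2
feature kinds x 2 repetitions).  Fusion proceeds bottom-up:

1. per (phonetization, feature kind): the two repetition softmaxes are
   combined with five rules — element-wise mean, median, minimum,
   maximum and product — and the five results are averaged;
2. per phonetization: the two feature-kind softmaxes are averaged;
3. across the three phonetizations: the five rules are applied again
   and averaged.

The final vector's argmax is the estimated mMRC score (ties resolved
toward the healthier class).  Metrics: 4-class accuracy and the binary
healthy-vs-dyspnea AUC computed with the rank-sum (Mann-Whitney)
formulation with tie correction, scoring each subject by 1 - P(class 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FUSION_RULES = ("mean", "median", "min", "max", "product")


def _as_matrix(vectors) -> np.ndarray:
    m = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    if m.size == 0:
        raise ValueError("empty softmax list")
    return m


def _renormalize(v: np.ndarray) -> np.ndarray:
    s = v.sum()
    if s <= 0:
        return np.full_like(v, 1.0 / len(v))
    return v / s


def combine_rule(vectors, rule: str) -> np.ndarray:
    """Element-wise combination of softmax vectors by one rule.

    min/max/product do not preserve the simplex, so every output is
    renormalized to sum to one.
    """
    m = _as_matrix(vectors)
    if rule == "mean":
        out = m.mean(axis=0)
    elif rule == "median":
        out = np.median(m, axis=0)
    elif rule == "min":
        out = m.min(axis=0)
    elif rule == "max":
        out = m.max(axis=0)
    elif rule == "product":
        out = m.prod(axis=0)
    else:
        raise ValueError(f"unknown fusion rule {rule!r}")
    return _renormalize(out)


def five_rule_fuse(vectors) -> np.ndarray:
    """Average of the five rule outputs; stays on the simplex."""
    outs = [combine_rule(vectors, r) for r in FUSION_RULES]
    return _renormalize(np.mean(outs, axis=0))


@dataclass
class SubjectPrediction:
    subject_id: str
    true_class: int
    final_softmax: np.ndarray
    predicted_class: int
    phonetization_softmax: dict[str, np.ndarray] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def subject_score(
    leaves: dict[tuple[str, str], list[np.ndarray]],
    subject_id: str = "",
    true_class: int = -1,
) -> SubjectPrediction:
    """Fuse a subject's leaf softmaxes into a final mMRC prediction.

    ``leaves`` maps (phonetization, feature_kind) to the per-repetition
    softmax vectors.  Missing feature kinds are skipped (supporting
    time-dependent / time-independent ablations); missing repetitions
    are fused over whatever is available and flagged.
    """
    if not leaves:
        raise ValueError("no leaf softmaxes given")
    flags = []
    by_phon: dict[str, list[np.ndarray]] = {}
    for (phon, _kind), reps in leaves.items():
        if not reps:
            continue
        if len(reps) < 2:
            flags.append(f"single repetition for {phon}/{_kind}")
        fused = five_rule_fuse(reps)  # level 1: across repetitions
        by_phon.setdefault(phon, []).append(fused)
    if not by_phon:
        raise ValueError("no usable leaves")
    phon_vecs = {
        phon: _renormalize(np.mean(kinds, axis=0))  # level 2: across feature kinds
        for phon, kinds in by_phon.items()
    }
    final = five_rule_fuse(list(phon_vecs.values()))  # level 3: across phonetizations
    pred = int(np.argmax(final))  # argmax ties resolve to the lowest class
    return SubjectPrediction(subject_id, true_class, final, pred, phon_vecs, flags)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------


def accuracy(predictions: list[SubjectPrediction]) -> float:
    """4-class accuracy in percent."""
    if not predictions:
        raise ValueError("no predictions")
    correct = sum(p.predicted_class == p.true_class for p in predictions)
    return 100.0 * correct / len(predictions)


def dyspnea_score(final_softmax: np.ndarray) -> float:
    """Binary dyspnea-presence score: 1 - P(class 0)."""
    return float(1.0 - final_softmax[0])


def binary_auc(final_softmaxes, true_classes) -> float:
    """Healthy-vs-dyspnea AUC via the rank-sum formulation with tie correction.

    Subjects with true class 0 are the healthy group; classes 1-3 are
    the dyspnea group.  Scores are 1 - P(class 0).
    """
    scores = np.array([dyspnea_score(np.asarray(v)) for v in final_softmaxes])
    truth = np.asarray(true_classes)
    pos = scores[truth > 0]
    neg = scores[truth == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both healthy and dyspnea groups must be non-empty")
    from scipy.stats import rankdata

    allscores = np.concatenate([pos, neg])
    ranks = rankdata(allscores)  # midranks handle ties
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))
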