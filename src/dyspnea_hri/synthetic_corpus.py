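"""Synthetic stand-in for the clinical telephone vocalization database.

The real corpus — 100 subjects scored on the mMRC dyspnea scale
producing three controlled phonetizations (/ae-ae/, /sa-sa/ and
counting 1-to-30) twice each — is private clinical data.  This module
generates a synthetic corpus with the statistical structure the
downstream classifiers exploit: dyspnea severity shortens phonation,
inserts pauses, raises F0 jitter and adds audible breath noise.  No
claim of clinical fidelity is made; the generator is a controlled test
bed whose class-dependence is known by construction.

Each vocalization carries an event log (syllable/pause/breath
timestamps), so structural tests can assert construction properties
without audio analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import (
    DEFAULT_CLASS_COUNTS,
    N_CLASSES,
    PHONETIZATIONS,
    ClassProfile,
    ConfigurationError,
    GeneratorProfile,
)
from .audio import write_wav


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    mmrc_class: int
    group: str  # "healthy" | "patient"
    diagnosis: str = "none"  # metadata only; does not alter synthesis

    def __post_init__(self) -> None:
        if (self.mmrc_class == 0) != (self.group == "healthy"):
            raise ConfigurationError("mmrc_class 0 iff group healthy")
        if not 0 <= self.mmrc_class < N_CLASSES:
            raise ConfigurationError("mmrc_class out of range")


@dataclass
class Event:
    kind: str  # "syllable" | "pause" | "breath"
    start: float
    end: float


@dataclass
class Vocalization:
    subject_id: str
    mmrc_class: int
    phonetization: str
    repetition: int
    audio: np.ndarray
    rate: int
    events: list[Event] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return len(self.audio) / self.rate


# --------------------------------------------------------------------------
# subjects
# --------------------------------------------------------------------------

_PATIENT_DIAGNOSES = ("copd", "pf", "covid")


def generate_subjects(
    n_total: int = 100,
    n_per_class: tuple[int, int, int, int] = DEFAULT_CLASS_COUNTS,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Create the subject roster: ``n_per_class[c]`` subjects in mMRC class c.

    Class 0 subjects are the healthy group; patients get a diagnosis
    label (COPD / pulmonary fibrosis / post-COVID) carried as metadata
    only.
    """
    if sum(n_per_class) != n_total:
        raise ConfigurationError("sum(n_per_class) must equal n_total")
    if any(n < 1 for n in n_per_class):
        raise ConfigurationError("every class needs at least one subject")
    rng = np.random.default_rng(seed)
    subjects = []
    idx = 0
    for cls, n in enumerate(n_per_class):
        for _ in range(n):
            group = "healthy" if cls == 0 else "patient"
            diagnosis = "none" if cls == 0 else _PATIENT_DIAGNOSES[int(rng.integers(3))]
            subjects.append(
                SubjectRecord(f"s{idx:03d}", cls, group, diagnosis)
            )
            idx += 1
    return subjects


# --------------------------------------------------------------------------
# waveform building blocks
# --------------------------------------------------------------------------

# Vowel-like resonant filter: cascaded second-order resonators roughly at
# /a/-ish formant positions. Fixed across classes; severity acts on timing
# and F0 statistics, not on the vocal-tract shape.
_FORMANTS = ((700.0, 110.0), (1220.0, 120.0), (2600.0, 160.0))


def _resonator_coeffs(freq: float, bw: float, rate: int):
    r = np.exp(-np.pi * bw / rate)
    theta = 2.0 * np.pi * freq / rate
    a = np.array([1.0, -2.0 * r * np.cos(theta), r * r])
    b = np.array([1.0 - r])
    return b, a


def _vowel_segment(
    dur: float, f0_start: float, f0_end: float, jitter_sd: float,
    rate: int, rng: np.random.Generator,
) -> np.ndarray:
    """Harmonic pulse train through the fixed vowel resonator cascade."""
    n = max(int(round(dur * rate)), int(0.02 * rate))
    pulses = np.zeros(n)
    t = 0.0
    while t < dur:
        frac = t / dur if dur > 0 else 0.0
        f0 = (f0_start + (f0_end - f0_start) * frac) * (
            1.0 + jitter_sd * rng.standard_normal()
        )
        f0 = max(f0, 40.0)
        i = int(round(t * rate))
        if i < n:
            pulses[i] = 1.0
        t += 1.0 / f0
    x = pulses
    for freq, bw in _FORMANTS:
        b, a = _resonator_coeffs(freq, bw, rate)
        x = lfilter(b, a, x)
    ramp = min(int(0.02 * rate), n // 2)
    env = np.ones(n)
    env[:ramp] = np.linspace(0.0, 1.0, ramp)
    env[n - ramp:] = np.linspace(1.0, 0.0, ramp)
    x *= env
    rms = np.sqrt(np.mean(x**2)) or 1.0
    return 0.1 * x / rms


def _fricative_segment(dur: float, rate: int, rng: np.random.Generator) -> np.ndarray:
    """High-passed noise burst approximating /s/."""
    from scipy.signal import butter, sosfilt

    n = max(int(round(dur * rate)), int(0.02 * rate))
    sos = butter(4, 2500.0, btype="highpass", fs=rate, output="sos")
    x = sosfilt(sos, rng.standard_normal(n))
    ramp = min(int(0.01 * rate), n // 2)
    env = np.ones(n)
    env[:ramp] = np.linspace(0.0, 1.0, ramp)
    env[n - ramp:] = np.linspace(1.0, 0.0, ramp)
    x *= env
    rms = np.sqrt(np.mean(x**2)) or 1.0
    return 0.05 * x / rms


def _breath_segment(dur: float, gain_db: float, rate: int, rng: np.random.Generator) -> np.ndarray:
    """Band-limited (300-2000 Hz) noise burst emulating audible breathing."""
    from scipy.signal import butter, sosfilt

    n = max(int(round(dur * rate)), int(0.05 * rate))
    sos = butter(4, (300.0, 2000.0), btype="bandpass", fs=rate, output="sos")
    x = sosfilt(sos, rng.standard_normal(n))
    env = np.sin(np.linspace(0.0, np.pi, n)) ** 2
    x *= env
    rms = np.sqrt(np.mean(x**2)) or 1.0
    return 0.1 * 10.0 ** (gain_db / 20.0) * x / rms


# --------------------------------------------------------------------------
# vocalization synthesis
# --------------------------------------------------------------------------

_N_SYLLABLES = {"ae": 2, "sa": 2, "count": 30}
_BASE_GAP = {"ae": 0.15, "sa": 0.15, "count": 0.06}  # articulation gap (s)
_BREATH_DUR = 0.30
_MAX_GAP_FRACTION = 0.5  # pauses+breaths never exceed half the content budget


def synthesize_vocalization(
    subject: SubjectRecord,
    phonetization: str,
    repetition: int,
    profile: GeneratorProfile | None = None,
    seed: int = 0,
) -> Vocalization:
    """Synthesize one controlled vocalization for a subject.

    /ae-ae/ is two sustained vowel holds; /sa-sa/ alternates a fricative
    onset with the vowel hold; counting is 30 short vowel bursts
    separated by articulation gaps.  The subject's mMRC class selects
    the :class:`ClassProfile` driving content duration, pause and
    breath insertion, and F0 jitter.  Reproducible for a fixed seed.
    """
    if phonetization not in PHONETIZATIONS:
        raise ValueError(f"unknown phonetization {phonetization!r}")
    if repetition not in (1, 2):
        raise ValueError("repetition must be 1 or 2")
    profile = profile or GeneratorProfile()
    cls: ClassProfile = profile.classes[subject.mmrc_class]
    rate = profile.rate
    rng = np.random.default_rng(seed)

    # Content-duration budget; gaps are carved out of it so the total
    # utterance length stays calibrated.
    content = max(rng.normal(cls.duration_mean, cls.duration_sd), 2.0)
    n_syl = _N_SYLLABLES[phonetization]
    n_gaps = n_syl - 1
    base_gap = _BASE_GAP[phonetization]

    # Draw pause/breath structure for every inter-syllable gap up front;
    # identical seeds across classes then make pause time monotone in
    # severity (same uniforms against a larger pause_prob).
    gap_u = rng.random(n_gaps)
    pause_raw = np.abs(rng.normal(cls.pause_mean, 0.3 * cls.pause_mean, n_gaps))
    breath_u = rng.random(n_gaps)
    pause_on = gap_u < cls.pause_prob
    breath_on = breath_u < cls.breath_prob
    pause_dur = np.where(pause_on, np.maximum(pause_raw, 0.05), 0.0)
    breath_dur = np.where(breath_on, _BREATH_DUR, 0.0)

    budget = _MAX_GAP_FRACTION * content - n_gaps * base_gap
    extra = float(pause_dur.sum() + breath_dur.sum())
    if extra > budget > 0:
        scale = budget / extra
        pause_dur *= scale
        breath_dur *= scale

    phonation = content - n_gaps * base_gap - float(pause_dur.sum() + breath_dur.sum())
    weights = rng.uniform(0.8, 1.2, n_syl)
    syl_dur = phonation * weights / weights.sum()

    # Slow utterance-level F0 drift; per-period jitter on top.
    f0_slope = rng.normal(0.0, 0.03) * cls.f0_base  # Hz per second

    pieces: list[np.ndarray] = []
    events: list[Event] = []
    t = profile.edge_silence
    pieces.append(np.zeros(int(round(profile.edge_silence * rate))))
    for i in range(n_syl):
        d = float(syl_dur[i])
        f0_a = cls.f0_base + f0_slope * (t - profile.edge_silence)
        f0_b = cls.f0_base + f0_slope * (t - profile.edge_silence + d)
        if phonetization == "sa":
            fric = _fricative_segment(0.25 * d, rate, rng)
            vowel = _vowel_segment(0.75 * d, f0_a, f0_b, cls.f0_jitter_sd, rate, rng)
            seg = np.concatenate([fric, vowel])
        else:
            seg = _vowel_segment(d, f0_a, f0_b, cls.f0_jitter_sd, rate, rng)
        pieces.append(seg)
        events.append(Event("syllable", t, t + len(seg) / rate))
        t += len(seg) / rate
        if i < n_gaps:
            gap_pieces = [np.zeros(int(round(base_gap * rate)))]
            t_gap = t + base_gap
            if breath_dur[i] > 0:
                br = _breath_segment(float(breath_dur[i]), cls.breath_gain_db, rate, rng)
                gap_pieces.append(br)
                events.append(Event("breath", t_gap, t_gap + len(br) / rate))
                t_gap += len(br) / rate
            if pause_dur[i] > 0:
                gap_pieces.append(np.zeros(int(round(float(pause_dur[i]) * rate))))
                events.append(Event("pause", t_gap, t_gap + float(pause_dur[i])))
                t_gap += float(pause_dur[i])
            gap = np.concatenate(gap_pieces)
            pieces.append(gap)
            t += len(gap) / rate
    pieces.append(np.zeros(int(round(profile.edge_silence * rate))))

    audio = np.concatenate(pieces)
    audio = audio + profile.noise_floor_rms * rng.standard_normal(len(audio))
    peak = np.max(np.abs(audio))
    if peak > 0.95:
        audio *= 0.95 / peak
    return Vocalization(
        subject.subject_id, subject.mmrc_class, phonetization, repetition,
        audio.astype(np.float64), rate, events,
    )


# --------------------------------------------------------------------------
# corpus assembly
# --------------------------------------------------------------------------


def iter_corpus_specs(subjects: list[SubjectRecord], seed: int = 0):
    """Yield (subject, phonetization, repetition, per-file seed) for the corpus.

    Per-file seeds are derived from the master seed through a
    SeedSequence spawn so that the corpus is reproducible file-by-file.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(subjects) * len(PHONETIZATIONS) * 2)
    i = 0
    for subject in subjects:
        for phon in PHONETIZATIONS:
            for rep in (1, 2):
                file_seed = int(children[i].generate_state(1)[0] % (2**31))
                yield subject, phon, rep, file_seed
                i += 1


def generate_corpus(
    subjects: list[SubjectRecord],
    profile: GeneratorProfile | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    keep_audio: bool = True,
) -> tuple[list[Vocalization], pd.DataFrame]:
    """Generate the full corpus: |subjects| x 3 phonetizations x 2 repetitions.

    Returns the vocalizations and a metadata table (one row per file).
    When ``out_dir`` is given, writes ``<subject>_<type>_<rep>.wav``
    plus an event-log JSON sidecar per file and ``metadata.csv``.
    With ``keep_audio=False`` the returned vocalizations carry empty
    audio buffers (metadata and events only), which keeps large corpus
    statistics cheap.
    """
    if not subjects:
        raise ConfigurationError("subject list is empty")
    profile = profile or GeneratorProfile()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    vocs: list[Vocalization] = []
    rows = []
    for subject, phon, rep, file_seed in iter_corpus_specs(subjects, seed):
        voc = synthesize_vocalization(subject, phon, rep, profile, file_seed)
        rows.append(
            dict(
                subject_id=subject.subject_id,
                mmrc_class=subject.mmrc_class,
                group=subject.group,
                diagnosis=subject.diagnosis,
                phonetization=phon,
                repetition=rep,
                duration=voc.duration,
                seed=file_seed,
            )
        )
        if out_path is not None:
            stem = f"{subject.subject_id}_{phon}_{rep}"
            write_wav(out_path / f"{stem}.wav", voc.audio, voc.rate)
            with open(out_path / f"{stem}.events.json", "w") as fh:
                json.dump([e.__dict__ for e in voc.events], fh)
        if not keep_audio:
            # the true duration stays in the metadata row
            voc = Vocalization(
                voc.subject_id, voc.mmrc_class, voc.phonetization,
                voc.repetition, np.zeros(0), voc.rate, voc.events,
            )
        vocs.append(voc)
    meta = pd.DataFrame(rows)
    if out_path is not None:
        meta.to_csv(out_path / "metadata.csv", index=False)
    return vocs, meta


def total_pause_time(voc: Vocalization) -> float:
    return sum(e.end - e.start for e in voc.events if e.kind == "pause")


def syllable_count(voc: Vocalization) -> int:
    return sum(1 for e in voc.events if e.kind == "syllable")
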