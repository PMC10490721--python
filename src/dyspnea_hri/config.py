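"""Configuration objects for the dyspnea-estimation pipeline.

Every tunable of the synthetic corpus, the acoustic scene and the
classifier stack lives in a dataclass here, with defaults set to the
study conditions: a 100-subject corpus (34 healthy, 66 patients),
three controlled phonetizations repeated twice (600 vocalizations,
12.7 s grand-mean duration), a 104 m^3 room with RT60 = 0.5 s, a
4-microphone linear array 2 m from the speaker, a noise source 45
degrees away at 10 dB SNR, and a head that either stays fixed or
sweeps +/-50 degrees at 0.42 rad/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


# --------------------------------------------------------------------------
# synthetic corpus
# --------------------------------------------------------------------------

PHONETIZATIONS = ("ae", "sa", "count")
N_CLASSES = 4  # mMRC 0..3 (3 and 4 merged)


@dataclass(frozen=True)
class ClassProfile:
    """Per-mMRC-class generator parameters.

    ``duration_mean``/``duration_sd`` govern the phonated *content*
    length in seconds (edge silences excluded); ``pause_prob`` is the
    per-syllable-gap probability of an inserted silent pause;
    ``breath_prob`` the per-gap probability of an audible breath burst.
    F0 jitter is a relative (unitless) SD applied per pitch period.
    """

    duration_mean: float
    duration_sd: float
    pause_prob: float
    pause_mean: float
    f0_base: float
    f0_jitter_sd: float
    breath_prob: float
    breath_gain_db: float


@dataclass(frozen=True)
class GeneratorProfile:
    """Full synthetic-corpus generator profile (one ClassProfile per class)."""

    classes: tuple[ClassProfile, ...] = (
        ClassProfile(13.25, 0.15 * 13.25, 0.05, 0.25, 125.0, 0.010, 0.00, -20.0),
        ClassProfile(12.60, 0.15 * 12.60, 0.15, 0.35, 120.0, 0.020, 0.10, -18.0),
        ClassProfile(11.20, 0.15 * 11.20, 0.30, 0.45, 115.0, 0.040, 0.25, -15.0),
        ClassProfile(9.85, 0.15 * 9.85, 0.45, 0.55, 110.0, 0.060, 0.40, -12.0),
    )
    rate: int = 16000
    edge_silence: float = 0.4  # s of near-silence before and after content
    noise_floor_rms: float = 1e-4  # keeps edge intervals non-degenerate

    def __post_init__(self) -> None:
        if len(self.classes) != N_CLASSES:
            raise ConfigurationError(f"need {N_CLASSES} class profiles")
        for c in self.classes:
            if not (0.0 <= c.pause_prob <= 1.0 and 0.0 <= c.breath_prob <= 1.0):
                raise ConfigurationError("probabilities must lie in [0, 1]")
            if c.duration_mean <= 0 or c.duration_sd <= 0 or c.pause_mean <= 0:
                raise ConfigurationError("durations must be positive")
        means = [c.duration_mean for c in self.classes]
        pauses = [c.pause_prob for c in self.classes]
        if any(a < b for a, b in zip(means, means[1:])):
            raise ConfigurationError("duration means must be non-increasing in class")
        if any(a > b for a, b in zip(pauses, pauses[1:])):
            raise ConfigurationError("pause probabilities must be non-decreasing in class")


DEFAULT_CLASS_COUNTS = (34, 22, 22, 22)  # healthy, then mMRC 1..3 of the 66 patients


# --------------------------------------------------------------------------
# acoustic scene
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ArrayGeometry:
    """Linear microphone array: offsets d_l (m) from the reference microphone."""

    mic_offsets: tuple[float, ...] = (0.0, 0.04, 0.08, 0.12)
    speed_of_sound: float = 343.0

    def __post_init__(self) -> None:
        if self.mic_offsets[0] != 0.0:
            raise ConfigurationError("reference microphone offset must be 0")
        if any(a >= b for a, b in zip(self.mic_offsets, self.mic_offsets[1:])):
            raise ConfigurationError("microphone offsets must be strictly increasing")

    @property
    def n_mics(self) -> int:
        return len(self.mic_offsets)


@dataclass(frozen=True)
class RoomSpec:
    """Shoebox room; default dimensions give the study's ~104 m^3 volume."""

    dimensions: tuple[float, float, float] = (6.5, 5.35, 3.0)
    rt60: float = 0.5
    array_origin: tuple[float, float, float] = (2.6, 1.4, 1.4)

    def __post_init__(self) -> None:
        if min(self.dimensions) <= 0:
            raise ConfigurationError("room dimensions must be positive")
        if self.rt60 <= 0:
            raise ConfigurationError("rt60 must be positive")
        if not all(0 < p < d for p, d in zip(self.array_origin, self.dimensions)):
            raise ConfigurationError("array origin must lie inside the room")

    @property
    def volume(self) -> float:
        x, y, z = self.dimensions
        return x * y * z


@dataclass(frozen=True)
class MotionProfile:
    """Head motion: static at ``angle`` or triangular sweep between limits."""

    kind: str = "static"  # "static" | "dynamic"
    angle: float = 0.0  # degrees, static look/head angle
    rate: float = 0.42  # rad/s, dynamic angular speed
    limit: float = 50.0  # degrees, symmetric sweep limits

    def __post_init__(self) -> None:
        if self.kind not in ("static", "dynamic"):
            raise ConfigurationError("motion kind must be 'static' or 'dynamic'")
        if self.kind == "dynamic" and self.rate <= 0:
            raise ConfigurationError("dynamic motion rate must be positive")


@dataclass(frozen=True)
class SceneConfig:
    """One capture scenario: source distance/SNR and noise placement."""

    distance: float = 2.0  # m from reference microphone to the speech source
    speech_snr_db: float = 10.0
    noise_separation: float = 45.0  # degrees between speech and noise sources
    robot_env_ratio_db: tuple[float, float] = (-5.0, 5.0)
    motion: MotionProfile = field(default_factory=MotionProfile)
    sensor_noise_db: float = -40.0  # uncorrelated per-mic noise below speech level

    def __post_init__(self) -> None:
        lo, hi = self.robot_env_ratio_db
        if lo > hi:
            raise ConfigurationError("robot/env ratio range must be ordered")


# --------------------------------------------------------------------------
# RIR training grid (33 conditions: 3 distances x 11 head angles)
# --------------------------------------------------------------------------

GRID_DISTANCES = (1.0, 2.0, 3.0)
GRID_ANGLES = tuple(float(a) for a in range(-50, 51, 10))
TRAIN_SNR_RANGE = (5.0, 15.0)


# --------------------------------------------------------------------------
# features / classifiers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureConfig:
    """Feature front-end: telephone-provenance 8 kHz analysis."""

    rate: int = 8000
    window_s: float = 0.050
    overlap: float = 0.5
    dft_size: int = 512
    n_mel: int = 14
    spectral_keep_frac: float = 0.75  # lowest bins kept for the counting task
    f0_min: float = 60.0
    f0_max: float = 400.0
    f0_window_s: float = 0.050
    f0_hop_s: float = 0.010
    voicing_threshold: float = 0.45


# --------------------------------------------------------------------------
# yaml round-trip
# --------------------------------------------------------------------------


def profile_to_dict(profile: GeneratorProfile) -> dict:
    return asdict(profile)


def profile_from_dict(d: dict) -> GeneratorProfile:
    classes = tuple(ClassProfile(**c) for c in d["classes"])
    rest = {k: v for k, v in d.items() if k != "classes"}
    return GeneratorProfile(classes=classes, **rest)


def load_profile(path: str | Path) -> GeneratorProfile:
    with open(path) as fh:
        return profile_from_dict(yaml.safe_load(fh))


def save_profile(profile: GeneratorProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(profile_to_dict(profile), fh)
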