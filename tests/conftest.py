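import numpy as np
import pytest

from dyspnea_hri.config import ArrayGeometry, ClassProfile, GeneratorProfile, RoomSpec
from dyspnea_hri.synthetic_corpus import generate_subjects, synthesize_vocalization


@pytest.fixture(scope="session")
def geometry():
    return ArrayGeometry()


@pytest.fixture(scope="session")
def room():
    return RoomSpec()


@pytest.fixture(scope="session")
def tiny_subjects():
    """One subject per mMRC class."""
    return generate_subjects(4, (1, 1, 1, 1), seed=0)


def short_profile(scale: float = 0.25) -> GeneratorProfile:
    """Generator profile with shortened content durations for fast tests;
    class structure (pauses, jitter, breath) is unchanged."""
    base = GeneratorProfile()
    classes = tuple(
        ClassProfile(
            duration_mean=c.duration_mean * scale,
            duration_sd=c.duration_sd * scale,
            pause_prob=c.pause_prob,
            pause_mean=c.pause_mean * scale,
            f0_base=c.f0_base,
            f0_jitter_sd=c.f0_jitter_sd,
            breath_prob=c.breath_prob,
            breath_gain_db=c.breath_gain_db,
        )
        for c in base.classes
    )
    return GeneratorProfile(classes=classes)


@pytest.fixture(scope="session")
def short_voc(tiny_subjects):
    """A short class-0 /ae/ vocalization for scene/beamforming tests."""
    return synthesize_vocalization(tiny_subjects[0], "ae", 1, short_profile(), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
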