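"""Shared low-level DSP: array steering delays and fractional delay lines."""

from __future__ import annotations

import numpy as np

from .config import ArrayGeometry


def das_delays(geometry: ArrayGeometry, doa_deg: float) -> np.ndarray:
    """Steering delays tau_l = (d_l / v) * sin(phi) in seconds.

    phi is the direction of arrival measured from broadside; microphone 1
    (offset 0) is the reference, so tau_1 == 0.  Positive phi means the
    wavefront reaches the far microphones first.
    """
    if abs(doa_deg) > 90.0:
        raise ValueError("|DOA| must be <= 90 degrees for a linear array")
    d = np.asarray(geometry.mic_offsets, dtype=np.float64)
    return d / geometry.speed_of_sound * np.sin(np.deg2rad(doa_deg))


def delay_filter(frac: float, taps: int = 8) -> tuple[np.ndarray, int]:
    """Hann-windowed sinc interpolator for a fractional delay in [0, 1).

    Returns (h, offset) such that y[i] = sum_j h[j] * x[i - j + offset]
    delays x by ``frac`` samples.
    """
    half = taps // 2
    j = np.arange(-half + 1, half + 1)  # e.g. -3..4 for 8 taps
    h = np.sinc(j - frac)
    win = np.hanning(2 * taps + 1)[taps - half + 1 + np.arange(taps)]
    h = h * win
    h /= h.sum()
    return h, half - 1


def fractional_delay(x: np.ndarray, delay_samples: float, taps: int = 8) -> np.ndarray:
    """Delay a signal by a (possibly fractional, possibly negative) number
    of samples using windowed-sinc interpolation; output length preserved."""
    n0 = int(np.floor(delay_samples))
    frac = delay_samples - n0
    h, offset = delay_filter(frac, taps)
    y = np.convolve(x, h, mode="full")[offset: offset + len(x)]
    shift = n0
    out = np.zeros_like(x, dtype=np.float64)
    if shift >= 0:
        if shift < len(x):
            out[shift:] = y[: len(x) - shift]
    else:
        if -shift < len(x):
            out[: len(x) + shift] = y[-shift:]
    return out
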