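"""Minimal WAV I/O and resampling helpers (PCM 16-bit via scipy)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly


def write_wav(path: str | Path, audio: np.ndarray, rate: int) -> None:
    """Write float audio in [-1, 1] as PCM 16-bit; channels-last for multichannel."""
    x = np.asarray(audio, dtype=np.float64)
    if x.ndim == 2 and x.shape[0] < x.shape[1]:
        x = x.T  # (n_samples, n_channels) on disk
    x = np.clip(x, -1.0, 1.0)
    wavfile.write(str(path), rate, (x * 32767.0).astype(np.int16))


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a WAV file into float64 in [-1, 1]; multichannel as (L, n_samples)."""
    rate, data = wavfile.read(str(path))
    if data.dtype == np.int16:
        x = data.astype(np.float64) / 32767.0
    elif data.dtype == np.int32:
        x = data.astype(np.float64) / 2147483647.0
    else:
        x = data.astype(np.float64)
    if x.ndim == 2:
        x = x.T
    return x, int(rate)


def resample(audio: np.ndarray, rate_in: int, rate_out: int) -> np.ndarray:
    if rate_in == rate_out:
        return audio
    g = np.gcd(rate_in, rate_out)
    return resample_poly(audio, rate_out // g, rate_in // g, axis=-1)
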