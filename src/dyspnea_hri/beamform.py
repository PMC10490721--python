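"""Delay-and-sum and MVDR spatial filtering for the 4-microphone array.

Delay-and-sum time-aligns the channels toward the direction of arrival
and sums them, y(t) = sum_l x_l(t - tau_l) with tau_l = (d_l/v) sin(phi)
(no 1/L normalization).  MVDR minimizes output noise power subject to a
unit (distortionless) gain in the look direction: per frame m and
frequency bin w,

    w^H = v^H Sigma_N^-1 / (v^H Sigma_N^-1 v),    Y = w^H X,

with steering vector v encoding the inter-microphone phase shifts of
the look direction (see :func:`steering_vector`) and Sigma_N the noise
spatial covariance estimated from noise-only frames (diagonal-loaded
for invertibility).  The module also houses the STFT machinery and the
edge-interval SNR estimator used to score the beamformers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._dsp import das_delays, delay_filter, fractional_delay  # noqa: F401  (re-export)
from .config import ArrayGeometry

DIAGONAL_LOADING = 1e-3
DEFAULT_FRAME_S = 0.032
EDGE_DURATION_S = 0.3


# --------------------------------------------------------------------------
# STFT
# --------------------------------------------------------------------------


@dataclass
class SpectralFrames:
    """Per-channel complex short-time spectra X[l, m, w].

    ``x`` has shape (L, M, num_freq_bins) with
    num_freq_bins == dft_size // 2 + 1.
    """

    x: np.ndarray
    rate: int
    frame_length: int
    hop: int
    dft_size: int
    n_samples: int

    @property
    def n_channels(self) -> int:
        return self.x.shape[0]

    @property
    def n_frames(self) -> int:
        return self.x.shape[1]

    @property
    def num_freq_bins(self) -> int:
        return self.dft_size // 2 + 1

    @property
    def bin_freqs(self) -> np.ndarray:
        return np.fft.rfftfreq(self.dft_size, 1.0 / self.rate)

    def frame_times(self) -> np.ndarray:
        """Center time (s) of each frame."""
        return (np.arange(self.n_frames) * self.hop + self.frame_length / 2) / self.rate


def _sqrt_hann(n: int) -> np.ndarray:
    return np.sqrt(np.hanning(n + 1)[:n])


def stft(
    channels: np.ndarray,
    rate: int,
    frame_length: int | None = None,
    overlap: float = 0.5,
    dft_size: int | None = None,
) -> SpectralFrames:
    """Square-root-Hann STFT of one or more channels (COLA at 50% overlap)."""
    x = np.atleast_2d(np.asarray(channels, dtype=np.float64))
    if x.size == 0:
        raise ValueError("empty input")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    frame_length = frame_length or int(round(DEFAULT_FRAME_S * rate))
    dft_size = dft_size or frame_length
    if dft_size < frame_length:
        raise ValueError("dft_size must be >= frame_length")
    hop = max(int(round(frame_length * (1.0 - overlap))), 1)
    n = x.shape[1]
    n_frames = max((n - frame_length) // hop + 1, 1)
    win = _sqrt_hann(frame_length)
    idx = np.arange(frame_length)[None, :] + hop * np.arange(n_frames)[:, None]
    pad = np.zeros((x.shape[0], max(idx.max() + 1 - n, 0)))
    xp = np.concatenate([x, pad], axis=1)
    frames = xp[:, idx] * win  # (L, M, frame_length)
    spec = np.fft.rfft(frames, n=dft_size, axis=2)
    return SpectralFrames(spec, rate, frame_length, hop, dft_size, n)


def istft(frames: SpectralFrames) -> np.ndarray:
    """Overlap-add inverse of :func:`stft`; returns (L, n_samples) or (n,) mono."""
    spec = frames.x
    win = _sqrt_hann(frames.frame_length)
    blocks = np.fft.irfft(spec, n=frames.dft_size, axis=2)[:, :, : frames.frame_length]
    blocks = blocks * win
    L, M, _ = blocks.shape
    total = (M - 1) * frames.hop + frames.frame_length
    out = np.zeros((L, total))
    norm = np.zeros(total)
    for m in range(M):
        s = m * frames.hop
        out[:, s: s + frames.frame_length] += blocks[:, m]
        norm[s: s + frames.frame_length] += win**2
    norm = np.maximum(norm, 1e-12)
    out /= norm
    if total < frames.n_samples:  # trailing partial frame was never analyzed
        out = np.pad(out, ((0, 0), (0, frames.n_samples - total)))
    out = out[:, : frames.n_samples]
    return out[0] if L == 1 else out


# --------------------------------------------------------------------------
# delay-and-sum
# --------------------------------------------------------------------------


def delay_and_sum(
    capture,
    doa: float | np.ndarray | None = None,
    geometry: ArrayGeometry | None = None,
    block_s: float = 0.02,
) -> np.ndarray:
    """Delay-and-sum beamformer output.

    ``capture`` is an :class:`~dyspnea_hri.array_sim.ArrayCapture` (or
    any object with ``channels``, ``rate`` and optionally
    ``doa_track``).  A scalar ``doa`` steers statically; otherwise the
    capture's per-sample DOA track is followed block-wise.
    """
    geometry = geometry or ArrayGeometry()
    channels = np.asarray(capture.channels, dtype=np.float64)
    rate = capture.rate
    L, n = channels.shape
    if doa is None:
        doa = getattr(capture, "doa_track", None)
        if doa is None:
            raise ValueError("no DOA given and the capture has no doa_track")
    if np.isscalar(doa):
        taus = das_delays(geometry, float(doa)) * rate
        return sum(
            fractional_delay(channels[l], taus[l]) for l in range(L)
        )
    doa = np.asarray(doa, dtype=np.float64)
    if doa.shape != (n,):
        raise ValueError("doa_track length must match the capture")
    block = max(int(round(block_s * rate)), 1)
    out = np.zeros(n)
    for start in range(0, n, block):
        end = min(start + block, n)
        phi = float(np.mean(doa[start:end]))
        taus = das_delays(geometry, phi) * rate
        for l in range(L):
            lo = max(start - 64, 0)
            hi = min(end + 64, n)
            seg = fractional_delay(channels[l, lo:hi], taus[l])
            out[start:end] += seg[start - lo: end - lo]
    return out


# --------------------------------------------------------------------------
# MVDR
# --------------------------------------------------------------------------


def steering_vector(
    geometry: ArrayGeometry, doa_deg: float, freqs: np.ndarray
) -> np.ndarray:
    """Per-frequency steering phasors, shape (num_freq_bins, L).

    A wavefront from phi reaches microphone l tau_l seconds *before*
    the reference, so its spatial signature under the DFT convention is
    v_l = exp(+j 2 pi f tau_l); applying w = v/L in Y = w^H X delays
    each channel by tau_l, i.e. exactly the delay-and-sum alignment.
    """
    taus = das_delays(geometry, doa_deg)
    return np.exp(2j * np.pi * freqs[:, None] * taus[None, :])


def edge_noise_mask(frames: SpectralFrames, edge_duration: float = EDGE_DURATION_S) -> np.ndarray:
    """Frame mask flagging the leading/trailing non-speech edge intervals."""
    t = frames.frame_times()
    total = frames.n_samples / frames.rate
    return (t <= edge_duration) | (t >= total - edge_duration)


def estimate_noise_covariance(
    frames: SpectralFrames,
    noise_mask: np.ndarray,
    loading: float = DIAGONAL_LOADING,
) -> tuple[np.ndarray, bool]:
    """Noise spatial covariance per bin from noise-flagged frames.

    Returns (Sigma_N, flagged) where Sigma_N has shape (num_freq_bins,
    L, L): the sample covariance over noise frames plus diagonal
    loading ``loading * trace/L``.  ``flagged`` is True when fewer
    noise frames than channels were available (loading dominates).
    """
    noise_mask = np.asarray(noise_mask, dtype=bool)
    if noise_mask.shape != (frames.n_frames,):
        raise ValueError("noise_mask must have one flag per frame")
    if not noise_mask.any():
        raise ValueError(
            "no noise-only frames available; fall back to the edge-interval mask"
        )
    xn = frames.x[:, noise_mask, :]  # (L, Mn, B)
    L, mn, b = xn.shape
    xn = np.moveaxis(xn, 2, 0)  # (B, L, Mn)
    sigma = np.einsum("bli,bki->blk", xn, np.conj(xn)) / mn
    tr = np.real(np.trace(sigma, axis1=1, axis2=2)) / L
    eye = np.eye(L)
    sigma = sigma + (loading * np.maximum(tr, 1e-12))[:, None, None] * eye
    flagged = mn < L or np.all(tr <= 1e-12)
    return sigma, flagged


def mvdr_weights(steering: np.ndarray, sigma_n: np.ndarray) -> np.ndarray:
    """Distortionless MVDR weights w = Sigma^-1 v / (v^H Sigma^-1 v).

    Accepts a single (L,) / (L, L) pair or stacked (..., L) / (..., L, L)
    arrays; satisfies w^H v == 1 at every (frame, bin).
    """
    v = np.asarray(steering, dtype=np.complex128)
    sigma = np.asarray(sigma_n, dtype=np.complex128)
    squeeze = v.ndim == 1
    if squeeze:
        v = v[None, :]
        sigma = sigma[None, :, :]
    try:
        tilde = np.linalg.solve(sigma, v[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "noise covariance singular even after diagonal loading"
        ) from exc
    denom = np.einsum("...l,...l->...", np.conj(v), tilde)
    w = tilde / denom[..., None]
    return w[0] if squeeze else w


def mvdr_filter(
    capture,
    doa: float | np.ndarray | None = None,
    geometry: ArrayGeometry | None = None,
    noise_mask: np.ndarray | None = None,
    frame_length: int | None = None,
    loading: float = DIAGONAL_LOADING,
) -> np.ndarray:
    """MVDR beamformer output, Y(m, w) = w(m, w)^H X(m, w), back in time domain.

    The noise covariance comes from noise-flagged frames (default: the
    0.3 s edge intervals).  For dynamic captures the steering vector is
    rebuilt per frame from the DOA track.
    """
    geometry = geometry or ArrayGeometry()
    channels = np.atleast_2d(np.asarray(capture.channels, dtype=np.float64))
    rate = capture.rate
    L = channels.shape[0]
    if L == 1:
        return channels[0].copy()
    frames = stft(channels, rate, frame_length=frame_length)
    if noise_mask is None:
        noise_mask = edge_noise_mask(frames)
    sigma, _ = estimate_noise_covariance(frames, noise_mask, loading)
    freqs = frames.bin_freqs

    if doa is None:
        doa = getattr(capture, "doa_track", None)
        if doa is None:
            raise ValueError("no DOA given and the capture has no doa_track")
    if np.isscalar(doa):
        v = steering_vector(geometry, float(doa), freqs)  # (B, L)
        w = mvdr_weights(v, sigma)  # (B, L)
        y = np.einsum("bl,lmb->mb", np.conj(w), frames.x)
    else:
        doa = np.asarray(doa, dtype=np.float64)
        times = np.minimum(
            (frames.frame_times() * rate).astype(int), len(doa) - 1
        )
        frame_doa = doa[times]
        y = np.empty((frames.n_frames, frames.num_freq_bins), dtype=np.complex128)
        for m in range(frames.n_frames):
            v = steering_vector(geometry, float(frame_doa[m]), freqs)
            w = mvdr_weights(v, sigma)
            y[m] = np.einsum("bl,lb->b", np.conj(w), frames.x[:, m, :])
    out_frames = SpectralFrames(
        y[None, :, :], rate, frames.frame_length, frames.hop,
        frames.dft_size, frames.n_samples,
    )
    return istft(out_frames)


# --------------------------------------------------------------------------
# SNR estimation
# --------------------------------------------------------------------------


def estimate_snr(
    samples: np.ndarray, rate: int, edge_duration: float = EDGE_DURATION_S,
    eps: float = 1e-12,
) -> float:
    """SNR (dB) using the noise energy of the 0.3 s edge intervals.

    Noise power is the mean power of the leading and trailing
    ``edge_duration`` seconds; the interior total power minus the noise
    power estimates the speech power.  Returns a floor-limited value
    for all-noise inputs.
    """
    x = np.asarray(samples, dtype=np.float64)
    ne = int(round(edge_duration * rate))
    if len(x) <= 2 * ne:
        raise ValueError("file shorter than twice the edge duration")
    p_noise = float(np.mean(np.concatenate([x[:ne], x[-ne:]]) ** 2))
    interior = x[ne:-ne]
    p_total = float(np.mean(interior**2))
    p_noise = max(p_noise, eps)
    return 10.0 * np.log10(max(p_total - p_noise, eps) / p_noise)
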