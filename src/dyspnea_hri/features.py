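"""Feature extraction for dyspnea estimation.

Two feature families are computed per vocalization at the telephone
front-end rate of 8 kHz:

* time-independent: a 3-vector — the SD of the mean-normalized F0
  curve, the mean normalized F0 slope, and the phonetization duration
  in seconds;
* time-dependent: per-frame matrices from 50 ms windows with 50%
  overlap and a 512-point FFT (257 bins) — 14 log-mel filter energies
  for /ae-ae/ and /sa-sa/, and for the counting task the lowest 75% of
  log-spectral bins plus their first-difference deltas (193 x 2 = 386
  dims/frame).

Mean-and-variance normalization (MVN) statistics are fitted over the
whole database by default; zero padding to the longest training
utterance of the same phonetization fixes the matrix size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import resample
from .config import ConfigurationError, FeatureConfig


# --------------------------------------------------------------------------
# framing helpers
# --------------------------------------------------------------------------


def _frame_signal(x: np.ndarray, window: int, hop: int) -> np.ndarray:
    n = len(x)
    if n < window:
        raise ValueError("input shorter than one analysis window")
    n_frames = (n - window) // hop + 1
    idx = np.arange(window)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def _power_spectrum(audio: np.ndarray, rate: int, cfg: FeatureConfig) -> np.ndarray:
    x = resample(np.asarray(audio, dtype=np.float64), rate, cfg.rate)
    window = int(round(cfg.window_s * cfg.rate))
    hop = max(int(round(window * (1.0 - cfg.overlap))), 1)
    frames = _frame_signal(x, window, hop) * np.hanning(window)
    spec = np.fft.rfft(frames, n=cfg.dft_size, axis=1)
    return np.abs(spec) ** 2  # (M, dft_size//2 + 1)


# --------------------------------------------------------------------------
# F0
# --------------------------------------------------------------------------


@dataclass
class F0Track:
    f0: np.ndarray  # Hz; 0 on unvoiced frames
    voiced: np.ndarray  # bool per frame
    hop_s: float


def extract_f0(audio: np.ndarray, rate: int, cfg: FeatureConfig | None = None) -> F0Track:
    """Frame-by-frame F0 via normalized autocorrelation peak picking.

    Search range 60-400 Hz; a frame is voiced when the normalized
    autocorrelation peak exceeds the voicing threshold (0.45) and has
    non-negligible energy.  Octave-down errors are avoided by taking
    the smallest lag within 90% of the best peak.
    """
    cfg = cfg or FeatureConfig()
    x = resample(np.asarray(audio, dtype=np.float64), rate, cfg.rate)
    if x.size == 0:
        raise ValueError("empty audio")
    fs = cfg.rate
    window = int(round(cfg.f0_window_s * fs))
    hop = int(round(cfg.f0_hop_s * fs))
    frames = _frame_signal(x, window, hop)
    frames = frames - frames.mean(axis=1, keepdims=True)
    m, n = frames.shape

    lag_min = int(np.floor(fs / cfg.f0_max))
    lag_max = min(int(np.ceil(fs / cfg.f0_min)), n - 1)

    # normalized cross-correlation r[t] = sum x_i x_{i+t} / sqrt(e1[t] e2[t])
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=1)[:, : lag_max + 1]
    csq = np.concatenate(
        [np.zeros((m, 1)), np.cumsum(frames**2, axis=1)], axis=1
    )
    total = csq[:, -1]
    lags = np.arange(lag_max + 1)
    e1 = csq[:, n - lags]  # sum_{i<n-t} x_i^2
    e2 = total[:, None] - csq[:, lags]  # sum_{i>=t} x_i^2
    denom = np.sqrt(np.maximum(e1 * e2, 1e-20))
    ncc = ac / denom

    band = ncc[:, lag_min: lag_max + 1]
    best = np.argmax(band, axis=1)
    best_val = band[np.arange(m), best]
    # prefer the smallest lag nearly as good as the best (octave control)
    thresh = 0.9 * best_val[:, None]
    first_good = np.argmax(band >= thresh, axis=1)
    lag = first_good + lag_min
    peak = band[np.arange(m), first_good]

    energy = frames.var(axis=1)
    voiced = (peak > cfg.voicing_threshold) & (energy > 1e-8)

    # parabolic interpolation around the picked lag
    f0 = np.zeros(m)
    for i in np.flatnonzero(voiced):
        t = lag[i]
        if 1 <= t < ncc.shape[1] - 1:
            y0, y1, y2 = ncc[i, t - 1], ncc[i, t], ncc[i, t + 1]
            denom_p = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom_p if abs(denom_p) > 1e-12 else 0.0
            t = t + np.clip(delta, -0.5, 0.5)
        f0[i] = fs / t
    return F0Track(f0, voiced, hop / fs)


# --------------------------------------------------------------------------
# time-independent features
# --------------------------------------------------------------------------


@dataclass
class TimeIndependentVector:
    f0_spread: float
    f0_norm_slope_mean: float
    duration: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.f0_spread, self.f0_norm_slope_mean, self.duration])


def time_independent_features(
    audio: np.ndarray, rate: int, cfg: FeatureConfig | None = None
) -> TimeIndependentVector:
    """The 3-vector of time-independent features.

    * ``f0_spread``: SD of F0/mean(F0) over voiced frames (unitless);
    * ``f0_norm_slope_mean``: mean over consecutive voiced-frame pairs
      of (dF0/dt) / mean(F0) (1/s);
    * ``duration``: file length in seconds.

    With fewer than two voiced frames the F0 terms are zeroed and the
    vector is flagged degenerate.
    """
    track = extract_f0(audio, rate, cfg)
    duration = len(audio) / rate
    vf = track.f0[track.voiced]
    if vf.size < 2:
        return TimeIndependentVector(0.0, 0.0, duration, degenerate=True)
    mean_f0 = float(np.mean(vf))
    spread = float(np.std(vf / mean_f0))
    vidx = np.flatnonzero(track.voiced)
    pair_mask = np.diff(vidx) >= 1
    dt = np.diff(vidx) * track.hop_s
    df = np.diff(track.f0[vidx])
    slopes = (df / dt) / mean_f0
    slope_mean = float(np.mean(slopes[pair_mask])) if pair_mask.any() else 0.0
    return TimeIndependentVector(spread, slope_mean, duration)


# --------------------------------------------------------------------------
# time-dependent features
# --------------------------------------------------------------------------

LOG_FLOOR = 1e-10


def mel_filterbank(cfg: FeatureConfig) -> np.ndarray:
    """Triangular mel filterbank, (n_mel, num_freq_bins), spanning 0..rate/2."""
    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(mel):
        return 700.0 * (10.0 ** (np.asarray(mel) / 2595.0) - 1.0)

    n_bins = cfg.dft_size // 2 + 1
    f_max = cfg.rate / 2.0
    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(f_max), cfg.n_mel + 2)
    hz_pts = mel_to_hz(mel_pts)
    bin_freqs = np.fft.rfftfreq(cfg.dft_size, 1.0 / cfg.rate)
    fb = np.zeros((cfg.n_mel, n_bins))
    for i in range(cfg.n_mel):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (bin_freqs - lo) / max(ctr - lo, 1e-9)
        down = (hi - bin_freqs) / max(hi - ctr, 1e-9)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


def mel_features(audio: np.ndarray, rate: int, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Log-mel energies for /ae-ae/ and /sa-sa/: (n_frames, 14)."""
    cfg = cfg or FeatureConfig()
    power = _power_spectrum(audio, rate, cfg)
    fb = mel_filterbank(cfg)
    return np.log(np.maximum(power @ fb.T, LOG_FLOOR))


def n_kept_bins(cfg: FeatureConfig) -> int:
    """Lowest-bin count for the counting task: ceil(0.75 * 257) = 193."""
    return int(np.ceil(cfg.spectral_keep_frac * (cfg.dft_size // 2 + 1)))


def counting_spectral_features(
    audio: np.ndarray, rate: int, cfg: FeatureConfig | None = None
) -> np.ndarray:
    """Log-spectrum features for the 1-to-30 counting task.

    The lowest 193 of 257 log-power bins concatenated with their
    first-difference deltas (zero-prepended): (n_frames, 386).
    """
    cfg = cfg or FeatureConfig()
    power = _power_spectrum(audio, rate, cfg)
    static = np.log(np.maximum(power[:, : n_kept_bins(cfg)], LOG_FLOOR))
    delta = np.diff(static, axis=0, prepend=static[:1])
    delta[0] = 0.0
    return np.concatenate([static, delta], axis=1)


# --------------------------------------------------------------------------
# MVN
# --------------------------------------------------------------------------

VAR_FLOOR = 1e-8


@dataclass
class MVNStats:
    mean: np.ndarray
    var: np.ndarray
    flagged_dims: np.ndarray  # bool per dim: variance hit the floor


def fit_mvn(rows: np.ndarray) -> MVNStats:
    """Fit per-dimension mean/variance over the whole fitting population."""
    rows = np.asarray(rows, dtype=np.float64)
    mean = rows.mean(axis=0)
    var = rows.var(axis=0)
    flagged = var < VAR_FLOOR
    return MVNStats(mean, np.maximum(var, VAR_FLOOR), flagged)


def apply_mvn(features: np.ndarray, stats: MVNStats) -> np.ndarray:
    out = (np.asarray(features, dtype=np.float64) - stats.mean) / np.sqrt(stats.var)
    if stats.flagged_dims.any():
        out[..., stats.flagged_dims] = 0.0
    return out


def invert_mvn(features: np.ndarray, stats: MVNStats) -> np.ndarray:
    return np.asarray(features) * np.sqrt(stats.var) + stats.mean


# --------------------------------------------------------------------------
# padding
# --------------------------------------------------------------------------


def pad_to_length(features: np.ndarray, pad_length: int) -> np.ndarray:
    """Zero-pad (or truncate, flag-free) a (frames x dims) matrix to
    ``pad_length`` rows; pad rows are exactly zero."""
    if pad_length <= 0:
        raise ConfigurationError("pad_length must be positive")
    features = np.asarray(features, dtype=np.float64)
    m, d = features.shape
    if m >= pad_length:
        return features[:pad_length].copy()
    out = np.zeros((pad_length, d))
    out[:m] = features
    return out
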