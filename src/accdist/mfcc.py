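"""Mel-frequency cepstral features for word-level pronunciation comparison.

Each word waveform becomes a T x 39 feature matrix: per 25 ms Hamming frame
(10 ms step) the first 12 mel-cepstral coefficients plus log frame energy,
followed by their first and second temporal derivatives (delta and
double-delta).  The chain is pre-emphasis -> framing -> periodogram ->
triangular mel filterbank -> log -> orthonormal DCT-II.

Conventions not fixed by the method itself (mel formula, filter count, FFT
size, delta window, energy definition) follow the HTK lineage; see the
methods note for the exact choices and their rationale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.fft import dct, rfft

from .audio_segments import Waveform

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MfccConfig:
    """Feature-extraction parameters.

    preemphasis: first-order high-pass coefficient (H(z) = 1 - a z^-1).
    frame_length / frame_step: analysis window and hop, in seconds.
    n_cepstra: cepstral coefficients kept (the 0th is dropped in favour of
        the explicit log-energy feature).
    n_filters: triangular mel filters.
    fft_size: zero-padded DFT length (must cover one frame).
    delta_window: half-width N of the delta regression.
    low_freq / high_freq: filterbank band edges in Hz (None = Nyquist).
    energy_floor: absolute fallback floor guarding log(0); the operative
        floor is relative (80 dB below the utterance's peak energy).
    """

    preemphasis: float = 0.97
    frame_length: float = 0.025
    frame_step: float = 0.010
    n_cepstra: int = 12
    n_filters: int = 26
    fft_size: int = 512
    delta_window: int = 2
    low_freq: float = 0.0
    high_freq: float | None = None
    energy_floor: float = 1e-30

    def validate(self, rate: int) -> None:
        if not 0 <= self.preemphasis < 1:
            raise ValueError("preemphasis must be in [0, 1)")
        if self.frame_step > self.frame_length:
            raise ValueError("frame_step must not exceed frame_length")
        if self.n_cepstra >= self.n_filters:
            raise ValueError("n_cepstra must be smaller than n_filters")
        if self.fft_size < round(self.frame_length * rate):
            raise ValueError(
                f"fft_size {self.fft_size} smaller than one frame "
                f"({round(self.frame_length * rate)} samples at {rate} Hz)"
            )


@dataclass
class FeatureMatrix:
    """Time-ordered frames of 39 coefficients.

    Columns 0-11: cepstra c1..c12, column 12: log energy, columns 13-25:
    deltas of the 13 statics, columns 26-38: double-deltas.
    """

    frames: np.ndarray
    frame_step: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 2 or self.frames.shape[0] < 1:
            raise ValueError("FeatureMatrix requires a non-empty 2-D array")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("FeatureMatrix entries must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def pre_emphasize(x: np.ndarray, alpha: float) -> np.ndarray:
    """First-order high-pass: y[0] = x[0], y[t] = x[t] - alpha x[t-1]."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 1:
        raise ValueError("empty signal")
    return np.concatenate(([x[0]], x[1:] - alpha * x[:-1]))


def frame_count(n_samples: int, rate: int, cfg: MfccConfig) -> int:
    """Number of frames: 1 + floor((L - W) / H) for L >= W, else 1 (padded)."""
    W = round(cfg.frame_length * rate)
    H = round(cfg.frame_step * rate)
    return 1 if n_samples < W else 1 + (n_samples - W) // H


def _raw_frames(x: np.ndarray, rate: int, cfg: MfccConfig) -> np.ndarray:
    W = round(cfg.frame_length * rate)
    H = round(cfg.frame_step * rate)
    if x.size < W:
        # Very short function words still get one (symmetrically zero-padded)
        # analysis window.
        pad = W - x.size
        log.warning(
            "signal of %d samples shorter than one %d-sample frame; padding", x.size, W
        )
        x = np.pad(x, (pad // 2, pad - pad // 2))
    T = 1 + (x.size - W) // H
    idx = np.arange(W)[None, :] + H * np.arange(T)[:, None]
    return x[idx]


def frame_signal(x: np.ndarray, rate: int, cfg: MfccConfig = MfccConfig()) -> np.ndarray:
    """Split into overlapping frames and apply the Hamming window."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty signal")
    return _raw_frames(x, rate, cfg) * np.hamming(round(cfg.frame_length * rate))


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(rate: int, cfg: MfccConfig) -> np.ndarray:
    """Triangular filters, centers equally spaced in mel; (n_filters, K) weights."""
    high = rate / 2.0 if cfg.high_freq is None else cfg.high_freq
    mels = np.linspace(hz_to_mel(cfg.low_freq), hz_to_mel(high), cfg.n_filters + 2)
    bins = np.floor((cfg.fft_size + 1) * mel_to_hz(mels) / rate).astype(int)
    fb = np.zeros((cfg.n_filters, cfg.fft_size // 2 + 1))
    for j in range(cfg.n_filters):
        lo, mid, hi = bins[j], bins[j + 1], bins[j + 2]
        for k in range(lo, mid):
            fb[j, k] = (k - lo) / max(mid - lo, 1)
        for k in range(mid, hi):
            fb[j, k] = (hi - k) / max(hi - mid, 1)
    return fb


def _power_spectrum(frames: np.ndarray, cfg: MfccConfig) -> np.ndarray:
    spec = rfft(frames, n=cfg.fft_size, axis=-1)
    return (spec.real**2 + spec.imag**2) / cfg.fft_size


def _floor_energies(fbe: np.ndarray, cfg: MfccConfig) -> np.ndarray:
    """Floor filterbank outputs before the log.

    The floor sits 80 dB below the utterance's peak filter energy, so a
    global gain shifts every log energy (floored or not) uniformly and the
    cepstra stay gain-invariant; the absolute ``energy_floor`` is the
    fallback for all-silent input.
    """
    return np.maximum(fbe, max(1e-8 * fbe.max(), cfg.energy_floor))


def mel_filterbank_energies(frame: np.ndarray, rate: int,
                            cfg: MfccConfig = MfccConfig()) -> np.ndarray:
    """Filterbank outputs of one windowed frame, floored before any log."""
    frame = np.atleast_2d(np.asarray(frame, dtype=np.float64))
    energies = _power_spectrum(frame, cfg) @ mel_filterbank(rate, cfg).T
    return _floor_energies(energies, cfg)[0]


def _deltas(statics: np.ndarray, N: int) -> np.ndarray:
    """Regression deltas with edge-frame replication."""
    padded = np.pad(statics, ((N, N), (0, 0)), mode="edge")
    T = statics.shape[0]
    num = np.zeros_like(statics)
    for n in range(1, N + 1):
        num += n * (padded[N + n : N + n + T] - padded[N - n : N - n + T])
    return num / (2.0 * sum(n * n for n in range(1, N + 1)))


def compute_mfcc(w: Waveform, cfg: MfccConfig = MfccConfig()) -> FeatureMatrix:
    """Full feature chain for one word waveform; deterministic."""
    cfg.validate(w.rate)
    emphasized = pre_emphasize(w.samples, cfg.preemphasis)
    raw = _raw_frames(emphasized, w.rate, cfg)
    # Log frame energy on the pre-emphasized, un-windowed frame.  Floored
    # relative to the utterance's loudest frame (same rationale as
    # _floor_energies) so silence frames track a global gain.
    frame_e = (raw**2).sum(axis=1)
    e_floor = max(1e-8 * frame_e.max(), cfg.energy_floor)
    energy = np.log(np.maximum(frame_e, e_floor))
    windowed = raw * np.hamming(raw.shape[1])
    fbe = _floor_energies(
        _power_spectrum(windowed, cfg) @ mel_filterbank(w.rate, cfg).T, cfg
    )
    cepstra = dct(np.log(fbe), type=2, norm="ortho", axis=1)[:, 1 : cfg.n_cepstra + 1]
    statics = np.hstack([cepstra, energy[:, None]])
    d1 = _deltas(statics, cfg.delta_window)
    d2 = _deltas(d1, cfg.delta_window)
    return FeatureMatrix(frames=np.hstack([statics, d1, d2]), frame_step=cfg.frame_step)


# ---------------------------------------------------------------------------
# flat key=value config serialization (CLI --config)

_FLOAT_KEYS = {"preemphasis", "frame_length", "frame_step", "low_freq", "energy_floor"}
_INT_KEYS = {"n_cepstra", "n_filters", "fft_size", "delta_window"}


def load_config(path) -> MfccConfig:
    """Read a flat ``key = value`` file overriding :class:`MfccConfig` defaults."""
    overrides: dict = {}
    for raw in open(path, encoding="utf-8"):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw.rstrip()}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key in _FLOAT_KEYS:
            overrides[key] = float(value)
        elif key in _INT_KEYS:
            overrides[key] = int(value)
        elif key == "high_freq":
            overrides[key] = None if value.lower() == "none" else float(value)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return replace(MfccConfig(), **overrides)


def save_config(cfg: MfccConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key in (*_FLOAT_KEYS, *_INT_KEYS, "high_freq"):
            fh.write(f"{key} = {getattr(cfg, key)}\n")
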