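"""Speaker-based cepstral mean and variance normalization.

Feature dimensions are standardized per speaker — mean removed and scaled to
unit (population) variance — with statistics pooled over all frames of all
the speaker's word matrices.  This suppresses channel and talker-specific
offsets so that cross-speaker comparisons reflect pronunciation rather than
recording conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .mfcc import FeatureMatrix

#: Below this, a feature dimension is considered degenerate (constant) and is
#: only mean-subtracted, avoiding division blow-up on silent channels.
DEGENERATE_STD = 1e-10


@dataclass
class CmvnStats:
    """Per-speaker, per-dimension mean and population standard deviation."""

    mean: np.ndarray
    std: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.std = np.asarray(self.std, dtype=np.float64)
        if self.mean.shape != self.std.shape or self.mean.ndim != 1:
            raise ValueError("mean and std must be 1-D vectors of equal length")
        if np.any(self.std < 0):
            raise ValueError("standard deviations must be non-negative")


def _frames(m) -> np.ndarray:
    return m.frames if isinstance(m, FeatureMatrix) else np.asarray(m, dtype=np.float64)


def estimate_stats(features: Sequence[FeatureMatrix] | Iterable) -> CmvnStats:
    """Pool all frames of a speaker's matrices; per-column mean and 1/N std."""
    mats = [_frames(m) for m in features]
    if not mats:
        raise ValueError("estimate_stats requires at least one feature matrix")
    pooled = np.vstack(mats)
    if pooled.shape[0] < 2:
        raise ValueError(f"need >= 2 pooled frames for variance, got {pooled.shape[0]}")
    return CmvnStats(
        mean=pooled.mean(axis=0),
        std=pooled.std(axis=0),  # population (divide by N)
        n_frames=pooled.shape[0],
    )


def apply_cmvn(features: FeatureMatrix, stats: CmvnStats) -> FeatureMatrix:
    """Standardize: (c - mean) / std, mean-subtract only where std ~ 0."""
    frames = _frames(features)
    if frames.shape[1] != stats.mean.size:
        raise ValueError(
            f"dimension mismatch: features have {frames.shape[1]} columns, "
            f"stats have {stats.mean.size}"
        )
    if not (np.all(np.isfinite(stats.mean)) and np.all(np.isfinite(stats.std))):
        raise ValueError("CMVN statistics must be finite")
    divisor = np.where(stats.std < DEGENERATE_STD, 1.0, stats.std)
    normalized = (frames - stats.mean) / divisor
    step = features.frame_step if isinstance(features, FeatureMatrix) else 0.01
    return FeatureMatrix(frames=normalized, frame_step=step)
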