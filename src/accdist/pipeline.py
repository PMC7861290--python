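"""End-to-end pronunciation distance pipeline.

For each target speaker: segment the recording into words, extract MFCC
features per word, estimate and apply speaker-level CMVN, compute the
length-normalized DTW distance to each reference speaker word by word,
average over words, then average over the whole reference set.  Two reduced
modes isolate the contribution of each preprocessing stage:

* ``segmentation_only`` — per-word DTW on raw (un-normalized) features;
* ``normalization_only`` — one DTW over the whole unsegmented recording on
  CMVN-applied features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .audio_segments import read_alignment, read_audio, resample, segment
from .cmvn import apply_cmvn, estimate_stats
from .dtw import dtw_distance
from .mfcc import FeatureMatrix, MfccConfig, compute_mfcc

log = logging.getLogger(__name__)

MODES = ("full", "segmentation_only", "normalization_only")

#: Key under which the whole unsegmented recording is stored in
#: normalization-only mode.
WHOLE_RECORDING = "<recording>"


@dataclass
class PipelineConfig:
    """Working sampling rate, feature parameters, and comparison options."""

    rate: int = 11025
    mfcc: MfccConfig = field(default_factory=MfccConfig)
    squared_cost: bool = False
    expected_words: tuple[str, ...] | None = None
    alignment_dialect: str = "auto"


def discover_speakers(directory: str | Path) -> list[tuple[str, Path, Path | None]]:
    """(speaker_id, wav, alignment) triples, sorted by speaker id."""
    directory = Path(directory)
    out = []
    for wav in sorted(directory.glob("*.wav")):
        align = None
        for ext in (".csv", ".TextGrid", ".textgrid"):
            cand = wav.with_suffix(ext)
            if cand.exists():
                align = cand
                break
        out.append((wav.stem, wav, align))
    if not out:
        raise FileNotFoundError(f"no WAV files in {directory}")
    return out


def prepare_speaker(wav_path: Path, align_path: Path | None, speaker_id: str,
                    config: PipelineConfig, mode: str = "full",
                    ) -> dict[str, FeatureMatrix]:
    """Load, segment, featurize, and (mode permitting) normalize one speaker."""
    w = resample(read_audio(wav_path), config.rate)
    if mode == "normalization_only":
        fm = compute_mfcc(w, config.mfcc)
        stats = estimate_stats([fm])
        return {WHOLE_RECORDING: apply_cmvn(fm, stats)}
    if align_path is None:
        raise FileNotFoundError(f"speaker {speaker_id!r}: no alignment file")
    alignment = read_alignment(align_path, dialect=config.alignment_dialect)
    utterance = segment(w, alignment, speaker_id, expected_words=config.expected_words)
    features = {k: compute_mfcc(v, config.mfcc) for k, v in utterance.words.items()}
    if mode == "segmentation_only":
        return features
    stats = estimate_stats(list(features.values()))
    return {k: apply_cmvn(fm, stats) for k, fm in features.items()}


def speaker_pair_distance(target: Mapping[str, FeatureMatrix],
                          reference: Mapping[str, FeatureMatrix],
                          word_list: Sequence[str] | None = None,
                          squared: bool = False) -> tuple[float, int]:
    """Mean DTW distance over the words shared by both speakers.

    Returns (mean distance, number of words used).  Words are matched by
    key; with ``word_list`` given, only those words enter the comparison.
    """
    shared = sorted(set(target) & set(reference))
    if word_list is not None:
        wanted = set(word_list)
        shared = [k for k in shared if k in wanted]
    if not shared:
        raise ValueError("no shared words between target and reference")
    dists = [dtw_distance(target[k], reference[k], squared=squared).distance
             for k in shared]
    return float(np.mean(dists)), len(shared)


def distance_to_reference_set(target: Mapping[str, FeatureMatrix],
                              references: Sequence[Mapping[str, FeatureMatrix]],
                              word_list: Sequence[str] | None = None,
                              squared: bool = False) -> float:
    """Unweighted mean of pair distances over the reference set."""
    if not references:
        raise ValueError("empty reference list")
    return float(np.mean([
        speaker_pair_distance(target, ref, word_list, squared)[0]
        for ref in references
    ]))


def pair_distance_matrix(target_dir: str | Path, reference_dir: str | Path,
                         config: PipelineConfig | None = None,
                         mode: str = "full",
                         ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Distances of every target to every reference.

    Returns (distance matrix, n-shared-words matrix, skipped speaker ids);
    both frames are indexed by target id with one column per reference id.
    Speakers whose audio or alignment cannot be read are skipped with a
    logged warning.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    config = config or PipelineConfig()
    skipped: list[str] = []

    refs: dict[str, dict[str, FeatureMatrix]] = {}
    for sid, wav, align in discover_speakers(reference_dir):
        try:
            refs[sid] = prepare_speaker(wav, align, sid, config, mode)
        except Exception as exc:
            log.warning("skipping reference %s: %s", sid, exc)
            skipped.append(sid)
    if not refs:
        raise ValueError(f"no usable reference speakers in {reference_dir}")

    rows, nrows, index = [], [], []
    for sid, wav, align in discover_speakers(target_dir):
        try:
            feats = prepare_speaker(wav, align, sid, config, mode)
        except Exception as exc:
            log.warning("skipping target %s: %s", sid, exc)
            skipped.append(sid)
            continue
        drow, nrow = [], []
        for rid in refs:
            d, n = speaker_pair_distance(feats, refs[rid], squared=config.squared_cost)
            drow.append(d)
            nrow.append(n)
        rows.append(drow)
        nrows.append(nrow)
        index.append(sid)
    cols = list(refs)
    return (pd.DataFrame(rows, index=index, columns=cols),
            pd.DataFrame(nrows, index=index, columns=cols), skipped)


def run_measure(target_dir: str | Path, reference_dir: str | Path,
                config: PipelineConfig | None = None,
                mode: str = "full") -> pd.DataFrame:
    """Mean distance of each target speaker to the whole reference set.

    Columns: target_speaker_id, mean_distance, n_words_used,
    n_references_used.  Deterministic given inputs and config.
    """
    D, N, _ = pair_distance_matrix(target_dir, reference_dir, config, mode)
    return pd.DataFrame({
        "target_speaker_id": D.index,
        "mean_distance": D.mean(axis=1).to_numpy(),
        "n_words_used": N.min(axis=1).astype(int).to_numpy(),
        "n_references_used": D.shape[1],
    }).reset_index(drop=True)


def run_baseline(mode: str, target_dir: str | Path, reference_dir: str | Path,
                 config: PipelineConfig | None = None) -> pd.DataFrame:
    """The two reduced measures (segmentation-only / normalization-only)."""
    if mode not in ("segmentation_only", "normalization_only"):
        raise ValueError(f"baseline mode must be segmentation_only or "
                         f"normalization_only, got {mode!r}")
    return run_measure(target_dir, reference_dir, config, mode=mode)


def reference_subset_experiment(target_dir: str | Path, reference_dir: str | Path,
                                ratings: pd.DataFrame | str | Path,
                                sizes: Sequence[int], n_draws: int = 10,
                                seed: int = 0,
                                config: PipelineConfig | None = None,
                                mode: str = "full") -> pd.DataFrame:
    """Correlation with ratings as a function of reference-set size.

    For each size, ``n_draws`` seeded uniform subsets of the reference pool
    are drawn without replacement; the Pearson correlation between ratings
    and the subset-averaged distances is recorded.  Returns one row per
    size: (size, mean_r, std_r).
    """
    if isinstance(ratings, (str, Path)):
        ratings = pd.read_csv(ratings)
    D, _, _ = pair_distance_matrix(target_dir, reference_dir, config, mode)
    n_refs = D.shape[1]
    if max(sizes) > n_refs:
        raise ValueError(f"subset size {max(sizes)} exceeds reference pool ({n_refs})")
    merged = ratings.set_index("speaker_id").loc[D.index]
    y = merged["mean_rating"].to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        rs = []
        for _ in range(n_draws):
            cols = rng.choice(n_refs, size=size, replace=False)
            x = D.iloc[:, np.sort(cols)].mean(axis=1).to_numpy()
            rs.append(pearsonr(x, y)[0])
        rows.append((size, float(np.mean(rs)), float(np.std(rs))))
    return pd.DataFrame(rows, columns=["size", "mean_r", "std_r"])
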