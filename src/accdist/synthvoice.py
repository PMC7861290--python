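"""Deterministic synthetic-speech generator for end-to-end testing.

Source–filter synthesis: a jittered glottal impulse train shaped by a
-12 dB/oct tilt and a cascade of second-order formant resonators.  The
generator covers exactly the dimensions the distance measure is meant to be
sensitive to — vowel quality on an F1/F2 grid, pitch contour, syllable
duration — plus the recording-channel differences it should (but cannot
fully) ignore.  All randomness flows from explicit seeds; regenerating with
the same seed is bit-identical.

`make_cohort` writes a miniature speaker archive (WAV + CSV alignments +
planted native-likeness ratings) in the on-disk layout the pipeline
consumes: reference talkers cluster around one vowel grid, target talkers
are displaced from it in proportion to a planted accent magnitude (vowel
space compressed toward schwa, syllables lengthened).
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import firwin2, lfilter, resample as _fft_resample

from .audio_segments import Waveform, write_audio

#: Approximate adult-male monophthong targets (F1, F2, F3 in Hz) for the 12
#: Dutch vowels used in the isolated-vowel experiments.
DUTCH_VOWELS: Mapping[str, tuple[float, float, float]] = MappingProxyType({
    "a": (795.0, 1301.0, 2565.0),
    "ɑ": (679.0, 1051.0, 2619.0),
    "ɛ": (583.0, 1725.0, 2471.0),
    "e": (440.0, 2017.0, 2553.0),
    "ø": (443.0, 1497.0, 2260.0),
    "ɪ": (388.0, 2003.0, 2577.0),
    "i": (294.0, 2208.0, 2766.0),
    "ɔ": (523.0, 866.0, 2491.0),
    "u": (339.0, 810.0, 2323.0),
    "o": (487.0, 911.0, 2481.0),
    "ʏ": (426.0, 1588.0, 2245.0),
    "y": (305.0, 1730.0, 2208.0),
})

FORMANT_BANDWIDTHS = (80.0, 100.0, 140.0)
SCHWA = (500.0, 1500.0, 2500.0)

#: Pseudo-words of the default synthetic cohort: label -> vowel sequence.
COHORT_WORDS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("please", ("i",)),
    ("call", ("ɔ",)),
    ("store", ("o",)),
    ("bags", ("a",)),
    ("big", ("ɪ",)),
    ("blue", ("u",)),
    ("maybe", ("e", "ø")),
    ("brother", ("ʏ", "ɑ")),
)


@dataclass(frozen=True)
class TalkerSpec:
    """One synthetic talker: base pitch, vowel targets, and variability.

    ``jitter`` is the relative rendition-to-rendition variability (applied
    to f0, pitch periods, and formants); ``duration`` is seconds per
    syllable nucleus.
    """

    f0: float = 120.0
    formant_grid: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: DUTCH_VOWELS
    )
    jitter: float = 0.02
    duration: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        for v, (f1, f2, f3) in self.formant_grid.items():
            if not f1 < f2 < f3:
                raise ValueError(f"vowel {v!r}: formants must satisfy F1 < F2 < F3")


def _rng(*tokens) -> np.random.Generator:
    """Independent stream keyed by arbitrary tokens (strings hashed stably)."""
    entropy = [
        t if isinstance(t, (int, np.integer)) else zlib.crc32(str(t).encode())
        for t in tokens
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _resonator_coeffs(freq: float, bandwidth: float, rate: int):
    r = np.exp(-np.pi * bandwidth / rate)
    b1 = 2.0 * r * np.cos(2.0 * np.pi * freq / rate)
    b2 = -r * r
    return [1.0 - b1 - b2], [1.0, -b1, -b2]


def _synth_samples(spec: TalkerSpec, vowel: str, rate: int, rendition: int,
                   f0_mult: np.ndarray | None = None) -> np.ndarray:
    """Core synthesis for one vowel nucleus of length round(duration*rate)."""
    if vowel not in spec.formant_grid:
        raise ValueError(f"unknown vowel {vowel!r} (grid: {sorted(spec.formant_grid)})")
    rng = _rng(spec.seed, "vowel", vowel, rendition)
    n = round(spec.duration * rate)
    f0 = spec.f0 * (1.0 + spec.jitter * rng.standard_normal())
    formants = np.asarray(spec.formant_grid[vowel]) * (
        1.0 + 0.5 * spec.jitter * rng.standard_normal(3)
    )
    if f0_mult is None:
        f0_mult = np.ones(n)

    # Jittered impulse train at the (possibly ramped) instantaneous f0.
    excitation = np.zeros(n)
    t = 0.0
    while t < n:
        excitation[int(t)] = 1.0
        period = rate / (f0 * f0_mult[min(int(t), n - 1)])
        t += period * (1.0 + 0.25 * spec.jitter * rng.standard_normal())

    # Glottal spectral tilt (~ -12 dB/oct): two leaky integrators.
    y = lfilter([1.0], [1.0, -0.97], excitation)
    y = lfilter([1.0], [1.0, -0.97], y)
    for freq, bw in zip(formants, FORMANT_BANDWIDTHS):
        b, a = _resonator_coeffs(float(freq), bw, rate)
        y = lfilter(b, a, y)

    y -= y.mean()
    fade = min(round(0.010 * rate), n // 4)
    if fade > 0:
        ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(fade) / fade)
        y[:fade] *= ramp
        y[-fade:] *= ramp[::-1]
    peak = np.abs(y).max()
    return 0.3 * y / peak if peak > 0 else y


def synth_vowel(spec: TalkerSpec, vowel: str, rate: int = 11025,
                rendition: int = 0) -> Waveform:
    """One rendition of an isolated vowel; deterministic in (spec, rendition)."""
    samples = _synth_samples(spec, vowel, rate, rendition)
    return Waveform(samples=samples, rate=rate, meta={
        "kind": "vowel", "talker": spec, "vowels": (vowel,),
        "rendition": rendition, "spans": [(0.0, samples.size / rate)],
    })


def synth_word(spec: TalkerSpec, vowels: Sequence[str], rate: int = 11025,
               rendition: int = 0, gap: float = 0.030,
               f0_ramp: tuple[float, float] | None = None) -> Waveform:
    """A multi-syllable pseudo-word: vowel nuclei separated by short gaps.

    ``f0_ramp=(a, b)`` scales the instantaneous f0 linearly from a to b over
    the voiced portion of the word (a rising-intonation resynthesis).
    """
    n_gap = round(gap * rate)
    n_syl = round(spec.duration * rate)
    pieces, spans = [], []
    total_voiced = len(vowels) * n_syl
    pos_voiced = 0
    pos = 0
    for k, v in enumerate(vowels):
        mult = None
        if f0_ramp is not None:
            a, b = f0_ramp
            frac = (pos_voiced + np.arange(n_syl)) / max(total_voiced - 1, 1)
            mult = a + (b - a) * frac
        piece = _synth_samples(spec, v, rate, rendition * 16 + k, f0_mult=mult)
        spans.append((pos / rate, (pos + piece.size) / rate))
        pieces.append(piece)
        pos += piece.size
        pos_voiced += n_syl
        if k < len(vowels) - 1:
            pieces.append(np.zeros(n_gap))
            pos += n_gap
    samples = np.concatenate(pieces)
    return Waveform(samples=samples, rate=rate, meta={
        "kind": "word", "talker": spec, "vowels": tuple(vowels),
        "rendition": rendition, "spans": spans,
    })


def apply_intonation(w: Waveform, contour: str) -> Waveform:
    """Flat: identity.  Rising: resynthesize with f0 ramped x1.0 -> x1.5.

    Requires a waveform produced by :func:`synth_vowel` or
    :func:`synth_word` (resynthesis metadata must be present).
    """
    if contour == "flat":
        return w
    if contour != "rising":
        raise ValueError(f"unknown contour {contour!r}")
    meta = w.meta
    if "talker" not in meta:
        raise ValueError(
            "apply_intonation requires voiced synthetic input from "
            "synth_vowel/synth_word"
        )
    return synth_word(
        meta["talker"], meta["vowels"], rate=w.rate,
        rendition=meta["rendition"], f0_ramp=(1.0, 1.5),
    )


def stretch_segment(w: Waveform, span: tuple[float, float], factor: float) -> Waveform:
    """Time-dilate the samples inside ``span`` (seconds) by ``factor``."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    start, end = span
    if not (0 <= start < end <= w.duration + 1e-9):
        raise ValueError(f"span {span} outside waveform of {w.duration:.3f}s")
    if factor == 1.0:
        return w
    i0, i1 = int(np.floor(start * w.rate)), int(np.floor(end * w.rate))
    segment = w.samples[i0:i1]
    stretched = _fft_resample(segment, round(segment.size * factor))
    samples = np.concatenate([w.samples[:i0], stretched, w.samples[i1:]])
    return Waveform(samples=samples, rate=w.rate, meta={})


def simulate_device(w: Waveform, device: str = "coloured", seed: int = 0) -> Waveform:
    """Recording-channel simulation.

    ``flat`` is the identity; ``coloured`` applies a fixed mild band-shaping
    FIR (a few dB of ripple across the band, delay-compensated) plus
    low-level seeded noise — a stand-in for a different microphone.
    """
    if device == "flat":
        return w
    if device != "coloured":
        raise ValueError(f"unknown device {device!r}")
    taps = firwin2(31, [0.0, 0.15, 0.3, 0.5, 0.7, 1.0],
                   [1.0, 1.35, 0.65, 1.25, 0.6, 0.5])
    shaped = np.convolve(w.samples, taps, mode="same")
    rng = _rng(seed, "device")
    noise = 0.01 * np.std(w.samples) * rng.standard_normal(shaped.size)
    return Waveform(samples=shaped + noise, rate=w.rate, meta={})


# ---------------------------------------------------------------------------
# cohort generation


def _channel_filter(rng: np.random.Generator) -> np.ndarray:
    """Per-speaker random mild channel colouring (consumer-device spread)."""
    gains = rng.uniform(0.5, 1.5, size=5)
    return firwin2(31, [0.0, 0.2, 0.45, 0.7, 1.0], list(gains[:4]) + [gains[4] * 0.5])


def _accented_grid(grid: Mapping[str, tuple[float, float, float]],
                   magnitude: float) -> dict[str, tuple[float, float, float]]:
    """Vowel-space centralization: pull every vowel toward schwa by
    70% x magnitude.  Reduced, centralized vowel qualities are a documented
    signature of strong foreign accents; at full magnitude the peripheral
    vowel distinctions largely merge."""
    out = {}
    for v, fs in grid.items():
        out[v] = tuple(
            f + 0.7 * magnitude * (s - f) for f, s in zip(fs, SCHWA)
        )
    return out


@dataclass
class Cohort:
    root: Path
    targets_dir: Path
    references_dir: Path
    ratings_csv: Path
    magnitudes_csv: Path
    word_labels: tuple[str, ...]


def _write_speaker(directory: Path, speaker_id: str, spec: TalkerSpec,
                   words: Sequence[tuple[str, tuple[str, ...]]], rate: int,
                   rng: np.random.Generator) -> None:
    channel = _channel_filter(rng)
    gain = rng.uniform(0.2, 0.8)
    noise_level = rng.uniform(0.001, 0.004)
    # Complete recordings carry speaker-specific disfluencies between the
    # words — filled pauses ("uh") that word segmentation removes but an
    # unsegmented comparison has to swallow.
    filler_spec = replace(
        spec, formant_grid={"ə": (500.0, 1500.0, 2500.0)},
        duration=rng.uniform(0.15, 0.40),
    )
    pieces, entries = [], []
    pos = round(rng.uniform(0.10, 0.30) * rate)
    pieces.append(np.zeros(pos))
    for k, (label, vowels) in enumerate(words):
        word = synth_word(spec, vowels, rate=rate, rendition=k)
        entries.append((label, pos / rate, (pos + word.samples.size) / rate))
        pieces.append(word.samples)
        pos += word.samples.size
        n_sil = round(rng.uniform(0.10, 0.30) * rate)
        pieces.append(np.zeros(n_sil))
        pos += n_sil
        if rng.random() < 0.5:
            filler = 0.8 * _synth_samples(filler_spec, "ə", rate, rendition=50 + k)
            pieces.append(filler)
            pos += filler.size
            n_sil = round(rng.uniform(0.10, 0.30) * rate)
            pieces.append(np.zeros(n_sil))
            pos += n_sil
    samples = np.concatenate(pieces)
    samples = gain * np.convolve(samples, channel, mode="same")
    samples += noise_level * rng.standard_normal(samples.size)
    write_audio(directory / f"{speaker_id}.wav", Waveform(samples=samples, rate=rate))
    with open(directory / f"{speaker_id}.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["word", "start", "end"])
        for label, s, e in entries:
            writer.writerow([label, repr(s), repr(e)])


def make_cohort(out_dir: str | Path, n_targets: int = 20, n_references: int = 10,
                accent_magnitudes: Sequence[float] | None = None, seed: int = 0,
                rate: int = 11025,
                words: Sequence[tuple[str, tuple[str, ...]]] = COHORT_WORDS) -> Cohort:
    """Write a synthetic speaker archive in the layout the pipeline consumes.

    References share one vowel grid (with small per-talker variation);
    target *t* is displaced from it in proportion to its planted accent
    magnitude.  Planted native-likeness ratings decrease affinely in
    magnitude (7-point scale) with light seeded noise.  Every speaker gets
    an individual pitch, speaking rate, level, channel colouring, and
    silence pattern, so the un-normalized and un-segmented baselines face
    realistic nuisance variation.
    """
    root = Path(out_dir)
    targets_dir, references_dir = root / "targets", root / "references"
    targets_dir.mkdir(parents=True, exist_ok=True)
    references_dir.mkdir(parents=True, exist_ok=True)
    if accent_magnitudes is None:
        accent_magnitudes = np.linspace(0.0, 1.0, n_targets)
    magnitudes = np.asarray(list(accent_magnitudes), dtype=np.float64)
    if magnitudes.size != n_targets:
        raise ValueError("need one accent magnitude per target")
    if np.any(magnitudes < 0):
        raise ValueError("accent magnitudes must be non-negative")

    def talker(rng: np.random.Generator, grid, talker_seed: int) -> TalkerSpec:
        varied = {
            v: tuple(np.asarray(fs) * (1.0 + 0.02 * rng.standard_normal(3)))
            for v, fs in grid.items()
        }
        return TalkerSpec(
            f0=rng.uniform(110.0, 150.0),
            formant_grid=varied,
            jitter=0.02,
            duration=rng.uniform(0.24, 0.32),
            seed=talker_seed,
        )

    for r in range(n_references):
        rng = _rng(seed, "reference", r)
        spec = talker(rng, DUTCH_VOWELS, int(rng.integers(2**31)))
        _write_speaker(references_dir, f"ref{r:02d}", spec, words, rate, rng)

    ratings, mags = [], []
    for t in range(n_targets):
        rng = _rng(seed, "target", t)
        a = float(magnitudes[t])
        grid = _accented_grid(DUTCH_VOWELS, a)
        spec = talker(rng, grid, int(rng.integers(2**31)))
        spec = replace(spec, duration=spec.duration * (1.0 + 0.3 * a))
        sid = f"tgt{t:02d}"
        _write_speaker(targets_dir, sid, spec, words, rate, rng)
        rating = float(np.clip(7.0 - 5.5 * a + 0.15 * rng.standard_normal(), 1.0, 7.0))
        ratings.append((sid, rating))
        mags.append((sid, a))

    ratings_csv = root / "ratings.csv"
    with open(ratings_csv, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["speaker_id", "mean_rating"])
        writer.writerows([(s, repr(v)) for s, v in ratings])
    magnitudes_csv = root / "magnitudes.csv"
    with open(magnitudes_csv, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["speaker_id", "magnitude"])
        writer.writerows([(s, repr(v)) for s, v in mags])
    (root / "words.txt").write_text("\n".join(lab for lab, _ in words) + "\n", "utf-8")
    return Cohort(
        root=root, targets_dir=targets_dir, references_dir=references_dir,
        ratings_csv=ratings_csv, magnitudes_csv=magnitudes_csv,
        word_labels=tuple(lab for lab, _ in words),
    )
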