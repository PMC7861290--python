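"""Audio input, resampling, and word-level segmentation.

Recordings of a read elicitation paragraph arrive as mono PCM WAV files
together with word-boundary annotations produced by a forced aligner (Praat
TextGrid interval tier) or exported as CSV.  This module reads both, brings
every recording to one common working sampling rate, and slices it into
per-word waveforms that the feature-extraction stage consumes.

Annotations use seconds; sample slices are 0-based and half-open,
``[floor(start*rate), floor(end*rate))``, so a gap-free alignment
concatenates back to the original sample run exactly.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

log = logging.getLogger(__name__)

#: Interval labels treated as silence/non-speech and dropped from alignments.
SILENCE_LABELS = frozenset({"", "sp", "sil", "spn", "<sil>"})


class AudioFormatError(ValueError):
    """Raised when an audio file cannot be read as PCM WAV."""


class AlignmentError(ValueError):
    """Raised for malformed or invalid word-boundary annotations."""


@dataclass
class Waveform:
    """Mono audio: float samples (nominal range [-1, 1]) plus sampling rate.

    ``meta`` carries optional provenance (the synthetic-voice generator uses
    it to enable resynthesis); it never affects acoustic computations.
    """

    samples: np.ndarray
    rate: int
    meta: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("Waveform requires a non-empty 1-D sample array")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.rate


@dataclass(frozen=True)
class WordInterval:
    label: str
    start: float
    end: float


@dataclass
class WordAlignment:
    """Ordered, non-overlapping labeled (word, start, end) intervals."""

    entries: list[WordInterval]

    def __post_init__(self) -> None:
        for e in self.entries:
            if not (0 <= e.start < e.end):
                raise AlignmentError(
                    f"interval {e.label!r} has invalid bounds [{e.start}, {e.end}]"
                )
        self.entries = sorted(self.entries, key=lambda e: e.start)
        offenders = [
            (a.label, b.label)
            for a, b in zip(self.entries, self.entries[1:])
            if b.start < a.end - 1e-9
        ]
        if offenders:
            raise AlignmentError(f"overlapping intervals: {offenders}")

    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class SegmentedUtterance:
    """One speaker's recording sliced into per-word waveforms.

    Keys repeat the annotation labels in reading order; a duplicated word
    gets an occurrence suffix (``her``, ``her#2``, ...) so that every token
    is retained and tokens match positionally across speakers reading the
    same text.
    """

    speaker_id: str
    words: Mapping[str, Waveform]

    def __post_init__(self) -> None:
        rates = {w.rate for w in self.words.values()}
        if len(rates) > 1:
            raise ValueError(f"mixed sampling rates in utterance: {sorted(rates)}")


def paragraph_words() -> tuple[str, ...]:
    """The 69 words of the standard elicitation paragraph, in reading order."""
    text = resources.files("accdist.data").joinpath("paragraph_words.txt").read_text("utf-8")
    return tuple(text.split())


def read_audio(path: str | Path) -> Waveform:
    """Read a PCM WAV file as a mono float waveform scaled to [-1, 1]."""
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises bare ValueError on bad RIFF
        raise AudioFormatError(f"cannot read {path} as PCM WAV: {exc}") from exc
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"{path}: unsupported WAV sample format {data.dtype}")
    if samples.ndim == 2:  # average channels to mono
        samples = samples.mean(axis=1)
    return Waveform(samples=np.asarray(samples, dtype=np.float64), rate=int(rate))


def write_audio(path: str | Path, w: Waveform) -> None:
    """Write a waveform as 16-bit PCM WAV (values clipped to [-1, 1])."""
    clipped = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(Path(path), w.rate, np.round(clipped * 32767.0).astype(np.int16))


def resample(w: Waveform, target_rate: int) -> Waveform:
    """Band-limited (polyphase) resampling to ``target_rate``.

    Output length is ``round(len * target_rate / rate)`` — duration is
    conserved to within one sample.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == w.rate:
        return w
    g = math.gcd(target_rate, w.rate)
    out = resample_poly(w.samples, target_rate // g, w.rate // g)
    n_out = round(w.samples.size * target_rate / w.rate)
    if out.size > n_out:
        out = out[:n_out]
    elif out.size < n_out:
        out = np.pad(out, (0, n_out - out.size))
    return Waveform(samples=out, rate=target_rate)


# ---------------------------------------------------------------------------
# alignment reading / writing


def read_alignment(path: str | Path, dialect: str = "auto", tier: str = "words") -> WordAlignment:
    """Read word boundaries from a CSV (columns word,start,end) or TextGrid.

    Silent intervals (labels in :data:`SILENCE_LABELS`) are dropped; the
    remaining entries are sorted and validated (no overlaps).
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "textgrid" if path.suffix.lower() == ".textgrid" else "csv"
    if dialect == "csv":
        entries = _read_alignment_csv(path)
    elif dialect == "textgrid":
        entries = _read_alignment_textgrid(path, tier)
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    kept = [e for e in entries if e.label.strip().lower() not in SILENCE_LABELS]
    return WordAlignment(entries=kept)


def write_alignment(a: WordAlignment, path: str | Path, dialect: str = "csv",
                    tier: str = "words") -> None:
    """Write an alignment as CSV or as a (long-format) TextGrid interval tier."""
    path = Path(path)
    if dialect == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["word", "start", "end"])
            for e in a.entries:
                writer.writerow([e.label, repr(e.start), repr(e.end)])
    elif dialect == "textgrid":
        _write_textgrid(a, path, tier)
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")


def _read_alignment_csv(path: Path) -> list[WordInterval]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        cols = set(reader.fieldnames or [])
        if not {"word", "start", "end"} <= cols:
            raise AlignmentError(
                f"{path}: CSV alignment needs columns word,start,end (found {sorted(cols)})"
            )
        try:
            return [
                WordInterval(row["word"], float(row["start"]), float(row["end"]))
                for row in reader
            ]
        except (TypeError, ValueError) as exc:
            raise AlignmentError(f"{path}: malformed CSV alignment row: {exc}") from exc


_TG_TOKEN = re.compile(r'"(?:[^"]|"")*"|<exists>|[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?')


def _textgrid_tokens(text: str) -> list[str]:
    """Reduce a TextGrid (long or short text format) to its value tokens.

    In the long format every value sits on a line ``key = value``; in the
    short format the value stands alone.  Either way the values occur in the
    same order, so one token stream serves both.
    """
    tokens: list[str] = []
    for line in text.splitlines()[2:]:  # skip the two file-type header lines
        s = line.strip()
        if not s or s.endswith("]:") or s.endswith("[]:"):
            continue
        if "=" in s:
            s = s.split("=", 1)[1].strip()
        elif s.endswith(":"):  # bare section header such as "intervals:"
            continue
        m = _TG_TOKEN.search(s)  # search, not fullmatch: "tiers? <exists>"
        if m:
            tokens.append(m.group(0))
    return tokens


def _read_alignment_textgrid(path: Path, tier: str) -> list[WordInterval]:
    text = Path(path).read_text("utf-8")
    if "ooTextFile" not in text.splitlines()[0]:
        raise AlignmentError(f"{path}: not a Praat TextGrid")
    toks = _textgrid_tokens(text)

    def unquote(t: str) -> str:
        return t[1:-1].replace('""', '"') if t.startswith('"') else t

    try:
        pos = 2  # global xmin, xmax
        if toks[pos] != "<exists>":
            raise AlignmentError(f"{path}: TextGrid has no tiers")
        pos += 1
        n_tiers = int(float(toks[pos])); pos += 1
        tiers_found = []
        for _ in range(n_tiers):
            klass = unquote(toks[pos]); name = unquote(toks[pos + 1]); pos += 4
            n_items = int(float(toks[pos])); pos += 1
            if klass == "IntervalTier":
                entries = []
                for _ in range(n_items):
                    xmin, xmax = float(toks[pos]), float(toks[pos + 1])
                    label = unquote(toks[pos + 2]); pos += 3
                    entries.append(WordInterval(label, xmin, xmax))
                if name == tier:
                    return entries
                tiers_found.append(name)
            else:  # point tier: (time, mark) pairs — skipped
                pos += 2 * n_items
                tiers_found.append(name)
    except (IndexError, ValueError) as exc:
        raise AlignmentError(f"{path}: malformed TextGrid: {exc}") from exc
    raise AlignmentError(
        f"{path}: no interval tier named {tier!r} (tiers: {tiers_found})"
    )


def _write_textgrid(a: WordAlignment, path: Path, tier: str) -> None:
    xmax = a.entries[-1].end if a.entries else 1.0
    # Praat requires the tier to tile [0, xmax]; gaps become empty intervals,
    # which read_alignment drops again.
    cells: list[tuple[float, float, str]] = []
    t = 0.0
    for e in a.entries:
        if e.start > t + 1e-12:
            cells.append((t, e.start, ""))
        cells.append((e.start, e.end, e.label))
        t = e.end
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax!r}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        f'        name = "{tier}"',
        "        xmin = 0",
        f"        xmax = {xmax!r}",
        f"        intervals: size = {len(cells)}",
    ]
    for i, (xmin, xmax_i, label) in enumerate(cells, start=1):
        lines += [
            f"        intervals [{i}]:",
            f"            xmin = {xmin!r}",
            f"            xmax = {xmax_i!r}",
            f'            text = "{label.replace(chr(34), chr(34) * 2)}"',
        ]
    Path(path).write_text("\n".join(lines) + "\n", "utf-8")


# ---------------------------------------------------------------------------
# segmentation


def occurrence_keys(labels: Sequence[str]) -> list[str]:
    """Disambiguate repeated labels: ``her`` -> ``her``, ``her#2``, ``her#3``."""
    seen: dict[str, int] = {}
    keys = []
    for lab in labels:
        seen[lab] = seen.get(lab, 0) + 1
        keys.append(lab if seen[lab] == 1 else f"{lab}#{seen[lab]}")
    return keys


def validate_word_labels(a: WordAlignment, expected: Sequence[str]) -> None:
    """Check the alignment labels equal the expected word sequence."""
    got = [lab.lower() for lab in a.labels()]
    want = [w.lower() for w in expected]
    if got != want:
        missing = [w for w in want if w not in got]
        extra = [w for w in got if w not in want]
        raise AlignmentError(
            f"alignment labels do not match the expected {len(want)}-word list "
            f"(got {len(got)} words; missing {missing[:5]}, unexpected {extra[:5]})"
        )


def segment(w: Waveform, a: WordAlignment, speaker_id: str,
            expected_words: Sequence[str] | None = None) -> SegmentedUtterance:
    """Slice a recording into per-word waveforms.

    Word *k* receives samples ``[floor(start_k*rate), floor(end_k*rate))``.
    With ``expected_words`` given, the alignment labels must match that word
    sequence exactly (e.g. the 69-word paragraph).
    """
    if expected_words is not None:
        validate_word_labels(a, expected_words)
    words: dict[str, Waveform] = {}
    for key, e in zip(occurrence_keys(a.labels()), a.entries):
        i0 = math.floor(e.start * w.rate)
        i1 = math.floor(e.end * w.rate)
        if i1 > w.samples.size:
            raise AlignmentError(
                f"word {e.label!r} ends at {e.end:.3f}s, beyond the audio "
                f"({w.duration:.3f}s) of speaker {speaker_id!r}"
            )
        if i1 <= i0:
            raise AlignmentError(f"word {e.label!r} spans zero samples")
        words[key] = Waveform(samples=w.samples[i0:i1].copy(), rate=w.rate)
    return SegmentedUtterance(speaker_id=speaker_id, words=words)
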