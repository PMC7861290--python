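import numpy as np
import pytest
from scipy.io import wavfile

from accdist.audio_segments import (
    AlignmentError,
    Waveform,
    WordAlignment,
    WordInterval,
    occurrence_keys,
    paragraph_words,
    read_alignment,
    read_audio,
    resample,
    segment,
    write_alignment,
    write_audio,
)


class TestReadAudio:
    def test_silence_round_trip(self, tmp_path):
        path = tmp_path / "sil.wav"
        wavfile.write(path, 16000, np.zeros(16000, dtype=np.int16))
        w = read_audio(path)
        assert w.rate == 16000
        assert w.samples.size == 16000
        assert np.all(w.samples == 0)

    def test_stereo_opposite_channels_average_to_zero(self, tmp_path):
        x = (10000 * np.sin(2 * np.pi * 440 * np.arange(800) / 8000)).astype(np.int16)
        stereo = np.stack([x, -x], axis=1)
        path = tmp_path / "st.wav"
        wavfile.write(path, 8000, stereo)
        w = read_audio(path)
        assert np.abs(w.samples).max() < 1.0 / 32768

    def test_write_read_round_trip_within_quantization(self, tmp_path, rng):
        x = 0.5 * rng.standard_normal(4000).clip(-1, 1)
        orig = Waveform(samples=x, rate=8000)
        path = tmp_path / "r.wav"
        write_audio(path, orig)
        back = read_audio(path)
        assert back.rate == 8000
        # 16-bit PCM quantization step is 2/65536
        assert np.abs(back.samples - x).max() <= 1.0 / 32767 + 1e-12

    def test_garbage_file_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.wav"
        path.write_bytes(b"not a riff file at all")
        with pytest.raises(ValueError, match="bad.wav"):
            read_audio(path)


class TestResample:
    def test_identity_when_rates_match(self):
        w = Waveform(samples=np.ones(100), rate=11025)
        assert resample(w, 11025) is w

    def test_downsample_length(self):
        w = Waveform(samples=np.random.default_rng(0).standard_normal(22050), rate=22050)
        out = resample(w, 11025)
        assert out.rate == 11025
        assert out.samples.size == 11025

    def test_sine_frequency_preserved(self):
        t = np.arange(44100) / 44100
        w = Waveform(samples=np.sin(2 * np.pi * 500 * t), rate=44100)
        out = resample(w, 11025)
        spectrum = np.abs(np.fft.rfft(out.samples))
        peak_hz = np.argmax(spectrum) * 11025 / out.samples.size
        assert abs(peak_hz - 500) < 2.0

    @pytest.mark.parametrize("n,src,dst", [(16000, 16000, 11025), (5000, 22050, 8000)])
    def test_duration_preserved_within_one_sample(self, n, src, dst, rng):
        w = Waveform(samples=rng.standard_normal(n), rate=src)
        out = resample(w, dst)
        assert abs(out.samples.size - n * dst / src) <= 1.0


class TestAlignmentIO:
    def test_csv_basic(self, tmp_path):
        path = tmp_path / "a.csv"
        path.write_text("word,start,end\nplease,0.10,0.45\ncall,0.50,0.80\n")
        a = read_alignment(path)
        assert a.labels() == ["please", "call"]
        assert a.entries[0].start == pytest.approx(0.10)

    def test_silence_intervals_dropped(self, tmp_path):
        a = WordAlignment([WordInterval("please", 0.1, 0.4), WordInterval("call", 0.6, 0.9)])
        path = tmp_path / "a.TextGrid"
        write_alignment(a, path, dialect="textgrid")
        text = path.read_text()
        assert 'text = ""' in text  # the gap became an empty interval
        back = read_alignment(path, dialect="textgrid")
        assert back.labels() == ["please", "call"]

    def test_cross_dialect_equivalence(self, tmp_path):
        a = WordAlignment([
            WordInterval("six", 0.0, 0.31),
            WordInterval("spoons", 0.31, 0.75),
            WordInterval("of", 0.9, 1.02),
        ])
        csv_path, tg_path = tmp_path / "a.csv", tmp_path / "a.TextGrid"
        write_alignment(a, csv_path, dialect="csv")
        write_alignment(a, tg_path, dialect="textgrid")
        from_csv = read_alignment(csv_path)
        from_tg = read_alignment(tg_path)
        assert from_csv.labels() == from_tg.labels() == a.labels()
        for x, y in zip(from_csv.entries, from_tg.entries):
            assert x.start == pytest.approx(y.start, abs=1e-12)
            assert x.end == pytest.approx(y.end, abs=1e-12)

    def test_overlap_rejected(self):
        with pytest.raises(AlignmentError, match="overlap"):
            WordAlignment([WordInterval("a", 0.0, 0.5), WordInterval("b", 0.4, 0.9)])

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("label,from,to\nx,0,1\n")
        with pytest.raises(AlignmentError, match="word,start,end"):
            read_alignment(path)

    def test_short_format_textgrid(self, tmp_path):
        # Praat's compact serialization: values without "key =" prefixes.
        path = tmp_path / "short.TextGrid"
        path.write_text(
            'File type = "ooTextFile"\n'
            'Object class = "TextGrid"\n'
            "\n0\n1.0\n<exists>\n1\n"
            '"IntervalTier"\n"words"\n0\n1.0\n2\n'
            '0\n0.4\n"please"\n0.4\n1.0\n"call"\n'
        )
        a = read_alignment(path, dialect="textgrid")
        assert a.labels() == ["please", "call"]


class TestSegment:
    def test_sample_count_for_interval(self):
        w = Waveform(samples=np.arange(10000, dtype=float), rate=10000)
        a = WordAlignment([WordInterval("word", 0.5, 0.9)])
        utt = segment(w, a, "spk")
        assert utt.words["word"].samples.size == 4000

    def test_paragraph_validation_passes_and_counts_69(self):
        words = paragraph_words()
        assert len(words) == 69
        rate = 8000
        entries = [
            WordInterval(lab, i * 0.2, i * 0.2 + 0.15) for i, lab in enumerate(words)
        ]
        w = Waveform(samples=np.random.default_rng(1).standard_normal(
            int(69 * 0.2 * rate) + rate), rate=rate)
        utt = segment(w, WordAlignment(entries), "spk", expected_words=words)
        assert len(utt.words) == 69

    def test_validation_rejects_wrong_words(self):
        w = Waveform(samples=np.zeros(8000), rate=8000)
        a = WordAlignment([WordInterval("wrong", 0.1, 0.5)])
        with pytest.raises(AlignmentError, match="expected"):
            segment(w, a, "spk", expected_words=["please"])

    def test_gap_free_alignment_concatenates_exactly(self, rng):
        rate = 9000
        w = Waveform(samples=rng.standard_normal(9000), rate=rate)
        bounds = [0.1, 0.31, 0.62, 0.75, 0.99]
        a = WordAlignment([
            WordInterval(f"w{i}", s, e)
            for i, (s, e) in enumerate(zip(bounds, bounds[1:]))
        ])
        utt = segment(w, a, "spk")
        joined = np.concatenate([utt.words[f"w{i}"].samples for i in range(4)])
        i0, i1 = int(np.floor(0.1 * rate)), int(np.floor(0.99 * rate))
        np.testing.assert_array_equal(joined, w.samples[i0:i1])

    def test_interval_beyond_audio_named(self):
        w = Waveform(samples=np.zeros(800), rate=8000)
        a = WordAlignment([WordInterval("tail", 0.05, 0.5)])
        with pytest.raises(AlignmentError, match="tail"):
            segment(w, a, "spk")

    def test_duplicate_labels_get_occurrence_suffix(self):
        assert occurrence_keys(["her", "to", "her", "her"]) == [
            "her", "to", "her#2", "her#3"
        ]
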