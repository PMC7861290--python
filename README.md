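# accdist — acoustic pronunciation distances

`accdist` measures how strongly accented a speaker's pronunciation is —
without phonetic transcription. Speakers read a common word list; each word
is represented as speaker-normalized mel-cepstral features (MFCC + CMVN),
word pairs are compared with length-normalized dynamic time warping, and
the word distances are averaged over a set of native reference speakers.
The result is one acoustic distance per target speaker that can be
validated against human native-likeness ratings.

It is aimed at phoneticians, dialectometrists, and speech researchers who
want a transcription-free accent-strength or pronunciation-distance measure
plus the statistics used to validate one.

## The measure

For target frames x₁…xₙ and reference frames y₁…yₘ (39-dim vectors: 12
mel-cepstra c₁…c₁₂, log energy, and their Δ/ΔΔ), features are standardized
per speaker,

    ĉ(i,t) = (c(i,t) − c̄(i)) / σ(i),

and compared by dynamic time warping with Euclidean frame costs
d(xᵢ, yⱼ) = ‖xᵢ − yⱼ‖ and the recursion

    γ(i,j) = d(xᵢ, yⱼ) + min(γ(i−1,j−1), γ(i−1,j), γ(i,j−1)),

giving the word distance γ(n,m)/(n+m). Word distances are averaged per
speaker pair and then over all references. Two reduced modes —
segmentation-only (no CMVN) and normalization-only (no word segmentation) —
isolate what each preprocessing stage contributes.

A fully seeded synthetic-voice module (`accdist.synthvoice`) generates
miniature speaker cohorts with planted accent magnitudes and ratings, so the
entire pipeline is testable without recordings; `accdist.evalstats` provides
the validation statistics (Pearson correlation, multiple regression,
Steiger's z for dependent correlations, Bark-scaled formant distances,
classical MDS).

## Worked example

Generate a synthetic cohort (20 accented targets, 10 native-like
references), run the measure, and correlate with the planted ratings:

```sh
accdist synth --out cohort --seed 3
accdist run --targets cohort/targets --references cohort/references \
    --out distances.csv --no-validate-paragraph
accdist evaluate --distances distances.csv --ratings cohort/ratings.csv \
    --out report.json
```

The last command prints, for this seed:

```
r = -0.966 (p = 5.20e-12, n = 20); report written to report.json
```

`distances.csv` holds one row per target, e.g.

```
target_speaker_id,mean_distance,n_words_used,n_references_used
tgt00,2.9226...,8,10
tgt19,3.6316...,8,10
```

`mean_distance` is the average normalized DTW cost to the references:
tgt00 (no planted accent) sits near the reference-to-reference floor while
tgt19 (strongest planted accent) is farthest, and the strong negative r
says the distances track the planted native-likeness ratings, as the
measure intends. `--no-validate-paragraph` is needed because the synthetic
cohort uses its own 8-word list; with real archive recordings the default
validates alignments against the standard 69-word elicitation paragraph.

For real data, each speaker directory entry is `<id>.wav` plus `<id>.csv`
(columns `word,start,end` in seconds) or `<id>.TextGrid` (interval tier
named `words`, long or short format).

## Layout

- `accdist.audio_segments` — WAV I/O, resampling, TextGrid/CSV alignments,
  word slicing
- `accdist.mfcc` — 39-dimensional cepstral features
- `accdist.cmvn` — speaker-based cepstral mean and variance normalization
- `accdist.dtw` — length-normalized dynamic time warping
- `accdist.pipeline` — end-to-end measure, baselines, reference-subset
  experiment, CLI backend
- `accdist.evalstats` — validation statistics and plots
- `accdist.synthvoice` — seeded synthetic talkers and cohorts
- `accdist.experiments` — perturbation and vowel-grid experiments

See `docs/methods.md` for the model, parameter defaults, and the design of
the synthetic cohort.
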