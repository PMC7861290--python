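# Methods

## The measure

`accdist` scores how far a target speaker's pronunciation of a common word
list lies from a set of reference speakers, using only the audio:

1. **Segmentation.** Each recording is resampled to one working rate
   (default 11,025 Hz) and sliced into words using externally produced
   word-boundary annotations (forced-aligner TextGrids or CSV). Only the
   annotated word intervals enter the comparison; pauses and disfluencies
   between them are discarded.
2. **Features.** Every word becomes a T×39 matrix: per 25 ms Hamming frame
   (10 ms hop) the first 12 mel-cepstral coefficients (orthonormal DCT-II of
   the log energies of 26 triangular mel filters, 0th coefficient dropped),
   log frame energy, and the delta / double-delta regression derivatives of
   those 13 statics.
3. **Normalization (CMVN).** Each of the 39 dimensions is standardized per
   speaker — mean removed, scaled to unit population variance — with
   statistics pooled over all frames of all the speaker's words. This
   suppresses channel colouring, level, and other per-speaker offsets.
4. **Comparison.** For each shared word, dynamic time warping with
   Euclidean frame costs and the three-move recursion
   γ(i,j) = d(i,j) + min(γ(i−1,j−1), γ(i−1,j), γ(i,j−1)) yields the minimum
   cumulative cost γ(n,m), normalized by (n+m). Word distances are averaged
   per speaker pair, and pair distances averaged over the reference set.

Two reduced modes isolate the preprocessing stages: *segmentation-only*
(word DTW on un-normalized features) and *normalization-only* (one DTW over
the whole unsegmented recording on CMVN-applied features).

## Parameter choices

The frame geometry (25 ms / 10 ms), pre-emphasis coefficient (0.97), the
12-cepstra+energy+Δ+ΔΔ layout, per-speaker CMVN with population (1/N)
variance, unit DTW step weights without a warping window, and the (n+m)
normalization define the measure. Several surrounding conventions are not
fixed by the measure itself; this package uses the HTK-lineage defaults and
exposes all of them in `MfccConfig`:

| parameter | default | note |
|---|---|---|
| mel scale | 2595·log10(1+f/700) | HTK convention |
| mel filters | 26 | HTK-era default |
| FFT size | 512 | smallest power of two ≥ 25 ms up to ~20 kHz |
| delta window N | 2 | regression Δ with edge-frame replication |
| energy | log Σx² per pre-emphasized, un-windowed frame | |
| working rate | 11,025 Hz | all audio resampled before features, so every comparison shares one rate |

The frame cost is the **rooted** Euclidean distance (a squared variant sits
behind `squared=True`); Bark scaling uses the Traunmüller formula
z = 26.81·f/(1960+f) − 0.53, with Zwicker's as an option.

Numerical details:

- **Energy flooring.** Filterbank outputs and frame energies are floored
  80 dB below the utterance's peak before the log (absolute fallback 1e-30
  guards log(0) on all-silent input). A relative floor keeps the cepstra
  and the energy column exactly gain-invariant, so a global level change
  cancels in CMVN; the pipeline is scale-invariant to ~1e-6.
- **Degenerate CMVN dimensions.** Columns with pooled σ < 1e-10 are only
  mean-subtracted.
- **Short words.** A word shorter than one analysis window is zero-padded
  symmetrically to a single frame, with a logged warning.
- **Slicing convention.** Annotations are in seconds; word *k* receives
  samples [floor(start·rate), floor(end·rate)), half-open and 0-based, so a
  gap-free alignment concatenates back to the original samples exactly.
- **Repeated words.** The 69-word elicitation paragraph repeats several
  words ("her" ×4, "the" ×3, …). Word keys carry an occurrence suffix
  (`her`, `her#2`, …) assigned in reading order, so all 69 tokens are kept
  and matched positionally across speakers. Speakers missing a word are
  compared over the intersection of available words, which is recorded as
  `n_words_used`.
- **DTW implementation.** The cost matrix is materialized fully (row-blocked
  to bound memory) and the recursion runs as a compiled (numba) loop with
  the textbook cell order, so results are bit-identical to the naive
  dynamic program — and to exhaustive enumeration over warping paths, which
  the test suite checks exactly.
- **MDS orientation.** Classical (Torgerson) MDS orients each axis so its
  largest-magnitude loading is positive, making plots reproducible despite
  the eigenvector sign indeterminacy.

## The synthetic validation cohort

Real validation of an accent measure needs recordings and human
native-likeness ratings. To make every stage testable without them,
`synthvoice` builds a fully seeded miniature speaker archive by source–
filter synthesis: jittered glottal impulse trains with a −12 dB/oct tilt,
filtered by second-order resonators at per-vowel (F1, F2, F3) targets from
a 12-monophthong grid.

`make_cohort` emulates the study conditions in the on-disk layout the
pipeline consumes (WAV + CSV alignments + ratings CSV):

- **References** (default 10): one shared vowel grid with 2% per-talker
  formant variation; per-talker pitch (110–150 Hz), syllable duration
  (0.24–0.32 s), level (0.2–0.8), mild random channel colouring (±~6 dB
  band ripple), and low-level noise. A single-gender cohort is used so the
  planted accent, not pitch class, dominates the distances.
- **Targets** (default 20) carry a planted accent magnitude a ∈ [0, 1]
  (evenly spaced): vowels centralize toward schwa by 70%·a — the vowel
  reduction/merger typical of strong foreign accents — and syllables
  lengthen by 30%·a.
- **Ratings** are planted as 7 − 5.5·a plus N(0, 0.15) noise, clipped to
  the 1–7 scale.
- **Disfluencies.** Recordings interleave seeded filled pauses (schwa
  vocalizations) and variable silences between words. These lie outside the
  word boundaries, so the full measure never sees them — but the
  unsegmented (normalization-only) baseline must swallow them, reproducing
  the reason segmentation matters on real data.

What the generator deliberately does **not** model: consonants and true
articulatory dynamics, coarticulation, prosodic phrasing, rater
disagreement, or aligner boundary errors. Passing the synthetic checks
shows the pipeline's machinery is correct and ordered as expected — not
that real-data correlations of any particular size would be obtained.

Two controlled experiments mirror the measure's sensitivity analyses
(`experiments`):

- **Perturbations.** One talker repeats a two-syllable pseudo-word; the
  rendition-to-rendition distance is the floor. Variants with a coloured
  recording channel, a rising f0 contour (×1.0→×1.5), or the first syllable
  stretched ×1.5 must exceed that floor — checked over 20 seeded
  repetitions.
- **Vowel grid.** One talker repeats each of the 12 vowels 10 times; mean
  DTW distances between vowels are correlated with Bark-scaled (F1, F2)
  distances of the planted targets, and visualized with classical MDS.

## Evaluation statistics

`evalstats` wraps the validation toolkit: Pearson correlation with human
(or planted) ratings (scipy), OLS multiple regression with intercept and
two-sided t tests (statsmodels; no multiple-testing correction), Steiger's
modified z for dependent correlations sharing one variable (Fisher
transforms of r12 and r13, pooled-r̄ covariance term via
ψ = r23(1−2r̄²) − ½r̄²(1−2r̄²−r23²)), Bark-scaled formant distances, and
Torgerson classical MDS with variance-explained fractions. When `evaluate`
performs the Steiger comparison it uses the joined speaker count as n.

## Problem sizes

The default test-suite and acceptance-script conditions are the cohort of
20 targets × 10 references × 8 words at 11,025 Hz, 20 seeded repetitions of
the perturbation experiment, a 12-vowel × 10-rendition grid, and 2,000
simulated replicates for the Steiger null calibration. The whole suite runs
in well under a minute of compute per experiment on one CPU.

## Known limitations

- MFCCs at a 26-filter resolution retain pitch information; cross-talker f0
  differences contribute a distance floor that CMVN cannot remove (visible
  in the nonzero rendition-to-rendition distances).
- The measure remains sensitive to recording-channel differences in the
  un-normalized baseline, and partially even after CMVN (channel effects
  interact with the signal nonlinearly through framing and flooring).
- Forced alignment itself is out of scope: word boundaries are consumed,
  never produced, and their quality bounds the measure's quality.
- The generator's accent model is purely vocalic and durational; segmental
  insertions/deletions and consonantal substitutions are not simulated.
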