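#!/usr/bin/env python
"""Recompute the headline accent-strength correlation on real archive data.

Not part of the test suite: requires user-downloaded Speech Accent Archive
recordings.  Expects two directories of speakers (WAV + word alignment per
speaker, CSV or TextGrid — see README) and a ratings CSV with columns
speaker_id,mean_rating.  Runs the full measure (resample to 11,025 Hz,
69-word segmentation, MFCC, speaker CMVN, length-normalized word DTW
averaged over the reference set) and prints the Pearson correlation between
the resulting distances and the ratings.

    python scripts/saa_headline.py --targets DIR --references DIR \\
        --ratings ratings.csv --out distances.csv
"""

import argparse
from pathlib import Path

import pandas as pd

from accdist.audio_segments import paragraph_words
from accdist.evalstats import evaluate
from accdist.pipeline import PipelineConfig, run_measure


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--targets", type=Path, required=True)
    parser.add_argument("--references", type=Path, required=True)
    parser.add_argument("--ratings", type=Path, required=True)
    parser.add_argument("--out", type=Path, default=Path("distances.csv"))
    parser.add_argument("--rate", type=int, default=11025)
    parser.add_argument("--no-validate", action="store_true",
                        help="skip the 69-word paragraph check")
    args = parser.parse_args()

    config = PipelineConfig(
        rate=args.rate,
        expected_words=None if args.no_validate else paragraph_words(),
    )
    table = run_measure(args.targets, args.references, config)
    table.to_csv(args.out, index=False)
    report = evaluate(table, pd.read_csv(args.ratings))
    print(f"n = {report['n']} speakers")
    print(f"Pearson r = {report['pearson_r']:.3f} (p = {report['pearson_p']:.2e})")


if __name__ == "__main__":
    main()
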