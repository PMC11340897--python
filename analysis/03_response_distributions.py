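#!/usr/bin/env python
"""Summarise how the retained cohort interprets each phrase.

Per phrase: the 25th/50th/75th percentiles of the 0-100 ratings with a
percentile-bootstrap CI on the median, and a kernel density profile on the
bounded response scale — the numeric content of the study's ridgeline
figures and percentile tables.
"""

import argparse
from pathlib import Path

import pandas as pd

from vocabrank import density_profile, percentile_summary, read_ratings, read_vocabularies
from vocabrank.stats import summary_frame

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    parser.add_argument("--n-boot", type=int, default=10_000)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    table = read_ratings(args.cohort / "retained.csv")
    vocabularies = read_vocabularies(args.cohort / "vocab.json")

    summaries, densities = [], []
    for voc in vocabularies:
        summ = percentile_summary(table, voc, n_boot=args.n_boot, seed=args.seed)
        df = summary_frame(summ)
        df.insert(0, "vocabulary_id", voc.vocabulary_id)
        df.insert(1, "dimension", voc.dimension_label)
        summaries.append(df)
        block = table.block(voc)
        for phrase in voc.phrases:
            prof = density_profile(block[phrase].dropna())
            densities.append(
                pd.DataFrame(
                    {
                        "vocabulary_id": voc.vocabulary_id,
                        "dimension": voc.dimension_label,
                        "phrase": phrase,
                        "grid": prof.grid,
                        "density": prof.density,
                    }
                )
            )

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(out / "percentile_summary.csv", index=False)
    pd.concat(densities, ignore_index=True).to_csv(out / "density_profiles.csv", index=False)

    print("per-phrase quartiles (median with 95% bootstrap CI):")
    with pd.option_context("display.width", 120):
        print(summary.round(1).to_string(index=False))
    print(f"\nwrote {out}/percentile_summary.csv and density_profiles.csv")


if __name__ == "__main__":
    main()
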