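#!/usr/bin/env python
"""How well do implied rankings agree with the intended ranking?

Per vocabulary x dimension block: the matched-ranking proportion with its
Sison-Glaz simultaneous CI, the distinct implied rankings and their
frequencies, the distribution of normalised Kendall distances from the
intended order, and the phrase-level rank concordance matrix.
"""

import argparse
from pathlib import Path

import pandas as pd

from vocabrank import (
    concordance_matrix,
    distance_distribution,
    matched_proportion,
    ranking_frequencies,
    read_ratings,
    read_vocabularies,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    args = parser.parse_args()

    table = read_ratings(args.cohort / "retained.csv")
    vocabularies = read_vocabularies(args.cohort / "vocab.json")
    out = ROOT / "results"
    out.mkdir(exist_ok=True)

    matched_rows, freq_frames, kd_frames, conc_frames = [], [], [], []
    for voc in vocabularies:
        est = matched_proportion(table, voc)
        freq = ranking_frequencies(table, voc)
        dist = distance_distribution(table, voc)
        conc = concordance_matrix(table, voc)
        matched_rows.append(
            {
                "vocabulary_id": voc.vocabulary_id,
                "dimension": voc.dimension_label,
                "n": freq.n_total,
                "proportion": est.point,
                "ci_low": est.lower,
                "ci_high": est.upper,
                "n_distinct_rankings": freq.n_distinct,
            }
        )
        for df, store in ((freq.to_frame(), freq_frames),
                          (dist.distances, kd_frames),
                          (conc.to_frame(), conc_frames)):
            df = df.copy()
            df.insert(0, "vocabulary_id", voc.vocabulary_id)
            df.insert(1, "dimension", voc.dimension_label)
            store.append(df)
        print(
            f"{voc.vocabulary_id:>11s} / {voc.dimension_label:<19s} "
            f"matched {100 * est.point:5.1f}% "
            f"[{100 * est.lower:.1f}%, {100 * est.upper:.1f}%]  "
            f"({freq.n_distinct} distinct rankings, "
            f"mean normalised Kd {dist.distances.kd_normalized.mean():.3f})"
        )

    pd.DataFrame(matched_rows).to_csv(out / "matched_proportions.csv", index=False)
    pd.concat(freq_frames, ignore_index=True).to_csv(out / "ranking_frequencies.csv", index=False)
    pd.concat(kd_frames, ignore_index=True).to_csv(out / "kd_distribution.csv", index=False)
    pd.concat(conc_frames, ignore_index=True).to_csv(out / "concordance.csv", index=False)
    print(f"\nwrote matched_proportions, ranking_frequencies, kd_distribution, concordance -> {out}/")


if __name__ == "__main__":
    main()
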