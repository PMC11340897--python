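#!/usr/bin/env python
"""Paired comparison of the two vocabularies on each dimension.

Within participants, did the alternative vocabulary produce more intended
rankings than the journal vocabulary?  Reports the 2x2 paired match table,
exact and mid-p McNemar p-values, and the conditional odds ratio with its
mid-p Clopper-Pearson CI.
"""

import argparse
from pathlib import Path

import pandas as pd

from vocabrank import compare_vocabularies, read_ratings, read_vocabularies

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    args = parser.parse_args()

    table = read_ratings(args.cohort / "retained.csv")
    vocabularies = read_vocabularies(args.cohort / "vocab.json")
    by_dim: dict[str, list] = {}
    for voc in vocabularies:
        by_dim.setdefault(voc.dimension_label, []).append(voc)

    rows = []
    for dim, vocs in sorted(by_dim.items()):
        # orient so b counts alternative-only matches (odds ratio > 1 means
        # the alternative vocabulary communicates its ordering better)
        vocs = sorted(vocs, key=lambda v: v.vocabulary_id != "alternative")
        res = compare_vocabularies(table, vocs[0], vocs[1])
        orr = res.odds_ratio
        rows.append(
            {
                "dimension": dim,
                "vocab_a": res.vocab_a,
                "vocab_b": res.vocab_b,
                "n11": res.table.n11,
                "n10": res.table.n10,
                "n01": res.table.n01,
                "n00": res.table.n00,
                "p_exact": res.p_exact,
                "p_midp": res.p_midp,
                "odds_ratio": orr.point if orr else float("nan"),
                "or_ci_low": orr.lower if orr else float("nan"),
                "or_ci_high": orr.upper if orr else float("nan"),
            }
        )
        print(
            f"{dim}: {res.vocab_a} vs {res.vocab_b}  "
            f"b={res.table.b} c={res.table.c}  "
            f"OR={orr.point:.1f} [{orr.lower:.2f}, {orr.upper:.2f}]  "
            f"mid-p={res.p_midp:.3g}"
            if orr
            else f"{dim}: no discordant pairs (p = 1)"
        )

    out = ROOT / "results" / "mcnemar.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
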