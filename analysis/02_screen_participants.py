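#!/usr/bin/env python
"""Apply the sequential exclusion screen to the simulated cohort.

Reads results/cohort/ratings.csv, removes participants criterion by
criterion (attention failure, > 30 min, incomplete, < 5 min), writes the
retained table and the auditable exclusion cascade.
"""

import argparse
from pathlib import Path

from vocabrank import apply_exclusions, read_ratings, write_ratings

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    args = parser.parse_args()

    table = read_ratings(args.cohort / "ratings.csv")
    retained, log = apply_exclusions(table)

    write_ratings(retained, args.cohort / "retained.csv")
    frame = log.to_frame()
    frame.insert(0, "initial_n", log.initial_n)
    frame["retained_n"] = log.retained_n
    out = ROOT / "results" / "exclusion_log.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out, index=False)

    print(f"started with {log.initial_n} participants")
    for criterion, removed in log.steps:
        print(f"  {criterion:>15s}: removed {removed}")
    print(f"retained {log.retained_n} eligible participants -> {args.cohort}/retained.csv")


if __name__ == "__main__":
    main()
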