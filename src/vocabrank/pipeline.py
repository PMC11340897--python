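"""End-to-end orchestration: load -> exclude -> summarise -> rank -> compare.

`run_full_analysis` executes every stage of the rating analysis on one
table, writes each result family as delimited text to an output directory,
and returns the in-memory :class:`AnalysisReport`.  `compare_vocabularies`
performs the paired (within-participant) comparison of two vocabularies on a
shared dimension via the exact/mid-p McNemar machinery.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .errors import ValidationError
from .io import (
    ExclusionCriteria,
    ExclusionLog,
    RatingTable,
    Vocabulary,
    apply_exclusions,
)
from .ranking import (
    ConcordanceMatrix,
    DistanceDistribution,
    RankingFrequencyTable,
    concordance_matrix,
    distance_distribution,
    intended_order,
    matched_proportion,
    matches_intended,
    ranking_frequencies,
    _block_orders,
)
from .stats import (
    IntervalEstimate,
    PairedMatchTable,
    PercentileSummary,
    mcnemar_exact_p,
    mcnemar_or_ci,
    percentile_summary,
    summary_frame,
)

__all__ = ["VocabularyComparison", "AnalysisReport", "compare_vocabularies", "run_full_analysis"]


@dataclass(frozen=True)
class VocabularyComparison:
    """Paired comparison of two vocabularies on one dimension."""

    dimension: str
    vocab_a: str
    vocab_b: str
    table: PairedMatchTable
    p_exact: float
    p_midp: float
    odds_ratio: IntervalEstimate | None  # None when there are no discordant pairs
    dropped: tuple[str, ...]  # participants incomplete in either block


@dataclass
class AnalysisReport:
    """All result families of one analysis run, keyed (vocabulary, dimension)."""

    exclusion_log: ExclusionLog
    summaries: dict[tuple[str, str], list[PercentileSummary]]
    matched: dict[tuple[str, str], IntervalEstimate]
    comparisons: list[VocabularyComparison]
    frequencies: dict[tuple[str, str], RankingFrequencyTable]
    distances: dict[tuple[str, str], DistanceDistribution]
    concordance: dict[tuple[str, str], ConcordanceMatrix]
    provenance: dict


def compare_vocabularies(
    table: RatingTable,
    vocab_a: Vocabulary,
    vocab_b: Vocabulary,
    alpha: float = 0.05,
) -> VocabularyComparison:
    """Within-participant comparison of matched-ranking status under two
    vocabularies sharing a dimension.

    Builds the 2x2 paired match table over participants complete in both
    blocks (others are dropped and reported), then returns the exact and
    mid-p McNemar p-values and the conditional odds ratio ``b/c`` (first-only
    over second-only matches) with its mid-p Clopper-Pearson CI.
    """
    if vocab_a.dimension_label != vocab_b.dimension_label:
        raise ValidationError(
            f"vocabularies grade different dimensions: "
            f"{vocab_a.dimension_label!r} vs {vocab_b.dimension_label!r}"
        )
    status: dict[str, dict[str, bool]] = {}
    dropped: set[str] = set()
    for voc in (vocab_a, vocab_b):
        orders, missing = _block_orders(table, voc)
        dropped.update(missing)
        for o in orders:
            status.setdefault(o.participant_id, {})[voc.vocabulary_id] = (
                matches_intended(o, voc)
            )
    paired = {
        pid: s for pid, s in status.items()
        if pid not in dropped and len(s) == 2
    }
    dropped.update(pid for pid in status if pid not in paired)
    if not paired:
        raise ValidationError("no participants complete in both blocks")
    n11 = sum(s[vocab_a.vocabulary_id] and s[vocab_b.vocabulary_id] for s in paired.values())
    n10 = sum(s[vocab_a.vocabulary_id] and not s[vocab_b.vocabulary_id] for s in paired.values())
    n01 = sum(not s[vocab_a.vocabulary_id] and s[vocab_b.vocabulary_id] for s in paired.values())
    n00 = len(paired) - n11 - n10 - n01
    match2x2 = PairedMatchTable(n11=n11, n10=n10, n01=n01, n00=n00)
    return VocabularyComparison(
        dimension=vocab_a.dimension_label,
        vocab_a=vocab_a.vocabulary_id,
        vocab_b=vocab_b.vocabulary_id,
        table=match2x2,
        p_exact=mcnemar_exact_p(match2x2, midp=False),
        p_midp=mcnemar_exact_p(match2x2, midp=True),
        odds_ratio=(
            mcnemar_or_ci(match2x2, alpha=alpha) if n10 + n01 > 0 else None
        ),
        dropped=tuple(sorted(dropped)),
    )


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_full_analysis(
    table: RatingTable,
    vocabularies: Sequence[Vocabulary],
    alpha: float = 0.05,
    n_boot: int = 10_000,
    seed: int = 0,
    out_dir: str | Path | None = None,
    criteria: ExclusionCriteria = ExclusionCriteria(),
    log=None,
) -> AnalysisReport:
    """Run every analysis stage and (optionally) write the report tables.

    Stages, in order: sequential exclusion screen; per-phrase quartile
    summaries with bootstrap median CIs; matched-ranking proportions with
    simultaneous CIs; distinct-ranking frequencies; Kendall-distance
    distributions; concordance matrices; paired McNemar comparisons for every
    dimension rated under exactly two vocabularies.  Deterministic for fixed
    inputs and seed; the written tables are byte-identical across re-runs.
    """
    log = log or (lambda msg: print(msg, file=sys.stderr))
    retained, excl_log = apply_exclusions(table, criteria)
    log(f"exclusions: {excl_log.initial_n} -> {excl_log.retained_n} participants")

    summaries, matched, freqs, dists, concs = {}, {}, {}, {}, {}
    for voc in vocabularies:
        key = (voc.vocabulary_id, voc.dimension_label)
        summaries[key] = percentile_summary(retained, voc, n_boot=n_boot, seed=seed)
        matched[key] = matched_proportion(retained, voc, alpha=alpha)
        freqs[key] = ranking_frequencies(retained, voc)
        dists[key] = distance_distribution(retained, voc)
        concs[key] = concordance_matrix(retained, voc)
        log(
            f"{voc.vocabulary_id}/{voc.dimension_label}: "
            f"{freqs[key].n_total} complete participants, "
            f"matched {100 * matched[key].point:.1f}%"
        )

    comparisons = []
    by_dim: dict[str, list[Vocabulary]] = {}
    for voc in vocabularies:
        by_dim.setdefault(voc.dimension_label, []).append(voc)
    for dim, vocs in by_dim.items():
        if len(vocs) == 2:
            comparisons.append(compare_vocabularies(retained, vocs[0], vocs[1], alpha=alpha))

    provenance = {
        "package_version": __version__,
        "seed": seed,
        "alpha": alpha,
        "n_boot": n_boot,
        "config_hash": _config_hash(
            {
                "alpha": alpha,
                "n_boot": n_boot,
                "seed": seed,
                "criteria": vars(criteria),
                "vocabularies": [
                    (v.vocabulary_id, v.dimension_label, v.phrases) for v in vocabularies
                ],
            }
        ),
    }
    report = AnalysisReport(
        exclusion_log=excl_log,
        summaries=summaries,
        matched=matched,
        comparisons=comparisons,
        frequencies=freqs,
        distances=dists,
        concordance=concs,
        provenance=provenance,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: AnalysisReport, out_dir: str | Path) -> None:
    """Write every result family as delimited text plus a JSON manifest.

    All tables are deterministic; the manifest records provenance (config
    hash, seed, package version) and the write timestamp.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    excl = report.exclusion_log.to_frame()
    excl.insert(0, "initial_n", report.exclusion_log.initial_n)
    excl["retained_n"] = report.exclusion_log.retained_n
    excl.to_csv(out / "exclusion_log.csv", index=False)

    rows = []
    for (vid, dim), summaries in report.summaries.items():
        df = summary_frame(summaries)
        df.insert(0, "vocabulary_id", vid)
        df.insert(1, "dimension", dim)
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(out / "percentile_summary.csv", index=False)

    pd.DataFrame(
        [
            {
                "vocabulary_id": vid,
                "dimension": dim,
                "proportion": est.point,
                "ci_low": est.lower,
                "ci_high": est.upper,
                "level": est.level,
                "method": est.method,
            }
            for (vid, dim), est in report.matched.items()
        ]
    ).to_csv(out / "matched_proportions.csv", index=False)

    pd.DataFrame(
        [
            {
                "dimension": c.dimension,
                "vocab_a": c.vocab_a,
                "vocab_b": c.vocab_b,
                "n11": c.table.n11,
                "n10": c.table.n10,
                "n01": c.table.n01,
                "n00": c.table.n00,
                "p_exact": c.p_exact,
                "p_midp": c.p_midp,
                "odds_ratio": c.odds_ratio.point if c.odds_ratio else float("nan"),
                "or_ci_low": c.odds_ratio.lower if c.odds_ratio else float("nan"),
                "or_ci_high": c.odds_ratio.upper if c.odds_ratio else float("nan"),
            }
            for c in report.comparisons
        ]
    ).to_csv(out / "mcnemar.csv", index=False)

    rows = []
    for (vid, dim), freq in report.frequencies.items():
        df = freq.to_frame()
        df.insert(0, "vocabulary_id", vid)
        df.insert(1, "dimension", dim)
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(out / "ranking_frequencies.csv", index=False)

    rows = []
    for (vid, dim), dist in report.distances.items():
        df = dist.distances.copy()
        df.insert(0, "vocabulary_id", vid)
        df.insert(1, "dimension", dim)
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(out / "kd_distribution.csv", index=False)

    rows = []
    for (vid, dim), conc in report.concordance.items():
        df = conc.to_frame()
        df.insert(0, "vocabulary_id", vid)
        df.insert(1, "dimension", dim)
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(out / "concordance.csv", index=False)

    manifest = dict(report.provenance)
    manifest["written_at"] = datetime.now(timezone.utc).isoformat(timespec="seconds")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
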