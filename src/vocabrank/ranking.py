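"""Implied rankings and their agreement with a vocabulary's intended order.

Continuous 0-100 ratings of each phrase imply, per participant, a weak order
over the vocabulary (ties allowed when two phrases get the same rating).
This module derives those orders and quantifies agreement with the intended
ranking: exact match, distinct-ranking frequencies, Kendall's tau distance
(raw and normalised), and a per-phrase rank concordance matrix.

Tie conventions, applied throughout: tied ratings get tied midranks; a tied
order never counts as matching the strict intended ranking; a phrase pair
tied in exactly one of two orders contributes 0.5 discordance to Kendall's
distance; in the concordance matrix a tie group spreads fractionally over
the integer rank positions it spans.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .io import RatingTable, Vocabulary
from .stats import IntervalEstimate, sison_glaz_ci

__all__ = [
    "WeakOrder",
    "RankingFrequencyTable",
    "DistanceDistribution",
    "ConcordanceMatrix",
    "implied_ranking",
    "intended_order",
    "matches_intended",
    "ranking_frequencies",
    "kendall_distance",
    "normalized_kendall_distance",
    "distance_distribution",
    "concordance_matrix",
    "matched_proportion",
]


@dataclass(frozen=True)
class WeakOrder:
    """One participant's implied ranking of a vocabulary's phrases.

    ``ranks`` maps each phrase to its midrank (1 = best); tied phrases share
    an averaged rank, so for k phrases the ranks always sum to k(k+1)/2.
    """

    participant_id: str
    vocabulary_id: str
    ranks: dict[str, float]

    def __post_init__(self) -> None:
        k = len(self.ranks)
        if k < 1:
            raise ValidationError("empty weak order")
        total = sum(self.ranks.values())
        if abs(total - k * (k + 1) / 2) > 1e-9:
            raise ValidationError(
                f"ranks are not a midrank assignment: sum {total} != {k*(k+1)/2}"
            )

    @property
    def has_ties(self) -> bool:
        vals = list(self.ranks.values())
        return len(set(vals)) < len(vals)

    def label(self) -> str:
        """Human-readable order string, e.g. ``"a > b = c > d"``."""
        groups: dict[float, list[str]] = {}
        for phrase, r in self.ranks.items():
            groups.setdefault(r, []).append(phrase)
        parts = [
            " = ".join(sorted(groups[r])) for r in sorted(groups)
        ]
        return " > ".join(parts)


@dataclass(frozen=True)
class RankingFrequencyTable:
    """Distinct implied rankings and how many participants produced each."""

    vocabulary_id: str
    entries: tuple[tuple[str, int], ...]  # (order label, count), descending count
    n_distinct: int
    n_total: int
    excluded: tuple[str, ...] = ()  # participants dropped for missing phrases

    def __post_init__(self) -> None:
        if sum(c for _, c in self.entries) != self.n_total:
            raise ValidationError("frequency counts do not sum to n_total")
        if sum(1 for _, c in self.entries if c > 0) != self.n_distinct:
            raise ValidationError("n_distinct inconsistent with entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["ranking", "count"])


@dataclass(frozen=True)
class DistanceDistribution:
    """Per-participant Kendall distances from the intended ranking."""

    vocabulary_id: str
    distances: pd.DataFrame  # columns participant_id, kd, kd_normalized

    def histogram(self) -> pd.DataFrame:
        """Counts over the distinct attained normalised distances."""
        h = (
            self.distances.groupby("kd_normalized").size().rename("count").reset_index()
        )
        return h.sort_values("kd_normalized", ignore_index=True)


@dataclass(frozen=True)
class ConcordanceMatrix:
    """Intended-rank x observed-rank percentage table for one vocabulary.

    ``cell[i - 1, j - 1]`` is the percentage of participants whose phrase with
    intended rank i received observed rank j; tied observed ranks distribute
    fractionally over the positions the tie spans, so every row and every
    column sums to 100.
    """

    vocabulary_id: str
    phrases: tuple[str, ...]
    cell: np.ndarray
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        n = len(self.phrases)
        rows = [
            {
                "phrase": self.phrases[i],
                "intended_rank": i + 1,
                "observed_rank": j + 1,
                "percent": self.cell[i, j],
            }
            for i in range(n)
            for j in range(n)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


def implied_ranking(
    ratings: Mapping[str, float],
    vocabulary: Vocabulary,
    participant_id: str = "",
) -> WeakOrder:
    """Derive a participant's implied ranking from their phrase ratings.

    Higher ratings get numerically smaller (better) ranks; equal ratings get
    tied midranks.  Every phrase of the vocabulary must be rated.
    """
    missing = [p for p in vocabulary.phrases if p not in ratings or pd.isna(ratings[p])]
    if missing:
        raise ValidationError(f"missing rating(s) for phrase(s): {missing}")
    values = np.array([float(ratings[p]) for p in vocabulary.phrases])
    ranks = rankdata(-values, method="average")
    return WeakOrder(
        participant_id=participant_id,
        vocabulary_id=vocabulary.vocabulary_id,
        ranks={p: float(r) for p, r in zip(vocabulary.phrases, ranks)},
    )


def intended_order(vocabulary: Vocabulary) -> WeakOrder:
    """The vocabulary's own intended ranking as a (strict) weak order."""
    return WeakOrder(
        participant_id="<intended>",
        vocabulary_id=vocabulary.vocabulary_id,
        ranks={p: float(r) for p, r in vocabulary.intended_rank.items()},
    )


def matches_intended(order: WeakOrder, vocabulary: Vocabulary) -> bool:
    """True iff the order is strict and equals the intended ranking exactly.

    A tied order never matches, even when no rated pair contradicts the
    intended direction: a match requires the participant to have separated
    every phrase as intended.
    """
    if set(order.ranks) != set(vocabulary.phrases):
        raise ValidationError("order does not cover the vocabulary's phrases")
    if order.has_ties:
        return False
    return all(order.ranks[p] == r for p, r in vocabulary.intended_rank.items())


def _block_orders(
    table: RatingTable, vocabulary: Vocabulary
) -> tuple[list[WeakOrder], list[str]]:
    """Implied orders for every participant complete in this block; second
    return value lists participants dropped for missing phrases."""
    block = table.block(vocabulary)
    orders, dropped = [], []
    for pid, row in block.iterrows():
        if row.isna().any():
            dropped.append(str(pid))
            continue
        orders.append(implied_ranking(row.to_dict(), vocabulary, participant_id=str(pid)))
    return orders, dropped


def ranking_frequencies(
    table: RatingTable, vocabulary: Vocabulary
) -> RankingFrequencyTable:
    """Tabulate distinct implied rankings (tie patterns kept distinct).

    Participants missing any phrase of the block are excluded and reported in
    the table's ``excluded`` field.
    """
    orders, dropped = _block_orders(table, vocabulary)
    counts: dict[str, int] = {}
    for o in orders:
        key = o.label()
        counts[key] = counts.get(key, 0) + 1
    entries = tuple(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return RankingFrequencyTable(
        vocabulary_id=vocabulary.vocabulary_id,
        entries=entries,
        n_distinct=len(entries),
        n_total=len(orders),
        excluded=tuple(dropped),
    )


def kendall_distance(order_a: WeakOrder, order_b: WeakOrder) -> float:
    """Kendall's tau distance between two weak orders over the same phrases.

    Counts phrase pairs ordered oppositely in the two orders; a pair tied in
    exactly one order contributes 0.5 (a pair tied in both contributes 0).
    On strict orders this equals the minimum number of adjacent
    transpositions converting one order into the other.  Symmetric.
    """
    if set(order_a.ranks) != set(order_b.ranks):
        raise ValidationError("orders cover different phrase sets")
    d = 0.0
    for p, q in combinations(order_a.ranks, 2):
        da = order_a.ranks[p] - order_a.ranks[q]
        db = order_b.ranks[p] - order_b.ranks[q]
        if da == 0 and db == 0:
            continue
        if da == 0 or db == 0:
            d += 0.5
        elif (da > 0) != (db > 0):
            d += 1.0
    return d


def normalized_kendall_distance(order_a: WeakOrder, order_b: WeakOrder) -> float:
    """Kendall distance divided by its maximum n(n-1)/2, in [0, 1]."""
    n = len(order_a.ranks)
    if n < 2:
        raise ValidationError("normalised distance undefined for n < 2")
    return kendall_distance(order_a, order_b) / (n * (n - 1) / 2.0)


def distance_distribution(
    table: RatingTable, vocabulary: Vocabulary
) -> DistanceDistribution:
    """Per-participant (normalised) Kendall distance from the intended ranking."""
    target = intended_order(vocabulary)
    orders, _ = _block_orders(table, vocabulary)
    rows = []
    for o in orders:
        kd = kendall_distance(o, target)
        rows.append(
            {
                "participant_id": o.participant_id,
                "kd": kd,
                "kd_normalized": kd / (vocabulary.n * (vocabulary.n - 1) / 2.0),
            }
        )
    df = pd.DataFrame(rows, columns=["participant_id", "kd", "kd_normalized"])
    return DistanceDistribution(vocabulary_id=vocabulary.vocabulary_id, distances=df)


def concordance_matrix(
    table: RatingTable, vocabulary: Vocabulary
) -> ConcordanceMatrix:
    """Percentage of participants assigning each phrase each observed rank.

    A tie group of t phrases sharing midrank r occupies the t consecutive
    integer positions centred on r; each member contributes 1/t of a
    participant to each of those positions, preserving row and column sums.
    """
    orders, _ = _block_orders(table, vocabulary)
    if not orders:
        raise ValidationError("no complete participants in this block")
    n = vocabulary.n
    counts = np.zeros((n, n))
    intended = vocabulary.intended_rank
    for o in orders:
        tie_size: dict[float, int] = {}
        for r in o.ranks.values():
            tie_size[r] = tie_size.get(r, 0) + 1
        for phrase, r in o.ranks.items():
            t = tie_size[r]
            first = int(round(r - (t - 1) / 2.0))
            for pos in range(first, first + t):
                counts[intended[phrase] - 1, pos - 1] += 1.0 / t
    return ConcordanceMatrix(
        vocabulary_id=vocabulary.vocabulary_id,
        phrases=vocabulary.phrases,
        cell=100.0 * counts / len(orders),
        n_total=len(orders),
    )


def matched_proportion(
    table: RatingTable, vocabulary: Vocabulary, alpha: float = 0.05
) -> IntervalEstimate:
    """Proportion of participants whose implied ranking matches the intended one.

    The interval is the matched category's Sison-Glaz simultaneous CI on the
    (matched, unmatched) counts.
    """
    orders, _ = _block_orders(table, vocabulary)
    if not orders:
        raise ValidationError("no complete participants in this block")
    matched = sum(matches_intended(o, vocabulary) for o in orders)
    return sison_glaz_ci([matched, len(orders) - matched], alpha=alpha)[0]
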