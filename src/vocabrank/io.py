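"""Reading, writing and screening of vocabulary definitions and rating tables.

A *vocabulary* is an ordered list of evaluative phrases for one dimension
(e.g. importance), most positive first; the listed order defines the intended
ranks 1..n.  A *rating table* holds one row per participant x phrase with a
0-100 slider rating, plus per-participant metadata (completion time,
attention-check outcome) used by the sequential exclusion screen.

File formats are deliberately plain: delimited text with a header for ratings
(comma by default, tab accepted) and a small JSON document for vocabularies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "Vocabulary",
    "RatingTable",
    "ExclusionCriteria",
    "ExclusionLog",
    "read_ratings",
    "write_ratings",
    "read_vocabularies",
    "write_vocabularies",
    "apply_exclusions",
]

#: Columns a rating file must provide.
REQUIRED_COLUMNS = ("participant_id", "vocabulary_id", "dimension", "phrase", "rating")
#: Optional per-row / per-participant columns carried through when present.
OPTIONAL_COLUMNS = ("presentation_order", "duration_minutes", "attention_pass")


@dataclass(frozen=True)
class Vocabulary:
    """An ordered evaluative vocabulary for one dimension.

    Parameters
    ----------
    vocabulary_id
        Identifier shared by all dimensions of one vocabulary (e.g. ``"elife"``).
    dimension_label
        The evaluative dimension the phrases grade (e.g. ``"importance"``).
    phrases
        Phrase texts, most positive first.  The listed order defines the
        intended rank: ``phrases[0]`` has intended rank 1.
    """

    vocabulary_id: str
    dimension_label: str
    phrases: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "phrases", tuple(self.phrases))
        if len(self.phrases) < 2:
            raise ValidationError(
                f"vocabulary {self.vocabulary_id!r}/{self.dimension_label!r} "
                f"needs at least 2 phrases, got {len(self.phrases)}"
            )
        if len(set(self.phrases)) != len(self.phrases):
            dupes = sorted({p for p in self.phrases if list(self.phrases).count(p) > 1})
            raise ValidationError(
                f"duplicate phrase(s) {dupes} in vocabulary "
                f"{self.vocabulary_id!r}/{self.dimension_label!r}"
            )

    @property
    def n(self) -> int:
        """Number of phrases."""
        return len(self.phrases)

    @property
    def intended_rank(self) -> dict[str, int]:
        """Mapping phrase -> intended rank (1 = most positive)."""
        return {p: i + 1 for i, p in enumerate(self.phrases)}


@dataclass
class RatingTable:
    """Long-format participant x phrase ratings plus participant metadata.

    ``records`` has one row per (participant_id, vocabulary_id, dimension,
    phrase) with a numeric ``rating`` in [0, 100].  ``meta`` is indexed by
    participant_id and carries ``duration_minutes`` (NaN if unknown) and
    ``attention_pass`` (True if unknown) plus any extra columns.
    """

    records: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"records missing required column(s): {missing}")
        self.records = self.records.reset_index(drop=True)
        bad = self.records[
            (self.records["rating"] < 0) | (self.records["rating"] > 100)
            | self.records["rating"].isna()
        ]
        if len(bad):
            raise ValidationError(
                "rating outside [0, 100] (or unparseable) in rows "
                f"{list(bad.index[:20])}: values {list(bad['rating'][:20])}"
            )
        key = ["participant_id", "vocabulary_id", "phrase"]
        dup = self.records.duplicated(subset=key)
        if dup.any():
            raise ValidationError(
                f"duplicate (participant, vocabulary, phrase) rows: "
                f"{self.records.loc[dup, key].head(10).to_dict('records')}"
            )
        unmet = set(self.records["participant_id"]) - set(self.meta.index)
        if unmet:
            raise ValidationError(f"records reference participants without metadata: {sorted(unmet)[:10]}")

    @property
    def participants(self) -> list[str]:
        """Participant ids present in the records, in first-seen order."""
        return list(dict.fromkeys(self.records["participant_id"]))

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def block(self, vocabulary: Vocabulary) -> pd.DataFrame:
        """Participant x phrase rating matrix for one vocabulary x dimension.

        Rows are participants, columns the vocabulary's phrases in intended
        order; missing responses are NaN.
        """
        sub = self.records[
            (self.records["vocabulary_id"] == vocabulary.vocabulary_id)
            & (self.records["dimension"] == vocabulary.dimension_label)
        ]
        wide = sub.pivot_table(
            index="participant_id", columns="phrase", values="rating", aggfunc="first"
        )
        return wide.reindex(columns=list(vocabulary.phrases))

    def select_participants(self, keep: Iterable[str]) -> "RatingTable":
        keep = set(keep)
        rec = self.records[self.records["participant_id"].isin(keep)].copy()
        meta = self.meta.loc[self.meta.index.isin(keep)].copy()
        return RatingTable(rec, meta)


@dataclass(frozen=True)
class ExclusionCriteria:
    """Sequential participant-exclusion rules.

    Applied in the fixed order: attention-check failure, overlong completion
    (> ``max_minutes``), incomplete responding (fewer than
    ``expected_statements`` ratings; inferred from the table when None), and
    overly fast completion (< ``min_minutes``).
    """

    max_minutes: float = 30.0
    min_minutes: float = 5.0
    expected_statements: int | None = None


@dataclass
class ExclusionLog:
    """Audit trail of a sequential exclusion run."""

    initial_n: int
    steps: list[tuple[str, int]]
    retained_n: int

    def __post_init__(self) -> None:
        removed = sum(n for _, n in self.steps)
        if any(n < 0 for _, n in self.steps):
            raise ValidationError("negative removal count in exclusion log")
        if self.initial_n - removed != self.retained_n:
            raise ValidationError(
                f"exclusion log arithmetic broken: {self.initial_n} - {removed} "
                f"!= {self.retained_n}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [{"criterion": name, "removed_n": n} for name, n in self.steps]
        df = pd.DataFrame(rows, columns=["criterion", "removed_n"])
        df.attrs["initial_n"] = self.initial_n
        df.attrs["retained_n"] = self.retained_n
        return df


# ---------------------------------------------------------------------------
# rating table I/O


def _detect_sep(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_ratings(path: str | Path, sep: str | None = None) -> RatingTable:
    """Read a delimited rating file into a :class:`RatingTable`.

    The file needs a header naming at least ``participant_id``,
    ``vocabulary_id``, ``dimension``, ``phrase`` and ``rating``; optional
    ``duration_minutes`` / ``attention_pass`` columns populate the metadata
    (files without them are accepted, with attention assumed passed and
    duration unknown).  Unparseable ratings are reported, never silently
    dropped.
    """
    path = Path(path)
    if sep is None:
        sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"participant_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s): {missing}")

    rating = pd.to_numeric(df["rating"], errors="coerce")
    bad = df.index[rating.isna() & df["rating"].notna()]
    if len(bad):
        raise ValidationError(
            f"{path.name}: unparseable rating values in data rows "
            f"{[int(i) + 2 for i in bad[:20]]} (1-based incl. header): "
            f"{list(df.loc[bad[:20], 'rating'])}"
        )
    out_of_range = df.index[(rating < 0) | (rating > 100)]
    if len(out_of_range):
        raise ValidationError(
            f"{path.name}: rating outside [0, 100] in data rows "
            f"{[int(i) + 2 for i in out_of_range[:20]]}: "
            f"{list(rating[out_of_range[:20]])}"
        )
    df = df.assign(rating=rating)

    meta_cols = {}
    if "duration_minutes" in df.columns:
        meta_cols["duration_minutes"] = pd.to_numeric(df["duration_minutes"], errors="coerce")
    if "attention_pass" in df.columns:
        meta_cols["attention_pass"] = df["attention_pass"].map(
            {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
        )
    for extra in ("education_level", "subject_area"):
        if extra in df.columns:
            meta_cols[extra] = df[extra]
    meta = (
        df[["participant_id"]].assign(**meta_cols)
        .groupby("participant_id", sort=False).first()
    )
    if "duration_minutes" not in meta.columns:
        meta["duration_minutes"] = np.nan
    if "attention_pass" not in meta.columns:
        meta["attention_pass"] = True
    meta["attention_pass"] = meta["attention_pass"].fillna(True).astype(bool)
    if (meta["duration_minutes"].dropna() < 0).any():
        raise ValidationError(f"{path.name}: negative duration_minutes")

    rec_cols = [c for c in (*REQUIRED_COLUMNS, "presentation_order") if c in df.columns]
    return RatingTable(df[rec_cols].copy(), meta)


def write_ratings(table: RatingTable, path: str | Path, sep: str = ",") -> None:
    """Write a rating table as delimited text (inverse of :func:`read_ratings`)."""
    df = table.records.merge(
        table.meta.reset_index().rename(columns={"index": "participant_id"}),
        on="participant_id",
        how="left",
    )
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# vocabulary I/O


def read_vocabularies(path: str | Path) -> list[Vocabulary]:
    """Read vocabulary definitions from a JSON document.

    Accepts either one object or a list of objects shaped
    ``{"vocabulary_id": ..., "dimensions": [{"dimension_label": ...,
    "phrases": [...]}, ...]}``; phrases are listed most positive first and
    receive intended ranks 1..n in that order.
    """
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if isinstance(doc, Mapping):
        doc = [doc]
    out: list[Vocabulary] = []
    for entry in doc:
        try:
            vid = entry["vocabulary_id"]
            dims = entry["dimensions"]
        except KeyError as exc:
            raise FormatError(f"vocabulary entry missing key {exc}") from None
        for dim in dims:
            out.append(
                Vocabulary(
                    vocabulary_id=vid,
                    dimension_label=dim["dimension_label"],
                    phrases=tuple(dim["phrases"]),
                )
            )
    return out


def write_vocabularies(vocabularies: Sequence[Vocabulary], path: str | Path) -> None:
    """Write vocabularies as the JSON layout read by :func:`read_vocabularies`."""
    by_id: dict[str, list[Vocabulary]] = {}
    for v in vocabularies:
        by_id.setdefault(v.vocabulary_id, []).append(v)
    doc = [
        {
            "vocabulary_id": vid,
            "dimensions": [
                {"dimension_label": v.dimension_label, "phrases": list(v.phrases)}
                for v in vs
            ],
        }
        for vid, vs in by_id.items()
    ]
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# exclusion screen


def apply_exclusions(
    table: RatingTable, criteria: ExclusionCriteria = ExclusionCriteria()
) -> tuple[RatingTable, ExclusionLog]:
    """Apply the sequential exclusion screen and return the retained table + log.

    Criteria run in a fixed order (attention failure, overtime, incomplete,
    too fast); a participant removed by an earlier criterion is not counted
    again later, so the log attributes each exclusion to exactly one cause.
    Participants with unknown duration are never excluded on timing grounds.
    """
    meta = table.meta
    all_ids = table.participants
    counts = table.records.groupby("participant_id", sort=False).size()
    expected = criteria.expected_statements
    if expected is None:
        expected = (
            table.records[["vocabulary_id", "dimension", "phrase"]]
            .drop_duplicates()
            .shape[0]
        )

    def fails(pid: str, criterion: str) -> bool:
        dur = meta.at[pid, "duration_minutes"] if pid in meta.index else np.nan
        if criterion == "attention_fail":
            return pid in meta.index and not bool(meta.at[pid, "attention_pass"])
        if criterion == "overtime":
            return bool(pd.notna(dur) and dur > criteria.max_minutes)
        if criterion == "incomplete":
            return int(counts.get(pid, 0)) < expected
        if criterion == "too_fast":
            return bool(pd.notna(dur) and dur < criteria.min_minutes)
        raise ValueError(criterion)

    remaining = list(all_ids)
    steps: list[tuple[str, int]] = []
    for criterion in ("attention_fail", "overtime", "incomplete", "too_fast"):
        dropped = [pid for pid in remaining if fails(pid, criterion)]
        steps.append((criterion, len(dropped)))
        remaining = [pid for pid in remaining if pid not in set(dropped)]

    log = ExclusionLog(initial_n=len(all_ids), steps=steps, retained_n=len(remaining))
    return table.select_participants(remaining), log
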