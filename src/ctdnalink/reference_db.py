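"""The reference of known mutations (COSMIC-style export).

The reference is a CSV with columns ``gene, aa_change, classification,
fathmm_score`` — one row per known mutation, classified pathogenic or
neutral with a FATHMM pathogenicity-severity score in [0, 1].  It is
loaded into an in-memory index keyed by ``(gene, aa_change)`` for exact
O(1) lookup; an optional SQLite export mirrors the same single-table
schema.  Refreshing the reference is a manual re-load of a newer CSV —
no network code lives here.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Classification", "ReferenceEntry", "ReferenceIndex", "load_reference"]


class Classification(str, Enum):
    PATHOGENIC = "PATHOGENIC"
    NEUTRAL = "NEUTRAL"


@dataclass(frozen=True)
class ReferenceEntry:
    """One known mutation: gene, protein change, class and FATHMM score."""

    gene: str
    aa_change: str
    classification: Classification
    fathmm_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fathmm_score <= 1.0:
            raise ValueError(f"fathmm_score {self.fathmm_score} outside [0, 1]")


def _key(gene: str, aa_change: str) -> tuple[str, str]:
    return gene.strip().upper(), aa_change.strip()


class ReferenceIndex:
    """Deduplicated, exact-key index over reference entries."""

    def __init__(self, entries: dict[tuple[str, str], ReferenceEntry]):
        self._entries = entries

    def lookup(self, gene: str, aa_change: str) -> ReferenceEntry | None:
        """Exact-key lookup; a miss returns None, never raises."""
        return self._entries.get(_key(gene, aa_change))

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    @property
    def entries(self) -> list[ReferenceEntry]:
        return [self._entries[k] for k in sorted(self._entries)]

    def to_sqlite(self, path: str | Path, table: str = "reference") -> None:
        """Export the index as a single-table SQLite database."""
        con = sqlite3.connect(path)
        try:
            con.execute(f"DROP TABLE IF EXISTS {table}")
            con.execute(
                f"CREATE TABLE {table} (gene TEXT, aa_change TEXT, "
                "classification TEXT, fathmm_score REAL, "
                "PRIMARY KEY (gene, aa_change))"
            )
            con.executemany(
                f"INSERT INTO {table} VALUES (?, ?, ?, ?)",
                [
                    (e.gene, e.aa_change, e.classification.value, e.fathmm_score)
                    for e in self.entries
                ],
            )
            con.commit()
        finally:
            con.close()


def _better(a: ReferenceEntry, b: ReferenceEntry) -> ReferenceEntry:
    # Conservative dedup for clinical review: keep the higher FATHMM
    # score; on a tie prefer the PATHOGENIC classification.
    if b.fathmm_score > a.fathmm_score:
        return b
    if b.fathmm_score == a.fathmm_score and (
        b.classification is Classification.PATHOGENIC
        and a.classification is not Classification.PATHOGENIC
    ):
        return b
    return a


def load_reference(path: str | Path) -> ReferenceIndex:
    """Load and deduplicate a reference CSV into a :class:`ReferenceIndex`.

    Rows with a FATHMM score outside [0, 1] or an unknown classification
    are rejected with a warning; duplicate ``(gene, aa_change)`` keys are
    resolved toward the highest score (PATHOGENIC winning ties).  A CSV
    with a header but no rows yields a valid empty reference.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"gene", "aa_change", "classification", "fathmm_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reference {path} missing columns: {sorted(missing)}")

    entries: dict[tuple[str, str], ReferenceEntry] = {}
    n_dropped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        try:
            score = float(row["fathmm_score"])
            entry = ReferenceEntry(
                gene=row["gene"].strip().upper(),
                aa_change=row["aa_change"].strip(),
                classification=Classification(row["classification"].strip().upper()),
                fathmm_score=score,
            )
        except ValueError:
            logger.warning("%s line %d: invalid reference row %r; dropped", path, i, row)
            n_dropped += 1
            continue
        key = _key(entry.gene, entry.aa_change)
        entries[key] = _better(entries[key], entry) if key in entries else entry
    logger.info(
        "reference %s: %d entries indexed (%d raw rows, %d rejected)",
        path, len(entries), len(df), n_dropped,
    )
    return ReferenceIndex(entries)
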