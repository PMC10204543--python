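"""Reading and normalization of per-sample variant report tables.

A liquid-biopsy sequencing report arrives as a TSV/CSV table with one row
per observed gene + amino-acid change and its variant allele frequency
(VAF).  This module turns such tables into canonical
:class:`VariantRecord` collections: protein changes are rewritten from
three-letter HGVS (``p.Gly12Asp``) to the one-letter form (``p.G12D``)
used as the join key against the mutation reference, allele frequencies
are put on the percent scale, and in-report duplicate calls are
collapsed.  A :class:`CohortStore` guards against loading the same sample
twice.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "SampleReport",
    "CohortStore",
    "normalize_aa_change",
    "parse_report",
    "write_report",
    "is_duplicate_sample",
    "load_reports_dir",
    "DEFAULT_COLUMNS",
]

#: Canonical -> default input column names.
DEFAULT_COLUMNS: dict[str, str] = {
    "gene": "GENE",
    "aa_change": "AA",
    "allele_frequency": "AF",
    "nt_change": "NT",
    "depth": "DEPTH",
}

# Three-letter residue codes (HGVS capitalization), including the stop
# codon and the rare selenocysteine/pyrrolysine residues.
AA_3TO1: dict[str, str] = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Sec": "U", "Pyl": "O", "Ter": "*",
}

_THREE_LETTER_RE = re.compile("|".join(AA_3TO1))

# One-letter HGVS p. grammar accepted after conversion.  A "location" is a
# residue letter (or *) followed by a position; events are substitution
# (incl. synonymous "=" and nonsense "*"), frameshift, deletion,
# duplication, insertion, and delins.
_RES = r"[A-Z\*]"
_LOC = rf"{_RES}\d+"
_EVENT = (
    rf"(?:{_LOC}(?:{_RES}|=|\*)"            # substitution / synonymous
    rf"|{_LOC}{_RES}?fs(?:\*\d*)?"           # frameshift
    rf"|{_LOC}(?:_{_LOC})?delins{_RES}+"     # deletion-insertion
    rf"|{_LOC}(?:_{_LOC})?del{_RES}*"        # deletion
    rf"|{_LOC}(?:_{_LOC})?dup"               # duplication
    rf"|{_LOC}_{_LOC}ins{_RES}+"             # insertion
    rf")"
)
_NORMALIZED_RE = re.compile(rf"^(?:p\.)?{_EVENT}$")


def normalize_aa_change(aa_raw: str) -> str:
    """Normalize a protein-change string to one-letter HGVS p. form.

    Three-letter residue codes are mapped to one-letter (``Gly`` -> ``G``,
    ``Ter`` -> ``*``); the ``p.`` prefix, frameshift suffixes and
    del/ins/dup tokens are preserved; strings already in one-letter form
    pass through unchanged.  Strings that do not resolve to a recognizable
    protein change return ``""`` (the row stays in the report but cannot
    join the reference).
    """
    if aa_raw is None:
        return ""
    s = str(aa_raw).strip()
    if not s or s.lower() in {"nan", "none", "-", "."}:
        return ""
    converted = _THREE_LETTER_RE.sub(lambda m: AA_3TO1[m.group(0)], s)
    if _NORMALIZED_RE.match(converted):
        return converted
    logger.warning("unrecognizable amino-acid change %r; row will be non-joinable", aa_raw)
    return ""


@dataclass(frozen=True)
class VariantRecord:
    """One observed gene / amino-acid change / VAF row of a report."""

    sample_id: str
    gene: str
    aa_change_raw: str
    aa_change: str
    allele_frequency: float
    nt_change: str | None = None
    depth: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_frequency <= 100.0:
            raise ValueError(
                f"allele_frequency {self.allele_frequency} outside [0, 100] "
                f"for {self.gene} {self.aa_change_raw}"
            )
        if not self.gene:
            raise ValueError("gene symbol must be nonempty")

    @property
    def joinable(self) -> bool:
        """Whether this row can be matched against the reference."""
        return bool(self.aa_change)


@dataclass
class SampleReport:
    """All variant rows of one liquid-biopsy report."""

    sample_id: str
    records: list[VariantRecord]
    draw_date: str | None = None
    source_path: str = ""
    parse_errors: list[str] = field(default_factory=list)


def _resolve_columns(
    df: pd.DataFrame, column_map: Mapping[str, str] | None
) -> dict[str, str | None]:
    names = dict(DEFAULT_COLUMNS)
    if column_map:
        names.update(column_map)
    resolved: dict[str, str | None] = {}
    for canonical, actual in names.items():
        resolved[canonical] = actual if actual in df.columns else None
    for required in ("gene", "aa_change", "allele_frequency"):
        if resolved[required] is None:
            raise ValueError(
                f"required column {names[required]!r} (for {required}) "
                f"not found; available: {list(df.columns)}"
            )
    return resolved


def _dedup_records(records: list[VariantRecord]) -> list[VariantRecord]:
    # Amplicon reports may repeat a call once per amplicon: keep the row
    # with the highest depth, else the first occurrence.
    best: dict[tuple[str, str], VariantRecord] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        key = (rec.gene, rec.aa_change if rec.aa_change else rec.aa_change_raw)
        if key not in best:
            best[key] = rec
            order.append(key)
        else:
            incumbent = best[key]
            if (rec.depth or 0) > (incumbent.depth or 0):
                best[key] = rec
    return [best[k] for k in order]


def parse_report(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    af_scale: str = "percent",
    sample_id: str | None = None,
    draw_date: str | None = None,
) -> SampleReport:
    """Parse one variant report table into a :class:`SampleReport`.

    Parameters
    ----------
    path
        TSV (default) or CSV file with a header row.
    column_map
        Overrides for canonical column names (keys ``gene``,
        ``aa_change``, ``allele_frequency``, ``nt_change``, ``depth``).
    af_scale
        ``"percent"`` (values already 0-100) or ``"fraction"``
        (values 0-1, multiplied by 100 on load).
    sample_id
        Defaults to the file stem.

    Raises
    ------
    ValueError
        On a missing required column, an empty report, or an unknown
        ``af_scale``.
    """
    if af_scale not in ("percent", "fraction"):
        raise ValueError(f"af_scale must be 'percent' or 'fraction', got {af_scale!r}")
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"empty report: {path}")
    cols = _resolve_columns(df, column_map)
    sid = sample_id if sample_id is not None else path.stem

    records: list[VariantRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        gene = str(row[cols["gene"]]).strip().upper()
        aa_raw = str(row[cols["aa_change"]]).strip()
        af_text = str(row[cols["allele_frequency"]]).strip().rstrip("%")
        try:
            af = float(af_text)
        except ValueError:
            errors.append(f"line {i}: non-numeric allele frequency {af_text!r}; row dropped")
            continue
        if af_scale == "fraction":
            af *= 100.0
        depth: int | None = None
        if cols["depth"] is not None and str(row[cols["depth"]]).strip():
            try:
                depth = int(float(row[cols["depth"]]))
            except ValueError:
                depth = None
        nt = None
        if cols["nt_change"] is not None and str(row[cols["nt_change"]]).strip():
            nt = str(row[cols["nt_change"]]).strip()
        try:
            records.append(
                VariantRecord(
                    sample_id=sid,
                    gene=gene,
                    aa_change_raw=aa_raw,
                    aa_change=normalize_aa_change(aa_raw),
                    allele_frequency=af,
                    nt_change=nt,
                    depth=depth,
                )
            )
        except ValueError as exc:
            errors.append(f"line {i}: {exc}; row dropped")
    for msg in errors:
        logger.warning("%s: %s", path, msg)
    records = _dedup_records(records)
    if not records:
        raise ValueError(f"empty report (no parseable rows): {path}")
    return SampleReport(
        sample_id=sid,
        records=records,
        draw_date=draw_date,
        source_path=str(path),
        parse_errors=errors,
    )


def write_report(report: SampleReport, path: str | Path) -> None:
    """Write a report back to the canonical TSV dialect (round-trippable)."""
    path = Path(path)
    rows = [
        {
            "GENE": r.gene,
            "AA": r.aa_change_raw,
            "AF": repr(r.allele_frequency),
            "NT": r.nt_change if r.nt_change is not None else "",
            "DEPTH": r.depth if r.depth is not None else "",
        }
        for r in report.records
    ]
    pd.DataFrame(rows, columns=["GENE", "AA", "AF", "NT", "DEPTH"]).to_csv(
        path, sep="\t", index=False
    )


class CohortStore:
    """In-memory cohort of loaded reports, keyed by sample id.

    Loading the same sample id twice is skipped with a warning, never
    silently merged.
    """

    def __init__(self) -> None:
        self._reports: dict[str, SampleReport] = {}

    def add(self, report: SampleReport) -> bool:
        """Add a report; return False (and skip) if already present."""
        if report.sample_id in self._reports:
            logger.warning("sample %s already loaded; skipping duplicate", report.sample_id)
            return False
        self._reports[report.sample_id] = report
        return True

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._reports

    def __len__(self) -> int:
        return len(self._reports)

    def __iter__(self) -> Iterable[SampleReport]:
        return iter(self._reports.values())

    @property
    def reports(self) -> list[SampleReport]:
        """Reports in deterministic (sample id) order."""
        return [self._reports[k] for k in sorted(self._reports)]


def is_duplicate_sample(sample_id: str, store: CohortStore) -> bool:
    """True iff *sample_id* is already loaded in *store*."""
    return sample_id in store


def load_reports_dir(
    reports_dir: str | Path,
    column_map: Mapping[str, str] | None = None,
    af_scale: str = "percent",
    metadata_csv: str | Path | None = None,
) -> CohortStore:
    """Load every ``*.tsv``/``*.csv`` report under a directory.

    An optional metadata sidecar CSV (columns ``sample_id, draw_date``)
    supplies draw dates.  Duplicate sample ids are skipped with a warning.
    """
    reports_dir = Path(reports_dir)
    dates: dict[str, str] = {}
    meta = metadata_csv
    if meta is None:
        candidate = reports_dir / "metadata.csv"
        meta = candidate if candidate.exists() else None
    if meta is not None:
        mdf = pd.read_csv(meta, dtype=str)
        dates = dict(zip(mdf["sample_id"], mdf["draw_date"]))
    store = CohortStore()
    paths = sorted(
        p
        for p in reports_dir.iterdir()
        if p.suffix.lower() in (".tsv", ".csv") and p.name != "metadata.csv"
    )
    for p in paths:
        report = parse_report(p, column_map=column_map, af_scale=af_scale)
        report.draw_date = dates.get(report.sample_id)
        store.add(report)
    logger.info("loaded %d reports from %s", len(store), reports_dir)
    return store
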