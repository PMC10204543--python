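"""Pathogenicity annotation, variant flags, and report-level QC.

Each report row is joined against the mutation reference on
``(gene, aa_change)`` and assigned one of three tiers:

* ``PATHOGENIC`` — matched, classified pathogenic, FATHMM score at or
  above the pathogenic cutoff (default 0.8; 1 is maximal severity);
* ``LOWER`` — matched but with a very low score (< 0.5 by default);
* ``NEUTRAL`` — everything else, including reference misses (absence of
  evidence is not treated as pathogenicity).

Two variant-level flags support downstream filtering: a germline flag
for allele frequencies around 50% (heterozygous) or near 100%
(homozygous) — inherited variants present in all cells, hence not tumor
signal — and a low-AF flag for frequencies below 1%.

Report-level QC mirrors the sequencing sanity checks: a report with
fewer than 32 gene+mutation rows, or with a pathogenic-per-gene ratio
above 0.25, is flagged for review.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .reference_db import Classification, ReferenceIndex
from .report_io import SampleReport, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Tier",
    "AnnotationConfig",
    "AnnotatedVariant",
    "QCResult",
    "AnnotatedReport",
    "assign_tier",
    "flag_germline",
    "flag_low_af",
    "qc_report",
    "annotate_report",
    "annotated_to_frame",
]


class Tier(str, Enum):
    PATHOGENIC = "PATHOGENIC"
    NEUTRAL = "NEUTRAL"
    LOWER = "LOWER"


@dataclass(frozen=True)
class AnnotationConfig:
    """Cutoffs and bands for tiering, flags, and QC."""

    pathogenic_cutoff: float = 0.8
    lower_cutoff: float = 0.5
    germline_het_band: tuple[float, float] = (40.0, 60.0)
    germline_hom_min: float = 90.0
    low_af_threshold: float = 1.0
    qc_min_rows: int = 32
    qc_max_ratio: float = 0.25
    # "pathogenic_per_gene": pathogenic-tier rows / distinct genes in the
    # report.  "rows_per_panel_gene": total rows / panel size.
    qc_ratio_mode: str = "pathogenic_per_gene"
    qc_panel_size: int = 56

    def __post_init__(self) -> None:
        if not self.lower_cutoff < self.pathogenic_cutoff:
            raise ValueError(
                f"lower_cutoff ({self.lower_cutoff}) must be below "
                f"pathogenic_cutoff ({self.pathogenic_cutoff})"
            )
        if self.low_af_threshold <= 0:
            raise ValueError("low_af_threshold must be positive")
        if self.qc_ratio_mode not in ("pathogenic_per_gene", "rows_per_panel_gene"):
            raise ValueError(f"unknown qc_ratio_mode {self.qc_ratio_mode!r}")


@dataclass(frozen=True)
class AnnotatedVariant:
    """A report row after the reference join, tiering, and flags."""

    record: VariantRecord
    matched: bool
    classification: Classification | None
    fathmm_score: float | None
    tier: Tier
    germline_flag: bool
    low_af_flag: bool


@dataclass(frozen=True)
class QCResult:
    sample_id: str
    n_rows: int
    n_distinct_genes: int
    ratio: float
    low_row_count_flag: bool
    high_ratio_flag: bool


@dataclass
class AnnotatedReport:
    sample_id: str
    variants: list[AnnotatedVariant]
    qc: QCResult
    draw_date: str | None = None


def assign_tier(
    matched: bool,
    classification: Classification | None,
    fathmm_score: float | None,
    config: AnnotationConfig = AnnotationConfig(),
) -> Tier:
    """Tier a variant from its reference-join outcome.

    Matched + pathogenic + score >= cutoff (boundary inclusive: a score
    of exactly 0.8 counts) -> PATHOGENIC; matched with score below the
    lower cutoff -> LOWER; everything else, unmatched included -> NEUTRAL.
    """
    if matched and fathmm_score is not None:
        if (
            classification is Classification.PATHOGENIC
            and fathmm_score >= config.pathogenic_cutoff
        ):
            return Tier.PATHOGENIC
        if fathmm_score < config.lower_cutoff:
            return Tier.LOWER
    return Tier.NEUTRAL


def flag_germline(
    allele_frequency: float, config: AnnotationConfig = AnnotationConfig()
) -> bool:
    """True iff the AF sits in the heterozygous band or at/above the
    homozygous bound (defaults [40, 60] and >= 90 percent)."""
    lo, hi = config.germline_het_band
    return lo <= allele_frequency <= hi or allele_frequency >= config.germline_hom_min


def flag_low_af(
    allele_frequency: float, threshold: float = 1.0
) -> bool:
    """True iff AF is strictly below *threshold* percent."""
    return allele_frequency < threshold


def qc_report(
    annotated: list[AnnotatedVariant],
    sample_id: str,
    config: AnnotationConfig = AnnotationConfig(),
) -> QCResult:
    """Compute report-level QC counts and flags.

    ``n_rows`` is the number of gene+mutation rows; the default ratio is
    pathogenic-tier rows per distinct gene in the report.  The two flags
    (fewer than ``qc_min_rows`` rows; ratio above ``qc_max_ratio``) are
    independent.
    """
    n_rows = len(annotated)
    genes = {v.record.gene for v in annotated}
    n_genes = len(genes)
    n_pathogenic = sum(1 for v in annotated if v.tier is Tier.PATHOGENIC)
    if config.qc_ratio_mode == "rows_per_panel_gene":
        ratio = n_rows / config.qc_panel_size if config.qc_panel_size else 0.0
    else:
        if n_genes == 0:
            logger.warning("sample %s has no genes; QC ratio defined as 0", sample_id)
            ratio = 0.0
        else:
            ratio = n_pathogenic / n_genes
    return QCResult(
        sample_id=sample_id,
        n_rows=n_rows,
        n_distinct_genes=n_genes,
        ratio=ratio,
        low_row_count_flag=n_rows < config.qc_min_rows,
        high_ratio_flag=ratio > config.qc_max_ratio,
    )


def annotate_report(
    report: SampleReport,
    reference: ReferenceIndex,
    config: AnnotationConfig = AnnotationConfig(),
) -> AnnotatedReport:
    """Join a report against the reference and attach tiers, flags and QC.

    Annotation is a pure function of (report, reference, config); the
    original record order is preserved.  Rows with an empty normalized
    amino-acid change never match.
    """
    variants: list[AnnotatedVariant] = []
    for rec in report.records:
        entry = reference.lookup(rec.gene, rec.aa_change) if rec.joinable else None
        matched = entry is not None
        classification = entry.classification if entry else None
        score = entry.fathmm_score if entry else None
        variants.append(
            AnnotatedVariant(
                record=rec,
                matched=matched,
                classification=classification,
                fathmm_score=score,
                tier=assign_tier(matched, classification, score, config),
                germline_flag=flag_germline(rec.allele_frequency, config),
                low_af_flag=flag_low_af(rec.allele_frequency, config.low_af_threshold),
            )
        )
    qc = qc_report(variants, report.sample_id, config)
    return AnnotatedReport(
        sample_id=report.sample_id,
        variants=variants,
        qc=qc,
        draw_date=report.draw_date,
    )


def annotated_to_frame(reports: list[AnnotatedReport]) -> pd.DataFrame:
    """Flatten annotated reports into one tidy DataFrame (CSV-ready)."""
    rows = []
    for rep in reports:
        for v in rep.variants:
            rows.append(
                {
                    "sample_id": rep.sample_id,
                    "gene": v.record.gene,
                    "aa_change_raw": v.record.aa_change_raw,
                    "aa_change": v.record.aa_change,
                    "allele_frequency": v.record.allele_frequency,
                    "matched": v.matched,
                    "classification": v.classification.value if v.classification else "",
                    "fathmm_score": v.fathmm_score if v.fathmm_score is not None else "",
                    "tier": v.tier.value,
                    "germline_flag": v.germline_flag,
                    "low_af_flag": v.low_af_flag,
                }
            )
    columns = [
        "sample_id", "gene", "aa_change_raw", "aa_change", "allele_frequency",
        "matched", "classification", "fathmm_score", "tier",
        "germline_flag", "low_af_flag",
    ]
    return pd.DataFrame(rows, columns=columns)
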