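"""Per-patient longitudinal pathogenic-VAF tables.

Once anonymous reports are grouped into patients, each patient's blood
draws are ordered (by draw date when available for every member, else
lexicographically by sample id) and every pathogenic mutation the
patient has ever shown is tracked across all draws.  Draws in which a
known pathogenic mutation is not detected get an explicit AF = 0 row —
remission and recurrence are invisible in long format otherwise.

The default (dashboard) view keeps pathogenic-tier, non-germline rows
and drops series never seen at or above the low-AF display threshold;
the full unfiltered table is always emitted alongside it.  Outputs are
CSV (canonical) with an optional single-file SQLite export, and are
byte-identical across reruns on identical input and configuration.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .annotate import AnnotatedReport, Tier, annotated_to_frame
from .patient_match import PatientGroup, SimilarityPair
from .reference_db import ReferenceIndex

logger = logging.getLogger(__name__)

__all__ = ["TimelineRow", "order_draws", "build_timeline", "timeline_to_frame", "export"]


@dataclass(frozen=True)
class TimelineRow:
    patient_id: str
    sample_id: str
    draw_index: int
    draw_date: str | None
    gene: str
    aa_change: str
    allele_frequency: float
    tier: str
    fathmm_score: float | None
    germline_flag: bool
    low_af_flag: bool


def order_draws(
    group: PatientGroup, reports_by_id: dict[str, AnnotatedReport]
) -> list[tuple[int, AnnotatedReport]]:
    """Order a patient's samples into draws 1..n.

    Uses draw date when every member has one; otherwise falls back to
    lexicographic sample-id order (with a warning if dates were partial).
    Date ties break by sample id.
    """
    members = [reports_by_id[sid] for sid in sorted(group.member_sample_ids)]
    dated = [r for r in members if r.draw_date]
    if dated and len(dated) < len(members):
        logger.warning(
            "patient %s: only %d/%d samples have draw dates; ordering by sample id",
            group.patient_id, len(dated), len(members),
        )
    if len(dated) == len(members) and members:
        members.sort(key=lambda r: (r.draw_date, r.sample_id))
    return [(i, r) for i, r in enumerate(members, start=1)]


def build_timeline(
    groups: list[PatientGroup],
    annotated_reports: list[AnnotatedReport],
    low_af_threshold: float = 1.0,
    apply_low_af_filter: bool = True,
) -> list[TimelineRow]:
    """Assemble the long-format pathogenic timeline across all patients.

    For each patient, every (gene, aa_change) that is pathogenic-tier
    and non-germline in at least one draw becomes a series with one row
    per draw; draws where the mutation is absent get AF = 0.  With the
    low-AF filter on, series whose maximum observed AF stays below
    *low_af_threshold* percent are dropped from this view.
    """
    reports_by_id = {r.sample_id: r for r in annotated_reports}
    rows: list[TimelineRow] = []
    for group in sorted(groups, key=lambda g: g.patient_id):
        ordered = order_draws(group, reports_by_id)
        # Collect the patient's pathogenic series and their per-draw hits.
        series: dict[tuple[str, str], dict[int, object]] = {}
        for draw_index, report in ordered:
            for v in report.variants:
                if v.tier is not Tier.PATHOGENIC or v.germline_flag:
                    continue
                series.setdefault((v.record.gene, v.record.aa_change), {})[draw_index] = v
        for (gene, aa), hits in sorted(series.items()):
            max_af = max(v.record.allele_frequency for v in hits.values())
            if apply_low_af_filter and max_af < low_af_threshold:
                continue
            for draw_index, report in ordered:
                v = hits.get(draw_index)
                rows.append(
                    TimelineRow(
                        patient_id=group.patient_id,
                        sample_id=report.sample_id,
                        draw_index=draw_index,
                        draw_date=report.draw_date,
                        gene=gene,
                        aa_change=aa,
                        allele_frequency=v.record.allele_frequency if v else 0.0,
                        tier=Tier.PATHOGENIC.value,
                        fathmm_score=v.fathmm_score if v else None,
                        germline_flag=False,
                        low_af_flag=v.low_af_flag if v else False,
                    )
                )
    return rows


def timeline_to_frame(rows: list[TimelineRow]) -> pd.DataFrame:
    columns = [
        "patient_id", "sample_id", "draw_index", "draw_date", "gene", "aa_change",
        "allele_frequency", "tier", "fathmm_score", "germline_flag", "low_af_flag",
    ]
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "sample_id": r.sample_id,
                "draw_index": r.draw_index,
                "draw_date": r.draw_date or "",
                "gene": r.gene,
                "aa_change": r.aa_change,
                "allele_frequency": r.allele_frequency,
                "tier": r.tier,
                "fathmm_score": r.fathmm_score if r.fathmm_score is not None else "",
                "germline_flag": r.germline_flag,
                "low_af_flag": r.low_af_flag,
            }
            for r in rows
        ],
        columns=columns,
    )


def _pairs_frame(pairs: list[SimilarityPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_a": p.sample_a,
                "sample_b": p.sample_b,
                "score": f"{p.score:.4f}",
                "band": p.band.value,
            }
            for p in sorted(pairs, key=lambda p: (p.sample_a, p.sample_b))
        ],
        columns=["sample_a", "sample_b", "score", "band"],
    )


def export(
    out_dir: str | Path,
    annotated_reports: list[AnnotatedReport],
    groups: list[PatientGroup],
    pairs: list[SimilarityPair],
    ambiguous: list[SimilarityPair],
    timeline: list[TimelineRow],
    timeline_full: list[TimelineRow] | None = None,
    reference: ReferenceIndex | None = None,
    sqlite: bool = False,
) -> dict[str, Path]:
    """Write all pipeline outputs as CSV (plus optional SQLite).

    Files: ``annotated.csv``, ``qc.csv``, ``pairs.csv``,
    ``ambiguous.csv``, ``groups.csv``, ``timeline.csv``,
    ``timeline_full.csv``, and optionally ``pipeline.sqlite`` with
    tables {reference, annotated, pairs, groups, timeline}.  Outputs are
    deterministic: rerunning on identical input yields identical bytes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reports = sorted(annotated_reports, key=lambda r: r.sample_id)

    annotated_df = annotated_to_frame(reports)
    qc_df = pd.DataFrame(
        [
            {
                "sample_id": r.qc.sample_id,
                "n_rows": r.qc.n_rows,
                "n_distinct_genes": r.qc.n_distinct_genes,
                "ratio": f"{r.qc.ratio:.4f}",
                "low_row_count_flag": r.qc.low_row_count_flag,
                "high_ratio_flag": r.qc.high_ratio_flag,
            }
            for r in reports
        ],
        columns=[
            "sample_id", "n_rows", "n_distinct_genes", "ratio",
            "low_row_count_flag", "high_ratio_flag",
        ],
    )
    groups_df = pd.DataFrame(
        [
            {"patient_id": g.patient_id, "sample_id": sid}
            for g in sorted(groups, key=lambda g: g.patient_id)
            for sid in sorted(g.member_sample_ids)
        ],
        columns=["patient_id", "sample_id"],
    )
    pairs_df = _pairs_frame(pairs)
    ambiguous_df = _pairs_frame(ambiguous)
    timeline_df = timeline_to_frame(timeline)
    timeline_full_df = timeline_to_frame(timeline_full if timeline_full is not None else [])

    written: dict[str, Path] = {}
    for name, df in [
        ("annotated", annotated_df),
        ("qc", qc_df),
        ("pairs", pairs_df),
        ("ambiguous", ambiguous_df),
        ("groups", groups_df),
        ("timeline", timeline_df),
        ("timeline_full", timeline_full_df),
    ]:
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path

    if sqlite:
        db_path = out_dir / "pipeline.sqlite"
        if db_path.exists():
            db_path.unlink()
        con = sqlite3.connect(db_path)
        try:
            if reference is not None:
                pd.DataFrame(
                    [
                        {
                            "gene": e.gene,
                            "aa_change": e.aa_change,
                            "classification": e.classification.value,
                            "fathmm_score": e.fathmm_score,
                        }
                        for e in reference.entries
                    ],
                    columns=["gene", "aa_change", "classification", "fathmm_score"],
                ).to_sql("reference", con, index=False)
            else:
                pd.DataFrame(
                    columns=["gene", "aa_change", "classification", "fathmm_score"]
                ).to_sql("reference", con, index=False)
            annotated_df.to_sql("annotated", con, index=False)
            pairs_df.to_sql("pairs", con, index=False)
            groups_df.to_sql("groups", con, index=False)
            timeline_df.to_sql("timeline", con, index=False)
            con.commit()
        finally:
            con.close()
        written["sqlite"] = db_path
    logger.info("wrote %d output files to %s", len(written), out_dir)
    return written
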