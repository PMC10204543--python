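"""End-to-end orchestration: parse -> annotate -> match -> timeline -> export."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotate, longitudinal, patient_match, reference_db, report_io

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_all"]


@dataclass
class PipelineConfig:
    """All tunables of the pipeline in one place (YAML-loadable)."""

    annotation: annotate.AnnotationConfig = field(default_factory=annotate.AnnotationConfig)
    match: patient_match.MatchConfig = field(default_factory=patient_match.MatchConfig)
    af_scale: str = "percent"
    apply_low_af_filter: bool = True
    sqlite: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config file; top-level keys ``annotation``, ``match``,
        ``af_scale``, ``apply_low_af_filter``, ``sqlite``.  Keyword
        overrides (e.g. from CLI flags) win over the file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        ann = {**data.get("annotation", {}), **overrides.pop("annotation", {})}
        mat = {**data.get("match", {}), **overrides.pop("match", {})}
        if "germline_het_band" in ann:
            ann["germline_het_band"] = tuple(ann["germline_het_band"])
        kwargs = {
            k: data[k]
            for k in ("af_scale", "apply_low_af_filter", "sqlite")
            if k in data
        }
        kwargs.update(overrides)
        return cls(
            annotation=annotate.AnnotationConfig(**ann),
            match=patient_match.MatchConfig(**mat),
            **kwargs,
        )


@dataclass
class PipelineResult:
    annotated_reports: list[annotate.AnnotatedReport]
    groups: list[patient_match.PatientGroup]
    pairs: list[patient_match.SimilarityPair]
    ambiguous: list[patient_match.SimilarityPair]
    timeline: list[longitudinal.TimelineRow]
    timeline_full: list[longitudinal.TimelineRow]
    written: dict[str, Path]


def run_all(
    reports_dir: str | Path,
    reference_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the whole pipeline over a directory of report tables.

    Reads every TSV/CSV report (plus an optional ``metadata.csv`` draw
    date sidecar), annotates against the reference, groups samples into
    patients, builds the longitudinal pathogenic-VAF tables, and writes
    all outputs to *out_dir*.  Deterministic for fixed inputs + config.
    """
    config = config or PipelineConfig()
    store = report_io.load_reports_dir(reports_dir, af_scale=config.af_scale)
    reference = reference_db.load_reference(reference_path)
    annotated = [
        annotate.annotate_report(r, reference, config.annotation)
        for r in store.reports
    ]
    groups, pairs, ambiguous = patient_match.match_cohort(annotated, config.match)
    timeline = longitudinal.build_timeline(
        groups,
        annotated,
        low_af_threshold=config.annotation.low_af_threshold,
        apply_low_af_filter=config.apply_low_af_filter,
    )
    timeline_full = longitudinal.build_timeline(
        groups, annotated, apply_low_af_filter=False
    )
    written = longitudinal.export(
        out_dir,
        annotated,
        groups,
        pairs,
        ambiguous,
        timeline,
        timeline_full=timeline_full,
        reference=reference,
        sqlite=config.sqlite,
    )
    return PipelineResult(
        annotated_reports=annotated,
        groups=groups,
        pairs=pairs,
        ambiguous=ambiguous,
        timeline=timeline,
        timeline_full=timeline_full,
        written=written,
    )
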