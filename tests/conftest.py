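import textwrap
from pathlib import Path

import pytest

from ctdnalink.annotate import AnnotationConfig, annotate_report
from ctdnalink.reference_db import load_reference
from ctdnalink.report_io import parse_report


@pytest.fixture
def write_tsv(tmp_path):
    """Write a small TSV report file and return its path."""

    def _write(name: str, body: str, header: str = "GENE\tAA\tAF") -> Path:
        path = tmp_path / name
        text = header + "\n" + textwrap.dedent(body).strip()
        path.write_text(text.strip() + "\n")
        return path

    return _write


@pytest.fixture
def toy_reference(tmp_path):
    """A small mutation reference: one hotspot per tier band."""
    path = tmp_path / "reference.csv"
    path.write_text(
        "gene,aa_change,classification,fathmm_score\n"
        "KRAS,p.G12D,PATHOGENIC,0.98\n"
        "BRAF,p.V600E,PATHOGENIC,0.97\n"
        "EGFR,p.Q787Q,NEUTRAL,0.62\n"
        "TP53,p.P72R,NEUTRAL,0.55\n"
        "ATM,p.F858L,PATHOGENIC,0.12\n"
    )
    return load_reference(path)


@pytest.fixture
def make_annotated(write_tsv, toy_reference):
    """Build an AnnotatedReport from inline rows: (gene, aa_raw, af)."""

    def _make(sample_id, rows, config=AnnotationConfig(), draw_date=None):
        body = "\n".join(f"{g}\t{aa}\t{af}" for g, aa, af in rows)
        path = write_tsv(f"{sample_id}.tsv", body)
        report = parse_report(path, sample_id=sample_id, draw_date=draw_date)
        return annotate_report(report, toy_reference, config)

    return _make
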