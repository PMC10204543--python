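"""Simulate a small liquid-biopsy cohort with known ground truth.

Generates 5 patients x 2 blood draws over the 56-gene oncology panel.
Each report carries the patient's germline fingerprint (heterozygous
variants near 50% allele frequency, homozygous near 100%) plus a few
low-frequency background calls; sample ids are shuffled so they carry
no patient information, exactly like real anonymous reports.
"""

import tempfile
from pathlib import Path

from ctdnalink import SimConfig, generate_cohort
from ctdnalink.report_io import parse_report

out = Path(tempfile.mkdtemp(prefix="ctdnalink_"))
cfg = SimConfig(n_patients=5, draws_per_patient=2, seed=42)
reports_dir, reference_csv, truth = generate_cohort(cfg, out)

print(f"wrote {len(truth.sample_to_patient)} reports to {reports_dir}")
print(f"reference: {reference_csv}")
print()

sid = sorted(truth.sample_to_patient)[0]
report = parse_report(reports_dir / f"{sid}.tsv")
print(f"first rows of {sid} (true patient {truth.sample_to_patient[sid]}):")
for rec in report.records[:6]:
    print(f"  {rec.gene:8s} {rec.aa_change:12s} AF {rec.allele_frequency:6.2f}%")
print()
print("Rows near 50% or 100% AF are the germline identity signal; the")
print("low-AF rows are background calls. The truth.csv mapping stays")
print("outside the pipeline's input directory — it is only a test oracle.")
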