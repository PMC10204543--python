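"""Group anonymous reports into patients by germline similarity.

Simulates 8 patients x 2 draws, annotates every report, and runs the
matching stage: each report becomes a sparse vector of its
non-pathogenic allele frequencies, k-means (K=2) pre-clusters the
cohort, pairs are scored by cosine similarity within clusters, and
samples left unmatched are rescued across clusters.  Pairs scoring
>= 0.98 are same-patient matches; [0.95, 0.98) is an ambiguous band
reported for manual review.
"""

import tempfile
from pathlib import Path

from ctdnalink import (
    Band,
    SimConfig,
    annotate_report,
    generate_cohort,
    load_reference,
    load_reports_dir,
    match_cohort,
)

out = Path(tempfile.mkdtemp(prefix="ctdnalink_"))
reports_dir, reference_csv, truth = generate_cohort(
    SimConfig(n_patients=8, draws_per_patient=2, seed=7), out
)
reference = load_reference(reference_csv)
annotated = [annotate_report(r, reference) for r in load_reports_dir(reports_dir).reports]

groups, pairs, ambiguous = match_cohort(annotated)

match_pairs = [p for p in pairs if p.band is Band.MATCH]
print(f"{len(annotated)} anonymous reports -> {len(groups)} patients, "
      f"{len(match_pairs)} MATCH pairs, {len(ambiguous)} ambiguous")
print()
for g in groups:
    members = sorted(g.member_sample_ids)
    true_labels = {truth.sample_to_patient[s] for s in members}
    score = g.supporting_pairs[0].score if g.supporting_pairs else float("nan")
    print(f"  {g.patient_id}: {', '.join(members)}  "
          f"(cosine {score:.4f}; truth: {', '.join(sorted(true_labels))})")
print()
print("Every recovered group contains exactly one true patient: the")
print("germline fingerprint separates same-patient pairs (score ~1)")
print("from cross-patient pairs (score ~0) by a wide margin.")
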