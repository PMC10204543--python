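"""Annotate a report against a known-mutation reference.

Builds a tiny report and reference inline, joins them on
(gene, one-letter amino-acid change), and prints the tier each row
receives: PATHOGENIC needs a reference match classified pathogenic with
FATHMM score >= 0.8; a matched score < 0.5 lands in LOWER; everything
else — including reference misses — is NEUTRAL.
"""

import tempfile
from pathlib import Path

from ctdnalink import annotate_report, load_reference, parse_report

tmp = Path(tempfile.mkdtemp(prefix="ctdnalink_"))

(tmp / "S001.tsv").write_text(
    "GENE\tAA\tAF\n"
    "KRAS\tp.Gly12Asp\t7.2\n"       # three-letter HGVS, normalized to p.G12D
    "EGFR\tp.Gln787Gln\t49.8\n"     # synonymous, ~50% AF: germline signal
    "ATM\tp.Phe858Leu\t3.1\n"
    "SMO\tp.Thr640Ala\t0.4\n"       # below the 1% display threshold
)
(tmp / "reference.csv").write_text(
    "gene,aa_change,classification,fathmm_score\n"
    "KRAS,p.G12D,PATHOGENIC,0.98\n"
    "EGFR,p.Q787Q,NEUTRAL,0.62\n"
    "ATM,p.F858L,PATHOGENIC,0.12\n"
)

report = parse_report(tmp / "S001.tsv")
reference = load_reference(tmp / "reference.csv")
annotated = annotate_report(report, reference)

print(f"{'gene':8s} {'aa':10s} {'AF%':>6s} {'tier':10s} germline low_af")
for v in annotated.variants:
    print(
        f"{v.record.gene:8s} {v.record.aa_change:10s} "
        f"{v.record.allele_frequency:6.2f} {v.tier.value:10s} "
        f"{str(v.germline_flag):8s} {v.low_af_flag}"
    )
qc = annotated.qc
print()
print(f"QC: {qc.n_rows} rows (<32 flags: {qc.low_row_count_flag}), "
      f"pathogenic/gene ratio {qc.ratio:.3f} (>0.25 flags: {qc.high_ratio_flag})")
print()
print("KRAS p.G12D is the tumor signal; the ~50% EGFR row is germline")
print("(patient identity); ATM matches with a low score (LOWER tier);")
print("the unmatched SMO row defaults to NEUTRAL and is flagged <1% AF.")
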