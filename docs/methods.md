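# Methods

## Problem setting

Targeted-panel sequencing of circulating cell-free DNA (ccfDNA) from
blood plasma yields, per sample, a table of observed variants: gene,
protein-level change, and variant allele frequency (VAF, percent).
Reports are anonymous. Two tasks stand between these tables and a
longitudinal view of a patient's tumor: deciding which observed
variants are pathogenic, and deciding which reports came from the same
person. `ctdnalink` implements both plus the bookkeeping around them;
this note records the model, the defaults, and the judgment calls.

## Annotation model

Reports are joined against a reference of known mutations keyed by
`(gene, one-letter HGVS p. change)`. Protein changes are normalized
with a 3→1 residue-code rewrite (`Ter` → `*`) that preserves the `p.`
prefix and the `fs`/`del`/`ins`/`dup`/`delins`/`=` event grammar;
strings that do not resolve to a recognizable protein change are kept
in the report (their VAF may still matter) but are non-joinable.
Normalization is idempotent.

Tier assignment uses the FATHMM pathogenicity-severity score attached
to each reference entry (range [0, 1]):

| condition | tier |
|---|---|
| matched ∧ classified pathogenic ∧ score ≥ 0.8 | PATHOGENIC |
| matched ∧ score < 0.5 | LOWER |
| anything else (incl. reference miss) | NEUTRAL |

The 0.8 boundary is inclusive: a score of exactly 0.8 is pathogenic.
Unmatched variants tier as NEUTRAL because absence of reference
evidence is not evidence of pathogenicity. Both cutoffs are
configurable (`AnnotationConfig`), with `lower_cutoff <
pathogenic_cutoff` enforced.

Reference deduplication keeps, per key, the entry with the highest
score, preferring the pathogenic classification on ties — the
conservative direction for a clinical-review context.

**Variant flags.** Germline: AF in [40, 60] or ≥ 90 percent (symmetric
bands around the heterozygous ~50% and homozygous ~100% expectations;
configurable). Low-AF: AF strictly below 1 percent.

**Report QC.** A report is flagged when it has fewer than 32
gene+mutation rows, or when its ratio exceeds 0.25. The ratio's
definition is genuinely ambiguous in the field practice this mirrors:
"mutations per gene" with total rows over the 56 panel genes would
exceed 0.25 for every report that passes the 32-row rule (32/56 ≈
0.57), so the two rules would be mutually inconsistent. The default
ratio is therefore pathogenic-tier rows per distinct gene in the
report, with `rows_per_panel_gene` available as an alternate
`qc_ratio_mode` for users who want the literal reading. QC flags are
informational; they gate nothing downstream.

## Patient matching

Each annotated report becomes a sparse nonnegative vector: keys are
`(gene, aa_change)` pairs of its **non**-pathogenic joinable rows
(germline-flagged rows included — they are the identity signal),
magnitudes are percent VAFs. Keying on the full mutation rather than
the gene alone prevents two patients who share a mutated gene but carry
different polymorphisms from colliding; a gene-level `key_mode` (which
sums a gene's AFs) is retained for comparison experiments.

Similarity is the cosine of the angle between two vectors over the
union of keys; with nonnegative magnitudes it lies in [0, 1], is
symmetric (terms are accumulated in sorted key order, so the score is
bit-identical under argument swap), and is invariant to positive
scaling. A zero-norm vector has no defined angle: the score is NaN,
never a silent 0, and such samples are excluded from scoring upstream
(they still appear as singleton groups).

Banding: score ≥ 0.98 → MATCH; 0.95 ≤ score < 0.98 → AMBIGUOUS;
else NO_MATCH. The MATCH threshold is inclusive. Ambiguous pairs are
reported separately for manual review and never used for grouping —
they capture sequencing-noise-degraded same-patient pairs and possibly
close relatives, which the method reports but does not resolve.

K-means (scikit-learn, k-means++ initialization, fixed `random_state`,
K = 2 by default) pre-clusters the dense matrix spanned by the union of
keys. Pairs are scored within clusters only; samples with no MATCH are
then pooled across clusters and exhaustively re-scored against each
other (`rescue_passes` rounds, stopping early when a round yields no
new MATCH). Exhaustive rescue is deterministic and strictly stronger
than randomized re-shuffling; with it, K = 1 and K = 2 produce
identical final groups on cohorts where rescue converges — the
pre-clustering is purely a compute optimization. Patient groups are
connected components (union-find) over MATCH edges, labelled `P0001…`
in order of smallest member sample id, so output is invariant to input
order.

The 0.98 / 0.95 thresholds are empirical calibrations for a 56-gene
panel with ~20 informative germline variants per patient; they are
config-exposed (`MatchConfig`) because their transferability to other
panels is an open question.

## Longitudinal tables

Within a recovered patient, draws are ordered by draw date when every
member sample has one, else lexicographically by sample id (date ties
break by id) — reports are anonymous, so the ordering key is a
documented convention, not a property of the data. Each `(gene,
aa_change)` that is pathogenic-tier and non-germline in at least one
draw becomes a series with one row per draw; absent draws get explicit
AF = 0 rows, making remission and recurrence visible in long format.
The default view drops series never observed at or above the 1% display
threshold; the unfiltered table is always written alongside. Outputs
are CSV (scores printed to 4 decimals) plus an optional single-file
SQLite database with tables `reference`, `annotated`, `pairs`,
`groups`, `timeline`; reruns on identical input and configuration are
byte-identical.

## Synthetic cohorts

The simulator generates what the pipeline assumes about real data:

* **Panel**: the 56 gene targets of the oncology amplicon panel; per
  gene, 12 syntactically valid synthetic p. substitutions form the
  germline key space (no real hotspot database is needed or implied).
* **Germline profiles**: 20 variants per patient sampled without
  replacement, homozygous with probability 0.2; profiles are resampled
  until every pair of patients differs in ≥ 30% of keys (Jaccard
  < 0.7). Base AFs per patient-variant: Normal(50, 2.5) heterozygous,
  Normal(97, 1.5) homozygous, clamped to [0, 100].
* **Per-draw jitter**: Normal(0, 1.5) percentage points added to each
  germline AF per report — re-sequencing noise. Gaussian noise with
  clamping was chosen over a Beta-binomial read-count model for
  transparency; read depths are simulated only as plausible integers
  since nothing downstream consumes them.
* **Somatic trajectories**: scripted per-draw VAF vectors per patient
  (e.g. `(0, 0, 6)` — a driver first detectable at draw 3). A VAF below
  the 1% detection floor means the row is **omitted** from that draw's
  report, mirroring an assay limit of detection, rather than written
  as AF = 0.
* **Background**: 3 random low-AF (1–8%) calls per report on keys
  outside the patient's profile.
* **Reference**: every scripted mutation present as PATHOGENIC with
  score in [0.8, 1.0], plus 40 NEUTRAL entries (scores [0.5, 0.8)) and
  5 low-score entries (< 0.5) drawn from the key space.
* **Anonymity**: sample ids are assigned after a seeded shuffle of the
  (patient, draw) list, so ids encode nothing; ground-truth labels are
  written outside the reports directory and never read by the pipeline.

The seed fully determines every output byte.

What the simulator does **not** model — and what passing tests
therefore do not show about real data: clonal evolution and realistic
tumor-fraction dynamics, sequencing-error substitution spectra,
indel-rich or noncanonical HGVS strings beyond the grammar above,
related individuals (siblings would legitimately score high), sample
contamination, and panel dropout of germline sites. The separation the
thresholds rely on (same-patient cosine ≥ 0.98, cross-patient < 0.95)
is a property of ~20-dimensional germline fingerprints with ≤ 2.5-point
AF noise; cohorts with fewer informative germline sites would need
recalibration.

## Numerical and design choices

* Cosine accumulates dot-product terms over sorted shared keys: exact
  symmetry, and equality with a brute-force double loop to < 1e-12.
* Scores are capped at 1.0 to absorb floating-point overshoot on
  near-parallel vectors.
* In-report duplicate calls (same gene + change) keep the
  highest-depth row, else the first occurrence.
* AF dialects: percent (default) or fraction (×100 on load); parsing
  either dialect of the same data yields identical records.
* Rows with unparseable protein changes or non-numeric/out-of-range
  AFs: the former are kept non-joinable, the latter dropped with a
  collected row-level error; an entirely empty report is a hard error.
* Degenerate inputs: empty reference (all lookups miss), zero-gene QC
  (ratio defined 0 with a warning), fewer samples than K (one cluster,
  warning), no MATCH edges (all singleton patients).

## Test problem sizes

Property tests run on fuzzed vectors and tier triples (hypothesis,
seeded); end-to-end checks simulate 30 patients × 2 draws (60 reports)
over the full 56-gene panel across 10 seeds for match precision and
patient recovery (Adjusted Rand Index), plus 3-patient × 3-draw cohorts
for the case-study trajectories. These sizes mirror the 60-sample
calibration setting of the workflow this package automates while
keeping the whole suite a matter of seconds.
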