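"""Synthetic liquid-biopsy cohorts with known ground truth.

The generator emulates the statistical structure the pipeline assumes
about targeted-panel plasma sequencing over a 56-gene oncology panel:

* each patient carries a personal germline profile — a set of
  (gene, amino-acid change) variants observed near 50% allele frequency
  when heterozygous and near 100% when homozygous, stable across draws
  up to per-draw sequencing jitter;
* somatic pathogenic mutations follow scripted per-draw VAF
  trajectories (new detection, remission, recurrence), and fall below
  the assay's detection floor (1% VAF) simply by being absent from the
  report — the assay reports nothing under its limit of detection;
* a few random low-AF neutral rows per report model background calls.

Alongside the reports the generator writes a matching mini reference
(every scripted pathogenic mutation present with a FATHMM score >= 0.8,
plus neutral and low-score entries) and a ground-truth table mapping
each anonymous sample id to its patient — the test oracle, kept out of
the pipeline's input directory.  A fixed seed fully determines every
output byte.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PANEL_56",
    "SimConfig",
    "PathogenicScenario",
    "GroundTruth",
    "generate_reference",
    "generate_patient_profile",
    "generate_cohort",
    "scenario_late_detection",
    "scenario_remission_recurrence",
]

#: The 56 gene targets of the oncology amplicon panel.
PANEL_56: tuple[str, ...] = (
    "ABL1", "AKT1", "ALK", "APC", "ATM", "BRAF", "CDH1", "CDKN2A", "CSF1R",
    "CTNNB1", "DDR2", "DNMT3A", "EGFR", "ERBB2", "ERBB4", "EZH2", "FBXW7",
    "FGFR1", "FGFR2", "FGFR3", "FLT3", "FOXL2", "GNA11", "GNAQ", "GNAS",
    "HNF1A", "HRAS", "IDH1", "IDH2", "JAK2", "JAK3", "KDR", "KIT", "KRAS",
    "MAP2K1", "MET", "MLH1", "MPL", "MSH6", "NOTCH1", "NPM1", "NRAS",
    "PDGFRA", "PIK3CA", "PTEN", "PTPN11", "RB1", "RET", "SMAD4", "SMARCB1",
    "SMO", "SRC", "STK11", "TP53", "TSC1", "VHL",
)

_AA1 = "ARNDCQEGHILKMFPSTWYV"
_N_SITES_PER_GENE = 12


# builtin `hash` on strings is salted per process; use a stable ordinal sum
def _stable_hash(s: str) -> int:
    return sum(ord(c) * (i + 1) for i, c in enumerate(s))


def _germline_key_space_stable(panel: tuple[str, ...]) -> list[tuple[str, str]]:
    """Enumerate syntactically valid synthetic p. changes per gene.

    Deterministic and seed-independent: the key space is a property of
    the panel, only the sampling from it is random.
    """
    keys: list[tuple[str, str]] = []
    for gene in panel:
        base = _stable_hash(gene)
        for k in range(_N_SITES_PER_GENE):
            ref = _AA1[(base + 3 * k) % 20]
            alt = _AA1[(base + 3 * k + 7) % 20]
            pos = 100 + 13 * k
            keys.append((gene, f"p.{ref}{pos}{alt}"))
    return keys


@dataclass(frozen=True)
class PathogenicScenario:
    """A scripted somatic mutation trajectory for one patient.

    ``vaf_by_draw`` gives the true VAF (percent) at each draw; a value
    below the detection floor means the mutation is absent from that
    draw's report.
    """

    patient_index: int
    gene: str
    aa_change: str
    vaf_by_draw: tuple[float, ...]


def scenario_late_detection(patient_index: int = 0) -> list[PathogenicScenario]:
    """A KRAS driver first appearing in the third of three draws."""
    return [PathogenicScenario(patient_index, "KRAS", "p.G12D", (0.0, 0.0, 6.0))]


def scenario_remission_recurrence(patient_index: int = 0) -> list[PathogenicScenario]:
    """BRAF-positive first draw, remission, then a new KRAS driver in
    the third draw (recurrence)."""
    return [
        PathogenicScenario(patient_index, "BRAF", "p.V600E", (8.0, 0.0, 0.0)),
        PathogenicScenario(patient_index, "KRAS", "p.G12D", (0.0, 0.0, 5.0)),
    ]


@dataclass
class SimConfig:
    """Cohort-simulation parameters (allele frequencies in percent)."""

    n_patients: int = 10
    draws_per_patient: int | list[int] = 2
    panel: tuple[str, ...] = PANEL_56
    n_germline_per_patient: int = 20
    het_af_mean: float = 50.0
    het_af_sd: float = 2.5
    hom_af_mean: float = 97.0
    hom_af_sd: float = 1.5
    hom_fraction: float = 0.2
    noise_sd: float = 1.5
    n_noise_rows: int = 3
    pathogenic_scenarios: list[PathogenicScenario] = field(default_factory=list)
    detection_floor: float = 1.0
    n_neutral_reference: int = 40
    n_lower_reference: int = 5
    seed: int = 0

    def draws_for(self, patient_index: int) -> int:
        if isinstance(self.draws_per_patient, int):
            return self.draws_per_patient
        return self.draws_per_patient[patient_index]

    def validate(self) -> None:
        if not self.panel:
            raise ValueError("panel must be nonempty")
        if self.n_germline_per_patient <= 0:
            raise ValueError(
                "n_germline_per_patient must be positive: the germline "
                "profile is the identity signal"
            )
        for s in self.pathogenic_scenarios:
            if s.gene not in self.panel:
                raise ValueError(f"scenario gene {s.gene} not on panel")
            if s.patient_index >= self.n_patients:
                raise ValueError(f"scenario patient {s.patient_index} out of range")
            if len(s.vaf_by_draw) != self.draws_for(s.patient_index):
                raise ValueError(
                    f"scenario for patient {s.patient_index} has "
                    f"{len(s.vaf_by_draw)} draw VAFs but the patient has "
                    f"{self.draws_for(s.patient_index)} draws"
                )


@dataclass
class GroundTruth:
    """Oracle labels for a generated cohort (never fed to the pipeline)."""

    sample_to_patient: dict[str, str]
    injected_pathogenic: dict[str, list[tuple[str, str, float]]]

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sample_id", "patient_id", "injected"])
            for sid in sorted(self.sample_to_patient):
                injected = ";".join(
                    f"{g}:{aa}:{vaf:.3f}"
                    for g, aa, vaf in self.injected_pathogenic.get(sid, [])
                )
                w.writerow([sid, self.sample_to_patient[sid], injected])


def generate_reference(
    panel: tuple[str, ...],
    scenarios: list[PathogenicScenario],
    n_neutral_entries: int,
    seed: int,
    path: str | Path,
    n_lower_entries: int = 5,
) -> Path:
    """Write a mini mutation-reference CSV.

    Every scenario mutation is present as PATHOGENIC with a FATHMM score
    in [0.8, 1.0]; *n_neutral_entries* NEUTRAL entries (scores in
    [0.5, 0.8)) and a handful of low-score entries (< 0.5) are drawn from
    the synthetic key space of the panel.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str, float]] = []
    seen: set[tuple[str, str]] = set()
    for s in sorted(set((s.gene, s.aa_change) for s in scenarios)):
        gene, aa = s
        if (gene, aa) in seen:
            continue
        seen.add((gene, aa))
        rows.append((gene, aa, "PATHOGENIC", round(float(rng.uniform(0.8, 1.0)), 3)))
    space = [k for k in _germline_key_space_stable(panel) if k not in seen]
    idx = rng.choice(len(space), size=min(len(space), n_neutral_entries + n_lower_entries),
                     replace=False)
    for j, i in enumerate(idx):
        gene, aa = space[int(i)]
        if j < n_neutral_entries:
            rows.append((gene, aa, "NEUTRAL", round(float(rng.uniform(0.5, 0.8)), 3)))
        else:
            rows.append((gene, aa, "PATHOGENIC", round(float(rng.uniform(0.05, 0.5)), 3)))
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["gene", "aa_change", "classification", "fathmm_score"])
        for gene, aa, cls, score in rows:
            w.writerow([gene, aa, cls, f"{score:.3f}"])
    return path


def generate_patient_profile(
    config: SimConfig,
    patient_index: int,
    rng: np.random.Generator,
    existing_profiles: list[dict[tuple[str, str], str]] | None = None,
    max_retries: int = 200,
) -> dict[tuple[str, str], str]:
    """Sample one patient's germline profile: key -> zygosity.

    ``n_germline_per_patient`` (gene, aa_change) keys are drawn without
    replacement from the panel's synthetic site space; each is
    homozygous with probability ``hom_fraction``.  Profiles must differ
    from every previously generated one in at least 30% of keys
    (Jaccard similarity of key sets < 0.7), resampling until satisfied.
    """
    config.validate()
    space = _germline_key_space_stable(config.panel)
    n = config.n_germline_per_patient
    if n > len(space):
        raise ValueError(
            f"n_germline_per_patient={n} exceeds the {len(space)} synthetic "
            "sites of the panel; enlarge the panel"
        )
    existing = existing_profiles or []
    for _ in range(max_retries):
        idx = rng.choice(len(space), size=n, replace=False)
        keys = {space[int(i)] for i in idx}
        ok = True
        for prof in existing:
            other = set(prof)
            jac = len(keys & other) / len(keys | other)
            if jac >= 0.7:
                ok = False
                break
        if ok:
            zyg = rng.random(n) < config.hom_fraction
            ordered = sorted(keys)
            return {k: ("hom" if z else "het") for k, z in zip(ordered, zyg)}
    raise RuntimeError(
        "could not generate a sufficiently distinct germline profile after "
        f"{max_retries} retries; use a larger panel or fewer germline variants"
    )


def _clamp(x: float) -> float:
    return min(100.0, max(0.0, x))


def generate_cohort(
    config: SimConfig, out_dir: str | Path
) -> tuple[Path, Path, GroundTruth]:
    """Generate a full synthetic cohort on disk.

    Writes one TSV report per (patient, draw) under ``<out_dir>/reports``
    (with a ``metadata.csv`` sidecar of draw dates), the mini reference
    at ``<out_dir>/reference.csv``, and the ground-truth labels at
    ``<out_dir>/truth.csv`` (outside the reports directory).  Returns
    ``(reports_dir, reference_csv, ground_truth)``.  The seed fully
    determines every byte.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    reports_dir = out_dir / "reports"
    reports_dir.mkdir(parents=True, exist_ok=True)

    # Germline profiles with pairwise-distinctness constraint, and a
    # stable per-(patient, variant) base AF reused across draws.
    profiles: list[dict[tuple[str, str], str]] = []
    for p in range(config.n_patients):
        profiles.append(generate_patient_profile(config, p, rng, profiles))
    base_af: list[dict[tuple[str, str], float]] = []
    for prof in profiles:
        afs: dict[tuple[str, str], float] = {}
        for key, zyg in sorted(prof.items()):
            if zyg == "hom":
                afs[key] = _clamp(float(rng.normal(config.hom_af_mean, config.hom_af_sd)))
            else:
                afs[key] = _clamp(float(rng.normal(config.het_af_mean, config.het_af_sd)))
        base_af.append(afs)

    scenarios_by_patient: dict[int, list[PathogenicScenario]] = {}
    for s in config.pathogenic_scenarios:
        scenarios_by_patient.setdefault(s.patient_index, []).append(s)

    # Anonymous sample ids: shuffle the (patient, draw) list so the id
    # carries no patient information.
    pd_list = [
        (p, d) for p in range(config.n_patients) for d in range(config.draws_for(p))
    ]
    order = list(range(len(pd_list)))
    rng.shuffle(order)
    sample_ids = {pd_list[j]: f"S{i + 1:04d}" for i, j in enumerate(order)}

    space = _germline_key_space_stable(config.panel)
    truth_patient: dict[str, str] = {}
    truth_injected: dict[str, list[tuple[str, str, float]]] = {}
    metadata: list[tuple[str, str]] = []
    start = date(2021, 1, 4)

    for p in range(config.n_patients):
        patient_label = f"T{p + 1:04d}"
        p_start = start + timedelta(days=int(rng.integers(0, 60)))
        for d in range(config.draws_for(p)):
            sid = sample_ids[(p, d)]
            draw_date = (p_start + timedelta(days=90 * d)).isoformat()
            metadata.append((sid, draw_date))
            truth_patient[sid] = patient_label
            rows: list[tuple[str, str, float, int]] = []
            for key, base in sorted(base_af[p].items()):
                af = _clamp(base + float(rng.normal(0.0, config.noise_sd)))
                rows.append((key[0], key[1], af, int(rng.integers(200, 2000))))
            injected: list[tuple[str, str, float]] = []
            for s in scenarios_by_patient.get(p, []):
                vaf = s.vaf_by_draw[d]
                if vaf >= config.detection_floor:
                    rows.append((s.gene, s.aa_change, vaf, int(rng.integers(200, 2000))))
                    injected.append((s.gene, s.aa_change, vaf))
            truth_injected[sid] = injected
            # background low-AF neutral calls, unique keys per report
            profile_keys = set(base_af[p]) | {
                (s.gene, s.aa_change) for s in scenarios_by_patient.get(p, [])
            }
            noise_space = [k for k in space if k not in profile_keys]
            if config.n_noise_rows and noise_space:
                idx = rng.choice(
                    len(noise_space),
                    size=min(config.n_noise_rows, len(noise_space)),
                    replace=False,
                )
                for i in idx:
                    gene, aa = noise_space[int(i)]
                    af = float(rng.uniform(config.detection_floor, 8.0))
                    rows.append((gene, aa, af, int(rng.integers(100, 800))))
            with open(reports_dir / f"{sid}.tsv", "w", newline="") as fh:
                fh.write("GENE\tAA\tAF\tDEPTH\n")
                for gene, aa, af, depth in rows:
                    fh.write(f"{gene}\t{aa}\t{af:.3f}\t{depth}\n")

    with open(reports_dir / "metadata.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "draw_date"])
        for sid, dd in sorted(metadata):
            w.writerow([sid, dd])

    reference_csv = generate_reference(
        config.panel,
        config.pathogenic_scenarios,
        config.n_neutral_reference,
        config.seed + 1,
        out_dir / "reference.csv",
        n_lower_entries=config.n_lower_reference,
    )
    truth = GroundTruth(sample_to_patient=truth_patient, injected_pathogenic=truth_injected)
    truth.write_csv(out_dir / "truth.csv")
    logger.info(
        "generated cohort: %d patients, %d reports, reference %d rows",
        config.n_patients, len(truth_patient),
        len(config.pathogenic_scenarios) + config.n_neutral_reference + config.n_lower_reference,
    )
    return reports_dir, reference_csv, truth
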