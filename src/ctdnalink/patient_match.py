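"""Grouping anonymous reports into patients by germline fingerprint.

Reports carry no identifiers, but the non-tumor variants they contain —
germline mutations, polymorphisms, synonymous changes — are a stable
per-person signature.  Each report becomes a sparse vector whose keys
are (gene, amino-acid change) pairs and whose magnitudes are allele
frequencies; pathogenic-tier rows are deliberately excluded, since the
tumor signal varies over time while the germline background does not.

Pairs of reports are scored by cosine similarity.  A score at or above
0.98 is a MATCH (same patient); [0.95, 0.98) is AMBIGUOUS — a potential
match reported for manual review but never used for grouping.  To avoid
scoring every pair in a large cohort, samples are first split by
k-means (K = 2 by default) and scored within clusters only; samples
left without a match are then pooled across clusters and exhaustively
re-scored (the "rescue" pass), so the pre-clustering is a compute
optimization, not a semantic one.  Final patient groups are the
connected components of the MATCH-edge graph.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from sklearn.cluster import KMeans

from .annotate import AnnotatedReport, Tier

logger = logging.getLogger(__name__)

__all__ = [
    "Band",
    "MatchConfig",
    "SampleVector",
    "SimilarityPair",
    "PatientGroup",
    "vectorize",
    "cosine_similarity",
    "kmeans_partition",
    "score_within_clusters",
    "rescue_unmatched",
    "group_patients",
    "match_cohort",
]


class Band(str, Enum):
    MATCH = "MATCH"
    AMBIGUOUS = "AMBIGUOUS"
    NO_MATCH = "NO_MATCH"


@dataclass(frozen=True)
class MatchConfig:
    """Thresholds and knobs of the matching stage.

    ``match_threshold`` (0.98) and ``ambiguous_low`` (0.95) are the
    empirically calibrated similarity cutoffs; ``k_clusters`` is the
    number of k-means buckets (2 here — it can grow with cohort size).
    """

    k_clusters: int = 2
    match_threshold: float = 0.98
    ambiguous_low: float = 0.95
    key_mode: str = "gene_mutation"  # or "gene"
    rescue_passes: int = 1
    random_seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 <= self.ambiguous_low < self.match_threshold <= 1.0:
            raise ValueError(
                f"need 0 <= ambiguous_low < match_threshold <= 1, got "
                f"{self.ambiguous_low}, {self.match_threshold}"
            )
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")
        if self.key_mode not in ("gene_mutation", "gene"):
            raise ValueError(f"unknown key_mode {self.key_mode!r}")


@dataclass
class SampleVector:
    """Sparse allele-frequency vector of one report's non-pathogenic rows."""

    sample_id: str
    components: dict[tuple[str, ...], float]

    @property
    def norm(self) -> float:
        return math.sqrt(sum(v * v for v in self.components.values()))


@dataclass(frozen=True)
class SimilarityPair:
    sample_a: str
    sample_b: str
    score: float
    band: Band


@dataclass
class PatientGroup:
    patient_id: str
    member_sample_ids: set[str]
    supporting_pairs: list[SimilarityPair] = field(default_factory=list)


def vectorize(report: AnnotatedReport, key_mode: str = "gene_mutation") -> SampleVector:
    """Build the identity vector of a report.

    Includes exactly the non-PATHOGENIC-tier rows with a nonempty
    normalized amino-acid change (germline-flagged rows included — they
    ARE the identity signal).  In ``gene`` mode the AFs of a gene's
    multiple variants are summed onto a single gene key.
    """
    components: dict[tuple[str, ...], float] = {}
    for v in report.variants:
        if v.tier is Tier.PATHOGENIC or not v.record.aa_change:
            continue
        key: tuple[str, ...]
        if key_mode == "gene":
            key = (v.record.gene,)
        else:
            key = (v.record.gene, v.record.aa_change)
        components[key] = components.get(key, 0.0) + v.record.allele_frequency
    if not components:
        logger.warning(
            "sample %s has no non-pathogenic joinable rows; excluded from matching",
            report.sample_id,
        )
    return SampleVector(sample_id=report.sample_id, components=components)


def cosine_similarity(v1: SampleVector, v2: SampleVector) -> float:
    """Cosine of the angle between two sparse AF vectors.

    Computed over the union of keys (absent keys contribute 0); with
    nonnegative magnitudes the score lies in [0, 1]: 1 for identical
    direction, 0 for disjoint supports.  If either vector has zero norm
    the score is undefined and NaN is returned, never a silent 0.
    """
    n1, n2 = v1.norm, v2.norm
    if n1 == 0.0 or n2 == 0.0:
        return float("nan")
    small, large = (
        (v1.components, v2.components)
        if len(v1.components) <= len(v2.components)
        else (v2.components, v1.components)
    )
    # accumulate in sorted key order so the score is exactly symmetric
    dot = 0.0
    for key in sorted(k for k in small if k in large):
        dot += small[key] * large[key]
    return min(1.0, dot / (n1 * n2))


def _band(score: float, config: MatchConfig) -> Band:
    if score >= config.match_threshold:
        return Band.MATCH
    if score >= config.ambiguous_low:
        return Band.AMBIGUOUS
    return Band.NO_MATCH


def _score_pair(v1: SampleVector, v2: SampleVector, config: MatchConfig) -> SimilarityPair:
    a, b = sorted((v1.sample_id, v2.sample_id))
    score = cosine_similarity(v1, v2)
    return SimilarityPair(sample_a=a, sample_b=b, score=score, band=_band(score, config))


def kmeans_partition(
    vectors: list[SampleVector], k: int, seed: int = 42
) -> dict[str, int]:
    """Assign each sample to one of *k* clusters (Lloyd's algorithm,
    k-means++ seeding, deterministic under a fixed seed).

    Vectors are densified over the union of their keys with absent keys
    as 0.  With fewer samples than clusters everything lands in one
    cluster (with a warning).
    """
    vectors = [v for v in vectors if v.components]
    if not vectors:
        return {}
    if k < 2 or len(vectors) < k:
        if 1 < k > len(vectors):
            logger.warning("fewer samples (%d) than clusters (%d); single cluster", len(vectors), k)
        return {v.sample_id: 0 for v in vectors}
    all_keys = sorted({key for v in vectors for key in v.components})
    index = {key: j for j, key in enumerate(all_keys)}
    X = np.zeros((len(vectors), len(all_keys)))
    for i, v in enumerate(vectors):
        for key, mag in v.components.items():
            X[i, index[key]] = mag
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    return {v.sample_id: int(lab) for v, lab in zip(vectors, labels)}


def score_within_clusters(
    vectors: list[SampleVector],
    assignment: dict[str, int],
    config: MatchConfig = MatchConfig(),
) -> list[SimilarityPair]:
    """Score and band every unordered pair within each cluster."""
    by_id = {v.sample_id: v for v in vectors}
    pairs: list[SimilarityPair] = []
    clusters: dict[int, list[str]] = {}
    for sid, lab in assignment.items():
        clusters.setdefault(lab, []).append(sid)
    for lab in sorted(clusters):
        members = sorted(clusters[lab])
        for a, b in itertools.combinations(members, 2):
            pairs.append(_score_pair(by_id[a], by_id[b], config))
    return pairs


def rescue_unmatched(
    pairs: list[SimilarityPair],
    vectors: list[SampleVector],
    assignment: dict[str, int],
    config: MatchConfig = MatchConfig(),
) -> list[SimilarityPair]:
    """Cross-cluster rescue of samples left without a MATCH.

    Samples with no MATCH-band pair are pooled across clusters and
    exhaustively pairwise-scored against each other (pairs already
    scored within a cluster are not re-scored); repeated for
    ``rescue_passes`` rounds or until no new MATCH appears.
    """
    by_id = {v.sample_id: v for v in vectors}
    seen: set[tuple[str, str]] = {(p.sample_a, p.sample_b) for p in pairs}
    matched: set[str] = set()
    for p in pairs:
        if p.band is Band.MATCH:
            matched.update((p.sample_a, p.sample_b))
    new_pairs: list[SimilarityPair] = []
    for _ in range(config.rescue_passes):
        pool = sorted(sid for sid in assignment if sid not in matched)
        round_pairs: list[SimilarityPair] = []
        for a, b in itertools.combinations(pool, 2):
            if (a, b) in seen:
                continue
            p = _score_pair(by_id[a], by_id[b], config)
            seen.add((a, b))
            round_pairs.append(p)
        new_matches = [p for p in round_pairs if p.band is Band.MATCH]
        new_pairs.extend(round_pairs)
        if not new_matches:
            break
        for p in new_matches:
            matched.update((p.sample_a, p.sample_b))
    return new_pairs


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def group_patients(
    all_pairs: list[SimilarityPair],
    sample_ids: list[str],
) -> tuple[list[PatientGroup], list[SimilarityPair]]:
    """Union-find connected components over MATCH-band edges.

    Returns the patient groups (singletons included for unmatched
    samples) and the AMBIGUOUS pairs as a separate review report —
    ambiguous edges are never used for grouping.  Patient ids are
    canonical: groups are ordered by their smallest member sample id and
    labelled ``P0001``, ``P0002``, ...
    """
    uf = _UnionFind(sorted(set(sample_ids)))
    match_pairs = [p for p in all_pairs if p.band is Band.MATCH]
    ambiguous = sorted(
        (p for p in all_pairs if p.band is Band.AMBIGUOUS),
        key=lambda p: (p.sample_a, p.sample_b),
    )
    for p in match_pairs:
        uf.union(p.sample_a, p.sample_b)
    components: dict[str, set[str]] = {}
    for sid in sorted(set(sample_ids)):
        components.setdefault(uf.find(sid), set()).add(sid)
    groups: list[PatientGroup] = []
    for i, root in enumerate(sorted(components, key=lambda r: min(components[r])), start=1):
        members = components[root]
        groups.append(
            PatientGroup(
                patient_id=f"P{i:04d}",
                member_sample_ids=members,
                supporting_pairs=[
                    p for p in match_pairs
                    if p.sample_a in members and p.sample_b in members
                ],
            )
        )
    return groups, ambiguous


def match_cohort(
    annotated_reports: list[AnnotatedReport],
    config: MatchConfig = MatchConfig(),
) -> tuple[list[PatientGroup], list[SimilarityPair], list[SimilarityPair]]:
    """Run the full matching stage: vectorize, pre-cluster, score,
    rescue, group.

    Returns ``(groups, all_scored_pairs, ambiguous_pairs)``.  Reports
    whose vectors are empty are excluded from scoring but still appear
    as singleton groups.  Output is invariant to input report order.
    """
    reports = sorted(annotated_reports, key=lambda r: r.sample_id)
    vectors = [vectorize(r, config.key_mode) for r in reports]
    scorable = [v for v in vectors if v.components]
    assignment = kmeans_partition(scorable, config.k_clusters, config.random_seed)
    pairs = score_within_clusters(scorable, assignment, config)
    pairs = pairs + rescue_unmatched(pairs, scorable, assignment, config)
    pairs.sort(key=lambda p: (p.sample_a, p.sample_b))
    groups, ambiguous = group_patients(pairs, [r.sample_id for r in reports])
    n_match = sum(1 for p in pairs if p.band is Band.MATCH)
    logger.info(
        "matching: %d samples, %d scored pairs, %d MATCH, %d AMBIGUOUS, %d groups",
        len(reports), len(pairs), n_match, len(ambiguous), len(groups),
    )
    return groups, pairs, ambiguous
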