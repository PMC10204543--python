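"""Vectorization, cosine scoring, clustering, rescue, and grouping."""

import itertools
import math

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctdnalink.patient_match import (
    Band,
    MatchConfig,
    SampleVector,
    cosine_similarity,
    group_patients,
    kmeans_partition,
    match_cohort,
    rescue_unmatched,
    score_within_clusters,
    vectorize,
)

CFG = MatchConfig()


def vec(sid, **components):
    return SampleVector(sid, {(k,): float(v) for k, v in components.items()})


def brute_force_cosine(v1: SampleVector, v2: SampleVector) -> float:
    """Two-loop dot/norm oracle over the union of keys."""
    keys = sorted(set(v1.components) | set(v2.components))
    a = [v1.components.get(k, 0.0) for k in keys]
    b = [v2.components.get(k, 0.0) for k in keys]
    dot = sum(x * y for x, y in zip(a, b))
    na = math.sqrt(sum(x * x for x in a))
    nb = math.sqrt(sum(y * y for y in b))
    return dot / (na * nb)


sparse_vectors = st.dictionaries(
    st.sampled_from([(f"G{i}",) for i in range(12)]),
    st.floats(0.01, 100),
    min_size=1,
    max_size=8,
)


class TestCosineSimilarity:
    def test_identical_vectors_score_one(self):
        v = vec("a", KRAS=50, EGFR=30)
        assert cosine_similarity(v, v) == 1.0

    def test_scalar_multiple_scores_one(self):
        v1 = vec("a", KRAS=50, EGFR=30)
        v2 = SampleVector("b", {k: 2.5 * m for k, m in v1.components.items()})
        assert cosine_similarity(v1, v2) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_supports_score_zero(self):
        assert cosine_similarity(vec("a", KRAS=50), vec("b", EGFR=30)) == 0.0

    def test_closed_form_three_four(self):
        v1 = vec("a", g1=3, g2=4)
        v2 = vec("b", g1=4, g2=3)
        assert cosine_similarity(v1, v2) == pytest.approx(24 / 25)

    def test_zero_norm_is_nan_sentinel(self):
        empty = SampleVector("a", {})
        assert math.isnan(cosine_similarity(empty, vec("b", KRAS=50)))

    @given(sparse_vectors, sparse_vectors)
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_oracle(self, c1, c2):
        v1, v2 = SampleVector("a", c1), SampleVector("b", c2)
        assert cosine_similarity(v1, v2) == pytest.approx(
            min(1.0, brute_force_cosine(v1, v2)), abs=1e-12
        )

    @given(sparse_vectors, sparse_vectors, st.floats(0.01, 50))
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_scale_invariance(self, c1, c2, scale):
        v1, v2 = SampleVector("a", c1), SampleVector("b", c2)
        s = cosine_similarity(v1, v2)
        assert cosine_similarity(v2, v1) == s
        scaled = SampleVector("c", {k: scale * m for k, m in c1.items()})
        assert cosine_similarity(scaled, v2) == pytest.approx(s, abs=1e-9)


class TestVectorize:
    def test_pathogenic_rows_excluded(self, make_annotated):
        rep = make_annotated("S1", [("EGFR", "p.Q787Q", 49.8), ("BRAF", "p.V600E", 12.0)])
        v = vectorize(rep)
        assert v.components == {("EGFR", "p.Q787Q"): 49.8}

    def test_all_pathogenic_report_gives_empty_vector(self, make_annotated):
        rep = make_annotated("S1", [("BRAF", "p.V600E", 12.0), ("KRAS", "p.G12D", 6.0)])
        assert vectorize(rep).components == {}

    def test_non_joinable_rows_excluded(self, make_annotated):
        rep = make_annotated("S1", [("SMO", "???", 20.0), ("EGFR", "p.Q787Q", 49.8)])
        assert list(vectorize(rep).components) == [("EGFR", "p.Q787Q")]

    def test_gene_mode_sums_per_gene(self, make_annotated):
        rep = make_annotated("S1", [("TP53", "p.P72R", 30.0), ("TP53", "p.R213R", 20.0)])
        v = vectorize(rep, key_mode="gene")
        assert v.components == {("TP53",): pytest.approx(50.0)}

    def test_germline_rows_included(self, make_annotated):
        rep = make_annotated("S1", [("EGFR", "p.Q787Q", 50.0)])
        assert vectorize(rep).components == {("EGFR", "p.Q787Q"): 50.0}


def family_vectors(n_per=3):
    """Two families on disjoint key sets, tight within-family angles."""
    fam_a = [vec(f"A{i}", **{f"GA{j}": 50 + i + j for j in range(6)}) for i in range(n_per)]
    fam_b = [vec(f"B{i}", **{f"GB{j}": 50 + i + j for j in range(6)}) for i in range(n_per)]
    return fam_a, fam_b


class TestKMeans:
    def test_k1_single_cluster(self):
        fam_a, fam_b = family_vectors()
        assignment = kmeans_partition(fam_a + fam_b, k=1)
        assert set(assignment.values()) == {0}

    def test_separates_disjoint_families(self):
        fam_a, fam_b = family_vectors()
        assignment = kmeans_partition(fam_a + fam_b, k=2, seed=0)
        labels_a = {assignment[v.sample_id] for v in fam_a}
        labels_b = {assignment[v.sample_id] for v in fam_b}
        assert len(labels_a) == len(labels_b) == 1 and labels_a != labels_b
        # oracle: within-family distances strictly below between-family
        def dist(u, w):
            keys = set(u.components) | set(w.components)
            return math.sqrt(
                sum((u.components.get(k, 0) - w.components.get(k, 0)) ** 2 for k in keys)
            )
        within = max(
            dist(u, w) for fam in (fam_a, fam_b) for u, w in itertools.combinations(fam, 2)
        )
        between = min(dist(u, w) for u in fam_a for w in fam_b)
        assert within < between

    def test_deterministic_under_seed(self):
        fam_a, fam_b = family_vectors()
        a1 = kmeans_partition(fam_a + fam_b, k=2, seed=7)
        a2 = kmeans_partition(fam_a + fam_b, k=2, seed=7)
        assert a1 == a2

    def test_fewer_samples_than_k_single_cluster(self):
        assignment = kmeans_partition([vec("a", G=1)], k=2)
        assert assignment == {"a": 0}


class TestScoring:
    def test_pair_count_is_n_choose_2(self):
        fam_a, _ = family_vectors(n_per=5)
        assignment = {v.sample_id: 0 for v in fam_a}
        pairs = score_within_clusters(fam_a, assignment, CFG)
        assert len(pairs) == 10

    def test_no_cross_cluster_pairs(self):
        fam_a, fam_b = family_vectors()
        assignment = {v.sample_id: 0 for v in fam_a} | {v.sample_id: 1 for v in fam_b}
        pairs = score_within_clusters(fam_a + fam_b, assignment, CFG)
        ids_a = {v.sample_id for v in fam_a}
        for p in pairs:
            assert (p.sample_a in ids_a) == (p.sample_b in ids_a)

    @pytest.mark.parametrize(
        "score,band",
        [(0.985, Band.MATCH), (0.98, Band.MATCH), (0.9799, Band.AMBIGUOUS),
         (0.96, Band.AMBIGUOUS), (0.95, Band.AMBIGUOUS), (0.9499, Band.NO_MATCH)],
    )
    def test_banding_thresholds(self, score, band):
        from ctdnalink.patient_match import _band
        assert _band(score, CFG) is band


class TestRescue:
    def test_split_pair_recovered_in_rescue(self):
        # same-"patient" twins forced into different clusters
        twin1 = vec("X1", G1=50, G2=50)
        twin2 = vec("X2", G1=50.5, G2=49.5)
        other = vec("Y1", H1=50, H2=50)
        vectors = [twin1, twin2, other]
        assignment = {"X1": 0, "X2": 1, "Y1": 1}
        pairs = score_within_clusters(vectors, assignment, CFG)
        assert not any(p.band is Band.MATCH for p in pairs)
        rescued = rescue_unmatched(pairs, vectors, assignment, CFG)
        match = [p for p in rescued if p.band is Band.MATCH]
        assert [(p.sample_a, p.sample_b) for p in match] == [("X1", "X2")]

    def test_all_matched_yields_no_new_pairs(self):
        fam_a, _ = family_vectors(n_per=2)
        assignment = {v.sample_id: 0 for v in fam_a}
        pairs = score_within_clusters(fam_a, assignment, CFG)
        assert all(p.band is Band.MATCH for p in pairs)
        assert rescue_unmatched(pairs, fam_a, assignment, CFG) == []

    def test_zero_rescue_passes_is_identity(self):
        twin1, twin2 = vec("X1", G1=50), vec("X2", G1=50)
        assignment = {"X1": 0, "X2": 1}
        cfg = MatchConfig(rescue_passes=0)
        pairs = score_within_clusters([twin1, twin2], assignment, cfg)
        assert rescue_unmatched(pairs, [twin1, twin2], assignment, cfg) == []


class TestGrouping:
    def _pair(self, a, b, score):
        from ctdnalink.patient_match import _band, SimilarityPair
        return SimilarityPair(a, b, score, _band(score, CFG))

    def test_transitive_closure_matches_networkx_oracle(self):
        pairs = [self._pair("A", "B", 0.99), self._pair("B", "C", 0.985),
                 self._pair("C", "D", 0.5), self._pair("E", "F", 0.99)]
        ids = list("ABCDEF")
        groups, _ = group_patients(pairs, ids)
        got = sorted(frozenset(g.member_sample_ids) for g in groups)

        g = nx.Graph()
        g.add_nodes_from(ids)
        g.add_edges_from((p.sample_a, p.sample_b) for p in pairs if p.score >= 0.98)
        want = sorted(frozenset(c) for c in nx.connected_components(g))
        assert got == want

    def test_no_matches_all_singletons(self):
        groups, _ = group_patients([], ["S1", "S2", "S3"])
        assert all(len(g.member_sample_ids) == 1 for g in groups)
        assert [g.patient_id for g in groups] == ["P0001", "P0002", "P0003"]

    def test_ambiguous_edge_reported_not_grouped(self):
        pairs = [self._pair("A", "B", 0.97)]
        groups, ambiguous = group_patients(pairs, ["A", "B"])
        assert len(groups) == 2
        assert [(p.sample_a, p.sample_b) for p in ambiguous] == [("A", "B")]


class TestEndToEnd:
    def _cohort(self, seed=3, n_patients=8):
        import tempfile
        from pathlib import Path

        from ctdnalink.annotate import annotate_report
        from ctdnalink.reference_db import load_reference
        from ctdnalink.report_io import load_reports_dir
        from ctdnalink.synthetic_data import SimConfig, generate_cohort

        tmp = Path(tempfile.mkdtemp())
        cfg = SimConfig(n_patients=n_patients, draws_per_patient=2, seed=seed)
        reports_dir, ref_csv, truth = generate_cohort(cfg, tmp)
        ref = load_reference(ref_csv)
        store = load_reports_dir(reports_dir)
        annotated = [annotate_report(r, ref) for r in store.reports]
        return annotated, truth

    def test_patient_recovery_perfect_on_low_noise_cohort(self):
        from sklearn.metrics import adjusted_rand_score

        annotated, truth = self._cohort()
        groups, pairs, _ = match_cohort(annotated)
        pred = {sid: g.patient_id for g in groups for sid in g.member_sample_ids}
        sids = sorted(truth.sample_to_patient)
        ari = adjusted_rand_score(
            [truth.sample_to_patient[s] for s in sids], [pred[s] for s in sids]
        )
        assert ari == 1.0
        assert not any(
            p.band is Band.MATCH
            and truth.sample_to_patient[p.sample_a] != truth.sample_to_patient[p.sample_b]
            for p in pairs
        )

    def test_output_invariant_to_input_order(self):
        annotated, _ = self._cohort(seed=5)
        g1, _, _ = match_cohort(annotated)
        g2, _, _ = match_cohort(list(reversed(annotated)))
        assert [sorted(g.member_sample_ids) for g in g1] == [
            sorted(g.member_sample_ids) for g in g2
        ]

    def test_k1_and_k2_agree(self):
        annotated, _ = self._cohort(seed=9)
        g1, _, _ = match_cohort(annotated, MatchConfig(k_clusters=1))
        g2, _, _ = match_cohort(annotated, MatchConfig(k_clusters=2))
        assert [sorted(g.member_sample_ids) for g in g1] == [
            sorted(g.member_sample_ids) for g in g2
        ]
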