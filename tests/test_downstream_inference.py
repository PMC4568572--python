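import networkx as nx
import numpy as np
import pytest

from ipactools.classification import IPACClass, IPACRecord
from ipactools.downstream_inference import (
    EvidenceSet,
    cluster_so,
    cross_sample_match,
    expression_correlation,
    inter_pac_distance,
    verify_against_evidence,
    verify_clusters,
)
from ipactools.errors import ParameterError
from ipactools.neighborhood import NeighborContext
from ipactools.pac_annotation import AnnotatedPAC, RegionCategory
from ipactools.pat_processing import PAC, CleavageSite


def so_record(pos, n_tags=3, chrom="c", strand="+", min_gene_dist=5000):
    pac = PAC(chrom, strand, pos, pos, [CleavageSite(chrom, pos, strand, n_tags)])
    ipac = AnnotatedPAC(pac, RegionCategory.INTERGENIC)
    ctx = NeighborContext(
        d5s=min_gene_dist, d3s=min_gene_dist, d5a=min_gene_dist, d3a=min_gene_dist
    )
    return IPACRecord(ipac, ctx, IPACClass.SO)


class TestInterPacDistance:
    def test_printed_inputs(self):
        assert inter_pac_distance(935, 2.17) == 431

    def test_single_pac_per_utr(self):
        assert inter_pac_distance(100, 1) == 100

    def test_zero_mean_rejected(self):
        with pytest.raises(ParameterError):
            inter_pac_distance(0, 2)
        with pytest.raises(ParameterError):
            inter_pac_distance(100, 0)


class TestClusterSO:
    def test_linkage_split(self):
        recs = [so_record(1000), so_record(1400), so_record(5000)]
        clusters, excluded = cluster_so(recs, linkage_nt=431)
        assert excluded == 0
        spans = sorted(cl.span for cl in clusters)
        assert spans == [(1000, 1400), (5000, 5000)]

    def test_near_gene_exclusion(self):
        recs = [so_record(1000, min_gene_dist=1500), so_record(9000, min_gene_dist=1999)]
        clusters, excluded = cluster_so(recs)
        assert clusters == []
        assert excluded == 2

    def test_singleton(self):
        clusters, excluded = cluster_so([so_record(1000)])
        assert len(clusters) == 1
        assert len(clusters[0].members) == 1

    def test_dominant_member_max_tags(self):
        recs = [so_record(1000, n_tags=3), so_record(1200, n_tags=9)]
        clusters, _ = cluster_so(recs, linkage_nt=431)
        assert clusters[0].dominant.ipac.pac.dominant_site == 1200

    @pytest.mark.parametrize("seed", range(30))
    def test_oracle_connected_components(self, seed):
        rng = np.random.default_rng(seed)
        positions = sorted(set(rng.integers(0, 20000, size=rng.integers(1, 50)).tolist()))
        linkage = int(rng.integers(10, 1000))
        recs = [so_record(p) for p in positions]
        clusters, _ = cluster_so(recs, linkage_nt=linkage)
        got = sorted(sorted(m.ipac.pac.dominant_site for m in c.members) for c in clusters)
        g = nx.Graph()
        g.add_nodes_from(positions)
        for i, p in enumerate(positions):
            for q in positions[i + 1 :]:
                if abs(p - q) <= linkage:
                    g.add_edge(p, q)
        assert got == sorted(sorted(c) for c in nx.connected_components(g))


class TestEvidence:
    def test_point_mode_within(self):
        ev = EvidenceSet("est", [("c", 10000, 10000, "+")], 500, "point")
        assert verify_against_evidence([("c", 10300)], ev) == [True]

    def test_interval_boundary(self):
        ev = EvidenceSet("novel", [("c", 5000, 6000, "+")], 200, "interval")
        assert verify_against_evidence([("c", 6200)], ev) == [True]
        assert verify_against_evidence([("c", 6201)], ev) == [False]

    def test_directional_downstream(self):
        ev = EvidenceSet("orf", [("c", 3000, 4000, "+")], 2000, "downstream")
        assert verify_against_evidence([("c", 5500)], ev) == [True]
        assert verify_against_evidence([("c", 2500)], ev) == [False]  # upstream

    def test_directional_minus_strand(self):
        ev = EvidenceSet("orf", [("c", 3000, 4000, "-")], 2000, "downstream")
        assert verify_against_evidence([("c", 1500)], ev) == [True]
        assert verify_against_evidence([("c", 4500)], ev) == [False]

    def test_window_monotonicity(self, rng):
        anchors = [("c", int(p), int(p) + 50, "+") for p in rng.integers(0, 50000, 20)]
        items = [("c", int(p)) for p in rng.integers(0, 50000, 100)]
        small = verify_against_evidence(items, EvidenceSet("e", anchors, 100, "interval"))
        large = verify_against_evidence(items, EvidenceSet("e", anchors, 1000, "interval"))
        assert all(l or not s for s, l in zip(small, large))

    def test_verify_clusters_marks_names(self):
        clusters, _ = cluster_so([so_record(1000)])
        ev = EvidenceSet("est", [("c", 900, 900, "+")], 500, "point")
        assert verify_clusters(clusters, ev) == 1
        assert clusters[0].verified_by == ["est"]


class TestCorrelation:
    def test_identity(self):
        r, p = expression_correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_negation(self):
        r, _ = expression_correlation([1, 2, 3, 4], [4, 3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_bivariate_normal_recovery(self):
        rng = np.random.default_rng(13)
        n, rho = 1000, 0.5
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        r, p = expression_correlation(x, y)
        assert abs(r - rho) < 0.06
        assert p < 1e-10

    def test_zero_variance_rejected(self):
        with pytest.raises(ParameterError):
            expression_correlation([1, 1, 1], [1, 2, 3])


def pacs_at(positions, strand="+", tags=None):
    return [
        PAC("c", strand, p, p, [CleavageSite("c", p, strand, (tags or {}).get(p, 3))])
        for p in positions
    ]


class TestCrossSample:
    def test_identical_sets(self):
        a = pacs_at([100, 500, 900], tags={100: 4, 500: 9, 900: 2})
        res = cross_sample_match(a, a)
        assert res.shared_fraction == 1.0
        assert res.count_correlation == pytest.approx(1.0)

    def test_disjoint_chroms(self):
        a = pacs_at([100])
        b = [PAC("d", "+", 100, 100, [CleavageSite("d", 100, "+", 3)])]
        assert cross_sample_match(a, b).shared_fraction == 0.0

    def test_boundary_at_window(self):
        a = pacs_at([1000, 3000])
        assert cross_sample_match(a, pacs_at([1050, 3050])).shared_fraction == 1.0
        assert cross_sample_match(a, pacs_at([1051, 3051])).shared_fraction == 0.0

    def test_strand_must_match(self):
        res = cross_sample_match(pacs_at([100]), pacs_at([100], strand="-"))
        assert res.shared_fraction == 0.0

    def test_one_to_one_greedy(self):
        # two A items compete for one B item: only one pair forms
        res = cross_sample_match(pacs_at([100, 120]), pacs_at([110]))
        assert len(res.shared_pairs) == 1
        assert res.shared_fraction == 0.5

    def test_asymmetry(self):
        a, b = pacs_at([100]), pacs_at([100, 500])
        assert cross_sample_match(a, b).shared_fraction == 1.0
        assert cross_sample_match(b, a).shared_fraction == 0.5
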