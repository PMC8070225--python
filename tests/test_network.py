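"""Synteny-aware cluster similarity network: filters, grouping, scoring."""

import itertools

import networkx as nx
import pytest

from smcsurvey import network as net
from smcsurvey import synthetic as syn
from smcsurvey.io import GeneModel

from conftest import make_hit, make_cluster

MBP = 1_000_000


def gene(gid, start, end, contig="ctg"):
    return GeneModel(gid, contig, start, end, "+", "M" * 100)


def pair_hit(q_start, s_start, length=300, ident=90.0, bitscore=200.0,
             qg=None, sg=None):
    qg = qg or gene(f"q@{q_start}", q_start, q_start + length)
    sg = sg or gene(f"s@{s_start}", s_start, s_start + length)
    return net.PairHit(make_hit(qg.gene_id, sg.gene_id, ident=ident,
                                bitscore=bitscore), qg, sg)


class TestFilterHits:
    def test_identity_floor(self):
        filt = net.HitFilter()
        assert net.filter_hits([make_hit(ident=29.9)], filt) == []
        assert len(net.filter_hits([make_hit(ident=30.0)], filt)) == 1

    def test_perfect_hit_retained(self):
        (h,) = net.filter_hits([make_hit(ident=100.0)], net.HitFilter())
        assert h.q_cov == h.s_cov == 100.0

    def test_bilateral_coverage(self):
        low_s_cov = make_hit(ident=90, s_end=50)   # s_cov 50
        assert net.filter_hits([low_s_cov], net.HitFilter()) == []
        unilateral = net.HitFilter(bilateral_coverage=False)
        assert len(net.filter_hits([low_s_cov], unilateral)) == 1

    def test_self_and_intra_cluster_hits_removed(self):
        hits = [make_hit("a", "a"), make_hit("a", "b"), make_hit("a", "c")]
        cluster_of = {"a": "c1", "b": "c1", "c": "c2"}
        kept = net.filter_hits(hits, net.HitFilter(), cluster_of=cluster_of)
        assert [(h.query_id, h.subject_id) for h in kept] == [("a", "c")]

    def test_mixed_threshold_count(self):
        hits = [make_hit(f"q{i}", f"s{i}") for i in range(8)]
        hits += [make_hit("q8", "s8", ident=25),         # identity fails
                 make_hit("q9", "s9", q_end=40),          # q_cov fails
                 make_hit("q10", "s10", s_end=40),        # s_cov fails
                 make_hit("q11", "s11", ident=10, q_end=30)]
        assert len(net.filter_hits(hits, net.HitFilter())) == 8

    def test_raising_identity_never_adds_edges(self, dataset, sim_hits):
        loose = net.build_network(dataset.clusters, sim_hits,
                                  net.HitFilter(min_identity=30))
        strict = net.build_network(dataset.clusters, sim_hits,
                                   net.HitFilter(min_identity=60))
        assert set(strict.edges) <= set(loose.edges)


class TestSyntenicRegions:
    def test_hits_in_small_region_form_one_group(self):
        hits = [pair_hit(0, 0), pair_hit(15_000, 12_000),
                pair_hit(38_000, 35_000)]
        groups = net.syntenic_regions(hits)
        assert [len(g) for g in groups] == [3]

    def test_gap_beyond_one_mbp_splits(self):
        hits = [pair_hit(0, 0), pair_hit(1_200_000 + 300, 1_200_000 + 300)]
        assert len(net.syntenic_regions(hits)) == 2

    def test_gap_under_one_mbp_joins(self):
        hits = [pair_hit(0, 0), pair_hit(900_000 + 300, 900_000 + 300)]
        assert len(net.syntenic_regions(hits)) == 1

    def test_boundary_exactly_one_mbp_is_inclusive(self):
        # gap measured between interval boundaries: second gene starts
        # exactly 1 Mbp after the first one ends
        hits = [pair_hit(0, 0, length=300),
                pair_hit(300 + MBP, 300 + MBP, length=300)]
        assert len(net.syntenic_regions(hits)) == 1
        hits2 = [pair_hit(0, 0, length=300),
                 pair_hit(301 + MBP, 301 + MBP, length=300)]
        assert len(net.syntenic_regions(hits2)) == 2

    def test_split_requires_gap_on_one_genome_only(self):
        hits = [pair_hit(0, 0), pair_hit(20_000, 2 * MBP)]
        assert len(net.syntenic_regions(hits)) == 2


def valid_group(hits, max_gap):
    """Independent validity predicate: scan in query order, every hit within
    max_gap of the running span on both genomes."""
    span_q = span_s = None
    for ph in sorted(hits, key=lambda p: p.query_gene.start):
        q, s = ph.query_gene, ph.subject_gene
        if span_q is None:
            span_q, span_s = (q.start, q.end), (s.start, s.end)
            continue
        gq = max(0, max(span_q[0] - q.end, q.start - span_q[1]))
        gs = max(0, max(span_s[0] - s.end, s.start - span_s[1]))
        if gq > max_gap or gs > max_gap:
            return False
        span_q = (min(span_q[0], q.start), max(span_q[1], q.end))
        span_s = (min(span_s[0], s.start), max(span_s[1], s.end))
    return True


def leftmost_longest_partition(hits, max_gap):
    """Enumerate all contiguous partitions of the query-sorted hits and pick
    the one that extends each group as far as possible left-to-right."""
    ordered = sorted(hits, key=lambda p: (p.query_gene.start,
                                          p.subject_gene.start,
                                          p.hit.subject_id))
    n = len(ordered)
    best = None
    for cuts in itertools.product([False, True], repeat=max(0, n - 1)):
        parts, cur = [], [ordered[0]]
        for i, cut in enumerate(cuts):
            if cut:
                parts.append(cur)
                cur = []
            cur.append(ordered[i + 1])
        parts.append(cur)
        if not all(valid_group(p, max_gap) for p in parts):
            continue
        key = tuple(len(p) for p in parts)
        # leftmost-longest: lexicographically maximal group sizes
        if best is None or key > best[0]:
            best = (key, parts)
    return best[1]


@pytest.mark.parametrize("seed", range(30))
def test_grouping_matches_exhaustive_enumeration(seed, rng):
    import numpy as np
    r = np.random.default_rng(seed)
    n = int(r.integers(1, 9))
    hits = []
    for k in range(n):
        qs = int(r.integers(0, 3 * MBP))
        ss = int(r.integers(0, 3 * MBP))
        hits.append(pair_hit(qs, ss, length=int(r.integers(200, 2000))))
    max_gap = int(r.choice([50_000, 500_000, MBP]))
    got = net.syntenic_regions(hits, max_gap)
    expect = leftmost_longest_partition(hits, max_gap)
    assert [[p.hit.query_id for p in g] for g in got] == \
        [[p.hit.query_id for p in g] for g in expect]


class TestScorePair:
    def three_gene_pair(self, reverse=False, ident=100.0):
        hits = []
        order = [2, 1, 0] if reverse else [0, 1, 2]
        for qi, si in zip(range(3), order):
            qg = gene(f"qa_g{qi}", 1000 * qi, 1000 * qi + 300)
            sg = gene(f"sb_g{si}", 1000 * si, 1000 * si + 300)
            hits.append(net.PairHit(
                make_hit(qg.gene_id, sg.gene_id, ident=ident), qg, sg))
        return hits

    def test_identical_clusters_hand_score(self):
        edge = net.score_pair(self.three_gene_pair(), net.HitFilter())
        assert edge.n_hit_genes == 3
        assert edge.synteny_score == 3
        assert edge.score == pytest.approx(4.5)  # 3 + 0.5 * 3
        assert edge.weight == pytest.approx(100.0)

    def test_reversed_subject_order_still_colinear(self):
        edge = net.score_pair(self.three_gene_pair(reverse=True),
                              net.HitFilter())
        assert edge.synteny_score == 3

    def test_single_match_mode(self):
        hits = self.three_gene_pair()[:1]
        assert net.score_pair(hits, net.HitFilter(min_hits=1)) is not None
        assert net.score_pair(hits, net.HitFilter(min_hits=2)) is None

    def test_no_hits_gives_none(self):
        assert net.score_pair([], net.HitFilter()) is None

    def test_score_symmetry_under_transposition(self):
        hits = self.three_gene_pair(ident=85.0)
        transposed = [net.PairHit(
            make_hit(ph.hit.subject_id, ph.hit.query_id,
                     ident=ph.hit.pct_identity,
                     bitscore=ph.hit.bitscore),
            ph.subject_gene, ph.query_gene) for ph in hits]
        a = net.score_pair(hits, net.HitFilter())
        b = net.score_pair(transposed, net.HitFilter())
        assert (a.n_hit_genes, a.score, a.weight) == \
               (b.n_hit_genes, b.score, b.weight)

    def test_synteny_score_bounded_by_hit_genes(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 7))
            hits = [pair_hit(int(rng.integers(0, 50_000)),
                             int(rng.integers(0, 50_000)))
                    for _ in range(n)]
            edge = net.score_pair(hits, net.HitFilter())
            assert edge.synteny_score <= edge.n_hit_genes <= len(hits)


class TestBuildNetwork:
    def test_single_cluster_no_edges(self):
        c = make_cluster("A__1_glim", [("A__1_glim_p1", 0, 300, "M" * 100)])
        G = net.build_network([c], [])
        assert G.number_of_nodes() == 1
        assert G.number_of_edges() == 0

    def test_planted_groups_become_components(self):
        cfg = syn.DatasetConfig(
            n_assemblies=5,
            groups=[syn.GroupSpec("nrps", 4), syn.GroupSpec("siderophore", 4),
                    syn.GroupSpec("terpene_ggps", 4),
                    syn.GroupSpec("pks", 4),
                    syn.GroupSpec("nrps_like_nps", 4)])
        ds = syn.generate_dataset(cfg, seed=21)
        hits = syn.generate_hit_table(ds, seed=21, between_rate=0.3)
        G = net.build_network(ds.clusters, hits)
        comps = {frozenset(c) for c in nx.connected_components(G)}
        truth_groups = {}
        for cid, g in ds.truth.group_of.items():
            truth_groups.setdefault(g, set()).add(cid)
        assert comps == {frozenset(v) for v in truth_groups.values()}

    def test_every_edge_satisfies_thresholds(self, dataset, sim_hits):
        filt = net.HitFilter()
        G = net.build_network(dataset.clusters, sim_hits, filt)
        for _, _, d in G.edges(data=True):
            assert d["weight"] >= filt.min_identity
            assert d["n_hit_genes"] >= filt.min_hits
            assert d["synteny_score"] <= d["n_hit_genes"]

    def test_min_hits_one_is_superset_of_two(self, dataset, sim_hits):
        single = net.build_network(dataset.clusters, sim_hits,
                                   net.HitFilter(min_hits=1))
        legacy = net.build_network(dataset.clusters, sim_hits,
                                   net.HitFilter(min_hits=2))
        assert set(legacy.edges) <= set(single.edges)

    def test_single_gene_regions_connect_only_in_single_match_mode(self):
        cfg = syn.DatasetConfig(
            n_assemblies=4,
            groups=[syn.GroupSpec("siderophore", 4)])
        ds = syn.generate_dataset(cfg, seed=5)
        # siderophore regions: keep only the core gene to force single hits
        for c in ds.clusters:
            del c.genes[1:]
        hits = syn.generate_hit_table(ds, seed=5)
        single = net.build_network(ds.clusters, hits, net.HitFilter(min_hits=1))
        legacy = net.build_network(ds.clusters, hits, net.HitFilter(min_hits=2))
        assert single.number_of_edges() > 0
        assert legacy.number_of_edges() == 0


class TestComponentSummary:
    def test_empty_graph_counts_singletons(self):
        G = nx.Graph()
        G.add_nodes_from(["a", "b", "c"])
        table = net.component_summary(G)
        assert len(table) == 3
        assert table["singleton"].all()

    def test_adding_edge_merges_two_components(self):
        G = nx.Graph()
        G.add_nodes_from("abcd")
        G.add_edge("a", "b")
        before = len(net.component_summary(G))
        G.add_edge("b", "c")
        assert len(net.component_summary(G)) == before - 1

    def test_type_composition(self):
        G = nx.Graph()
        G.add_node("x", assigned_type="NRPS")
        G.add_node("y", assigned_type="terpene")
        G.add_edge("x", "y")
        table = net.component_summary(G)
        assert table.loc[0, "types"] == "NRPS,terpene"


def test_graphml_and_edge_list_export(tmp_path, dataset, sim_hits):
    G = net.build_network(dataset.clusters, sim_hits)
    net.write_graphml(G, tmp_path / "g.graphml")
    back = nx.read_graphml(tmp_path / "g.graphml")
    assert back.number_of_nodes() == G.number_of_nodes()
    assert back.number_of_edges() == G.number_of_edges()
    net.write_edge_list(G, tmp_path / "edges.tsv")
    lines = (tmp_path / "edges.tsv").read_text().splitlines()
    assert len(lines) == G.number_of_edges() + 1
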