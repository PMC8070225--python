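"""Synteny-aware SMC similarity network.

All-vs-all homology hits between proteins of different candidate clusters
are filtered (identity >= 30%, bilateral coverage >= 60% by default),
grouped into syntenic regions (boundary gap <= 1 Mbp on both genomes) and
scored per cluster pair: score = n_hit_genes + synteny_weight * length of
the best colinear hit chain.  Single-match mode (min_hits = 1) captures the
frequent case of regions sharing only one gene — e.g. siderophore regions
consisting of a single IucA/IucC homologue; legacy behaviour requires two
syntenic hits.  Edges are weighted by the average percent identity over the
qualifying hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from smcsurvey.io import ClusterRegion, GeneModel, SimilarityHit
from smcsurvey.align import toy_local_align  # re-export  # noqa: F401


@dataclass(frozen=True)
class HitFilter:
    """Thresholds for admitting hits and emitting edges."""

    min_identity: float = 30.0
    min_coverage: float = 60.0
    max_boundary_gap: int = 1_000_000
    min_hits: int = 1            # 2 = legacy mode (no single-match edges)
    synteny_weight: float = 0.5
    bilateral_coverage: bool = True

    def __post_init__(self) -> None:
        if min(self.min_identity, self.min_coverage, self.max_boundary_gap,
               self.min_hits, self.synteny_weight) < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class PairHit:
    """A similarity hit lifted to gene context on both clusters."""

    hit: SimilarityHit
    query_gene: GeneModel
    subject_gene: GeneModel


@dataclass
class ClusterEdge:
    cluster_a: str
    cluster_b: str
    hits: list[PairHit] = field(default_factory=list)
    n_hit_genes: int = 0
    synteny_score: int = 0
    score: float = 0.0
    weight: float = 0.0


def filter_hits(hits: list[SimilarityHit], filt: HitFilter,
                cluster_of: dict[str, str] | None = None
                ) -> list[SimilarityHit]:
    """Retain hits clearing identity and coverage thresholds.

    Self-hits are always removed; with ``cluster_of`` supplied, intra-cluster
    hits are removed too.  With ``bilateral_coverage`` the 60% floor applies
    to query and subject coverage; otherwise to the query side only.
    """
    kept = []
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if cluster_of is not None and \
                cluster_of.get(h.query_id) == cluster_of.get(h.subject_id):
            continue
        if h.pct_identity < filt.min_identity or h.q_cov < filt.min_coverage:
            continue
        if filt.bilateral_coverage and h.s_cov < filt.min_coverage:
            continue
        kept.append(h)
    return kept


def _interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Distance between two genomic intervals; 0 when they overlap/touch."""
    if b_start >= a_end:
        return b_start - a_end
    if a_start >= b_end:
        return a_start - b_end
    return 0


def syntenic_regions(pair_hits: list[PairHit],
                     max_boundary_gap: int = 1_000_000) -> list[list[PairHit]]:
    """Group a cluster pair's hits into syntenic regions.

    Hits are scanned in query-gene order; a hit joins the current group iff
    the gap between the group's span boundary and the hit's gene interval is
    <= ``max_boundary_gap`` on BOTH genomes (boundary behaviour is
    inclusive: a gap of exactly the maximum still joins).
    """
    if not pair_hits:
        return []
    ordered = sorted(pair_hits,
                     key=lambda ph: (ph.query_gene.start, ph.subject_gene.start,
                                     ph.hit.subject_id))
    groups: list[list[PairHit]] = []
    span_q: tuple[int, int] | None = None
    span_s: tuple[int, int] | None = None
    for ph in ordered:
        qg, sg = ph.query_gene, ph.subject_gene
        if span_q is not None and \
                _interval_gap(*span_q, qg.start, qg.end) <= max_boundary_gap and \
                _interval_gap(*span_s, sg.start, sg.end) <= max_boundary_gap:
            groups[-1].append(ph)
            span_q = (min(span_q[0], qg.start), max(span_q[1], qg.end))
            span_s = (min(span_s[0], sg.start), max(span_s[1], sg.end))
        else:
            groups.append([ph])
            span_q = (qg.start, qg.end)
            span_s = (sg.start, sg.end)
    return groups


def _longest_colinear_chain(group: list[PairHit]) -> int:
    """Longest chain of hits colinear in gene order on both clusters.

    Strand-aware: the chain may run in forward or reversed subject order.
    O(n^2) longest-increasing-subsequence on (query start, subject start).
    """
    pairs = sorted((ph.query_gene.start, ph.subject_gene.start)
                   for ph in group)
    n = len(pairs)
    best = 0
    for direction in (1, -1):
        lis = [1] * n
        for i in range(n):
            for j in range(i):
                if pairs[j][0] < pairs[i][0] and \
                        direction * pairs[j][1] < direction * pairs[i][1]:
                    lis[i] = max(lis[i], lis[j] + 1)
        best = max(best, max(lis, default=0))
    return best


def score_pair(pair_hits: list[PairHit],
               filt: HitFilter) -> ClusterEdge | None:
    """Score one unordered cluster pair from its (already filtered) hits.

    The best syntenic group (most hits; ties by summed bitscore) supplies
    n_hit_genes (distinct query genes), the colinear-chain synteny score and
    the identity-averaged edge weight.  No edge when n_hit_genes falls below
    ``min_hits``.
    """
    if not pair_hits:
        return None
    groups = syntenic_regions(pair_hits, filt.max_boundary_gap)
    best = max(groups,
               key=lambda g: (len(g), sum(ph.hit.bitscore for ph in g)))
    n_hit_genes = len({ph.query_gene.gene_id for ph in best})
    if n_hit_genes < filt.min_hits:
        return None
    synteny = _longest_colinear_chain(best)
    edge = ClusterEdge(
        cluster_a="", cluster_b="", hits=best,
        n_hit_genes=n_hit_genes,
        synteny_score=synteny,
        score=n_hit_genes + filt.synteny_weight * synteny,
        weight=sum(ph.hit.pct_identity for ph in best) / len(best),
    )
    return edge


def build_network(clusters: list[ClusterRegion], all_hits: list[SimilarityHit],
                  filt: HitFilter | None = None) -> nx.Graph:
    """All-vs-all SMC similarity network.

    Nodes are cluster ids with type/family/assembly attributes; one edge per
    unordered cluster pair whose best syntenic hit group passes the filter.
    """
    if filt is None:
        filt = HitFilter()
    gene_of: dict[str, tuple[str, GeneModel]] = {}
    for c in clusters:
        for g in c.genes:
            gene_of[g.gene_id] = (c.cluster_id, g)
    cluster_of = {p: cid for p, (cid, _) in gene_of.items()}
    hits = filter_hits(all_hits, filt, cluster_of=cluster_of)

    by_pair: dict[tuple[str, str], list[PairHit]] = {}
    for h in hits:
        if h.query_id not in gene_of or h.subject_id not in gene_of:
            continue
        ca, qg = gene_of[h.query_id]
        cb, sg = gene_of[h.subject_id]
        if ca >= cb:  # one orientation per unordered pair
            continue
        by_pair.setdefault((ca, cb), []).append(PairHit(h, qg, sg))

    G = nx.Graph()
    for c in clusters:
        G.add_node(c.cluster_id,
                   assigned_type=c.assigned_type,
                   assembly=c.assembly_id,
                   core_families=",".join(sorted(c.core_families)),
                   n_genes=len(c.genes))
    for (ca, cb), phs in sorted(by_pair.items()):
        edge = score_pair(phs, filt)
        if edge is None:
            continue
        G.add_edge(ca, cb, weight=edge.weight, score=edge.score,
                   n_hit_genes=edge.n_hit_genes,
                   synteny_score=edge.synteny_score)
    return G


def component_summary(G: nx.Graph) -> pd.DataFrame:
    """Connected components with size, type composition and singleton flag."""
    rows = []
    components = sorted(nx.connected_components(G),
                        key=lambda comp: (-len(comp), min(comp)))
    for i, comp in enumerate(components, start=1):
        types = sorted({G.nodes[n].get("assigned_type", "unassigned")
                        for n in comp})
        rows.append({
            "component_id": i,
            "size": len(comp),
            "members": ",".join(sorted(comp)),
            "types": ",".join(types),
            "singleton": len(comp) == 1,
        })
    return pd.DataFrame(rows, columns=["component_id", "size", "members",
                                       "types", "singleton"])


def write_graphml(G: nx.Graph, path) -> None:
    nx.write_graphml(G, str(path))


def write_edge_list(G: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_a\tcluster_b\tweight\tscore\tn_hit_genes\t"
                 "synteny_score\n")
        for a, b, data in sorted(G.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['weight']:.4f}\t{data['score']:.4f}\t"
                     f"{data['n_hit_genes']}\t{data['synteny_score']}\n")
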