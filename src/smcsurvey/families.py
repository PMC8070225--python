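"""Protein families by the Markov Cluster Algorithm (MCL).

Proteins encoded in candidate SMCs are nodes of an undirected similarity
graph whose edges come from homology hits below an admission E-value
(default 1e-10).  Edge weights are the capped negative decimal logarithm of
the E-value.  MCL alternates expansion (matrix squaring) with inflation
(entrywise power and column renormalisation) until the stochastic matrix
converges; families are read off the attractor rows.  A silhouette-width
grid sampler supports the choice of admission threshold and inflation
(the survey's operating point is E = 1e-10, I = 1.55).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from smcsurvey.io import SimilarityHit

WEIGHT_CAP = 200.0  # -log10 E-value cap; handles E = 0


@dataclass
class SimilarityGraph:
    """Undirected weighted protein-similarity graph.

    Edge weight = min(cap, -log10(evalue)); reciprocal hits keep the larger
    weight.  No self-edges are stored (MCL adds its own self-loops).
    """

    nodes: list[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    e_threshold: float = 1e-10

    def weight(self, a: str, b: str) -> float:
        return self.edges.get((min(a, b), max(a, b)), 0.0)

    def distance(self, a: str, b: str) -> float:
        """d = 1 - weight/cap, 1.0 for non-edges, 0.0 on the diagonal."""
        if a == b:
            return 0.0
        w = self.weight(a, b)
        return 1.0 if w == 0.0 else 1.0 - w / WEIGHT_CAP


@dataclass
class ProteinFamily:
    """An MCL cluster of proteins, identified by its size rank."""

    family_id: str
    members: list[str]
    n_smcs: int = 0
    label: str = ""


@dataclass
class ParameterSample:
    e_threshold: float
    inflation: float
    mean_silhouette: float | None
    n_clusters: int
    flagged: bool = False


def evalue_weight(evalue: float) -> float:
    return min(WEIGHT_CAP, -np.log10(max(evalue, 1e-200)))


def build_similarity_graph(hits: list[SimilarityHit],
                           e_threshold: float = 1e-10) -> SimilarityGraph:
    """Admit hits at or below the E-value threshold; deduplicate per
    unordered pair keeping the best (largest) weight; drop self-hits."""
    nodes: set[str] = set()
    edges: dict[tuple[str, str], float] = {}
    for h in hits:
        nodes.add(h.query_id)
        nodes.add(h.subject_id)
        if h.query_id == h.subject_id or h.evalue > e_threshold:
            continue
        key = (min(h.query_id, h.subject_id), max(h.query_id, h.subject_id))
        w = evalue_weight(h.evalue)
        if w > edges.get(key, 0.0):
            edges[key] = w
    return SimilarityGraph(nodes=sorted(nodes), edges=edges,
                           e_threshold=e_threshold)


def mcl(graph: SimilarityGraph, inflation: float = 1.55,
        self_loop: float | None = None, prune_below: float = 1e-5,
        tol: float = 1e-6, max_iter: int = 100) -> list[ProteinFamily]:
    """Run MCL on the similarity graph and return the family partition.

    ``self_loop=None`` gives every node a loop equal to its maximum incident
    edge weight (1.0 for isolated nodes).  After convergence each node is
    assigned to the attractor (node with retained diagonal mass) holding the
    largest share of its column, ties to the smallest attractor index, so the
    output is always a partition.  Deterministic: no randomness anywhere.
    """
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    n = len(graph.nodes)
    if n == 0:
        return []
    index = {node: i for i, node in enumerate(graph.nodes)}
    M = np.zeros((n, n))
    for (a, b), w in graph.edges.items():
        M[index[a], index[b]] = w
        M[index[b], index[a]] = w
    if self_loop is None:
        loops = M.max(axis=0)
        loops[loops == 0.0] = 1.0
    else:
        loops = np.full(n, float(self_loop))
    np.fill_diagonal(M, loops)
    M /= M.sum(axis=0, keepdims=True)

    for _ in range(max_iter):
        prev = M
        M = M @ M                       # expansion
        M = np.power(M, inflation)      # inflation
        M /= M.sum(axis=0, keepdims=True)
        M[M < prune_below] = 0.0        # prune + renormalise
        M /= M.sum(axis=0, keepdims=True)
        if np.abs(M - prev).max() < tol:
            break

    attractors = np.flatnonzero(np.diag(M) > prune_below)
    if attractors.size == 0:           # degenerate; should not happen
        attractors = np.arange(n)
    # node -> attractor with the largest value; ties -> smallest index
    assignment = attractors[np.argmax(M[attractors, :], axis=0)]
    # attractors that tie for a shared node must land in one family:
    # canonicalise by repeatedly mapping each attractor to its own assignment
    canon = {int(a): int(assignment[a]) for a in attractors}
    def root(a: int) -> int:
        seen = set()
        while canon.get(a, a) != a and a not in seen:
            seen.add(a)
            a = canon.get(a, a)
        return a
    groups: dict[int, list[str]] = {}
    for j in range(n):
        groups.setdefault(root(int(assignment[j])), []).append(graph.nodes[j])
    families = sorted(groups.values(), key=lambda m: (-len(m), min(m)))
    width = max(4, len(str(len(families))))
    return [
        ProteinFamily(family_id=f"MCL{i + 1:0{width}d}", members=sorted(m))
        for i, m in enumerate(families)
    ]


def partition_labels(families: list[ProteinFamily]) -> dict[str, int]:
    return {p: i for i, fam in enumerate(families) for p in fam.members}


def mean_silhouette(graph: SimilarityGraph,
                    families: list[ProteinFamily]) -> float | None:
    """Mean silhouette width of the partition under d = 1 - weight/cap.

    Scored only over points in clusters of size >= 2; the nearest-other-
    cluster term b(i) ranges over every other cluster including singletons.
    Returns None when fewer than two clusters of size >= 2 exist.
    """
    eligible_clusters = [f for f in families if len(f.members) >= 2]
    if len(eligible_clusters) < 2:
        return None
    nodes = graph.nodes
    idx = {p: i for i, p in enumerate(nodes)}
    n = len(nodes)
    D = np.ones((n, n))
    np.fill_diagonal(D, 0.0)
    for (a, b), w in graph.edges.items():
        D[idx[a], idx[b]] = D[idx[b], idx[a]] = 1.0 - w / WEIGHT_CAP
    member_idx = [np.array([idx[p] for p in f.members]) for f in families]
    scores = []
    for ci, f in enumerate(families):
        if len(f.members) < 2:
            continue
        own = member_idx[ci]
        for i in own:
            a_i = D[i, own].sum() / (len(own) - 1)
            b_i = min(D[i, other].mean()
                      for cj, other in enumerate(member_idx) if cj != ci)
            scores.append((b_i - a_i) / max(a_i, b_i))
    return float(np.mean(scores))


def silhouette_sample(hits: list[SimilarityHit], thresholds: list[float],
                      inflations: list[float],
                      **mcl_kwargs) -> list[ParameterSample]:
    """Exhaustive grid evaluation of (E-threshold, inflation) pairs."""
    if not thresholds or not inflations:
        raise ValueError("parameter grid must be non-empty")
    samples = []
    for e in thresholds:
        graph = build_similarity_graph(hits, e_threshold=e)
        for i in inflations:
            fams = mcl(graph, inflation=i, **mcl_kwargs)
            sil = mean_silhouette(graph, fams)
            samples.append(ParameterSample(
                e_threshold=e, inflation=i, mean_silhouette=sil,
                n_clusters=len(fams), flagged=sil is None))
    return samples


ANNOTATABLE_CATEGORIES = frozenset(
    {"biosynthetic", "biosynthetic-additional", "transporter"})


def name_and_annotate(families: list[ProteinFamily],
                      ref_hits: list[tuple[SimilarityHit, str]] | None = None,
                      cluster_of: dict[str, str] | None = None,
                      min_dual_cov: float = 50.0,
                      major_threshold: int = 10) -> list[ProteinFamily]:
    """Attach SMC counts and annotation labels to size-ranked families.

    Families represented in at least ``major_threshold`` candidate SMCs are
    always labelled (reference consensus, or "unlabelled-major").  Smaller
    families of >= 2 members are labelled only when some reference hit shows
    more than ``min_dual_cov``% coverage of both query and hit protein and
    carries a biosynthetic / biosynthetic-additional / transporter category.
    ``ref_hits`` pairs each hit with its category or reference label string.
    """
    hits_by_query: dict[str, list[tuple[SimilarityHit, str]]] = {}
    for h, cat in (ref_hits or []):
        hits_by_query.setdefault(h.query_id, []).append((h, cat))
    for fam in families:
        if cluster_of is not None:
            fam.n_smcs = len({cluster_of[p] for p in fam.members
                              if p in cluster_of})
        qualifying: list[tuple[float, str]] = []
        for p in fam.members:
            for h, cat in hits_by_query.get(p, []):
                if h.q_cov > min_dual_cov and h.s_cov > min_dual_cov \
                        and cat in ANNOTATABLE_CATEGORIES:
                    qualifying.append((h.bitscore, f"{cat}:{h.subject_id}"))
        if fam.n_smcs >= major_threshold:
            fam.label = max(qualifying)[1] if qualifying else "unlabelled-major"
        elif len(fam.members) >= 2 and qualifying:
            fam.label = max(qualifying)[1]
    return families


def write_family_table(families: list[ProteinFamily], path,
                       cluster_of: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tprotein_id\tcluster_id\tlabel\n")
        for fam in families:
            for p in fam.members:
                cl = cluster_of.get(p, "") if cluster_of else ""
                fh.write(f"{fam.family_id}\t{p}\t{cl}\t{fam.label}\n")


def write_abc_edges(graph: SimilarityGraph, path) -> None:
    """ABC edge-list export (node, node, weight) for the reference MCL tool."""
    with open(path, "w") as fh:
        for (a, b), w in sorted(graph.edges.items()):
            fh.write(f"{a}\t{b}\t{w:.6g}\n")
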