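"""End-to-end SMC survey pipeline: ingest -> curate/type -> families ->
network -> Alien Index -> reports.

Every stage is an importable library call; :func:`run_pipeline` strings
them together, writes all artifact tables next to each other and returns a
:class:`RunReport` with per-stage record counts.  The pipeline is
deterministic for fixed inputs and configuration — reruns produce
byte-identical TSV outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from smcsurvey import __version__
from smcsurvey import alien_index as ai
from smcsurvey import families as fam
from smcsurvey import io as sio
from smcsurvey import network as net
from smcsurvey import typing_rules as tr

logger = logging.getLogger(__name__)

# Ordered, most-specific-first domain signatures for labelling MCL families
# with the presence/absence-matrix family names.  SQS_NDUF6 uses a
# package-defined "NDUF6" marker token (no public accession is established
# for that squalene-synthase subfamily).
FAMILY_SIGNATURES: tuple[tuple[str, frozenset[str]], ...] = (
    ("PKS-NRPS", frozenset({tr.PF_KS_N, tr.PF_KS_C, tr.PF_AMP_BINDING,
                            tr.PF_CONDENSATION, tr.PF_PP_BINDING})),
    ("NRPS", frozenset({tr.PF_AMP_BINDING, tr.PF_CONDENSATION,
                        tr.PF_PP_BINDING})),
    ("LYS2", frozenset({tr.PF_AMP_BINDING, tr.PF_PP_BINDING,
                        tr.PF_NAD_BINDING_4})),
    ("FAAL", frozenset({tr.PF_AMP_BINDING, tr.PF_PP_BINDING, tr.PF_FAAL_C})),
    ("PKS", frozenset({tr.PF_KS_N, tr.PF_KS_C})),
    ("SQS_NDUF6", frozenset({tr.PF_SQS_PSY, "NDUF6"})),
    ("NPS", frozenset({tr.PF_AMP_BINDING, tr.PF_PP_BINDING})),
    ("SID", frozenset({tr.PF_IUCA_IUCC})),
    ("SQS", frozenset({tr.PF_SQS_PSY})),
    ("GGPS", frozenset({tr.PF_POLYPRENYL_SYNT})),
    ("ERG7", frozenset({tr.PF_SQHOP_N})),
    ("TS2", frozenset({tr.IPR_TS2})),
    ("carRA_1", frozenset({tr.TIGR_LCPS})),
    ("carRA_2", frozenset({tr.IPR_LCPS})),
)


def core_family_map(member_groups: list[list[str]],
                    hits: list[sio.DomainHit]) -> dict[str, str]:
    """Label protein groups (e.g. MCL families) with core-family names by
    their pooled domain content; returns protein -> family label for every
    protein in a labelled group."""
    by_protein: dict[str, set[str]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, set()).add(h.accession)
    labels: dict[str, str] = {}
    for members in member_groups:
        pooled = set().union(*(by_protein.get(p, set()) for p in members)) \
            if members else set()
        for name, signature in FAMILY_SIGNATURES:
            if signature <= pooled:
                for p in members:
                    labels[p] = name
                break
    return labels


@dataclass
class RunConfig:
    """All pipeline inputs and thresholds.

    Defaults are the survey's operating point: MCL admission E-value 1e-10
    and inflation 1.55; network thresholds 30% identity, 60% coverage,
    1 Mbp boundary gap, single-match edges allowed; Alien Index admission
    E-value 1e-05.
    """

    regions: str = ""            # GenBank file or directory of *.gbk
    domain_table: str = ""       # generic domain TSV
    similarity_table: str = ""   # 14-column BLAST-style tabular
    taxonomic_hits: str = ""     # optional group-labelled hit TSV
    adenylpred_table: str = ""   # optional substrate-class predictions
    out_dir: str = "smc_out"
    e_threshold: float = 1e-10
    inflation: float = 1.55
    min_identity: float = 30.0
    min_coverage: float = 60.0
    max_boundary_gap: int = 1_000_000
    min_hits: int = 1
    synteny_weight: float = 0.5
    e_max: float = 1e-05
    seed: int = 0


@dataclass
class RunReport:
    counts: dict[str, int] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    version: str = __version__
    wall_time_s: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _read_regions(path: str) -> list[sio.ClusterRegion]:
    p = Path(path)
    if p.is_dir():
        clusters = []
        for f in sorted(p.glob("*.gbk")) + sorted(p.glob("*.gb")):
            clusters.extend(sio.read_cluster_genbank(f))
        return clusters
    return sio.read_cluster_genbank(p)


def ingest_adenylpred(path, known_proteins: set[str] | None = None
                      ) -> dict[str, str]:
    """Read AdenylPred-style substrate-class predictions (TSV with
    protein_id and predicted class columns); predictions for proteins
    outside the dataset are dropped with a logged count."""
    classes: dict[str, str] = {}
    unknown = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise sio.ParseError(f"malformed AdenylPred table {path}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise sio.ParseError(f"malformed AdenylPred row: {line!r}")
            pid, cls = parts[0], parts[1]
            if known_proteins is not None and pid not in known_proteins:
                unknown += 1
                continue
            classes[pid] = cls
    if unknown:
        logger.info("AdenylPred: %d predictions for unknown proteins ignored",
                    unknown)
    return classes


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage and write all artifacts under ``config.out_dir``."""
    t0 = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # -- ingest ------------------------------------------------------------
    stage = "ingest"
    try:
        clusters = _read_regions(config.regions) if config.regions else []
        domain_hits = sio.read_domain_table(config.domain_table) \
            if config.domain_table else []
        sim_hits = sio.read_similarity_table(config.similarity_table) \
            if config.similarity_table else []
        counts["clusters_in"] = len(clusters)
        counts["domain_hits"] = len(domain_hits)
        counts["similarity_hits"] = len(sim_hits)

        # -- typing / curation --------------------------------------------
        stage = "typing"
        rules = tr.default_rule_table()
        assignments = [tr.assign_type(c, domain_hits, rules) for c in clusters]
        retained_a, rejected_a = tr.curate(assignments, domain_hits)
        tr.write_typing_table(retained_a + rejected_a, out / "typing.tsv")
        retained_ids = {a.cluster_id for a in retained_a}
        by_id = {a.cluster_id: a for a in retained_a}
        curated = [c for c in clusters if c.cluster_id in retained_ids]
        for c in curated:
            c.assigned_type = by_id[c.cluster_id].primary_type
            c.hybrid_types = set(by_id[c.cluster_id].hybrid_types)
        counts["clusters_retained"] = len(curated)
        counts["clusters_rejected"] = len(rejected_a)

        # -- protein families ---------------------------------------------
        stage = "families"
        curated_proteins = {p for c in curated for p in c.protein_ids}
        cluster_of = {p: c.cluster_id for c in curated for p in c.protein_ids}
        fam_hits = [h for h in sim_hits
                    if h.query_id in curated_proteins
                    and h.subject_id in curated_proteins]
        graph = fam.build_similarity_graph(fam_hits,
                                           e_threshold=config.e_threshold)
        for p in sorted(curated_proteins - set(graph.nodes)):
            graph.nodes.append(p)
        graph.nodes.sort()
        families = fam.mcl(graph, inflation=config.inflation)
        families = fam.name_and_annotate(families, cluster_of=cluster_of)
        fam.write_family_table(families, out / "families.tsv",
                               cluster_of=cluster_of)
        fam.write_abc_edges(graph, out / "similarity_edges.abc")
        counts["families"] = len(families)

        family_map = core_family_map([f.members for f in families],
                                     domain_hits)
        for c in curated:
            c.core_families = {family_map[p] for p in c.protein_ids
                               if p in family_map}
        matrix = tr.core_family_matrix(curated, family_map)
        matrix.to_csv(out / "core_family_matrix.tsv", sep="\t")

        # -- similarity network -------------------------------------------
        stage = "network"
        filt = net.HitFilter(
            min_identity=config.min_identity,
            min_coverage=config.min_coverage,
            max_boundary_gap=config.max_boundary_gap,
            min_hits=config.min_hits,
            synteny_weight=config.synteny_weight)
        G = net.build_network(curated, sim_hits, filt)
        net.write_graphml(G, out / "network.graphml")
        net.write_edge_list(G, out / "network_edges.tsv")
        summary = net.component_summary(G)
        summary.to_csv(out / "components.tsv", sep="\t", index=False)
        counts["edges"] = G.number_of_edges()
        counts["components"] = len(summary)

        # -- Alien Index ----------------------------------------------------
        stage = "alien_index"
        if config.taxonomic_hits:
            tax_hits = ai.read_taxonomic_hits(config.taxonomic_hits)
            records = ai.ai_records(tax_hits, sorted(curated_proteins),
                                    e_max=config.e_max)
            for c in curated:
                c.avg_AI, c.avg_AI_core = ai.cluster_ai(c, records, family_map)
            ai.write_ai_table(records, out / "alien_index.tsv")
            ai.write_cluster_ai_table(curated, out / "cluster_ai.tsv")
            counts["ai_records"] = len(records)

        # -- optional substrate-class merge ---------------------------------
        if config.adenylpred_table:
            classes = ingest_adenylpred(config.adenylpred_table,
                                        known_proteins=curated_proteins)
            with open(out / "adenylpred_classes.tsv", "w") as fh:
                fh.write("protein_id\tfamily_id\tpredicted_class\n")
                fam_of = {p: f.family_id for f in families for p in f.members}
                for p in sorted(classes):
                    fh.write(f"{p}\t{fam_of.get(p, '')}\t{classes[p]}\n")
            counts["adenylpred_merged"] = len(classes)

        sio.write_cluster_table(curated, out / "clusters.tsv")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed: {exc}") from exc

    report = RunReport(
        counts=counts,
        parameters={k: v for k, v in asdict(config).items()},
        wall_time_s=round(time.monotonic() - t0, 3),
    )
    report.to_json(out / "run_report.json")
    return report
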