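"""Rule-based assignment of SMC types from protein-domain content.

A cluster's type is decided purely from the union of domain accessions over
its member proteins.  Each :class:`TypingRule` is a conjunction of any-of
accession sets (``all_of``) with an optional veto set (``none_of``); among
all satisfied rules the highest-priority one becomes the primary type and
the rest become hybrid types.  Curation rejects candidates whose only
signature is the 4'-phosphopantetheinyl transferase domain (fatty-acid
synthesis, not secondary metabolism) and candidates with no biosynthetic
signature at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from smcsurvey.io import ClusterRegion, DomainHit

# Pfam/TIGRFAM/InterPro accessions for the signature domains.
PF_AMP_BINDING = "PF00501"      # adenylate-forming (AMP-binding)
PF_PP_BINDING = "PF00550"       # phosphopantetheine attachment site
PF_NAD_BINDING_4 = "PF07993"    # male sterility protein / reductase
PF_CONDENSATION = "PF00668"     # condensation (C) domain
PF_THIOESTERASE = "PF00975"     # thioesterase
PF_IUCA_IUCC = "PF04183"        # NIS siderophore synthase hallmark
PF_FHUF = "PF06276"             # FhuF, corroborating siderophore domain
PF_DUF692 = "PF05114"           # bacteriocin-associated DUF692
PF_ACPS = "PF01648"             # 4'-phosphopantetheinyl transferase (FAS-like)
PF_POLYPRENYL_SYNT = "PF00348"  # prenyl-diphosphate synthase (GPPS/GGPS)
PF_SQS_PSY = "PF00494"          # squalene/phytoene synthase
PF_AMINO_OXIDASE = "PF01593"    # phytoene desaturase (amino-oxidase fold)
PF_KS_N = "PF00109"             # ketoacyl synthase N
PF_KS_C = "PF02801"             # ketoacyl synthase C
PF_SQHOP_N = "PF13249"          # squalene-hopene cyclase N (ERG7-like)
PF_SQHOP_C = "PF13243"          # squalene-hopene cyclase C (ERG7-like)
PF_FAAL_C = "PF13193"           # AMP-binding C, fatty acyl-AMP ligase marker
IPR_TS2 = "IPR034686"           # terpene cyclase-like 2
IPR_LCPS = "IPR017825"          # lycopene cyclase (carRA-like)
TIGR_LCPS = "TIGR03462"         # lycopene cyclase (carRA-like)

TERPENE_SIGNATURES = frozenset({
    PF_POLYPRENYL_SYNT, PF_SQS_PSY, PF_SQHOP_N, PF_SQHOP_C,
    IPR_TS2, IPR_LCPS, TIGR_LCPS,
})


@dataclass(frozen=True)
class TypingRule:
    """One SMC type definition.

    ``all_of`` is a list of accession sets; the rule is satisfied when every
    set contributes at least one accession (each set is an any-of list of
    alternatives) and no ``none_of`` accession is present.
    """

    type_label: str
    all_of: tuple[frozenset[str], ...]
    none_of: frozenset[str] = frozenset()
    priority: int = 0

    def __post_init__(self) -> None:
        if not self.all_of or any(len(s) == 0 for s in self.all_of):
            raise ValueError(f"rule {self.type_label}: all_of must be non-empty")

    def satisfied_by(self, accessions: set[str]) -> bool:
        if accessions & self.none_of:
            return False
        return all(accessions & alternatives for alternatives in self.all_of)


@dataclass
class TypeAssignment:
    cluster_id: str
    primary_type: str
    hybrid_types: set[str] = field(default_factory=set)
    matched_domains: set[str] = field(default_factory=set)
    curated: bool = True
    rejection_reason: str = ""

    def __post_init__(self) -> None:
        if not self.curated and not self.rejection_reason:
            raise ValueError("rejected assignment needs a rejection_reason")


def default_rule_table() -> list[TypingRule]:
    """The built-in SMC type rules.

    Priorities order NRPS > PKS > siderophore > terpene > NRPS-like >
    bacteriocin (lower number = higher priority).  A canonical NRPS needs
    adenylation, condensation and a thioesterase or carrier domain;
    NRPS-like clusters pair a carrier/reductase domain with an
    adenylate-forming domain but lack condensation; a single IucA_IucC
    homologue suffices for the siderophore call (FhuF corroborates but
    siderophore regions frequently carry the synthase gene alone).
    """
    return [
        TypingRule("NRPS", (
            frozenset({PF_AMP_BINDING}),
            frozenset({PF_CONDENSATION}),
            frozenset({PF_PP_BINDING, PF_THIOESTERASE}),
        ), priority=1),
        TypingRule("PKS", (
            frozenset({PF_KS_N, PF_KS_C}),
        ), priority=2),
        TypingRule("siderophore", (
            frozenset({PF_IUCA_IUCC}),
        ), priority=3),
        TypingRule("terpene", (
            TERPENE_SIGNATURES,
        ), priority=4),
        TypingRule("NRPS-like", (
            frozenset({PF_PP_BINDING, PF_NAD_BINDING_4}),
            frozenset({PF_AMP_BINDING}),
        ), none_of=frozenset({PF_CONDENSATION}), priority=5),
        TypingRule("bacteriocin", (
            frozenset({PF_DUF692}),
        ), priority=6),
    ]


def load_rule_table(path) -> list[TypingRule]:
    """Load a rule table from YAML: a list of {type_label, all_of (list of
    lists), none_of (list), priority} mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = [
        TypingRule(
            type_label=entry["type_label"],
            all_of=tuple(frozenset(s) for s in entry["all_of"]),
            none_of=frozenset(entry.get("none_of", [])),
            priority=int(entry["priority"]),
        )
        for entry in raw
    ]
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ValueError("rule priorities must be unique")
    return rules


def dump_rule_table(rules: list[TypingRule], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([
            {
                "type_label": r.type_label,
                "all_of": [sorted(s) for s in r.all_of],
                "none_of": sorted(r.none_of),
                "priority": r.priority,
            }
            for r in rules
        ], fh, sort_keys=False)


def cluster_accessions(cluster: ClusterRegion, hits: list[DomainHit]) -> set[str]:
    """Union of domain accessions over the cluster's proteins."""
    members = set(cluster.protein_ids)
    return {h.accession for h in hits if h.protein_id in members}


def assign_type(cluster: ClusterRegion, hits: list[DomainHit],
                rules: list[TypingRule] | None = None) -> TypeAssignment:
    """Assign the primary SMC type and any hybrid types to one cluster.

    The primary type is the highest-priority satisfied rule; every other
    satisfied rule is recorded as a hybrid type.  With no satisfied rule the
    cluster is "unassigned".  The result depends only on the cluster's
    domain-accession set — gene order is irrelevant.
    """
    if rules is None:
        rules = default_rule_table()
    accessions = cluster_accessions(cluster, hits)
    satisfied = sorted((r for r in rules if r.satisfied_by(accessions)),
                       key=lambda r: r.priority)
    if not satisfied:
        return TypeAssignment(cluster.cluster_id, "unassigned",
                              matched_domains=accessions)
    primary = satisfied[0]
    rule_domains = set().union(*primary.all_of)
    for r in satisfied[1:]:
        rule_domains |= set().union(*r.all_of)
    return TypeAssignment(
        cluster_id=cluster.cluster_id,
        primary_type=primary.type_label,
        hybrid_types={r.type_label for r in satisfied[1:]},
        matched_domains=accessions & rule_domains,
    )


REASON_FAS = "fatty-acid-synthesis-like"
REASON_NO_SIGNATURE = "no biosynthetic signature"


def curate(assignments: list[TypeAssignment], hits: list[DomainHit],
           cluster_proteins: dict[str, set[str]] | None = None
           ) -> tuple[list[TypeAssignment], list[TypeAssignment]]:
    """Split assignments into (retained, rejected).

    Unassigned clusters whose only domain signature is the ACPS
    4'-phosphopantetheinyl transferase (PF01648) are rejected as
    fatty-acid-synthesis related; other unassigned clusters are rejected
    for lacking any biosynthetic signature; all typed clusters are
    retained.  ``cluster_proteins`` maps cluster_id to its protein ids and
    is only needed when ``assignments`` lack ``matched_domains`` context.
    """
    retained, rejected = [], []
    domains_by_protein: dict[str, set[str]] = {}
    for h in hits:
        domains_by_protein.setdefault(h.protein_id, set()).add(h.accession)
    for a in assignments:
        if a.primary_type != "unassigned":
            retained.append(a)
            continue
        if cluster_proteins is not None:
            accs = set().union(*(domains_by_protein.get(p, set())
                                 for p in cluster_proteins[a.cluster_id])) \
                if cluster_proteins[a.cluster_id] else set()
        else:
            accs = set(a.matched_domains)
        # ACPS is the sole *signature* domain: non-signature noise domains do
        # not change the fatty-acid-synthesis verdict
        reason = REASON_FAS if PF_ACPS in accs else REASON_NO_SIGNATURE
        rejected.append(TypeAssignment(
            cluster_id=a.cluster_id, primary_type="unassigned",
            matched_domains=accs, curated=False, rejection_reason=reason))
    return retained, rejected


# Fixed column order of the gene-family presence/absence matrix.
CORE_FAMILY_COLUMNS = (
    "LYS2", "SID", "SQS", "SQS_NDUF6", "GGPS", "ERG7", "TS2",
    "carRA_1", "carRA_2", "NPS", "NRPS", "PKS", "PKS-NRPS", "FAAL",
)


def core_family_matrix(clusters: list[ClusterRegion],
                       family_map: dict[str, str],
                       assemblies: list[str] | None = None) -> pd.DataFrame:
    """Per-assembly presence/absence matrix of the core gene families.

    Cells encode copy number per genome: 0 absent, 1 single cluster carrying
    the family, 2 multiple clusters.  Assemblies with no clusters yield
    all-zero rows (they stay in the matrix).
    """
    if assemblies is None:
        assemblies = sorted({c.assembly_id for c in clusters})
    counts = pd.DataFrame(0, index=pd.Index(assemblies, name="assembly_id"),
                          columns=list(CORE_FAMILY_COLUMNS), dtype=int)
    for c in clusters:
        fams = {family_map[p] for p in c.protein_ids if p in family_map}
        for fam in fams & set(CORE_FAMILY_COLUMNS):
            counts.loc[c.assembly_id, fam] += 1
    return counts.clip(upper=2)


def match_reference_synthetases(hits, references: set[str] | dict[str, str],
                                min_identity: float = 30.0,
                                min_cov: float = 60.0) -> dict[str, str]:
    """Label query proteins with their best qualifying reference hit.

    ``references`` is a set of reference protein ids, or a mapping from
    reference id to a label (e.g. accession -> "malpicyclin synthetase").
    A hit qualifies when identity and both coverages clear the thresholds;
    ties are broken by bitscore.  Queries without a qualifying hit get no
    label.
    """
    labels: dict[str, str] = {}
    best_score: dict[str, float] = {}
    ref_label = references if isinstance(references, dict) else \
        {r: r for r in references}
    for h in hits:
        if h.subject_id not in ref_label:
            continue
        if (h.pct_identity < min_identity or h.q_cov < min_cov
                or h.s_cov < min_cov):
            continue
        if h.bitscore > best_score.get(h.query_id, float("-inf")):
            best_score[h.query_id] = h.bitscore
            labels[h.query_id] = ref_label[h.subject_id]
    return labels


def write_typing_table(assignments: list[TypeAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tprimary_type\thybrid_types\tcurated\treason\n")
        for a in sorted(assignments, key=lambda x: x.cluster_id):
            fh.write(f"{a.cluster_id}\t{a.primary_type}\t"
                     f"{','.join(sorted(a.hybrid_types))}\t"
                     f"{int(a.curated)}\t{a.rejection_reason}\n")
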