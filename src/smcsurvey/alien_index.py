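"""Alien Index screening for genes of putative bacterial origin.

For every SMC-encoded gene the best homology E-value within the recipient
lineage (higher fungi, *Dikarya*) is compared with the best within the
candidate donor group (Bacteria):

    AI = ln(best_E_dikarya + 1e-200) - ln(best_E_bacteria + 1e-200)

Positive AI means the bacterial hit is stronger — a candidate alien gene.
A group without any hit contributes best E = 1 (the weakest possible hit),
keeping AI finite.  Per cluster, AI is averaged over all genes (avg_AI) and
over the core-family genes only (avg_AI_core); genes with no hit in either
group contribute AI = 0 so annotation gaps do not bias the means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from smcsurvey.io import ClusterRegion

PSEUDOCOUNT = 1e-200
GROUPS = ("Dikarya", "Bacteria")

# Families whose genes count as "core" for avg_AI_core: the presence/absence
# matrix families plus the fatty acid acyl-CoA AMP ligase (FAAL) family.
DEFAULT_CORE_FAMILIES = frozenset({
    "LYS2", "SID", "SQS", "SQS_NDUF6", "GGPS", "ERG7", "TS2",
    "carRA_1", "carRA_2", "NPS", "NRPS", "PKS", "PKS-NRPS", "FAAL",
})


@dataclass(frozen=True)
class TaxonomicHit:
    """One taxonomically labelled homology hit."""

    protein_id: str
    subject_id: str
    group: str
    evalue: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass
class AlienIndexRecord:
    protein_id: str
    best_e_dikarya: float | None
    best_e_bacteria: float | None
    ai: float


def best_hits_by_group(hits: list[TaxonomicHit], e_max: float = 1e-05,
                       self_ids: dict[str, str] | None = None
                       ) -> dict[str, dict[str, float]]:
    """Per-protein minimum E-value per taxon group.

    Hits above the ``e_max`` admission threshold are discarded; a protein's
    match to its own database record (``self_ids`` maps protein_id to its
    own subject accession) is excluded.
    """
    best: dict[str, dict[str, float]] = {}
    for h in hits:
        if h.evalue > e_max:
            continue
        if self_ids is not None and self_ids.get(h.protein_id) == h.subject_id:
            continue
        per = best.setdefault(h.protein_id, {})
        if h.evalue < per.get(h.group, float("inf")):
            per[h.group] = h.evalue
    return best


def alien_index(best_e_dikarya: float | None,
                best_e_bacteria: float | None) -> float:
    """AI = ln(best_E_dikarya + 1e-200) - ln(best_E_bacteria + 1e-200).

    ``None`` (no hit in that group) is treated as E = 1.
    """
    ed = 1.0 if best_e_dikarya is None else best_e_dikarya
    eb = 1.0 if best_e_bacteria is None else best_e_bacteria
    if ed < 0 or eb < 0:
        raise ValueError("E-values must be >= 0")
    return math.log(ed + PSEUDOCOUNT) - math.log(eb + PSEUDOCOUNT)


def ai_records(hits: list[TaxonomicHit], protein_ids: list[str],
               e_max: float = 1e-05,
               self_ids: dict[str, str] | None = None
               ) -> dict[str, AlienIndexRecord]:
    """AI per protein; proteins without any admitted hit get AI = 0."""
    best = best_hits_by_group(hits, e_max=e_max, self_ids=self_ids)
    records = {}
    for p in protein_ids:
        per = best.get(p, {})
        ed = per.get("Dikarya")
        eb = per.get("Bacteria")
        ai = 0.0 if (ed is None and eb is None) else alien_index(ed, eb)
        records[p] = AlienIndexRecord(p, ed, eb, ai)
    return records


def cluster_ai(cluster: ClusterRegion,
               records: dict[str, AlienIndexRecord],
               family_map: dict[str, str] | None = None,
               core_families: frozenset[str] = DEFAULT_CORE_FAMILIES
               ) -> tuple[float, float | None]:
    """(avg_AI, avg_AI_core) for one cluster.

    avg_AI averages AI over all member genes; avg_AI_core over genes whose
    family label lies in the core set, ``None`` when the cluster carries no
    core gene.  Every member gene must have a record.
    """
    if not cluster.genes:
        raise ValueError(f"cluster {cluster.cluster_id} has no genes")
    ais = [records[p].ai for p in cluster.protein_ids]
    avg_ai = sum(ais) / len(ais)
    if family_map is None:
        return avg_ai, None
    core_ais = [records[p].ai for p in cluster.protein_ids
                if family_map.get(p) in core_families]
    avg_ai_core = sum(core_ais) / len(core_ais) if core_ais else None
    return avg_ai, avg_ai_core


def read_taxonomic_hits(path) -> list[TaxonomicHit]:
    """Read group-labelled hits: TSV with header
    protein_id, subject_id, group, evalue."""
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            hits.append(TaxonomicHit(
                protein_id=p[idx["protein_id"]],
                subject_id=p[idx["subject_id"]],
                group=p[idx["group"]],
                evalue=float(p[idx["evalue"]]),
            ))
    return hits


def write_taxonomic_hits(hits: list[TaxonomicHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tsubject_id\tgroup\tevalue\n")
        for h in hits:
            fh.write(f"{h.protein_id}\t{h.subject_id}\t{h.group}\t"
                     f"{h.evalue:.6g}\n")


def write_ai_table(records: dict[str, AlienIndexRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tbest_e_dikarya\tbest_e_bacteria\tai\n")
        for p in sorted(records):
            r = records[p]
            ed = "" if r.best_e_dikarya is None else f"{r.best_e_dikarya:.6g}"
            eb = "" if r.best_e_bacteria is None else f"{r.best_e_bacteria:.6g}"
            fh.write(f"{p}\t{ed}\t{eb}\t{r.ai:.6f}\n")


def write_cluster_ai_table(clusters: list[ClusterRegion], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tavg_AI\tavg_AI_core\n")
        for c in sorted(clusters, key=lambda x: x.cluster_id):
            core = "" if c.avg_AI_core is None else f"{c.avg_AI_core:.6f}"
            avg = "" if c.avg_AI is None else f"{c.avg_AI:.6f}"
            fh.write(f"{c.cluster_id}\t{avg}\t{core}\n")
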