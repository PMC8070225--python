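"""Data model and readers/writers for the formats SMC survey data travel in.

Internal coordinates are 0-based half-open throughout; GenBank and BLAST
tabular coordinates (1-based inclusive) are converted at the boundary.
Compound GenBank locations (``join``) are collapsed to their outer span:
the downstream synteny arithmetic operates at gene granularity and does not
model exon structure.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DOMAIN_DIALECTS = ("rpsblast-tab", "hmmscan-domtbl", "generic-tsv")


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


@dataclass(frozen=True)
class GenomeAssembly:
    """One genome assembly in the survey.

    ``has_annotation`` records whether gene models came from a supplied
    annotation (``_gff`` suffix convention in cluster ids) or from de novo
    prediction (``_glim``).
    """

    assembly_id: str
    taxon_label: str = ""
    has_annotation: bool = False

    def __post_init__(self) -> None:
        if not self.assembly_id:
            raise ValueError("assembly_id must be non-empty")


@dataclass
class GeneModel:
    """A protein-coding gene: genomic interval plus translation."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    protein: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if len(self.protein) == 0:
            raise ValueError(f"gene {self.gene_id}: empty protein")


@dataclass
class ClusterRegion:
    """A candidate secondary-metabolite cluster (SMC).

    ``cluster_id`` follows the ``<assembly>__<ordinal>_<source>`` convention
    (e.g. ``GCA_000507065__21_glim``).  Typing and Alien Index results are
    attached here once computed.
    """

    cluster_id: str
    assembly_id: str
    contig: str
    start: int
    end: int
    genes: list[GeneModel] = field(default_factory=list)
    assigned_type: str = "unassigned"
    hybrid_types: set[str] = field(default_factory=set)
    core_families: set[str] = field(default_factory=set)
    avg_AI: float | None = None
    avg_AI_core: float | None = None

    def __post_init__(self) -> None:
        self.genes.sort(key=lambda g: (g.start, g.gene_id))
        for g in self.genes:
            if not (self.start <= g.start and g.end <= self.end):
                raise ValueError(
                    f"cluster {self.cluster_id}: gene {g.gene_id} outside region"
                )

    @property
    def protein_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


@dataclass(frozen=True)
class DomainHit:
    """One protein-vs-domain match (rps-blast / hmmscan style)."""

    protein_id: str
    accession: str
    name: str
    evalue: float
    bitscore: float
    ali_start: int = 0
    ali_end: int = 1

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not self.ali_start < self.ali_end:
            raise ValueError("alignment interval must be non-empty")


@dataclass
class SimilarityHit:
    """One protein-vs-protein homology row (BLAST outfmt-6 style).

    Coverages are derived: ``q_cov = 100 * (q_end - q_start) / q_len`` — the
    query coverage is normalised to the length of the query sequence, and
    symmetrically for the subject.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    ali_len: int
    evalue: float
    bitscore: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    q_len: int
    s_len: int
    q_cov: float = field(init=False)
    s_cov: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError("pct_identity out of [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.q_len <= 0 or self.s_len <= 0:
            raise ValueError(
                f"hit {self.query_id} vs {self.subject_id}: undefined sequence length"
            )
        self.q_cov = 100.0 * (self.q_end - self.q_start) / self.q_len
        self.s_cov = 100.0 * abs(self.s_end - self.s_start) / self.s_len


# ---------------------------------------------------------------------------
# accession normalisation
# ---------------------------------------------------------------------------

_PFAM_CDD = re.compile(r"^pfam(\d{5})$", re.IGNORECASE)


def normalize_accession(acc: str) -> str:
    """Strip the version suffix and map CDD 'pfamNNNNN' ids to 'PFNNNNN'."""
    acc = acc.strip()
    acc = re.sub(r"\.\d+$", "", acc)
    m = _PFAM_CDD.match(acc)
    if m:
        return "PF" + m.group(1)
    return acc


# ---------------------------------------------------------------------------
# GenBank regions
# ---------------------------------------------------------------------------

def _assembly_from_cluster_id(cluster_id: str) -> str:
    return cluster_id.split("__")[0] if "__" in cluster_id else cluster_id


def read_cluster_genbank(path) -> list[ClusterRegion]:
    """Read candidate cluster regions from a GenBank flat file.

    One :class:`ClusterRegion` per record.  CDS features without a
    translation are skipped with a logged warning.  Compound locations are
    collapsed to their outer span.
    """
    clusters: list[ClusterRegion] = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # noqa: BLE001 - surface the record context
        raise ParseError(f"malformed GenBank file {path}: {exc}") from exc
    for rec in records:
        try:
            clusters.append(_record_to_cluster(rec))
        except ParseError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise ParseError(f"malformed record {rec.id!r} in {path}: {exc}") from exc
    return clusters


def _record_to_cluster(rec: SeqRecord) -> ClusterRegion:
    cluster_id = rec.id if rec.id not in ("", "<unknown id>") else rec.name
    contig = rec.annotations.get("contig_id", "") or cluster_id
    genes: list[GeneModel] = []
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        quals = feat.qualifiers
        gene_id = (
            quals.get("locus_tag", quals.get("protein_id", quals.get("gene", [None])))
        )[0]
        if gene_id is None:
            gene_id = f"{cluster_id}_cds{len(genes) + 1}"
        translation = quals.get("translation", [None])[0]
        if not translation:
            logger.warning(
                "record %s: CDS %s has no translation; skipped", cluster_id, gene_id
            )
            continue
        loc = feat.location
        if loc is None:
            raise ParseError(
                f"record {cluster_id}: CDS {gene_id} has an unparseable location")
        genes.append(
            GeneModel(
                gene_id=gene_id,
                contig=contig,
                start=int(loc.start),  # outer span; 0-based half-open already
                end=int(loc.end),
                strand="-" if loc.strand == -1 else "+",
                protein=str(translation),
                product=quals.get("product", [""])[0],
            )
        )
    return ClusterRegion(
        cluster_id=cluster_id,
        assembly_id=_assembly_from_cluster_id(cluster_id),
        contig=contig,
        start=0,
        end=len(rec.seq) if len(rec.seq) else max((g.end for g in genes), default=1),
        genes=genes,
    )


def write_cluster_genbank(clusters: list[ClusterRegion], path) -> None:
    """Write cluster regions as GenBank records (one per region).

    Nucleotide sequence is emitted as N-runs of the region length: only
    coordinates, strands and translations are modelled.
    """
    records = []
    for c in clusters:
        rec = SeqRecord(
            Seq("N" * (c.end - c.start)),
            id=c.cluster_id,
            name=c.cluster_id[:16].replace("__", "_"),
            description=f"candidate SMC region {c.cluster_id}",
            annotations={"molecule_type": "DNA", "contig_id": c.contig},
        )
        for g in c.genes:
            feat = SeqFeature(
                FeatureLocation(g.start - c.start, g.end - c.start,
                                strand=-1 if g.strand == "-" else 1),
                type="CDS",
                qualifiers={
                    "locus_tag": [g.gene_id],
                    "translation": [g.protein],
                    "product": [g.product or "hypothetical protein"],
                },
            )
            rec.features.append(feat)
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


# ---------------------------------------------------------------------------
# domain-hit tables
# ---------------------------------------------------------------------------

def read_domain_table(path, dialect: str = "generic-tsv",
                      max_evalue: float | None = None) -> list[DomainHit]:
    """Read protein-vs-domain hits.

    Dialects: ``rpsblast-tab`` (BLAST outfmt-6 with a CDD subject field),
    ``hmmscan-domtbl`` (HMMER3 --domtblout) and ``generic-tsv`` (headered
    columns protein_id, accession, name, evalue, bitscore, ali_start,
    ali_end).  Rows with E-value above ``max_evalue`` are dropped; rows with
    a non-numeric E-value are rejected with a logged warning.
    """
    if dialect not in DOMAIN_DIALECTS:
        raise ValueError(f"unknown domain-table dialect {dialect!r}")
    hits: list[DomainHit] = []
    with open(path) as fh:
        if dialect == "generic-tsv":
            hits = _parse_generic_domain_tsv(fh)
        elif dialect == "rpsblast-tab":
            hits = _parse_rpsblast(fh)
        else:
            hits = _parse_domtbl(fh)
    if max_evalue is not None:
        hits = [h for h in hits if h.evalue <= max_evalue]
    return hits


def _safe_float(token: str, context: str) -> float | None:
    try:
        return float(token)
    except ValueError:
        logger.warning("non-numeric E-value %r in %s; row rejected", token, context)
        return None


def _parse_generic_domain_tsv(fh) -> list[DomainHit]:
    hits = []
    header = fh.readline().rstrip("\n").split("\t")
    idx = {name: i for i, name in enumerate(header)}
    required = ("protein_id", "accession", "name", "evalue", "bitscore",
                "ali_start", "ali_end")
    missing = [c for c in required if c not in idx]
    if missing:
        raise ParseError(f"generic domain TSV missing columns: {missing}")
    for line in fh:
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        ev = _safe_float(parts[idx["evalue"]], parts[idx["protein_id"]])
        if ev is None:
            continue
        hits.append(DomainHit(
            protein_id=parts[idx["protein_id"]],
            accession=normalize_accession(parts[idx["accession"]]),
            name=parts[idx["name"]],
            evalue=ev,
            bitscore=float(parts[idx["bitscore"]]),
            ali_start=int(parts[idx["ali_start"]]),
            ali_end=int(parts[idx["ali_end"]]),
        ))
    return hits


_CDD_ACC = re.compile(r"(pfam\d{5}|PF\d{5}|TIGR\d{5}|IPR\d{6}|smart\d{5}|cd\d{5})",
                      re.IGNORECASE)


def _parse_rpsblast(fh) -> list[DomainHit]:
    """rps-blast outfmt-6: qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore; accession extracted from the
    subject field (e.g. ``gnl|CDD|pfam04183``)."""
    hits = []
    for line in fh:
        if not line.strip() or line.startswith("#"):
            continue
        p = line.rstrip("\n").split("\t")
        if len(p) < 12:
            raise ParseError(f"rpsblast row with {len(p)} columns (need 12)")
        m = _CDD_ACC.search(p[1])
        accession = normalize_accession(m.group(1)) if m else normalize_accession(p[1])
        ev = _safe_float(p[10], p[0])
        if ev is None:
            continue
        hits.append(DomainHit(
            protein_id=p[0], accession=accession, name=p[1], evalue=ev,
            bitscore=float(p[11]), ali_start=int(p[6]) - 1, ali_end=int(p[7]),
        ))
    return hits


def _parse_domtbl(fh) -> list[DomainHit]:
    """HMMER3 hmmscan --domtblout: whitespace-delimited, '#' comments."""
    hits = []
    for line in fh:
        if not line.strip() or line.startswith("#"):
            continue
        p = line.split()
        if len(p) < 23:
            raise ParseError(f"domtblout row with {len(p)} columns (need >=23)")
        ev = _safe_float(p[12], p[3])  # i-Evalue
        if ev is None:
            continue
        hits.append(DomainHit(
            protein_id=p[3],
            accession=normalize_accession(p[1]),
            name=p[0],
            evalue=ev,
            bitscore=float(p[13]),
            ali_start=int(p[17]) - 1,
            ali_end=int(p[18]),
        ))
    return hits


def write_domain_table(hits: list[DomainHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\taccession\tname\tevalue\tbitscore\tali_start\tali_end\n")
        for h in hits:
            fh.write(f"{h.protein_id}\t{h.accession}\t{h.name}\t{h.evalue:.6g}\t"
                     f"{h.bitscore:.6g}\t{h.ali_start}\t{h.ali_end}\n")


# ---------------------------------------------------------------------------
# protein-vs-protein similarity tables
# ---------------------------------------------------------------------------

def read_similarity_table(path, length_lookup: dict[str, int] | None = None
                          ) -> list[SimilarityHit]:
    """Read a 12- or 14-column BLAST-style tabular file.

    The 14-column variant appends ``qlen`` and ``slen``.  For 12-column
    input, ``length_lookup`` (protein_id -> residue length) must supply the
    lengths, otherwise the offending query/subject is reported in the error.
    BLAST 1-based inclusive residue coordinates are converted to 0-based
    half-open.
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) not in (12, 14):
                raise ParseError(
                    f"similarity row with {len(p)} columns (need 12 or 14)")
            q, s = p[0], p[1]
            if len(p) == 14:
                q_len, s_len = int(p[12]), int(p[13])
            else:
                if length_lookup is None:
                    raise ParseError(
                        f"12-column hit {q} vs {s}: sequence lengths absent and "
                        "no length lookup supplied")
                try:
                    q_len, s_len = length_lookup[q], length_lookup[s]
                except KeyError as exc:
                    raise ParseError(
                        f"hit {q} vs {s}: no length for {exc.args[0]}") from exc
            hits.append(SimilarityHit(
                query_id=q, subject_id=s, pct_identity=float(p[2]),
                ali_len=int(p[3]), evalue=float(p[10]), bitscore=float(p[11]),
                q_start=int(p[6]) - 1, q_end=int(p[7]),
                s_start=int(p[8]) - 1, s_end=int(p[9]),
                q_len=q_len, s_len=s_len,
            ))
    return hits


def write_similarity_table(hits: list[SimilarityHit], path,
                           header: bool = False) -> None:
    """Write hits as 14-column BLAST-style tabular (qlen/slen appended).

    ``header=False`` by default so the output is directly re-readable by
    :func:`read_similarity_table` and external BLAST tooling.
    """
    with open(path, "w") as fh:
        if header:
            fh.write("# qseqid\tsseqid\tpident\tlength\tmismatch\tgapopen\t"
                     "qstart\tqend\tsstart\tsend\tevalue\tbitscore\tqlen\tslen\n")
        for h in hits:
            mismatch = round(h.ali_len * (100.0 - h.pct_identity) / 100.0)
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t{h.ali_len}\t"
                f"{mismatch}\t0\t{h.q_start + 1}\t{h.q_end}\t{h.s_start + 1}\t"
                f"{h.s_end}\t{h.evalue:.3g}\t{h.bitscore:.1f}\t{h.q_len}\t{h.s_len}\n")


def write_cluster_table(clusters: list[ClusterRegion], path) -> None:
    """Summary TSV: one row per cluster with typing and AI annotations."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tassembly_id\tcontig\tstart\tend\tn_genes\t"
                 "assigned_type\thybrid_types\tcore_families\tavg_AI\tavg_AI_core\n")
        for c in clusters:
            fh.write(
                f"{c.cluster_id}\t{c.assembly_id}\t{c.contig}\t{c.start}\t{c.end}\t"
                f"{len(c.genes)}\t{c.assigned_type}\t"
                f"{','.join(sorted(c.hybrid_types))}\t"
                f"{','.join(sorted(c.core_families))}\t"
                f"{'' if c.avg_AI is None else format(c.avg_AI, '.6g')}\t"
                f"{'' if c.avg_AI_core is None else format(c.avg_AI_core, '.6g')}\n")
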