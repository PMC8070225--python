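"""Seeded synthetic SMC datasets with planted ground truth.

The generator emulates the structure of a multi-assembly SMC survey at desk
scale: cluster regions instantiated from per-type domain templates, protein
families with controlled pairwise identity shared across assemblies
(homologous cluster groups), and per-gene taxonomic best-hit tables with a
controlled bacterial-vs-fungal E-value asymmetry.  Everything is a pure
function of (config, seed); the planted truth is recorded alongside and
serialises to JSON bit-exactly.

Sequence families use a uniform-substitution mutation model: identity, not
evolutionary realism, is the controlled variable.  The synthetic E-value
law, E = 10^(-(identity/100) * length / 3) clipped to [1e-180, 10], is
chosen so the survey's 1e-10 admission threshold cleanly separates the
default within-family (80%) from between-family (~20%) identities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from smcsurvey import typing_rules as tr
from smcsurvey.alien_index import TaxonomicHit
from smcsurvey.io import ClusterRegion, DomainHit, GeneModel, SimilarityHit

AA = "ACDEFGHIKLMNPQRSTVWY"

# Accessions that never trigger a typing rule or core-family label: noise.
NOISE_ACCESSIONS = ("PF00067", "PF07690", "PF00083", "PF00153")


@dataclass(frozen=True)
class TypeTemplate:
    """Blueprint of one SMC type: ordered per-gene domain layouts.

    ``expected_type`` is the primary type the rule engine must recover;
    ``core_family`` the presence/absence-matrix label of the core gene
    (empty when the type has no matrix column); ``core_slot`` its index in
    the layout.
    """

    type_label: str
    domain_layout: tuple[tuple[str, ...], ...]
    expected_type: str
    core_family: str = ""
    core_slot: int = 0
    n_accessory: tuple[int, int] = (1, 3)
    gene_length: tuple[int, int] = (200, 400)


def default_templates() -> dict[str, TypeTemplate]:
    """Built-in templates, one per SMC type seen in the survey, plus the two
    curation negatives (fatty-acid-synthesis-like and signature-free)."""
    t = {}
    t["nrps"] = TypeTemplate(
        "nrps",
        ((tr.PF_AMP_BINDING, tr.PF_CONDENSATION, tr.PF_PP_BINDING),),
        expected_type="NRPS", core_family="NRPS",
        gene_length=(600, 1200))
    t["pks"] = TypeTemplate(
        "pks",
        ((tr.PF_KS_N, tr.PF_KS_C, tr.PF_PP_BINDING),),
        expected_type="PKS", core_family="PKS", gene_length=(600, 1200))
    t["pks_nrps"] = TypeTemplate(
        "pks_nrps",
        ((tr.PF_KS_N, tr.PF_KS_C, tr.PF_AMP_BINDING, tr.PF_CONDENSATION,
          tr.PF_PP_BINDING),),
        expected_type="NRPS", core_family="PKS-NRPS", gene_length=(900, 1500))
    t["siderophore"] = TypeTemplate(
        "siderophore",
        ((tr.PF_IUCA_IUCC, tr.PF_FHUF),),
        expected_type="siderophore", core_family="SID",
        n_accessory=(0, 1), gene_length=(400, 700))
    t["terpene_ggps"] = TypeTemplate(
        "terpene_ggps", ((tr.PF_POLYPRENYL_SYNT,),),
        expected_type="terpene", core_family="GGPS", gene_length=(250, 400))
    t["terpene_sqs"] = TypeTemplate(
        "terpene_sqs", ((tr.PF_SQS_PSY,),),
        expected_type="terpene", core_family="SQS", gene_length=(300, 450))
    t["terpene_erg7"] = TypeTemplate(
        "terpene_erg7", ((tr.PF_SQHOP_N, tr.PF_SQHOP_C),),
        expected_type="terpene", core_family="ERG7", gene_length=(600, 800))
    t["terpene_ts2"] = TypeTemplate(
        "terpene_ts2", ((tr.IPR_TS2,),),
        expected_type="terpene", core_family="TS2", gene_length=(300, 500))
    t["terpene_car"] = TypeTemplate(
        "terpene_car",
        ((tr.TIGR_LCPS,), (tr.PF_AMINO_OXIDASE,)),
        expected_type="terpene", core_family="carRA_1", gene_length=(400, 600))
    t["nrps_like_nps"] = TypeTemplate(
        "nrps_like_nps", ((tr.PF_AMP_BINDING, tr.PF_PP_BINDING),),
        expected_type="NRPS-like", core_family="NPS", gene_length=(800, 1100))
    t["nrps_like_lys2"] = TypeTemplate(
        "nrps_like_lys2",
        ((tr.PF_AMP_BINDING, tr.PF_PP_BINDING, tr.PF_NAD_BINDING_4),),
        expected_type="NRPS-like", core_family="LYS2", gene_length=(1000, 1400))
    t["faal"] = TypeTemplate(
        "faal", ((tr.PF_AMP_BINDING, tr.PF_PP_BINDING, tr.PF_FAAL_C),),
        expected_type="NRPS-like", core_family="FAAL", gene_length=(500, 700))
    t["bacteriocin"] = TypeTemplate(
        "bacteriocin", ((tr.PF_DUF692,),),
        expected_type="bacteriocin", n_accessory=(0, 2), gene_length=(150, 300))
    t["fas_like"] = TypeTemplate(
        "fas_like", ((tr.PF_ACPS,),),
        expected_type="rejected:" + tr.REASON_FAS,
        n_accessory=(0, 2), gene_length=(150, 300))
    t["no_signature"] = TypeTemplate(
        "no_signature", ((),),
        expected_type="rejected:" + tr.REASON_NO_SIGNATURE,
        n_accessory=(1, 3), gene_length=(200, 400))
    return t


@dataclass
class GroupSpec:
    """One homologous cluster group: n_members clusters from one template,
    one per assembly (round-robin), sharing protein families at the given
    within-group identity."""

    template: str
    n_members: int
    within_identity: float = 80.0
    bacterial_core: bool = False
    assemblies: list[int] | None = None
    intergenic: tuple[int, int] | None = None


@dataclass
class DatasetConfig:
    n_assemblies: int = 10
    groups: list[GroupSpec] = field(default_factory=list)
    noise_domain_rate: float = 0.0
    intergenic: tuple[int, int] = (200, 2000)


def default_config(n_assemblies: int = 10) -> DatasetConfig:
    """A small survey-like corpus: every built-in type represented, the
    low-copy siderophore family spread across most assemblies, and a
    handful of curation negatives."""
    return DatasetConfig(
        n_assemblies=n_assemblies,
        groups=[
            GroupSpec("siderophore", n_assemblies - 2),
            GroupSpec("terpene_ggps", 5),
            GroupSpec("terpene_sqs", 4),
            GroupSpec("terpene_car", 3),
            GroupSpec("nrps_like_lys2", n_assemblies),
            GroupSpec("nrps_like_nps", 6),
            GroupSpec("nrps", 4, bacterial_core=True),
            GroupSpec("pks", 3, bacterial_core=True),
            GroupSpec("faal", 2),
            GroupSpec("bacteriocin", 2, bacterial_core=True),
            GroupSpec("fas_like", 2),
            GroupSpec("no_signature", 1),
        ],
        noise_domain_rate=0.05,
    )


@dataclass
class SyntheticTruth:
    """Planted ground truth for every generated entity."""

    family_of: dict[str, str] = field(default_factory=dict)     # protein -> family key
    core_label_of: dict[str, str] = field(default_factory=dict)  # protein -> Fig-4 label
    group_of: dict[str, str] = field(default_factory=dict)      # cluster -> group key
    type_of: dict[str, str] = field(default_factory=dict)       # cluster -> expected type
    origin_of: dict[str, str] = field(default_factory=dict)     # protein -> fungal|bacterial
    copy_number: dict[str, int] = field(default_factory=dict)   # "assembly|family" -> count
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticDataset:
    assemblies: list[str]
    clusters: list[ClusterRegion]
    domain_hits: list[DomainHit]
    truth: SyntheticTruth
    config: DatasetConfig


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Independent point substitutions to a uniformly random different
    residue at the given per-site rate."""
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        choices = AA.replace(out[i], "")
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_family(seed: int | np.random.Generator, n_members: int,
                    target_identity: float, length: int) -> list[str]:
    """A protein family: one random ancestor, members derived by independent
    substitutions so expected pairwise identity is ~target_identity."""
    if target_identity <= 0:
        raise ValueError("target_identity must be positive")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    ancestor = "".join(AA[i] for i in rng.integers(len(AA), size=length))
    if target_identity >= 100.0:
        return [ancestor] * n_members
    # pairwise identity ~ (1-m)^2 (+ m^2/19 coincidences); invert the square
    rate = 1.0 - np.sqrt(target_identity / 100.0)
    return [mutate(rng, ancestor, rate) for _ in range(n_members)]


def pairwise_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def synthetic_evalue(identity: float, length: int) -> float:
    """Synthetic monotone E-value law, clipped to [1e-180, 10]."""
    return float(np.clip(10.0 ** (-(identity / 100.0) * length / 3.0),
                         1e-180, 10.0))


def generate_dataset(config: DatasetConfig | None = None,
                     seed: int = 0) -> SyntheticDataset:
    """Instantiate the configured homologous cluster groups on synthetic
    contigs and record the planted truth."""
    if config is None:
        config = default_config()
    templates = default_templates()
    rng = np.random.default_rng(seed)
    assemblies = [f"GCA_{1000000 + i:07d}" for i in range(config.n_assemblies)]
    ordinal = dict.fromkeys(assemblies, 0)
    clusters: list[ClusterRegion] = []
    domain_hits: list[DomainHit] = []
    truth = SyntheticTruth(seed=seed)

    for gi, spec in enumerate(config.groups):
        if spec.template not in templates:
            raise ValueError(f"unknown template {spec.template!r}")
        tpl = templates[spec.template]
        group_key = f"G{gi + 1:02d}_{spec.template}"
        member_assemblies = spec.assemblies if spec.assemblies is not None \
            else [i % config.n_assemblies for i in range(spec.n_members)]
        if len(member_assemblies) != spec.n_members:
            raise ValueError(
                f"group {group_key}: {len(member_assemblies)} assemblies for "
                f"{spec.n_members} members")
        n_acc = int(rng.integers(tpl.n_accessory[0], tpl.n_accessory[1] + 1))
        n_slots = len(tpl.domain_layout) + n_acc
        # one shared protein family per gene slot across the group
        slot_lengths = [int(rng.integers(*tpl.gene_length))
                        for _ in range(n_slots)]
        slot_seqs = [generate_family(rng, spec.n_members,
                                     spec.within_identity, L)
                     for L in slot_lengths]
        intergenic = spec.intergenic or config.intergenic
        for mi, ai in enumerate(member_assemblies):
            asm = assemblies[ai]
            ordinal[asm] += 1
            cid = f"{asm}__{ordinal[asm]}_glim"
            contig = f"{asm}_ctg{ordinal[asm]}"
            genes = []
            pos = int(rng.integers(1000, 5000))
            start = pos
            for slot in range(n_slots):
                protein = slot_seqs[slot][mi]
                pid = f"{cid}_p{slot + 1:02d}"
                g_start = pos
                g_end = g_start + 3 * len(protein) + 3
                strand = "+" if rng.random() < 0.7 else "-"
                genes.append(GeneModel(pid, contig, g_start, g_end, strand,
                                       protein,
                                       product=f"{spec.template} slot {slot}"))
                pos = g_end + int(rng.integers(*intergenic))
                layout = tpl.domain_layout[slot] \
                    if slot < len(tpl.domain_layout) else ()
                for acc in layout:
                    off = int(rng.integers(0, max(1, len(protein) - 50)))
                    domain_hits.append(DomainHit(
                        protein_id=pid, accession=acc, name=acc,
                        evalue=10.0 ** -float(rng.uniform(20, 60)),
                        bitscore=float(rng.uniform(100, 500)),
                        ali_start=off, ali_end=min(len(protein), off + 50)))
                if config.noise_domain_rate > 0 and \
                        rng.random() < config.noise_domain_rate:
                    acc = NOISE_ACCESSIONS[rng.integers(len(NOISE_ACCESSIONS))]
                    domain_hits.append(DomainHit(
                        protein_id=pid, accession=acc, name=acc,
                        evalue=10.0 ** -float(rng.uniform(5, 20)),
                        bitscore=float(rng.uniform(50, 200)),
                        ali_start=0, ali_end=min(len(protein), 40)))
                truth.family_of[pid] = f"{group_key}.s{slot + 1}"
                is_core_slot = (slot == tpl.core_slot
                                and slot < len(tpl.domain_layout))
                if is_core_slot and tpl.core_family:
                    truth.core_label_of[pid] = tpl.core_family
                bacterial = spec.bacterial_core and slot < len(tpl.domain_layout)
                truth.origin_of[pid] = "bacterial" if bacterial else "fungal"
            end = genes[-1].end + int(rng.integers(500, 2000))
            clusters.append(ClusterRegion(
                cluster_id=cid, assembly_id=asm, contig=contig,
                start=max(0, start - int(rng.integers(200, 1000))), end=end,
                genes=genes))
            truth.group_of[cid] = group_key
            truth.type_of[cid] = tpl.expected_type
            if tpl.core_family:
                key = f"{asm}|{tpl.core_family}"
                truth.copy_number[key] = truth.copy_number.get(key, 0) + 1
    return SyntheticDataset(assemblies=assemblies, clusters=clusters,
                            domain_hits=domain_hits, truth=truth,
                            config=config)


def generate_hit_table(dataset: SyntheticDataset, seed: int = 0,
                       identity_sd: float = 3.0,
                       between_rate: float = 0.0,
                       between_identity: tuple[float, float] = (15.0, 25.0)
                       ) -> list[SimilarityHit]:
    """All-vs-all homology hits consistent with the planted families.

    Intra-family pairs get full-coverage hits at the planted identity plus
    Gaussian noise, with E-values from the synthetic law.  Between-family
    hits appear only at ``between_rate`` > 0, with identity drawn from
    ``between_identity`` (kept below the 30% network threshold) and short
    local alignments (30-60 residues, as weak homology produces), so their
    law E-values stay above the 1e-10 family-graph admission threshold and
    their coverages below the 60% network floor.  The table is symmetric up
    to query/subject swap.
    """
    rng = np.random.default_rng(seed)
    by_family: dict[str, list[str]] = {}
    length_of: dict[str, int] = {}
    for c in dataset.clusters:
        for g in c.genes:
            by_family.setdefault(dataset.truth.family_of[g.gene_id],
                                 []).append(g.gene_id)
            length_of[g.gene_id] = len(g.protein)
    hits: list[SimilarityHit] = []

    def emit(a: str, b: str, ident: float, ali: int | None = None) -> None:
        la, lb = length_of[a], length_of[b]
        full = ali is None
        if full:
            ali = min(la, lb)
        ev = synthetic_evalue(ident, ali)
        bits = max(20.0, 2.0 * ali * ident / 100.0)
        for q, s, lq, ls in ((a, b, la, lb), (b, a, lb, la)):
            hits.append(SimilarityHit(
                query_id=q, subject_id=s, pct_identity=round(ident, 2),
                ali_len=ali, evalue=ev, bitscore=bits,
                q_start=0, q_end=lq if full else min(ali, lq),
                s_start=0, s_end=ls if full else min(ali, ls),
                q_len=lq, s_len=ls))

    fam_keys = sorted(by_family)
    for fam in fam_keys:
        members = sorted(by_family[fam])
        target = _family_identity(dataset, fam)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ident = float(np.clip(target + rng.normal(0.0, identity_sd),
                                      5.0, 100.0))
                emit(members[i], members[j], ident)
    if between_rate > 0:
        for i in range(len(fam_keys)):
            for j in range(i + 1, len(fam_keys)):
                for a in sorted(by_family[fam_keys[i]]):
                    for b in sorted(by_family[fam_keys[j]]):
                        if rng.random() < between_rate:
                            emit(a, b, float(rng.uniform(*between_identity)),
                                 ali=int(rng.integers(30, 60)))
    return hits


def _family_identity(dataset: SyntheticDataset, family_key: str) -> float:
    group_key = family_key.split(".")[0]
    gi = int(group_key[1:3]) - 1
    return dataset.config.groups[gi].within_identity


def planted_partition_hits(n_families: int = 5, family_size: int = 8,
                           within_evalue: float = 1e-40,
                           between_evalue: float = 1e-3,
                           seed: int = 0) -> tuple[list[SimilarityHit],
                                                   dict[str, int]]:
    """A planted-partition protein similarity table.

    Every within-family pair gets a hit at ``within_evalue``, every
    between-family pair at ``between_evalue``; the survey threshold
    (1e-10) then admits exactly the within-family edges.  Returns (hits,
    truth labels protein -> family index).
    """
    rng = np.random.default_rng(seed)
    hits = []
    labels = {}
    length = 300
    for f in range(n_families):
        for m in range(family_size):
            labels[f"F{f}_{m:02d}"] = f
    names = sorted(labels)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            same = labels[a] == labels[b]
            ev = within_evalue if same else between_evalue
            ident = 80.0 + rng.normal(0, 2) if same else 20.0 + rng.normal(0, 2)
            for q, s in ((a, b), (b, a)):
                hits.append(SimilarityHit(
                    query_id=q, subject_id=s,
                    pct_identity=float(np.clip(ident, 5, 100)),
                    ali_len=length, evalue=ev,
                    bitscore=float(-np.log10(max(ev, 1e-200)) * 2 + 30),
                    q_start=0, q_end=length, s_start=0, s_end=length,
                    q_len=length, s_len=length))
    return hits, labels


def generate_taxonomic_hits(dataset: SyntheticDataset, seed: int = 0,
                            effect_size: float = 20.0,
                            fungal_effect_size: float | None = None,
                            jitter: float = 3.0,
                            base_exponent: tuple[float, float] = (8.0, 30.0)
                            ) -> list[TaxonomicHit]:
    """Group-labelled best-hit tables with planted AI signal.

    Bacterial-origin genes get a bacterial best E-value smaller than the
    Dikarya one by ~``effect_size`` orders of magnitude (log-uniform jitter
    of +-``jitter``); fungal genes the reverse, with
    ``fungal_effect_size`` (defaults to ``effect_size``; 0 makes fungal
    genes taxonomically neutral).
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if fungal_effect_size is None:
        fungal_effect_size = effect_size
    rng = np.random.default_rng(seed)
    hits: list[TaxonomicHit] = []
    for c in dataset.clusters:
        for g in c.genes:
            u = float(rng.uniform(*base_exponent))
            j = float(rng.uniform(-jitter, jitter))
            if dataset.truth.origin_of[g.gene_id] == "bacterial":
                exp_b, exp_d = u + effect_size + j, u
            else:
                exp_b, exp_d = u, u + fungal_effect_size + j
            for group, exponent in (("Dikarya", exp_d), ("Bacteria", exp_b)):
                best = 10.0 ** -exponent
                hits.append(TaxonomicHit(g.gene_id, f"{group[:3]}_ref_best",
                                         group, best))
                # one weaker decoy hit per group
                hits.append(TaxonomicHit(
                    g.gene_id, f"{group[:3]}_ref_decoy", group,
                    min(1.0, best * 10.0 ** float(rng.uniform(1, 5)))))
    return hits
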