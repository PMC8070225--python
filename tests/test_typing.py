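"""Rule engine: type assignment, curation, core-family matrix."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from smcsurvey import typing_rules as tr
from smcsurvey.io import DomainHit

from conftest import make_cluster

RULES = tr.default_rule_table()
ALL_RULE_ACCESSIONS = sorted(
    set().union(*(set().union(*r.all_of) for r in RULES)))


def hits_for(cluster, accessions):
    """One domain hit per accession, spread over the cluster's proteins."""
    pids = cluster.protein_ids
    return [DomainHit(pids[i % len(pids)], acc, acc, 1e-30, 150.0, 0, 50)
            for i, acc in enumerate(sorted(accessions))]


def one_gene_cluster(cid="GCA_X__1_glim"):
    return make_cluster(cid, [("g1", 100, 400, "MKLV" * 25)])


def three_gene_cluster(cid="GCA_X__2_glim"):
    return make_cluster(cid, [("g1", 100, 400, "MKLV" * 25),
                              ("g2", 600, 900, "AHTR" * 25),
                              ("g3", 1200, 1500, "WCDE" * 25)])


def test_default_table_content():
    by_label = {r.type_label: r for r in RULES}
    sid = by_label["siderophore"]
    assert sid.all_of == (frozenset({tr.PF_IUCA_IUCC}),)  # FhuF not required
    nl = by_label["NRPS-like"]
    acc = {tr.PF_NAD_BINDING_4, tr.PF_AMP_BINDING}
    assert nl.satisfied_by(acc)
    assert not nl.satisfied_by(acc | {tr.PF_CONDENSATION})
    assert all(r.all_of and all(s for s in r.all_of) for r in RULES)
    priorities = [r.priority for r in RULES]
    assert len(set(priorities)) == len(priorities)
    order = [r.type_label for r in sorted(RULES, key=lambda r: r.priority)]
    assert order == ["NRPS", "PKS", "siderophore", "terpene", "NRPS-like",
                     "bacteriocin"]


@pytest.mark.parametrize("accessions,expected", [
    ({tr.PF_IUCA_IUCC, tr.PF_FHUF}, "siderophore"),
    ({tr.PF_IUCA_IUCC}, "siderophore"),
    (set(), "unassigned"),
    ({tr.PF_AMP_BINDING, tr.PF_CONDENSATION, tr.PF_PP_BINDING}, "NRPS"),
    ({tr.PF_AMP_BINDING, tr.PF_CONDENSATION, tr.PF_THIOESTERASE}, "NRPS"),
    ({tr.PF_POLYPRENYL_SYNT}, "terpene"),
    ({tr.PF_SQS_PSY}, "terpene"),
    ({tr.TIGR_LCPS}, "terpene"),
    ({"IPR034686"}, "terpene"),
    ({tr.PF_DUF692}, "bacteriocin"),
    ({tr.PF_KS_N}, "PKS"),
    ({tr.PF_ACPS}, "unassigned"),
])
def test_assign_type_examples(accessions, expected):
    cluster = three_gene_cluster()
    result = tr.assign_type(cluster, hits_for(cluster, accessions), RULES)
    assert result.primary_type == expected


def test_hybrid_nrps_with_siderophore_fragment():
    cluster = three_gene_cluster()
    accs = {tr.PF_AMP_BINDING, tr.PF_CONDENSATION, tr.PF_PP_BINDING,
            tr.PF_IUCA_IUCC}
    result = tr.assign_type(cluster, hits_for(cluster, accs), RULES)
    assert result.primary_type == "NRPS"
    assert "siderophore" in result.hybrid_types


def test_assignment_independent_of_gene_order():
    cluster = three_gene_cluster()
    accs = {tr.PF_AMP_BINDING, tr.PF_CONDENSATION, tr.PF_PP_BINDING}
    hits = hits_for(cluster, accs)
    base = tr.assign_type(cluster, hits, RULES)
    for seed in range(5):
        shuffled = hits[:]
        random.Random(seed).shuffle(shuffled)
        again = tr.assign_type(cluster, shuffled, RULES)
        assert (again.primary_type, again.hybrid_types) == \
               (base.primary_type, base.hybrid_types)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(base=st.sets(st.sampled_from(ALL_RULE_ACCESSIONS), max_size=6),
       extra=st.sampled_from(ALL_RULE_ACCESSIONS))
def test_adding_domains_is_monotone_except_vetoes(base, extra):
    """Adding a domain never removes a satisfied rule, unless the added
    domain is in that rule's veto set."""
    cluster = three_gene_cluster()
    before = tr.assign_type(cluster, hits_for(cluster, base), RULES)
    after = tr.assign_type(cluster, hits_for(cluster, base | {extra}), RULES)
    types_before = ({before.primary_type} | before.hybrid_types) - {"unassigned"}
    types_after = ({after.primary_type} | after.hybrid_types) - {"unassigned"}
    vetoed = {r.type_label for r in RULES if extra in r.none_of}
    assert types_before - vetoed <= types_after


def test_curation_reasons():
    fas = one_gene_cluster("GCA_X__3_glim")
    naked = one_gene_cluster("GCA_X__4_glim")
    terp = one_gene_cluster("GCA_X__5_glim")
    hits = hits_for(fas, {tr.PF_ACPS}) + hits_for(terp, {tr.PF_SQS_PSY})
    # re-key hits to distinct protein ids per cluster
    hits = [DomainHit(f"{h.protein_id}@{i}", h.accession, h.name, h.evalue,
                      h.bitscore, h.ali_start, h.ali_end)
            for i, h in enumerate(hits)]
    assigns = []
    for c, accs in [(fas, {tr.PF_ACPS}), (naked, set()),
                    (terp, {tr.PF_SQS_PSY})]:
        assigns.append(tr.assign_type(c, hits_for(c, accs), RULES))
    retained, rejected = tr.curate(assigns, [])
    assert [a.cluster_id for a in retained] == [terp.cluster_id]
    reasons = {a.cluster_id: a.rejection_reason for a in rejected}
    assert reasons[fas.cluster_id] == tr.REASON_FAS
    assert reasons[naked.cluster_id] == tr.REASON_NO_SIGNATURE
    assert all(a.rejection_reason for a in rejected)
    assert all(a.curated for a in retained)


def test_curation_batch_counts():
    clusters, assigns = [], []
    for i in range(20):
        c = one_gene_cluster(f"GCA_B__{i}_glim")
        accs = set() if i < 3 else {tr.PF_IUCA_IUCC}
        assigns.append(tr.assign_type(c, hits_for(c, accs), RULES))
    retained, rejected = tr.curate(assigns, [])
    assert len(retained) == 17
    assert len(rejected) == 3


def test_core_family_matrix_coding():
    c1 = make_cluster("A1__1_glim", [("A1__1_glim_p1", 0, 300, "M" * 100)])
    c2 = make_cluster("A1__2_glim", [("A1__2_glim_p1", 0, 300, "M" * 100)])
    c3 = make_cluster("A1__3_glim", [("A1__3_glim_p1", 0, 300, "M" * 100)])
    c4 = make_cluster("A2__1_glim", [("A2__1_glim_p1", 0, 300, "M" * 100)])
    fmap = {"A1__1_glim_p1": "NPS", "A1__2_glim_p1": "NPS",
            "A1__3_glim_p1": "NPS", "A2__1_glim_p1": "LYS2"}
    m = tr.core_family_matrix([c1, c2, c3, c4], fmap,
                              assemblies=["A1", "A2", "A3"])
    assert list(m.columns) == list(tr.CORE_FAMILY_COLUMNS)
    assert m.loc["A1", "NPS"] == 2          # multiple copies -> 2
    assert m.loc["A2", "LYS2"] == 1         # single copy
    assert m.loc["A3"].sum() == 0           # empty assembly kept, all zero
    assert set(m.values.ravel()) <= {0, 1, 2}


def test_core_family_matrix_recovers_planted_copy_numbers(dataset):
    m = tr.core_family_matrix(dataset.clusters, dataset.truth.core_label_of,
                              assemblies=dataset.assemblies)
    for key, count in dataset.truth.copy_number.items():
        asm, famlab = key.split("|")
        assert m.loc[asm, famlab] == min(count, 2)
    # cells without planted copies stay zero
    planted = {(k.split("|")[0], k.split("|")[1])
               for k in dataset.truth.copy_number}
    for asm in dataset.assemblies:
        for fam in tr.CORE_FAMILY_COLUMNS:
            if (asm, fam) not in planted:
                assert m.loc[asm, fam] == 0


def test_match_reference_synthetases():
    from conftest import make_hit
    refs = {"QOW41315": "malpicyclin", "QOW41314": "malpibaldin"}
    hits = [
        make_hit("p1", "QOW41315", ident=95.0, bitscore=900),
        make_hit("p1", "QOW41314", ident=28.0, bitscore=100),   # below identity
        make_hit("p2", "QOW41314", ident=80.0, q_end=40, bitscore=300),  # low cov
        make_hit("p3", "other_ref", ident=99.0, bitscore=999),
    ]
    labels = tr.match_reference_synthetases(hits, refs)
    assert labels == {"p1": "malpicyclin"}


def test_rule_table_yaml_round_trip(tmp_path):
    path = tmp_path / "rules.yaml"
    tr.dump_rule_table(RULES, path)
    back = tr.load_rule_table(path)
    assert back == RULES
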