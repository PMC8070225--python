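import numpy as np
import pytest

from smcsurvey import synthetic as syn
from smcsurvey.io import GeneModel, ClusterRegion, SimilarityHit


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic survey corpus (seeded)."""
    return syn.generate_dataset(seed=11)


@pytest.fixture(scope="session")
def sim_hits(dataset):
    return syn.generate_hit_table(dataset, seed=11)


def make_hit(q="a", s="b", ident=90.0, evalue=1e-40, q_len=100, s_len=100,
             q_start=0, q_end=None, s_start=0, s_end=None, bitscore=200.0,
             ali_len=None):
    q_end = q_len if q_end is None else q_end
    s_end = s_len if s_end is None else s_end
    return SimilarityHit(
        query_id=q, subject_id=s, pct_identity=ident,
        ali_len=ali_len or (q_end - q_start), evalue=evalue,
        bitscore=bitscore, q_start=q_start, q_end=q_end,
        s_start=s_start, s_end=s_end, q_len=q_len, s_len=s_len)


def make_cluster(cid, genes_spec, contig="ctg1", assembly=None):
    """genes_spec: list of (gene_id, start, end, protein) or
    (gene_id, start, end, protein, strand)."""
    genes = []
    for spec in genes_spec:
        strand = spec[4] if len(spec) > 4 else "+"
        genes.append(GeneModel(spec[0], contig, spec[1], spec[2], strand,
                               spec[3]))
    end = max(g.end for g in genes) + 100 if genes else 1000
    return ClusterRegion(cluster_id=cid,
                         assembly_id=assembly or cid.split("__")[0],
                         contig=contig, start=0, end=end, genes=genes)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
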