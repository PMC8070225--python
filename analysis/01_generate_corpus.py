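#!/usr/bin/env python
"""Generate the synthetic survey corpus used by the downstream analyses.

Ten assemblies carrying every built-in SMC type, homologous cluster groups
shared across assemblies at 80% within-group protein identity, a planted
bacterial-origin signal in the NRPS/PKS/bacteriocin groups, and two kinds
of curation negatives.  All outputs land in results/corpus/ in the exact
formats the survey readers consume.
"""

from pathlib import Path

from smcsurvey import alien_index as ai
from smcsurvey import io as sio
from smcsurvey import synthetic as syn

SEED = 2021
OUT = Path(__file__).resolve().parent.parent / "results" / "corpus"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ds = syn.generate_dataset(syn.default_config(), seed=SEED)
    sio.write_cluster_genbank(ds.clusters, OUT / "regions.gbk")
    sio.write_domain_table(ds.domain_hits, OUT / "domains.tsv")
    sim = syn.generate_hit_table(ds, seed=SEED, between_rate=0.2)
    sio.write_similarity_table(sim, OUT / "similarity.tsv")
    # accessory genes are taxonomically neutral; core genes of the
    # bacterial-flagged groups carry the 20-orders-of-magnitude asymmetry
    tax = syn.generate_taxonomic_hits(ds, seed=SEED, effect_size=20.0,
                                      fungal_effect_size=0.0)
    ai.write_taxonomic_hits(tax, OUT / "taxonomic_hits.tsv")
    ds.truth.to_json(OUT / "truth.json")

    n_genes = sum(len(c.genes) for c in ds.clusters)
    print(f"corpus: {len(ds.assemblies)} assemblies, "
          f"{len(ds.clusters)} candidate SMCs, {n_genes} genes")
    print(f"similarity hits: {len(sim)}; taxonomic hits: {len(tax)}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
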