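# smcsurvey

Analysis toolkit for surveying **secondary-metabolite gene clusters (SMCs,
also called biosynthetic gene clusters / BGCs)** across many fungal genome
assemblies — the kind of corpus produced when antiSMASH-style cluster
detection is run over public early-diverging fungi (Mucoromycota)
assemblies and the resulting candidate regions, domain annotations and
homology searches need to be curated, typed, grouped and screened for
horizontally transferred genes.

It is written for comparative genomicists who already have the upstream
search outputs (GenBank region files, rps-blast/hmmscan domain hits,
DIAMOND/BLAST tabular homology hits, taxonomically restricted best-hit
tables) and want a reproducible, scriptable downstream analysis.

## What it computes

1. **Rule-based typing and curation** (`smcsurvey.typing_rules`).
   A cluster's type is a pure function of the union of Pfam/TIGRFAM/
   InterPro accessions over its proteins. The built-in rules encode the
   canonical signatures — NRPS requires adenylation (PF00501),
   condensation (PF00668) and a thioesterase/carrier domain
   (PF00975/PF00550); NRPS-like pairs a carrier or reductase domain with
   adenylation but vetoes condensation; a single IucA_IucC homologue
   (PF04183) suffices for the NIS siderophore call; terpene clusters match
   any prenyl-synthase/squalene-synthase/cyclase signature; DUF692
   (PF05114) marks bacteriocins. Candidates whose only signature is the
   4'-phosphopantetheinyl transferase ACPS (PF01648) are rejected as fatty
   acid synthesis, and signature-free candidates are dropped.
2. **Protein families by the Markov Cluster Algorithm**
   (`smcsurvey.families`). A from-scratch MCL over the protein similarity
   graph (edge weight `min(200, -log10 E)`, admission E ≤ 1e-10, inflation
   I = 1.55), with silhouette-width sampling of the (threshold, inflation)
   grid, size-ranked family identifiers (MCL0001 = largest) and
   MIBIG-category-style annotation with a bilateral >50% coverage rule.
3. **Synteny-aware cluster similarity network** (`smcsurvey.network`).
   All-vs-all hits filtered at ≥30% identity and ≥60% coverage of both
   sequences, grouped into syntenic regions with ≤1 Mbp between boundary
   intervals on both genomes, and scored per cluster pair as

   `score = n_hit_genes + 0.5 × (longest colinear hit chain)`

   with edges weighted by average percent identity. Single-match edges
   (`min_hits=1`) capture regions sharing only one gene — typical of
   siderophore regions — while the legacy mode requires two syntenic hits.
4. **Alien Index screening** (`smcsurvey.alien_index`). Per gene,

   `AI = ln(bestE_Dikarya + 1e-200) − ln(bestE_Bacteria + 1e-200)`

   over hits admitted at E ≤ 1e-05; AI > 0 means the bacterial hit is
   stronger. Per cluster the mean over all genes (`avg_AI`) and over the
   core-family genes only (`avg_AI_core`, core set = the presence/absence
   matrix families plus FAAL).
5. **Synthetic surveys with planted truth** (`smcsurvey.synthetic`), so the
   full pipeline runs — and is tested — without any external databases.

## Worked example

```bash
smcsurvey generate --out-dir demo --seed 7
# wrote 50 cluster regions, 562 similarity hits, 528 taxonomic hits to demo

smcsurvey run --regions demo/regions.gbk --domains demo/domains.tsv \
  --similarity demo/similarity.tsv --taxonomic demo/taxonomic_hits.tsv \
  --out-dir demo_out
# clusters_in        50
# clusters_retained  47
# clusters_rejected  3
# families           30
# edges              118
# components         10
# ai_records         127
```

Of the 50 synthetic candidates, the 3 planted negatives (two PF01648-only
fatty-acid-synthesis-like regions, one region without any biosynthetic
signature) are rejected and 47 typed clusters remain; the proteins fall
into 30 MCL families; the similarity network's 10 connected components are
exactly the 10 planted homology groups. `demo_out/` holds the typing table,
family table, per-assembly core-family matrix (cells 0/1/2 = absent /
single copy / multiple copies), GraphML + TSV network exports, component
summary and the per-gene/per-cluster Alien Index tables, e.g.

```
cluster_id            avg_AI      avg_AI_core
GCA_1000000__1_glim   -51.375975  -51.539414
```

(negative: the core gene's best Dikarya hit is ~51 natural-log units
stronger than its best bacterial hit).

The numbered scripts under `analysis/` run the same stages as a narrative
study over a generated corpus in `results/` — silhouette parameter grid,
typing tallies, network single-match comparison and an AI breakdown by
planted gene origin.

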