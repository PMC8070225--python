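# Methods

This note documents the models and procedures implemented in `smcsurvey`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic data do and do not show.

## Candidate regions and coordinates

Candidate SMC regions arrive as GenBank records (one region per record)
whose CDS features carry identifiers and translations. Internally all
coordinates are 0-based half-open; GenBank's 1-based inclusive convention
is converted at the I/O boundary, which keeps every downstream distance
computation free of off-by-one ambiguity. Compound (`join`) locations are
collapsed to their outer span: the analysis operates at gene granularity
and never models exon structure, so the outer interval is the only
quantity the synteny arithmetic needs. How upstream exporters handle
overlapping or trans-spliced genes is not standardised; outer-span
collapse is this package's choice and the only one it supports.

Domain-hit accessions are normalised (version suffixes stripped, CDD
`pfamNNNNN` mapped to `PFNNNNN`) so rule matching is independent of
database versions.

## Typing rules

A cluster type is a conjunction of any-of accession sets plus an optional
veto set, evaluated on the union of domain accessions over the cluster's
proteins. This makes `assign_type` a pure function of the domain set:
gene order, copy number and hit scores are irrelevant, and adding domains
can only add satisfied rules (except through a veto). Among satisfied
rules the highest priority becomes the primary type (default order
NRPS > PKS > siderophore > terpene > NRPS-like > bacteriocin); the others
are recorded as hybrid types — e.g. a siderophore synthase inside an NRPS
region yields primary NRPS with a siderophore hybrid flag.

Several signature accessions had to be pinned where only domain names are
in common use: condensation = PF00668, thioesterase = PF00975,
ketosynthase = PF00109/PF02801, ERG7-like cyclase = PF13249/PF13243
(squalene-hopene cyclase N/C), FAAL marker = PF13193 (AMP-binding C).
The prenyl-diphosphate synthase accession is PF00348 (polyprenyl
synthetase). The `SQS_NDUF6` matrix column is keyed to a package-defined
`NDUF6` marker token because no single public accession pins that
squalene-synthase subfamily; supplying annotations that use the marker is
the caller's responsibility. Users can replace the whole table via a YAML
rule file; priorities must be unique.

Curation retains every cluster satisfying at least one rule. Unassigned
clusters are rejected with reason `no biosynthetic signature`, except
where the ACPS 4'-phosphopantetheinyl transferase (PF01648) signature is
present, which marks primary fatty-acid synthesis rather than secondary
metabolism and yields the reason `fatty-acid-synthesis-like`. Noise
domains (transporters, P450s, …) never alter the verdict because they are
not signatures.

## Protein families (MCL)

The similarity graph admits a protein-vs-protein hit iff its E-value is at
most the admission threshold (default 1e-10) and weights the undirected
edge `min(200, -log10 max(E, 1e-200))`; reciprocal hits keep the larger
weight. The cap handles E = 0 and bounds the dynamic range; the homology
search itself never states an edge weighting, and the capped log transform
is the conventional choice.

MCL runs on the dense column-stochastic matrix: self-loops equal to each
node's maximum incident weight (1.0 for isolated nodes), then repeated
expansion (matrix squaring), inflation (entrywise power, default
I = 1.55, then column renormalisation) and pruning (entries < 1e-5
dropped, renormalised) until the largest entry change falls below 1e-6 or
100 iterations. Families are read off attractors (nodes retaining
diagonal mass); each node joins the attractor holding the largest share
of its column, ties to the smallest attractor index, and attractors that
tie onto each other are merged transitively — so the output is always a
partition, even though MCL can in principle emit overlaps. There is no
randomness anywhere; identical inputs give identical families. Family
identifiers are assigned by size rank (MCL0001 = largest), ties broken by
the lexicographically smallest member id, so ids are reproducible.

The silhouette sampler scores a parameter grid exhaustively under the
distance d(a,b) = 1 − weight(a,b)/200, with d = 1 for non-edges. s(i) is
the standard (b−a)/max(a,b); only points in clusters of size ≥ 2 are
averaged, while the nearest-other-cluster term ranges over every other
cluster including singletons. With fewer than two clusters of size ≥ 2
the sample is flagged undefined instead of scored. The grid ranges and
the distance are this package's documented defaults; they support
choosing an operating point, not a claim about how any particular study
sampled.

Family annotation follows a two-tier rule: families represented in ≥ 10
candidate SMCs are always labelled (reference-hit consensus or
`unlabelled-major`), smaller families of ≥ 2 members only when a
reference hit covers > 50% of both query and hit protein and carries a
biosynthetic, biosynthetic-additional or transporter category.

## Similarity network

Hits between proteins of different clusters are admitted at ≥ 30%
identity and ≥ 60% coverage. Coverage is computed normalised to each
sequence's own length and applied to *both* sides by default: the
bilateral reading is the stricter, symmetric interpretation of a
"minimum sequence coverage" threshold, and a query-only mode
(`bilateral_coverage=False`) is available where the unilateral reading is
wanted.

Per cluster pair, hits are grouped into syntenic regions by a single scan
in query-gene order: a hit joins the current group iff the gap between
the group's span boundary and the hit's gene interval is ≤ 1 Mbp on both
genomes (the boundary is inclusive: exactly 1.0 Mbp still joins). The
best group (most hits, ties by summed bitscore) is scored

    score = n_hit_genes + synteny_weight × synteny_score

where `n_hit_genes` counts distinct query genes, `synteny_score` is the
longest chain of hits colinear in gene order on both clusters (strand-
aware: a chain may run in reversed subject order) and `synteny_weight`
defaults to 0.5. An edge is emitted when `n_hit_genes ≥ min_hits`;
`min_hits = 1` (single-match mode) is the default because fragmented
regions — siderophore regions in particular, which often consist of a
single IucA/IucC homologue — connect through one shared gene only, while
`min_hits = 2` reproduces the legacy behaviour. The edge weight is the
mean percent identity over the best group's hits; genes without hits do
not contribute zeros, since zero-padding would make single-match weights
meaningless. One edge per unordered pair (the best group only) keeps the
graph simple. Exports are GraphML and a TSV edge list; layout is a
presentation concern and is not computed.

## Toy local aligner

`toy_local_align` is a self-contained Smith–Waterman (BLOSUM62, affine
gaps: first gapped residue costs gap_open + gap_extend = 12, extensions
1) that produces BLAST-tabular-like hits so end-to-end runs need no
external aligner. Its E-value is the Karlin–Altschul approximation
E = K·m·n·exp(−λS) with fixed gapped parameters λ = 0.267, K = 0.041 and
is documented as an approximation — adequate for exercising thresholds,
not a database-search statistic.

## Alien Index

    AI = ln(bestE_Dikarya + 1e-200) − ln(bestE_Bacteria + 1e-200)

computed over hits admitted at E ≤ 1e-05, restricted to the two taxon
groups Dikarya (recipient lineage) and Bacteria (candidate donors), with
self-matches excluded. Natural logarithm and the 1e-200 pseudocount
follow the established AI convention. A group without any admitted hit
contributes bestE = 1 — "no hit" is the weakest possible hit — which
keeps AI finite; a gene with no hit in either group contributes AI = 0 to
cluster means rather than being dropped, because dropping would bias the
means toward annotated genes (both conventions are parameters). Per
cluster, `avg_AI` averages over all member genes and `avg_AI_core` over
genes labelled with a core family (the presence/absence-matrix families
plus FAAL); `avg_AI_core` is undefined for clusters without a core gene.
Reports present AI values; no numeric threshold for declaring a gene
"bacterial" is imposed.

## Synthetic data

The generator emulates the *structure* of a survey corpus, not its
biology: homologous cluster groups instantiated from per-type domain
templates across assemblies, one shared protein family per gene slot at a
controlled within-group identity (default 80%), intergenic gaps of
0.2–2 kb, a configurable noise-domain rate (default 5% per gene, drawn
from accessions that never trigger a rule), and per-gene taxonomic
best-hit tables with a planted bacterial-vs-fungal asymmetry (default 20
orders of magnitude with ±3 log-uniform jitter; accessory genes can be
made taxonomically neutral).

Mutations are uniform substitutions — identity, not evolutionary realism,
is the controlled variable; there are no indels, no substitution-matrix
bias, no gene structure and no phylogeny. The synthetic E-value law
E = 10^(−(identity/100)·L/3), clipped to [1e-180, 10], is applied to the
alignment length L: within-family hits are full-length (a 250-residue
gene at 80% identity gives E ≈ 1e-66, far below the 1e-10 admission
threshold) while between-family hits are drawn as short local alignments
of 30–60 residues at 15–25% identity (E ≥ ~1e-5, above the threshold,
with coverage below the 60% network floor). Weak homology genuinely
produces short alignments, and applying the law to full gene lengths
would have pushed 20%-identity hits below 1e-10, defeating the planted
separation.

Consequently, passing tests show that the algorithms recover *planted*
structure under controlled separation; they do not show robustness to the
gradual identity decay, domain shuffling, fragmentation and annotation
error of real assemblies.

## Pipeline

`run_pipeline` sequences ingest → typing/curation → MCL families →
core-family matrix → network → Alien Index and writes every table with
sorted, fixed-format rows, so reruns on identical inputs are
byte-identical. Counts satisfy retained + rejected = input on every run.
AdenylPred-style substrate predictions are ingested (never computed) and
merged by protein id. Stage failures abort with the stage name and the
offending record.

## Problem sizes

The test suite and the acceptance script run at desk scale: 200 clusters
for typing fidelity, 5 × 8 proteins for planted-partition recovery, 100
random graphs of ≤ 12 nodes for the MCL/silhouette oracles, 20 clusters
in 5 homology groups for network recovery, 200 clusters for AI sign
recovery, and a 10-assembly / 50-cluster corpus for the end-to-end runs.
These sizes exercise every code path while keeping the whole suite in the
seconds range; nothing in the implementation is specific to them.
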