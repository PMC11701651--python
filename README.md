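# ontoexpr

Ontology-driven integration of bulk and single-cell RNA-seq expression
data: qualitative **present/absent expression calls** tested against an
intergenic background null, quantitative **0–100 expression scores** from
normalized expression ranks, **post-composed condition graphs** for
cross-experiment and cross-species queries, and **anatomical/cell-type
enrichment** of gene lists.

## Who this is for

Comparing expression across experiments, protocols and species is hard:
count matrices from different studies cannot be merged without batch
correction that risks erasing the biology of interest, and cell-population
labels are free-text and study-specific. `ontoexpr` takes the opposite
route: each library (or pseudo-bulked cell population) is annotated to a
*condition* — the intersection of an anatomical entity, a cell type, a
developmental stage, a sex and a strain, each drawn from a multispecies
ontology or controlled vocabulary — and only two protocol-robust summaries
are integrated across samples: a p-value against a within-sample noise
null, and a within-sample expression rank.

## The model

**Present/absent calls.** A stringent reference set of intergenic regions
(genome regions free of annotated genes, with regions expressed like genes
discarded as dubious) defines the expression noise distribution of every
sample. For gene *g* in a sample with *n* reference regions, of which *k*
have abundance ≥ the gene's abundance, the right-tail empirical p-value is

    p = (k + 1) / (n + 1)

which is strictly positive and super-uniform under the null. Droplet
single-cell libraries are first pseudo-bulked per author-annotated cell
population (raw counts summed, then library-normalized); intergenic regions
quantified in the same matrix give each pseudo-bulk sample its own null.
Per-gene p-values from all samples annotated to a condition *or to any of
its descendant conditions* in the condition graph are combined (Fisher by
default; Stouffer and a best-BH combiner are available), and the gene is
called **present** in the condition iff the integrated p ≤ α (default
0.05), with a gold/silver/bronze confidence tier.

**Expression scores.** Within each sample, detectable genes get fractional
ranks by decreasing abundance (rank 1 = most expressed); ranks are
normalized by `rank · global_max / sample_max` so protocols measuring fewer
genes share one rank axis; normalized ranks are averaged over the
condition's own and descendant samples; and the mean rank `r̄` is inverted
to a score in (0, 100]:

    score = 100 · (M + 1 − r̄) / M

with *M* the condition's maximum normalized rank — the top expressed gene
of a condition scores exactly 100.

**Queries and enrichment.** Annotations are retrievable with ontology
reasoning (AND across condition axes, OR within an axis, optional
child-term expansion for anatomy/cell type/stage). Gene lists are tested
for anatomical/cell-type over-representation with an exact hypergeometric
test, genes being mapped to terms by their present calls; the `elim`
scheme removes genes of significant descendant terms from their ancestors
before testing them, so broad terms do not merely echo their children.

## Worked example

Everything runs from synthetic data with known ground truth — no downloads:

```sh
ontoexpr simulate --seed 7 -o demo --n-genes 300 --n-intergenic 120 \
    --n-dubious 12 --n-cells 60
ontoexpr calls -c demo/config.yaml -o demo_calls.tsv
# INFO ontoexpr: wrote 9600 calls to demo_calls.tsv
ontoexpr pattern --calls demo_calls.tsv -g G000001
```

The pattern output orders the gene's present conditions by score,
highest expression first:

```
anat_id         cell_type_id    stage_id        sex      strain     score  data_types  source_samples
ANAT:0000000    CELL:0000003    STAGE:0000000   any sex  wild type  64.25  sc_droplet  SC01_c2,SC02_c2
ANAT:0000000    CELL:0000003    STAGE:0000001   any sex  wild type  64.25  sc_droplet  SC01_c2,SC02_c2
ANAT:0000001    CELL:0000003    STAGE:0000000   any sex  wild type  64.25  sc_droplet  SC01_c2,SC02_c2
```

Reading one row: gene `G000001` is called present in the condition
(anatomical entity `ANAT:0000000`, cell type `CELL:0000003`, any stage,
any sex, wild type) with an expression score of 64.25 — i.e. it ranks in
the upper third of that condition's expression levels — supported by two
pseudo-bulked single-cell populations (`SC01_c2`, `SC02_c2`), which the
last column lets you trace back. The calls TSV itself carries one row per
gene × condition with the integrated p-value, state, quality tier,
contributing data types, sample counts and the score columns.

The other subcommands: `query` (ontology-reasoned annotation search with
`--include-children`), `scores`, `topanat` (enrichment of a gene list
from a calls file) and `pseudobulk` (raw per-population count export).

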