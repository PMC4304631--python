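# seedbin

Unsupervised, reference-free binning of metagenomic sequencing reads into
species-level clusters.

A metagenomic sample mixes reads from many organisms, most of which have no
reference genome; *binning* — partitioning the reads by source organism — is
a prerequisite for downstream assembly and annotation. Composition-based
clustering uses the tetranucleotide (4-mer) frequency profile as a genomic
signature, but a single short read (~80 bp) carries far too little
compositional information to be classified on its own. seedbin works around
this with a two-phase algorithm:

**Phase 1 — overlap grouping.** Two reads *r*, *s* are declared overlapping
(*r* ⊓ *s*) when they share at least *m* distinct q-mers (default q = 30,
m = 5 for short reads, m = 45 for ~700 bp reads); with q this large, shared
q-mers almost always come from genuinely overlapping positions on one
genome. An overlap graph *H = (V, E)* is built over the reads and
partitioned greedily into groups *G₁…Gₚ*. While a group grows, a *seed*
S(Gᵢ) — an independent set of the overlap graph, i.e. mutually
non-overlapping reads — is built alongside it, capped at S_max = 9000 bp of
total sequence. The seed is a near non-redundant sample of the group's
source genome.

**Phase 2 — signature clustering.** Each seed's normalised, strand-collapsed
4-mer frequency vector

&nbsp;&nbsp;&nbsp;&nbsp;*f*ᵢ = *h*ᵢ / |G|,&nbsp;&nbsp; |G| = Σⱼ (|rⱼ| − 4 + 1)

(136 entries after merging each 4-mer with its reverse complement) is
computed, and the p groups are merged into k clusters by k-means,
minimising the within-cluster sum of squares
Σⱼ Σ_{Gᵢ∈Cⱼ} ‖f^{S(Gᵢ)} − f̄_{Cⱼ}‖². Every read inherits its group's
cluster. The number of clusters k (the number of species) is assumed known.

Binning quality is scored against ground truth with the standard
cluster-purity **precision**, species-cohesion **recall** (penalised by
unassigned reads) and their harmonic-mean **F-measure**, computed from the
confusion matrix A_ij = reads of species j in cluster i.

The package also ships a synthetic-data generator (per-species Markov
composition models, uniform read sampling from both strands, substitution
errors, exact truth records), so the whole pipeline is testable at desk
scale without downloads.

## Worked example

Simulate two compositionally divergent species (GC-rich vs AT-rich, 8 kb
genomes) at 1:1 abundance, bin the reads, and score the result:

```sh
$ cat demo.yaml
read_length: 80
error_rate: 0.0
n_reads: 1000
seed: 0
species:
  - label: spA
    genome_length: 8000
    gc_bias: 0.72
  - label: spB
    genome_length: 8000
    gc_bias: 0.28

$ seedbin simulate --spec demo.yaml --out-fasta reads.fa --out-truth truth.tsv
INFO simulated 1000 reads from 2 species -> reads.fa, truth.tsv

$ seedbin bin -i reads.fa -o assign.tsv -k 2 --seed 0 --report report.json
INFO loaded 1000 reads from reads.fa
INFO p=61 groups, k=2 clusters, objective=0.442514, 3 k-means iterations, 0.15s
INFO cluster 0: 500 reads
INFO cluster 1: 500 reads

$ seedbin eval --assignments assign.tsv --truth truth.tsv
precision	100.00%
recall	100.00%
F-measure	100.00%
```

Phase 1 grouped the 1000 reads into p = 61 single-species groups; k-means
on the 61 seed signatures separated the two species perfectly, so all three
metrics are 100%. `assign.tsv` is a two-column TSV (read id, cluster id);
`report.json` records the parameters, seed, group count, k-means objective
and cluster sizes needed to reproduce the run exactly.

The same pipeline is available as a scikit-learn style estimator:

```python
import seedbin as sb

reads = sb.read_sequences("reads.fa")
binner = sb.TwoPhaseBinner(n_clusters=2, random_state=0).fit(reads)
binner.labels_          # per-read cluster labels
binner.n_groups_        # phase-1 group count p
binner.model_.objective # final within-cluster sum of squares
```

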