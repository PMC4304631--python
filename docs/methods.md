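# Methods notes

## The model

seedbin assumes a metagenomic sample is a mixture of reads drawn from k
unknown genomes, with k given. Two observations drive the design:

1. **Long q-mers are genome-specific.** For q around 30, the fraction of
   q-mers shared between different bacterial genomes is tiny, so reads that
   share several distinct q-mers almost certainly come from overlapping
   positions of the same genome. The overlap relation used here — at least
   m shared distinct q-mers — is therefore a proxy for "sampled from
   intersecting intervals of one genome". Shared q-mers are counted as
   *distinct q-mer types* (set intersection), which is robust to low-order
   repeats within a read.

2. **Tetranucleotide signatures survive in groups of non-overlapping
   reads.** A single short read is compositionally uninformative, but the
   4-mer frequency vector of a few kilobases of *non-redundant* sequence
   from one genome is a usable genomic signature. Hence each phase-1 group
   is represented by its seed — an independent set of the overlap graph —
   rather than by all of its (mutually redundant) reads.

## Parameters

| name | default | meaning and rationale |
|------|---------|----------------------|
| q | 30 | q-mer length for overlap detection; long enough that cross-genome sharing is negligible. |
| m | 5 (short) / 45 (long) | minimum shared distinct q-mers for an overlap. The short-read preset suits ~80 bp reads (an overlap of o bases yields o − q + 1 shared q-mers, so m = 5 requires ≥ 34 aligned bases); 45 suits ~700 bp reads. m = 0 is floored to 1: a literal ≥ 0 threshold would connect every pair and collapse phase 1 into one group. |
| l | 4 | signature l-mer length; 4-mers are the standard compositional signature, giving a 136-entry strand-collapsed vector. |
| S_max | 9000 bp | seed size cap. ~9 kb of non-redundant sequence is enough for a stable 4-mer signature; capping also limits the damage a wrong edge can do, and forces abundant, well-covered species to spawn several groups, which stabilises phase 2 (see below). |
| max_iter | 100 | k-means iteration cap; convergence is otherwise declared on bitwise-stable means. |
| restarts | 1 | independent k-means initialisations (lowest objective kept). The default preserves the single-run behaviour of the core algorithm; see limitations. |

## Algorithmic choices

**Grouping (phase 1).** Groups grow breadth-first from a uniformly random
remaining node, with neighbor pushes in ascending index order — the
expansion order is otherwise unconstrained, and FIFO gives reproducibility
and spreads the seed along the genome. A node joins the seed iff it has no
edge to any *current seed member* (non-seed members are not consulted). The
cap is checked after each seed admission; when exceeded, the whole group
stops growing and un-admitted frontier nodes return to the pool and found
later groups. Isolated reads become singleton groups and are clustered like
any other; nothing is filtered.

**Signatures.** Each l-window is counted once under its canonical class
(lexicographic minimum of the window and its reverse complement), which is
equivalent after normalisation to counting both strands and halving.
Windows containing N are skipped and excluded from the normaliser. The
coordinate system — canonical l-mers in lexicographic order — is fixed and
part of the dump format, so vectors are comparable across runs.

**k-means (phase 2).** Lloyd iterations on the seed signature vectors.
Initial means are k distinct feature vectors drawn without replacement
(drawing without replacement avoids duplicate means). Nearest-mean ties
break toward the lowest cluster index. If an assignment step empties a
cluster, the cluster is reseeded with the point farthest from its currently
assigned mean (donor clusters keep at least one member), so exactly k
non-empty clusters survive to termination whenever p ≥ k; repairs are
counted on the fitted model (`n_repairs`) because a repair step may locally
break the usual monotone descent of the objective. Convergence requires
exactly stable means, matching the "no change in cluster means" stopping
rule.

**Evaluation.** Precision excludes unassigned reads from numerator and
denominator; recall counts them in the denominator only; F is the harmonic
mean, defined as 0 when either factor is 0. Reads lacking a truth label are
rejected rather than dropped, for metric integrity. Cluster and species
index sets are inferred from the data.

## The synthetic generator

Genomes are sampled from per-species Markov chains over {A,C,G,T} (order 2
by default; order 0 reduces to i.i.d. base weights). Distinct transition
models stand in for phylogenetic distance: the stock "divergent pair" uses
GC-biased vs AT-biased rows (GC 0.72 vs 0.28, log-normally jittered per
context), roughly the span of real bacterial GC content, emulating a large
phylogenetic distance. Reads are sampled uniformly with a uniformly random
strand and substitution-only errors (default 1%); indels are not modelled —
the pipeline is alignment-free, so indels would only perturb q-mer sharing
in a way substitutions already probe. Truth records (species, genome,
0-based half-open interval) make the true-overlap relation — same genome
and intersecting intervals — exactly computable. Mates of a paired-end
fragment are emitted as two independent reads (`/1`, `/2`); the binning
algorithm itself never uses mate information.

What the generator does **not** emulate: sequencing-technology error
profiles (quality-dependent errors, homopolymer artefacts), genome-scale
repeat structure, horizontal transfer, conserved genes shared across
species, or realistic (Mbp) genome sizes. Passing tests on this generator
show the algorithm's internal logic and its composition-separation
mechanism work; they do not certify performance on real communities, where
inter-species composition distances are usually far smaller.

## Desk-scale study conditions used in the tests

The end-to-end recovery test uses 1000 error-free 80 bp reads from two
divergent species at 1:1 and 1:4 abundance (q = 30, m = 5, S_max = 9000,
k = 2, fixed seeds), with 8 kb genomes. The genome size matters: it sets
coverage (5–12× here, a realistic shotgun regime at 1/400 scale) and it
must be large enough (≥ ~6 kb) that a seed *can* exceed S_max — otherwise
the cap is vacuous, an abundant species collapses into a single group, and
phase 2 degenerates to clustering one tight vector against a cloud, which
the within-cluster-sum-of-squares objective resolves poorly. With the cap
operative, both species contribute several seeds and recovery is robust
across genome sizes 6–12 kb. The signature-separation test uses groups of
60 disjoint error-free 150 bp reads (~9 kb per group) from 60 kb genomes,
mirroring the seed design size.

## Numerical details and degenerate inputs

- Reads shorter than q contribute no q-mers (an empty q-mer set, never an
  error); reads shorter than l yield an all-zero signature with
  `total_lmers = 0`.
- Signature vectors are exact ratios of int64 counts; the normalisation
  property is asserted to 1e-12 or better.
- The overlap graph construction via q-mer posting lists is exactly
  equivalent to the all-pairs definition (property-tested against a
  brute-force oracle); no sketching or approximation is used.
- Seed size may overshoot S_max by at most one read length (the cap is
  checked after admission); the structural test allows exactly that slack.
- Group building consumes randomness only for start-node draws, and
  k-means only for initialisation, both from a single user seed, so a run
  is reproduced byte-for-byte by its (input, parameters, seed) triple.

## Known limitations

- k must be supplied; there is no model selection over the cluster count,
  and no abundance-based modelling.
- A single k-means initialisation (the default) occasionally lands in a
  poor local optimum when the number of groups is small; `restarts` (CLI
  `--restarts`) mitigates this at proportional cost.
- Species with very similar composition (e.g. congeneric pairs) are not
  separable by 4-mer signatures regardless of grouping quality.
- Very low coverage fragments phase-1 groups into tiny seeds whose
  signatures are multinomial-noise dominated; expect degraded precision
  below ~2× coverage for a species.
- Paired-end mate linkage is not exploited to join groups.
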