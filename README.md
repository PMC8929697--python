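# famsplit

Split biological sequence families into dissimilar training and test sets
using independent-set graph algorithms.

## The problem

Benchmarking remote-homology detection (and training sequence models in
general) requires test sequences that are *not* close relatives of the
training sequences — a random split of an evolutionarily related family
leaks near-identical sequences across the boundary and inflates measured
performance. The standard remedy is an identity-thresholded split: given a
multiple sequence alignment, find a training set and a test set such that

* no test sequence is more than **p%** identical to any training sequence
  (p = 25 for proteins, 60 for RNA, is typical), and
* no two test sequences are more than **q%** identical (q = 50 typical),

allowing some sequences to be placed in neither set.

Cast in graph terms: vertices are alignment rows, and pairs with identity
> p% are edges of a graph G1. Step 1 finds a *bipartite independent pair*
(BIP) — disjoint sets S, T with no edge crossing between them; the larger
side trains. Step 2 finds a *maximal independent set* in the q-threshold
graph G2 restricted to T; that is the test set. Percent identity here is
the number of identical aligned columns divided by the shorter ungapped
sequence length.

The package implements four splitters:

| algorithm | step 1 (BIP) | step 2 (IS) | character |
|---|---|---|---|
| **cobalt** | greedy sequential, random order + coin | greedy sequential | fast, randomized |
| **blue** | random-priority elections | random-priority elections | splits the most families, slower |
| **cluster** | largest single-linkage cluster vs. rest | one representative per q-component | deterministic partition |
| **indepsel** | independent Bernoulli(0.70) selection | greedy sequential | baseline |

Single-linkage clustering (`cluster`) fails whenever one *bridge* sequence
is > p% identical into two otherwise dissimilar groups — the family
collapses into one cluster. Cobalt and Blue can exclude the bridge and
split the family anyway; that ability is the point of the package. Because
Cobalt and Blue are randomized, the `until` (run-until-n, first success)
and `best` (best-of-n, maximize |train|·|test|) modes re-run them with
replayable per-iteration seeds.

Pairwise identities are computed lazily and cached: an edge is evaluated
only when an algorithm first asks for it, so a run never exceeds the
C(N,2) all-pairs cost (O(L·N²) worst case for length-L sequences) and is
usually far below it.

## Worked example

Generate a family of two 15-sequence clusters joined by one chimeric
bridge, then try to split it:

```python
from famsplit.msa_io import write_stockholm
from famsplit.synthetic import FamilySpec, generate_family

fam = generate_family(FamilySpec(cluster_sizes=(15, 15),
                                 within_identity=0.40, n_bridges=1, seed=11))
with open("demo.sto", "w") as fh:
    write_stockholm(fam, fh)
```

```console
$ famsplit split demo.sto --algorithm cluster --mode until --seed 1 \
      --train-out train.sto --test-out test.fa
failed to split 'DEMO': reached |train|=31, |test|=0 (need 10/2)   # exit 1

$ famsplit split demo.sto --algorithm cobalt --mode until --seed 1 \
      --train-out train.sto --test-out test.fa
split 'DEMO' with cobalt: |train|=15, |test|=15, excluded=1 (run 1 of 1)
```

The bridge merges everything into one single-linkage cluster, so `cluster`
has nothing to hold out (exit status 1). Cobalt excludes the single bridge
sequence and returns one cluster as the training set (written as a
Stockholm alignment, row order permuted) and the other as the test set
(ungapped FASTA, 15 sequences). Every returned split is re-validated
eagerly: no train/test pair above 25% identity, no test/test pair above
50%.

`famsplit batch` applies the same procedure to every record of a
concatenated multi-MSA (e.g. a Pfam seed file), skips families with fewer
than 12 sequences, and writes a TSV report with per-family sizes and the
aggregate pass fraction.

For library use, `make_graph_pair(aln, p, q)` builds the two lazy graphs
and `split(g_p, g_q, cfg, algorithm=...)` returns a `SplitResult`;
`benchmark.make_positive` / `make_negatives` turn a test set into a
profmark-style search benchmark (each test domain embedded once in
shuffled background sequence, plus length-matched decoys).

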