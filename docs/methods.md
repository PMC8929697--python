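# Methods

## The splitting model

A family is an alignment of N gapped rows over L columns. Two thresholds
define two graphs on the rows: G1 has an edge where pairwise identity
exceeds p% (default 25), G2 where it exceeds q% (default 50). A valid
split is a pair (train, test) with no G1 edge between the sets and no G2
edge inside the test set; rows in neither set are excluded. Both edge
conditions are strict inequalities, so a valid split satisfies
"identity ≤ p%" across the boundary. A split is *successful* when
|train| ≥ min_train and |test| ≥ min_test (defaults 10/2, the usual gate
for seed-alignment benchmarks; 400/20 is typical for full alignments).
Failure is a structured result (`success=False`), never an exception, so
batch drivers can count pass rates.

### Percent identity dialect

identities ÷ min(ungapped lengths), case-insensitive, computed on the
given aligned pair without realignment; columns where either row is gapped
never count as identities; ambiguity codes compare by literal character
equality. Identity between two entirely-gapped rows is undefined and
raises. This normalization by the shorter sequence is the convention of
profile-HMM benchmark pipelines; published Pfam-scale split rates are
sensitive to the exact dialect, so reproducing them requires this
definition.

### The four algorithms

*Greedy sequential IS* (Cobalt step 2): scan a uniform random permutation,
add a vertex iff no neighbor was added before it. Always maximal. A vertex
v is added whenever all its neighbors come later in the order, so
P(v ∈ IS) ≥ 1/(d(v)+1): low-degree vertices — the remote outliers a
benchmark most wants — are favored.

*Greedy sequential BIP* (Cobalt step 1): scan a random permutation; each
vertex flips a fair coin for a preferred side and joins it unless it has a
neighbor on the *opposite* side, in which case it tries the other side the
same way, else it is excluded. Only cross-side adjacency blocks placement:
sides may contain internal edges, which is deliberate — the training set
keeps its redundancy, as real query alignments do. Consequence worth
noting: on a clique the whole clique lands on whichever side is seeded
first and the other side stays empty (a clique family genuinely cannot be
split).

*Random-priority IS* (Blue step 2): election rounds over the live set;
every live vertex draws a fresh uniform label, and label-local-minima join
the set, removing themselves and their neighbors. Label ties (possible
only at finite float precision) break by vertex index, keeping runs
deterministic under a fixed generator.

*Random-priority BIP* (Blue step 1): per-vertex eligibility is tracked for
both sides. Each round, singly-eligible vertices become candidates for
their side and doubly-eligible ones pick a side by fair coin; all
candidates draw labels. S-candidates, in a fresh random order, enter S
when their label beats every neighbor that is a still-T-eligible
T-candidate, immediately revoking the T-eligibility of their neighbors;
surviving T-candidates then enter T and revoke S-eligibility of theirs.
The global minimum label is placed every round, so the loop terminates.

*Cluster*: the largest connected component of G1 (ties: smallest
contained vertex index) trains; the remainder contributes one uniformly
chosen representative per G2-component. The partition is deterministic —
hence the bridge failure mode — and the test set is an independent set in
G2 but not necessarily maximal.

*Independent Selection*: every vertex joins the training set independently
with probability p_select = 0.70; unselected vertices with no selected
G1-neighbor are the test candidates, reduced by the greedy sequential IS
in G2. No size-based swap is applied.

After either BIP, the larger side is declared the training set (equal
sizes: no swap, the first side trains), and step 2 runs on the smaller
side only.

### Isolated-outlier assignment laws

For a row with no G1 neighbor at all (and hence none in G2 when p < q):
Cluster always tests it; Independent Selection tests it with probability
exactly 1 − p_select = 0.30; Cobalt and Blue test it about half the time —
the outlier's side coin is independent of where the rest of the family
lands, but exact 50% holds only when the two events are independent and
the swap rule does not interact, which the tests therefore assert with a
tolerance on a one-cluster-plus-outlier fixture rather than as a universal
constant.

### Repetitions and seeding

Run *i* of a repetition driver uses `numpy.random.default_rng([seed, i])`,
so any iteration can be replayed in isolation. `run-until-n` returns the
first success (else the last failure); `best-of-n` runs all n and returns
the successful split maximizing |train|·|test|, earliest run winning ties.
With a fixed config seed every algorithm is bit-reproducible.

### Laziness

Identities are computed on first query and memoized in a cache keyed on
the unordered pair; the p- and q-graphs of one family share the cache.
Total evaluations are therefore bounded by C(N,2) per family regardless of
how many algorithms or repetitions run, and traversals (e.g. Cluster's
component discovery on well-separated families) evaluate strictly fewer.

## Pre- and post-processing

Before splitting, rows shorter than 70% of the mean ungapped length are
removed (fragment filter); the mean is computed once on the unfiltered
family and the filter is applied exactly once — re-application could
cascade because the mean shifts. Gap characters are `-` and `.`;
ungapped length counts everything else. All-gap columns created by
filtering are retained so column indices stay stable. Training sets are
written as single Stockholm records with randomly permuted row order;
test sets as ungapped FASTA (test sequences are consumed individually by
the benchmark embedder, so alignment is not preserved). The Stockholm
reader accepts multi-record, wrapped and interleaved input and preserves
`-` vs `.` verbatim; annotation lines are not retained. Duplicate IDs
inside one block are an error; a repeated ID across blocks is, by the
format's nature, interleaving and is concatenated.

## Benchmark construction

Positives: each (down-sampled, ≤ 10 per family) test domain is embedded
once into a synthetic sequence whose total length is drawn from the
empirical length distribution of a background FASTA database conditioned
to be ≥ the domain length (rejection), at a uniform position; flanks are
windows cut uniformly from the database (entries weighted by their number
of feasible starts) and Fisher–Yates-shuffled, one fresh window per
segment. Negatives (default 200,000) copy the three segment lengths of a
uniformly chosen positive and fill all three segments the same way.
Embedding coordinates are 0-based half-open; positives record their flank
source windows so composition can be audited.

## Synthetic data

The generator emulates the similarity *structure* that matters to the
splitters, not protein evolution. Each cluster is an independent uniform
random consensus over the 20-letter alphabet; members substitute each site
independently at rate m = 1 − √w so same-cluster identity concentrates at
the target w (per-pair sd ≈ 0.03 at L = 300, plus a ≈ +0.003 bias from
coincident substitutions). Cross-cluster and outlier identities sit at the
≈ 5% alphabet background, far below p = 25. Bridges are verbatim
half/half chimeras of two cluster consensuses, ≈ w/2 + background/2
identical to each parent cluster's members — above 25% whenever the
clusters are solidly above it. Defaults: two clusters of 15, w = 0.80,
L = 200. Fixtures that need a splittable test side use w = 0.40 (between
p and q, so clusters are single G1 components but G2-edgeless); fixtures
exercising the bridge failure mode use w = 0.40 with one bridge. There
are no indels, no rate heterogeneity and no phylogenetic correlation, so
passing tests demonstrate algorithmic correctness on controlled similarity
structure — not performance on real families, where identity distributions
are broad and graph structure is far messier.

Abstract graph generators (edgeless, complete, path, cycle, star,
Erdős–Rényi, two-cliques-plus-bridge) feed the splitters directly through
the adjacency escape hatch, which is how the exact-distribution and
maximality suites avoid sequence-level noise entirely.

## Verification strategy and problem sizes

The randomized algorithms are checked against independent brute-force
oracles: exhaustive enumeration of the (permutation × coin) outcome space
on all catalogue graphs with ≤ 5 vertices (empirical distributions over
200,000 runs must match within total-variation distance 0.01), maximality
by addability checking on 1,000 seeded Erdős–Rényi graphs with n ≤ 12,
and eager all-pairs recomputation for every lazy-graph answer and returned
split. The isolated-outlier laws use 10,000 runs on a 30-sequence family
(three-standard-error window for the 30% law; the Cluster law is exact).
These sizes make the whole suite complete in a few minutes on one core
while leaving the statistical assertions well-powered.

## Known limitations

* Published Pfam-scale split rates depend on the percent-identity dialect
  of the reference pipeline; `scripts/pfam_split_rates.py` reproduces the
  procedure but needs a local Pfam-A.seed and hours of compute.
* The batch report's elapsed-time column is wall clock and is the one
  field that varies between otherwise identical replays.
* The per-family `--timeout` uses SIGALRM and is therefore POSIX-only and
  a CLI-level convenience, not part of algorithm semantics.
* Blue's cost grows with the number of election rounds times live-set
  scans; for families beyond tens of thousands of rows Cobalt is the
  practical choice.
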