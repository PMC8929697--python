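"""Training/test splitting algorithms for sequence families.

Splitting a family is a two-step graph problem.  Step 1 finds a *bipartite
independent pair* (BIP) in the graph G1 whose edges join sequences more than
p% identical: two disjoint vertex sets S, T with no edge crossing between
them.  The larger side becomes the training set; internal edges within a
side are allowed (training sets deliberately retain redundancy).  Step 2
reduces redundancy in the candidate test side by finding a maximal
independent set in the graph G2 (threshold q%) restricted to T; that set is
the test set.  Sequences in neither set are excluded — excluding a few
bridging sequences is exactly what lets these methods split families that
single-linkage clustering cannot.

Four methods are provided:

* **Cobalt** — greedy sequential BIP (step 1) + greedy sequential maximal IS
  (step 2), both driven by a random vertex permutation.
* **Blue** — random-priority BIP (step 1) + random-priority maximal IS
  (step 2): multi-round elections where a vertex wins if its fresh uniform
  label beats all competing neighbors'.
* **Cluster** — single-linkage clustering: the largest connected component
  of G1 trains; one random representative per G2-component of the rest is
  tested.  Deterministic in the partition, so a single bridging sequence
  collapses everything into one cluster and the split fails.
* **Independent Selection** — each vertex joins the training set
  independently with probability ``p_select``; unselected vertices with no
  selected neighbor are the test candidates.

Cobalt and Blue are randomized; the ``run-until-n`` and ``best-of-n``
drivers exploit that by re-running with derived sub-seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .msa_io import Alignment
from .similarity import connected_components, largest_component, percent_identity

__all__ = [
    "SplitConfig",
    "SplitResult",
    "ValidationReport",
    "greedy_sequential_is",
    "greedy_sequential_bip",
    "random_priority_is",
    "random_priority_bip",
    "split_cobalt",
    "split_blue",
    "split_cluster",
    "split_independent_selection",
    "ALGORITHMS",
    "run_until_n",
    "best_of_n",
    "split",
    "validate_split",
    "check_split_graphs",
]


@dataclass(frozen=True)
class SplitConfig:
    """Thresholds, size minima, and repetition policy for a split.

    Parameters
    ----------
    p:
        Maximum train/test percent identity (edges of G1 are pairs > p%).
        25 is the usual protein setting; 60 is typical for RNA.
    q:
        Maximum test/test percent identity (edges of G2).
    min_train, min_test:
        A split is a *success* only if both sets reach these sizes.
    mode:
        ``"single"`` (one run), ``"until"`` (run-until-n: first success), or
        ``"best"`` (best-of-n: maximize |train|·|test| over n runs).
    n_reps:
        Repetition count for the ``until``/``best`` modes.
    seed:
        Master seed; run *i* uses an independent generator derived from
        ``(seed, i)`` so repetitions are replayable run-by-run.
    p_select:
        Independent Selection only: probability a vertex joins the training
        set.
    blue_greedy_step2:
        Use the greedy sequential IS instead of the random-priority IS for
        Blue's second step.
    """

    p: float = 25.0
    q: float = 50.0
    min_train: int = 10
    min_test: int = 2
    mode: str = "single"
    n_reps: int = 1
    seed: int = 0
    p_select: float = 0.70
    blue_greedy_step2: bool = False

    def __post_init__(self):
        if not (0 <= self.p <= 100 and 0 <= self.q <= 100):
            raise ValueError("p and q must be percentages in [0, 100]")
        if self.min_train < 1 or self.min_test < 1:
            raise ValueError("min_train and min_test must be at least 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        if not 0 < self.p_select < 1:
            raise ValueError("p_select must be strictly between 0 and 1")
        if self.mode not in ("single", "until", "best"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class SplitResult:
    """Outcome of one split attempt (train/test/excluded partition V)."""

    train: tuple[int, ...]
    test: tuple[int, ...]
    excluded: tuple[int, ...]
    algorithm: str
    seed: int | None
    iteration: int
    success: bool
    objective: int
    runs_used: int = 1


def _vertices(g, vertices: Sequence[int] | None) -> list[int]:
    return sorted(range(g.n_vertices) if vertices is None else vertices)


def _shuffled(rng, verts: list[int]) -> list[int]:
    return [verts[i] for i in rng.permutation(len(verts))]


def greedy_sequential_is(g, rng, vertices: Sequence[int] | None = None) -> tuple[int, ...]:
    """Greedy sequential maximal independent set (Cobalt step 2).

    Scans a uniformly random permutation of the vertices, adding each vertex
    iff it has no neighbor already chosen.  The result is always a maximal
    independent set; low-degree vertices ("outlier" sequences) are the most
    likely to be included.
    """
    chosen: list[int] = []
    for v in _shuffled(rng, _vertices(g, vertices)):
        if not any(g.edge(v, u) for u in chosen):
            chosen.append(v)
    return tuple(sorted(chosen))


def greedy_sequential_bip(g, rng, vertices: Sequence[int] | None = None) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Greedy sequential bipartite independent pair (Cobalt step 1).

    Scans a random permutation; each vertex flips a fair coin for a
    preferred side, joins it if it has no neighbor on the *opposite* side,
    otherwise tries the other side the same way, otherwise is left out.
    No edge ever crosses between the returned sides (sides may have internal
    edges).  The larger side is returned first; on a tie no swap occurs.
    """
    S: list[int] = []
    T: list[int] = []
    for v in _shuffled(rng, _vertices(g, vertices)):
        if rng.random() < 0.5:
            if not any(g.edge(v, w) for w in T):
                S.append(v)
            elif not any(g.edge(v, w) for w in S):
                T.append(v)
        else:
            if not any(g.edge(v, w) for w in S):
                T.append(v)
            elif not any(g.edge(v, w) for w in T):
                S.append(v)
    if len(S) < len(T):
        S, T = T, S
    return tuple(sorted(S)), tuple(sorted(T))


def random_priority_is(g, rng, vertices: Sequence[int] | None = None) -> tuple[int, ...]:
    """Random-priority maximal independent set (Blue step 2).

    Repeated election rounds over the live vertex set: every live vertex
    draws a fresh uniform label, and a vertex whose label beats all live
    neighbors' labels enters the set, knocking its neighbors out.  Label
    ties (possible only at finite precision) break by vertex index.
    """
    live = set(_vertices(g, vertices))
    chosen: list[int] = []
    while live:
        round_verts = sorted(live)
        labels = {v: rng.random() for v in round_verts}
        for v in _shuffled(rng, round_verts):
            if v not in live:
                continue
            nbrs = [w for w in round_verts if w != v and w in live and g.edge(v, w)]
            if all((labels[v], v) < (labels[w], w) for w in nbrs):
                chosen.append(v)
                live.discard(v)
                live.difference_update(nbrs)
    return tuple(sorted(chosen))


def random_priority_bip(g, rng, vertices: Sequence[int] | None = None) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Random-priority bipartite independent pair (Blue step 1).

    Tracks each vertex's eligibility for the two sides.  Per round: a vertex
    eligible for only one side becomes a candidate for it, a doubly-eligible
    vertex picks a side by fair coin; all candidates draw uniform labels.
    S-candidates are processed in random order — one enters S if its label
    beats every neighbor that is both a T-candidate and still T-eligible,
    immediately revoking the T-eligibility of its neighbors.  Surviving
    T-candidates then enter T, revoking S-eligibility of their neighbors.
    Rounds repeat until nobody is eligible; the larger side is returned
    first (tie: no swap).  No edge crosses between the returned sides.
    """
    verts = _vertices(g, vertices)
    S: list[int] = []
    T: list[int] = []
    elig_s, elig_t = set(verts), set(verts)
    while elig_s or elig_t:
        cand_s: set[int] = set()
        cand_t: set[int] = set()
        for v in sorted(elig_s | elig_t):
            if v in elig_s and v in elig_t:
                (cand_s if rng.random() < 0.5 else cand_t).add(v)
            elif v in elig_s:
                cand_s.add(v)
            else:
                cand_t.add(v)
        labels = {v: rng.random() for v in sorted(cand_s | cand_t)}
        for v in _shuffled(rng, sorted(cand_s)):
            rivals = [w for w in cand_t if w in elig_t and g.edge(v, w)]
            if all((labels[v], v) < (labels[w], w) for w in rivals):
                S.append(v)
                elig_s.discard(v)
                elig_t.discard(v)
                elig_t.difference_update([w for w in elig_t if g.edge(v, w)])
        survivors = sorted(w for w in cand_t if w in elig_t)
        T.extend(survivors)
        for v in survivors:
            elig_t.discard(v)
            elig_s.discard(v)
            elig_s.difference_update([w for w in elig_s if g.edge(v, w)])
    if len(S) < len(T):
        S, T = T, S
    return tuple(sorted(S)), tuple(sorted(T))


def _make_result(
    algorithm: str,
    n: int,
    train: Sequence[int],
    test: Sequence[int],
    cfg: SplitConfig,
    seed: int | None = None,
    iteration: int = 0,
) -> SplitResult:
    train_t = tuple(sorted(train))
    test_t = tuple(sorted(test))
    used = set(train_t) | set(test_t)
    excluded = tuple(v for v in range(n) if v not in used)
    success = len(train_t) >= cfg.min_train and len(test_t) >= cfg.min_test
    return SplitResult(
        train=train_t,
        test=test_t,
        excluded=excluded,
        algorithm=algorithm,
        seed=seed,
        iteration=iteration,
        success=success,
        objective=len(train_t) * len(test_t),
    )


def split_cobalt(g_p, g_q, cfg: SplitConfig, rng) -> SplitResult:
    """Cobalt: greedy sequential BIP, then greedy sequential IS on the
    smaller side under the q-threshold graph."""
    train, cand = greedy_sequential_bip(g_p, rng)
    test = greedy_sequential_is(g_q, rng, vertices=cand)
    return _make_result("cobalt", g_p.n_vertices, train, test, cfg)


def split_blue(g_p, g_q, cfg: SplitConfig, rng) -> SplitResult:
    """Blue: random-priority BIP, then random-priority IS (or the greedy
    variant if configured) on the smaller side under the q-graph."""
    train, cand = random_priority_bip(g_p, rng)
    step2 = greedy_sequential_is if cfg.blue_greedy_step2 else random_priority_is
    test = step2(g_q, rng, vertices=cand)
    return _make_result("blue", g_p.n_vertices, train, test, cfg)


def split_cluster(g_p, g_q, cfg: SplitConfig, rng) -> SplitResult:
    """Cluster: largest single-linkage cluster trains; one random
    representative per q-component of the remainder is tested.

    The test set is an independent set in the q-graph but not necessarily a
    maximal one.  The train/test partition itself is deterministic; only the
    choice of representatives uses randomness.
    """
    comps = connected_components(g_p)
    train = largest_component(comps)
    train_set = set(train)
    rest = sorted(v for v in range(g_p.n_vertices) if v not in train_set)
    test = [
        comp[int(rng.integers(len(comp)))]
        for comp in connected_components(g_q, vertices=rest)
    ]
    return _make_result("cluster", g_p.n_vertices, train, test, cfg)


def split_independent_selection(g_p, g_q, cfg: SplitConfig, rng) -> SplitResult:
    """Independent Selection: vertices join the training set independently
    with probability ``p_select``; unselected vertices with no selected
    neighbor are candidates, reduced by greedy sequential IS at threshold q.

    The training set is S as drawn — no size-based swap."""
    verts = range(g_p.n_vertices)
    train = [v for v in verts if rng.random() < cfg.p_select]
    train_set = set(train)
    cand = [
        v for v in verts
        if v not in train_set and not any(g_p.edge(v, s) for s in train)
    ]
    test = greedy_sequential_is(g_q, rng, vertices=cand)
    return _make_result("indepsel", g_p.n_vertices, train, test, cfg)


ALGORITHMS: dict[str, Callable] = {
    "cobalt": split_cobalt,
    "blue": split_blue,
    "cluster": split_cluster,
    "indepsel": split_independent_selection,
}


def _run_rng(seed: int, i: int):
    # Deterministic per-iteration stream: replaying run i alone reproduces it.
    return np.random.default_rng([int(seed), int(i)])


def _one_run(split_fn, g_p, g_q, cfg: SplitConfig, i: int) -> SplitResult:
    res = split_fn(g_p, g_q, cfg, _run_rng(cfg.seed, i))
    return replace(res, seed=cfg.seed, iteration=i)


def run_until_n(split_fn, g_p, g_q, cfg: SplitConfig) -> SplitResult:
    """Run at most ``cfg.n_reps`` times; return the first success, else the
    last (failed) attempt."""
    res = None
    for i in range(cfg.n_reps):
        res = _one_run(split_fn, g_p, g_q, cfg, i)
        if res.success:
            return replace(res, runs_used=i + 1)
    return replace(res, runs_used=cfg.n_reps)


def best_of_n(split_fn, g_p, g_q, cfg: SplitConfig) -> SplitResult:
    """Run exactly ``cfg.n_reps`` times; among successes return the split
    maximizing |train|·|test| (ties: earliest run), else the last failure."""
    best: SplitResult | None = None
    last: SplitResult | None = None
    for i in range(cfg.n_reps):
        last = _one_run(split_fn, g_p, g_q, cfg, i)
        if last.success and (best is None or last.objective > best.objective):
            best = last
    chosen = best if best is not None else last
    return replace(chosen, runs_used=cfg.n_reps)


def split(g_p, g_q, cfg: SplitConfig, algorithm: str | None = None) -> SplitResult:
    """Dispatch on algorithm name and repetition mode."""
    if algorithm is None:
        raise ValueError("algorithm name required")
    try:
        fn = ALGORITHMS[algorithm]
    except KeyError:
        raise ValueError(f"unknown algorithm {algorithm!r}") from None
    if cfg.mode == "single":
        return replace(_one_run(fn, g_p, g_q, cfg, 0), runs_used=1)
    if cfg.mode == "until":
        return run_until_n(fn, g_p, g_q, cfg)
    return best_of_n(fn, g_p, g_q, cfg)


@dataclass(frozen=True)
class ValidationReport:
    """Eager check of a split against the identity criteria."""

    passed: bool
    max_train_test_pid: float
    max_test_test_pid: float
    violations: tuple[tuple[int, int, float], ...] = field(default_factory=tuple)


def validate_split(aln: Alignment, result: SplitResult, p: float, q: float) -> ValidationReport:
    """Recompute every train×test and test×test identity eagerly.

    Passes iff every train/test pair is at most p% identical and every
    test/test pair at most q% identical (the graph edge condition is a
    strict inequality, so equality is allowed).
    """
    for v in (*result.train, *result.test):
        if not 0 <= v < aln.n_rows:
            raise IndexError(f"vertex {v} outside alignment with {aln.n_rows} rows")
    violations: list[tuple[int, int, float]] = []
    max_tt = 0.0
    for u in result.train:
        for v in result.test:
            pid = percent_identity(aln.seqs[u], aln.seqs[v])
            max_tt = max(max_tt, pid)
            if pid > p / 100.0:
                violations.append((u, v, pid))
    max_ss = 0.0
    test = result.test
    for i in range(len(test)):
        for j in range(i + 1, len(test)):
            pid = percent_identity(aln.seqs[test[i]], aln.seqs[test[j]])
            max_ss = max(max_ss, pid)
            if pid > q / 100.0:
                violations.append((test[i], test[j], pid))
    return ValidationReport(
        passed=not violations,
        max_train_test_pid=max_tt,
        max_test_test_pid=max_ss,
        violations=tuple(violations),
    )


def check_split_graphs(g_p, g_q, result: SplitResult) -> bool:
    """Graph-level validity: partition of V, no p-edge crossing train/test,
    no q-edge inside the test set.  Used for abstract-graph fixtures."""
    n = g_p.n_vertices
    parts = (*result.train, *result.test, *result.excluded)
    if sorted(parts) != list(range(n)):
        return False
    if any(g_p.edge(u, v) for u in result.train for v in result.test):
        return False
    test = result.test
    return not any(
        g_q.edge(test[i], test[j])
        for i in range(len(test))
        for j in range(i + 1, len(test))
    )
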