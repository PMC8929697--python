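"""Independent brute-force oracles used to check the randomized algorithms.

Everything here is deliberately written from the problem definitions —
exhaustive enumeration over permutation/coin spaces, transitive closure,
addability checks — and never calls the implementation under test.
"""

from collections import Counter
from fractions import Fraction
from itertools import permutations, product

import networkx as nx


def adj_sets(n, edges):
    adj = [set() for _ in range(n)]
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def is_independent(adj, subset):
    subset = list(subset)
    return not any(
        v in adj[u] for i, u in enumerate(subset) for v in subset[i + 1 :]
    )


def is_maximal_independent_set(adj, subset):
    s = set(subset)
    if not is_independent(adj, s):
        return False
    return all(v in s or adj[v] & s for v in range(len(adj)))


def no_crossing_edges(adj, side_a, side_b):
    return not any(v in adj[u] for u in side_a for v in side_b)


def greedy_is_run(adj, order):
    """Deterministic greedy sequential IS for a fixed vertex order."""
    chosen = []
    for v in order:
        if not adj[v] & set(chosen):
            chosen.append(v)
    return frozenset(chosen)


def greedy_is_distribution(adj):
    """Exact outcome distribution of the greedy sequential IS: uniform over
    all vertex permutations."""
    n = len(adj)
    counts = Counter(greedy_is_run(adj, order) for order in permutations(range(n)))
    total = sum(counts.values())
    return {k: Fraction(v, total) for k, v in counts.items()}


def greedy_bip_run(adj, order, coins):
    """Deterministic greedy sequential BIP for a fixed order and coin vector.

    ``coins[i]`` applies to the i-th vertex processed; True means the vertex
    prefers the first side.  A side may be joined only if the vertex has no
    neighbor on the *opposite* side.  The larger side is reported first
    (tie: no swap).
    """
    S, T = set(), set()
    for v, prefer_s in zip(order, coins):
        first, second = (S, T) if prefer_s else (T, S)
        other_of = {id(S): T, id(T): S}
        if not adj[v] & other_of[id(first)]:
            first.add(v)
        elif not adj[v] & other_of[id(second)]:
            second.add(v)
    if len(S) < len(T):
        S, T = T, S
    return frozenset(S), frozenset(T)


def greedy_bip_distribution(adj):
    """Exact outcome distribution of the greedy sequential BIP: uniform over
    (permutation x fair-coin-vector) space."""
    n = len(adj)
    counts = Counter(
        greedy_bip_run(adj, order, coins)
        for order in permutations(range(n))
        for coins in product((True, False), repeat=n)
    )
    total = sum(counts.values())
    return {k: Fraction(v, total) for k, v in counts.items()}


def components_via_networkx(n, edges):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])


def total_variation(exact: dict, empirical: Counter, n_samples: int) -> float:
    keys = set(exact) | set(empirical)
    return 0.5 * sum(
        abs(float(exact.get(k, 0)) - empirical.get(k, 0) / n_samples) for k in keys
    )
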