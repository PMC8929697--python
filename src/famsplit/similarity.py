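"""Pairwise percent identity and lazily evaluated similarity graphs.

A family's similarity structure is modelled as a graph whose vertices are
alignment rows and whose edges connect pairs with percent identity strictly
above a threshold.  Because the splitting algorithms typically touch only a
fraction of all pairs, edges are computed on first query and cached; the
worst case over a whole run is the C(n, 2) all-pairs cost, never more.

Percent identity dialect: number of alignment columns where both rows carry
the same residue, divided by the smaller of the two ungapped lengths.
Comparison is case-insensitive and a column where either row is gapped never
counts as an identity.  The same aligned pair is always compared as given
(no realignment).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .msa_io import GAP_CHARS, Alignment, ungapped_length

__all__ = [
    "percent_identity",
    "PidCache",
    "SimilarityGraph",
    "AdjacencyGraph",
    "make_graph",
    "make_graph_pair",
    "connected_components",
    "largest_component",
]


def percent_identity(a: str, b: str) -> float:
    """Percent identity between two equal-length gapped rows, in [0, 1].

    identities / min(ungapped length of a, ungapped length of b), where an
    identity is a column with the same residue (case-insensitive) in both
    rows and neither row gapped.

    Raises
    ------
    ValueError
        If the rows differ in length or either row is entirely gaps.
    """
    if len(a) != len(b):
        raise ValueError("rows must have equal (aligned) length")
    au, bu = a.upper(), b.upper()
    denom = min(ungapped_length(au), ungapped_length(bu))
    if denom == 0:
        raise ValueError("percent identity undefined: a row is entirely gaps")
    ident = sum(
        1 for x, y in zip(au, bu) if x == y and x not in GAP_CHARS and y not in GAP_CHARS
    )
    return ident / denom


class PidCache:
    """Shared cache of pairwise identities over one alignment's rows.

    Rows are pre-encoded as byte arrays so each evaluation is a few
    vectorized comparisons.  The cache is keyed on the unordered pair, so a
    pair is computed at most once no matter how many threshold graphs share
    the cache or how often it is queried.
    """

    def __init__(self, aln: Alignment):
        self.n = aln.n_rows
        self._encoded = []
        gap_codes = np.frombuffer("-.".encode("ascii"), dtype=np.uint8)
        for seq in aln.seqs:
            arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
            nongap = ~np.isin(arr, gap_codes)
            self._encoded.append((arr, nongap, int(nongap.sum())))
        self._values: dict[tuple[int, int], float] = {}

    @property
    def n_computed(self) -> int:
        """Distinct pairs whose identity has actually been evaluated."""
        return len(self._values)

    def pid(self, u: int, v: int) -> float:
        key = (u, v) if u < v else (v, u)
        val = self._values.get(key)
        if val is None:
            a, nga, la = self._encoded[u]
            b, ngb, lb = self._encoded[v]
            denom = min(la, lb)
            if denom == 0:
                raise ValueError("percent identity undefined: a row is entirely gaps")
            val = int(((a == b) & nga & ngb).sum()) / denom
            self._values[key] = val
        return val


class SimilarityGraph:
    """Lazy percent-identity graph over the rows of one alignment.

    ``edge(u, v)`` is true iff the pairwise identity is *strictly greater*
    than the threshold, so any returned split satisfies "identity at most
    the threshold" across the train/test boundary.
    """

    def __init__(self, aln: Alignment, threshold_percent: float, cache: PidCache | None = None):
        if not 0 <= threshold_percent <= 100:
            raise ValueError("threshold must be between 0 and 100 percent")
        self.alignment = aln
        self.threshold = threshold_percent / 100.0
        self.cache = cache if cache is not None else PidCache(aln)
        if self.cache.n != aln.n_rows:
            raise ValueError("cache was built for a different alignment")
        self._queried: set[tuple[int, int]] = set()

    @property
    def n_vertices(self) -> int:
        return self.alignment.n_rows

    @property
    def n_pairs_evaluated(self) -> int:
        """Distinct pairs this graph has been asked about."""
        return len(self._queried)

    def pid(self, u: int, v: int) -> float:
        return self.cache.pid(u, v)

    def edge(self, u: int, v: int) -> bool:
        if u == v:
            return False
        self._queried.add((u, v) if u < v else (v, u))
        return self.cache.pid(u, v) > self.threshold


class AdjacencyGraph:
    """Explicit graph over integer vertices, given as an edge list.

    Drop-in alternative to :class:`SimilarityGraph` so the splitting
    algorithms can run on abstract graphs (fixtures, enumeration studies)
    without any sequences behind them.
    """

    def __init__(self, n_vertices: int, edges: Iterable[tuple[int, int]]):
        self.n_vertices = n_vertices
        adj: list[set[int]] = [set() for _ in range(n_vertices)]
        for u, v in edges:
            if u == v:
                continue
            if not (0 <= u < n_vertices and 0 <= v < n_vertices):
                raise ValueError(f"edge ({u}, {v}) outside vertex range")
            adj[u].add(v)
            adj[v].add(u)
        self.adjacency = tuple(frozenset(s) for s in adj)

    def edge(self, u: int, v: int) -> bool:
        return v in self.adjacency[u]

    def degree(self, v: int) -> int:
        return len(self.adjacency[v])

    @property
    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in range(self.n_vertices) for v in self.adjacency[u] if u < v]


def make_graph(aln: Alignment, threshold_percent: float, cache: PidCache | None = None) -> SimilarityGraph:
    """Build the lazy similarity graph of ``aln`` at a percent threshold."""
    return SimilarityGraph(aln, threshold_percent, cache=cache)


def make_graph_pair(aln: Alignment, p: float, q: float) -> tuple[SimilarityGraph, SimilarityGraph]:
    """Graphs at the train/test (p) and test/test (q) thresholds.

    Both graphs share one identity cache, so a pair evaluated for one
    threshold is free for the other.
    """
    cache = PidCache(aln)
    return SimilarityGraph(aln, p, cache=cache), SimilarityGraph(aln, q, cache=cache)


def connected_components(g, vertices: Sequence[int] | None = None) -> list[list[int]]:
    """Connected components, discovered by traversal with lazy edge queries.

    Equivalent to single-linkage clustering at the graph's threshold.  The
    partition is a deterministic function of the graph (no randomness).
    Components are returned sorted by their smallest vertex, each internally
    sorted.
    """
    verts = sorted(range(g.n_vertices) if vertices is None else vertices)
    unvisited = set(verts)
    components: list[list[int]] = []
    for seed in verts:
        if seed not in unvisited:
            continue
        unvisited.discard(seed)
        comp = [seed]
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            found = [w for w in sorted(unvisited) if g.edge(v, w)]
            for w in found:
                unvisited.discard(w)
            comp.extend(found)
            frontier.extend(found)
        components.append(sorted(comp))
    components.sort(key=lambda c: c[0])
    return components


def largest_component(components: list[list[int]]) -> list[int]:
    """Largest component; ties broken by smallest contained vertex index."""
    return max(components, key=lambda c: (len(c), -min(c)))
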