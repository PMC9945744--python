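"""Undirected-graph substrate for PPI link prediction.

A protein-protein interaction network is modelled as a simple undirected
graph over opaque string identifiers.  All predictors in this package are
built from three primitives defined here:

* constant-time neighbor-set lookup ``N(a)``,
* the *L3-elements* ``(x, y, U, V)`` of a candidate (non-adjacent) pair,
  where ``U = N(x) ∩ N(N(y))`` and ``V = N(y) ∩ N(N(x))``,
* the count of length-3 simple paths (P4 subgraphs) ``x–u–v–y``.

Adjacency is stored as hash sets, so membership queries are O(1) and
extracting the L3-elements of a pair costs O(|N(x)|·|N(y)|).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "PPINetwork",
    "L3Neighborhood",
    "UnknownNodeError",
    "AdjacentPairError",
    "l3_elements",
    "count_p4",
]


class UnknownNodeError(KeyError):
    """Raised when a node identifier is not present in the network."""

    def __init__(self, node: str):
        super().__init__(node)
        self.node = node

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return f"unknown node: {self.node!r}"


class AdjacentPairError(ValueError):
    """Raised when an operation defined only for candidate (non-adjacent)
    pairs is applied to an existing edge."""


class PPINetwork:
    """Simple undirected graph with hash-set adjacency.

    Invariants maintained by construction and mutation:

    * symmetry: ``b in N(a)`` iff ``a in N(b)``;
    * no self-loops;
    * ``edge_count`` equals half the sum of neighbor-set sizes.

    Node identifiers are opaque, case-sensitive strings.  The graph is
    treated as immutable while predictors score it; simulations mutate a
    :meth:`copy`.
    """

    __slots__ = ("_adj", "_m")

    def __init__(self, edges: Iterable[tuple[str, str]] = (), nodes: Iterable[str] = ()):
        self._adj: dict[str, set[str]] = {}
        self._m = 0
        for n in nodes:
            self._adj.setdefault(n, set())
        for a, b in edges:
            self.add_edge(a, b)

    # -- construction / mutation -------------------------------------------

    def add_node(self, a: str) -> None:
        self._adj.setdefault(a, set())

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-loop rejected: {a!r}")
        na = self._adj.setdefault(a, set())
        nb = self._adj.setdefault(b, set())
        if b not in na:
            na.add(b)
            nb.add(a)
            self._m += 1

    def remove_edge(self, a: str, b: str) -> None:
        try:
            self._adj[a].remove(b)
            self._adj[b].remove(a)
        except KeyError as exc:
            raise KeyError(f"no such edge: {{{a!r}, {b!r}}}") from exc
        self._m -= 1

    def copy(self) -> "PPINetwork":
        new = PPINetwork()
        new._adj = {n: set(nbrs) for n, nbrs in self._adj.items()}
        new._m = self._m
        return new

    # -- queries ------------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    @property
    def edge_count(self) -> int:
        return self._m

    def __contains__(self, a: str) -> bool:
        return a in self._adj

    def __len__(self) -> int:
        return len(self._adj)

    def neighbors(self, a: str) -> set[str]:
        """Return ``N(a)``.  The returned set is live adjacency state and
        must not be mutated by callers."""
        try:
            return self._adj[a]
        except KeyError:
            raise UnknownNodeError(a) from None

    def degree(self, a: str) -> int:
        return len(self.neighbors(a))

    def has_edge(self, a: str, b: str) -> bool:
        return b in self._adj.get(a, ())

    def edges(self) -> Iterator[tuple[str, str]]:
        """Iterate edges as lexicographically sorted pairs, in sorted order
        (deterministic wherever iteration order could leak into results)."""
        for a in sorted(self._adj):
            for b in sorted(self._adj[a]):
                if a < b:
                    yield (a, b)

    def candidate_pairs(self) -> Iterator[tuple[str, str]]:
        """All unordered non-adjacent pairs of distinct nodes, sorted."""
        order = sorted(self._adj)
        for i, a in enumerate(order):
            na = self._adj[a]
            for b in order[i + 1:]:
                if b not in na:
                    yield (a, b)

    def __repr__(self) -> str:
        return f"PPINetwork(n={len(self._adj)}, m={self._m})"


@dataclass(frozen=True)
class L3Neighborhood:
    """The L3-elements of one candidate pair.

    ``U`` are neighbors of ``x`` at distance 2 from ``y`` and ``V`` the
    symmetric set for ``y``; the two sets may overlap, since a node adjacent
    to both endpoints' neighborhoods can take either role in a P4.
    """

    x: str
    y: str
    U: frozenset[str] = field(default_factory=frozenset)
    V: frozenset[str] = field(default_factory=frozenset)


def _check_candidate(net: PPINetwork, x: str, y: str) -> None:
    if x not in net:
        raise UnknownNodeError(x)
    if y not in net:
        raise UnknownNodeError(y)
    if x == y:
        raise ValueError(f"candidate pair must be two distinct nodes, got {x!r} twice")
    if net.has_edge(x, y):
        raise AdjacentPairError(f"{{{x!r}, {y!r}}} is an edge; candidate pairs must be non-adjacent")


def l3_elements(net: PPINetwork, x: str, y: str) -> L3Neighborhood:
    """Extract ``(x, y, U, V)`` for a non-adjacent pair.

    Computed by scanning ``a ∈ N(x)``, ``b ∈ N(y)`` and testing the edge
    ``{a, b}``, so the cost is O(|N(x)|·|N(y)|) with O(1) set membership.

    Raises
    ------
    AdjacentPairError
        If ``{x, y}`` is an edge (callers must filter candidates first).
    UnknownNodeError
        If either endpoint is not in the network.
    """
    _check_candidate(net, x, y)
    nx_, ny_ = net.neighbors(x), net.neighbors(y)
    U: set[str] = set()
    V: set[str] = set()
    for a in nx_:
        na = net.neighbors(a)
        for b in ny_:
            if b in na:
                U.add(a)
                V.add(b)
    return L3Neighborhood(x=x, y=y, U=frozenset(U), V=frozenset(V))


def count_p4(net: PPINetwork, x: str, y: str) -> int:
    """Number of length-3 simple paths ``x–u–v–y`` (u ∈ U, v ∈ V, {u,v} an
    edge).  ``u ≠ v`` is automatic: there are no self-loops, and
    non-adjacency of ``{x, y}`` forces ``u ≠ y`` and ``v ≠ x``."""
    elems = l3_elements(net, x, y)
    V = elems.V
    return sum(len(net.neighbors(u) & V) for u in elems.U)
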