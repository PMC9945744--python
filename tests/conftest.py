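"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately take a different route from the library:
L3-elements are built from the set definitions U = N(x) ∩ N(N(y)) with
networkx adjacency, P4 counts come from explicit simple-path enumeration,
and the predictor formulas are evaluated term by term with no factor
hoisting or caching.
"""

from __future__ import annotations

import math

import networkx as nx
import pytest

from l3npred import PPINetwork

# 6-node toy fixture: x-u1, x-u2, u1-v1, u2-v1, u2-v2, v1-y, v2-y
T1_EDGES = [
    ("x", "u1"), ("x", "u2"), ("u1", "v1"), ("u2", "v1"),
    ("u2", "v2"), ("v1", "y"), ("v2", "y"),
]


@pytest.fixture
def toy_t1() -> PPINetwork:
    return PPINetwork(T1_EDGES)


@pytest.fixture
def four_cycle() -> PPINetwork:
    """x-a-y-b-x: two common neighbors of degree 2."""
    return PPINetwork([("x", "a"), ("a", "y"), ("y", "b"), ("b", "x")])


@pytest.fixture
def disjoint_stars() -> PPINetwork:
    """Two stars centered on x and y with no connecting path."""
    return PPINetwork([("x", "s1"), ("x", "s2"), ("y", "t1"), ("y", "t2")])


def to_nx(net: PPINetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(net.edges())
    return g


def er_network(n: int, p: float, seed: int) -> PPINetwork:
    g = nx.gnp_random_graph(n, p, seed=seed)
    net = PPINetwork(nodes=(f"n{i}" for i in g.nodes))
    for a, b in g.edges:
        net.add_edge(f"n{a}", f"n{b}")
    return net


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_uv(g: nx.Graph, x, y):
    """U = N(x) ∩ N(N(y)), V = N(y) ∩ N(N(x)) straight from the definitions."""
    nx_, ny_ = set(g[x]), set(g[y])
    n_of_ny = set().union(*(set(g[b]) for b in ny_)) if ny_ else set()
    n_of_nx = set().union(*(set(g[a]) for a in nx_)) if nx_ else set()
    return nx_ & n_of_ny, ny_ & n_of_nx


def brute_count_p4(g: nx.Graph, x, y) -> int:
    """Count simple paths x-u-v-y by explicit path enumeration."""
    return sum(
        1 for path in nx.all_simple_paths(g, x, y, cutoff=3) if len(path) == 4
    )


def _f(tag, A, B):
    A, B = set(A), set(B)
    if tag == "f1":
        return len(A & B) / len(A) if A else 0.0
    if not A and not B:
        return 0.0
    return len(A & B) / len(A | B)


def brute_l3(g, x, y) -> float:
    U, V = brute_uv(g, x, y)
    return sum(
        1.0 / math.sqrt(g.degree(u) * g.degree(v))
        for u in U for v in V if g.has_edge(u, v)
    )


def brute_ch2(g, x, y) -> float:
    U, V = brute_uv(g, x, y)
    c = U | V
    total = 0.0
    for u in U:
        for v in V:
            if not g.has_edge(u, v):
                continue
            nu, nv = set(g[u]), set(g[v])
            num = math.sqrt((1 + len(nu & c)) * (1 + len(nv & c)))
            den = math.sqrt(
                (1 + len((nu - c) - {x, y})) * (1 + len((nv - c) - {x, y}))
            )
            total += num / den
    return total


def brute_sim(g, x, y) -> float:
    U, V = brute_uv(g, x, y)
    return sum(_f("f2", set(g[v]), set(g[x])) for v in V) + sum(
        _f("f2", set(g[u]), set(g[y])) for u in U
    )


def brute_l3n(g, x, y, tag, prime=False) -> float:
    """Straight-from-formula evaluation: no hoisting, no cached factors."""
    U, V = brute_uv(g, x, y)
    total = 0.0
    for u in U:
        for v in V:
            if not g.has_edge(u, v):
                continue
            if prime:
                nu, nv = set(g[u]), set(g[v])
            else:
                nu, nv = set(g[u]) - {x}, set(g[v]) - {y}
            total += (
                _f(tag, set(g[x]), U)
                * _f(tag, set(g[y]), V)
                * _f(tag, nu, V)
                * _f(tag, nv, U)
                * _f(tag, set(g[x]), nv)
                * _f(tag, set(g[y]), nu)
            )
    return total
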