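"""Candidate-pair score functions for PPI link prediction.

Two families are implemented:

* **CN-based** predictors score a pair from its common immediate neighbors:
  Common Neighbors (CN), Resource Allocation (RA), Adamic-Adar (AA) and
  Cannistraci Resource Allocation (CRA).

* **L3-based** predictors score a pair from the length-3 paths between its
  endpoints: the degree-normalized L3 score, CH2_L3, Sim, and the
  NormalizedL3 family L3N / L3N′ introduced here, which scores each P4 by
  how closely the neighborhood of the pair resembles an *ideal L3 graph*
  (complete bipartite U-V core with x attached to U and y to V).

L3N is parameterised by a set-similarity metric ``f``: the simple ratio
``f1(A,B) = |A∩B| / |A|`` or the Jaccard coefficient
``f2(A,B) = |A∩B| / |A∪B|``.  For a candidate pair {x, y} with L3-elements
(U, V) the L3N score is

    P_xy = f(N(x),U) · f(N(y),V) ·
           Σ_{(u,v) edges, u∈U, v∈V}  f(N¬x(u),V) · f(N¬y(v),U)
                                     · f(N(x),N¬y(v)) · f(N(y),N¬x(u))

where ``N¬b(a) = N(a) \\ {b}``.  The six factors measure the three
ideality conditions N(x)=U, N(y)=V; N¬x(u)=V, N¬y(v)=U; and
N(x)=N¬y(v), N(y)=N¬x(u).  L3N′ is the variant that keeps x and y inside
the intermediate neighborhoods (an offset of one in the denominators),
which rewards larger interfaces.

Two controls are provided: a raw P4 count and a uniform-random ranker.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .graph import PPINetwork, _check_candidate, count_p4, l3_elements

__all__ = [
    "metric_f1",
    "metric_f2",
    "get_metric",
    "score_cn",
    "score_ra",
    "score_aa",
    "score_cra",
    "score_l3",
    "score_ch2",
    "score_sim",
    "score_l3n",
    "score_l3n_prime",
    "score_p4_control",
    "score_rand",
    "RankedPredictions",
    "score_all_candidates",
    "PREDICTORS",
    "L3_FAMILY",
]


# ---------------------------------------------------------------------------
# similarity metrics


def metric_f1(A: Iterable[str], B: set[str] | frozenset[str]) -> float:
    """Simple ratio |A∩B| / |A|; 0 when A is empty (no-evidence convention)."""
    A = set(A) if not isinstance(A, (set, frozenset)) else A
    if not A:
        return 0.0
    return len(A & B) / len(A)


def metric_f2(A: Iterable[str], B: set[str] | frozenset[str]) -> float:
    """Jaccard coefficient |A∩B| / |A∪B|; 0 when both sets are empty."""
    A = set(A) if not isinstance(A, (set, frozenset)) else A
    if not A and not B:
        return 0.0
    inter = len(A & B)
    return inter / (len(A) + len(B) - inter)


_METRICS: dict[str, Callable[[set[str], set[str]], float]] = {
    "f1": metric_f1,
    "f2": metric_f2,
}


def get_metric(tag: str) -> Callable[[set[str], set[str]], float]:
    try:
        return _METRICS[tag]
    except KeyError:
        raise ValueError(f"unknown similarity metric {tag!r}; expected 'f1' or 'f2'") from None


# ---------------------------------------------------------------------------
# CN-based predictors


def score_cn(net: PPINetwork, x: str, y: str) -> float:
    _check_candidate(net, x, y)
    return float(len(net.neighbors(x) & net.neighbors(y)))


def score_ra(net: PPINetwork, x: str, y: str) -> float:
    """Resource Allocation: common neighbors weighted by 1/degree."""
    _check_candidate(net, x, y)
    return sum(1.0 / net.degree(z) for z in net.neighbors(x) & net.neighbors(y))


def score_aa(net: PPINetwork, x: str, y: str) -> float:
    """Adamic-Adar: common neighbors weighted by 1/log(degree), natural log.

    Common neighbors of degree ≤ 1 are skipped (a common neighbor always
    has degree ≥ 2, so the guard only matters for pathological inputs).
    """
    _check_candidate(net, x, y)
    total = 0.0
    for z in net.neighbors(x) & net.neighbors(y):
        d = net.degree(z)
        if d > 1:
            total += 1.0 / math.log(d)
    return total


def score_cra(net: PPINetwork, x: str, y: str) -> float:
    """CRA: each common neighbor a scored by f1(N(a), A), A the common set."""
    _check_candidate(net, x, y)
    A = net.neighbors(x) & net.neighbors(y)
    return sum(len(net.neighbors(a) & A) / net.degree(a) for a in A)


# ---------------------------------------------------------------------------
# L3-based predictors


def _uv_edges(net: PPINetwork, U: frozenset[str], V: frozenset[str]):
    """Ordered role assignments (u, v), u ∈ U, v ∈ V, {u,v} an edge.

    A node in U∩V may act as u in one term and v in another, but never
    fills both roles of a single term (simple paths only).
    """
    for u in U:
        for v in net.neighbors(u) & V:
            yield u, v


def score_l3(net: PPINetwork, x: str, y: str) -> float:
    """Degree-normalized P4 count: Σ 1/sqrt(|N(u)|·|N(v)|) over U-V edges."""
    elems = l3_elements(net, x, y)
    return sum(
        1.0 / math.sqrt(net.degree(u) * net.degree(v))
        for u, v in _uv_edges(net, elems.U, elems.V)
    )


def score_ch2(net: PPINetwork, x: str, y: str) -> float:
    """CH2_L3: rewards u, v connected inside c = U∪V and penalises
    neighbors external to c (local-community paradigm on L3 neighborhoods)."""
    elems = l3_elements(net, x, y)
    c = elems.U | elems.V
    total = 0.0
    for u, v in _uv_edges(net, elems.U, elems.V):
        nu, nv = net.neighbors(u), net.neighbors(v)
        internal = (1 + len(nu & c)) * (1 + len(nv & c))
        ext_u = len((nu - c) - {x, y})
        ext_v = len((nv - c) - {x, y})
        total += math.sqrt(internal) / math.sqrt((1 + ext_u) * (1 + ext_v))
    return total


def score_sim(net: PPINetwork, x: str, y: str) -> float:
    """Sim: independent Jaccard similarity of each v to x and each u to y."""
    elems = l3_elements(net, x, y)
    nx_, ny_ = net.neighbors(x), net.neighbors(y)
    return sum(metric_f2(net.neighbors(v), nx_) for v in elems.V) + sum(
        metric_f2(net.neighbors(u), ny_) for u in elems.U
    )


def score_l3n(net: PPINetwork, x: str, y: str, metric: str = "f1") -> float:
    """NormalizedL3 with deleted neighborhoods ``N¬x(u)``, ``N¬y(v)``.

    The two outer factors f(N(x),U)·f(N(y),V) do not depend on (u, v) and
    are hoisted out of the sum.
    """
    f = get_metric(metric)
    elems = l3_elements(net, x, y)
    U, V = elems.U, elems.V
    if not U or not V:
        return 0.0
    nx_, ny_ = net.neighbors(x), net.neighbors(y)
    outer = f(nx_, U) * f(ny_, V)
    if outer == 0.0:
        return 0.0
    # per-node factors reused across the O(|U|·|V|) terms
    fu = {u: (f(net.neighbors(u) - {x}, V), f(ny_, net.neighbors(u) - {x})) for u in U}
    fv = {v: (f(net.neighbors(v) - {y}, U), f(nx_, net.neighbors(v) - {y})) for v in V}
    total = 0.0
    for u, v in _uv_edges(net, U, V):
        total += fu[u][0] * fv[v][0] * fv[v][1] * fu[u][1]
    return outer * total


def score_l3n_prime(net: PPINetwork, x: str, y: str, metric: str = "f1") -> float:
    """NormalizedL3 variant with the full neighborhoods N(u), N(v) kept.

    Keeping x in N(u) (and y in N(v)) offsets every intermediate factor by
    one, so larger compatible interfaces score strictly higher.
    """
    f = get_metric(metric)
    elems = l3_elements(net, x, y)
    U, V = elems.U, elems.V
    if not U or not V:
        return 0.0
    nx_, ny_ = net.neighbors(x), net.neighbors(y)
    outer = f(nx_, U) * f(ny_, V)
    if outer == 0.0:
        return 0.0
    fu = {u: (f(net.neighbors(u), V), f(ny_, net.neighbors(u))) for u in U}
    fv = {v: (f(net.neighbors(v), U), f(nx_, net.neighbors(v))) for v in V}
    total = 0.0
    for u, v in _uv_edges(net, U, V):
        total += fu[u][0] * fv[v][0] * fv[v][1] * fu[u][1]
    return outer * total


def score_p4_control(net: PPINetwork, x: str, y: str) -> float:
    """Control predictor: the raw P4 count, with no normalization."""
    return float(count_p4(net, x, y))


def score_rand(x: str, y: str, rng: random.Random) -> float:
    """Negative control: an i.i.d. uniform(0,1) draw per pair."""
    return rng.random()


# ---------------------------------------------------------------------------
# registry and bulk ranking

# name -> callable(net, x, y) (rand is handled specially in ranking)
PREDICTORS: dict[str, Callable[[PPINetwork, str, str], float]] = {
    "cn": score_cn,
    "ra": score_ra,
    "aa": score_aa,
    "cra": score_cra,
    "l3": score_l3,
    "ch2": score_ch2,
    "sim": score_sim,
    "l3n_f1": lambda net, x, y: score_l3n(net, x, y, "f1"),
    "l3n_f2": lambda net, x, y: score_l3n(net, x, y, "f2"),
    "l3n_prime_f1": lambda net, x, y: score_l3n_prime(net, x, y, "f1"),
    "l3n_prime_f2": lambda net, x, y: score_l3n_prime(net, x, y, "f2"),
    "p4": score_p4_control,
    "rand": None,  # type: ignore[dict-item]
}

#: predictors whose score is nonzero only when a P4 exists
L3_FAMILY = frozenset(
    {"l3", "ch2", "sim", "l3n_f1", "l3n_f2", "l3n_prime_f1", "l3n_prime_f2", "p4"}
)


@dataclass(frozen=True)
class RankedPredictions:
    """Deterministic descending ranking of candidate pairs.

    Ties are broken by a seeded shuffle before the stable sort, so equal
    scores are permuted reproducibly rather than falling back to insertion
    order.
    """

    predictor: str
    ordering: tuple[tuple[tuple[str, str], float], ...]
    tie_seed: int

    def __len__(self) -> int:
        return len(self.ordering)

    def pairs(self) -> list[tuple[str, str]]:
        return [p for p, _ in self.ordering]

    def to_tsv(self, path) -> None:
        """Write a 3-column TSV (node-a, node-b, score), nodes sorted in-row."""
        with open(path, "w") as fh:
            fh.write(f"# predictor={self.predictor}\ttie_seed={self.tie_seed}\n")
            for (a, b), s in self.ordering:
                fh.write(f"{a}\t{b}\t{s:.12g}\n")


def score_all_candidates(
    net: PPINetwork,
    predictor: str,
    seed: int = 0,
    l3_only: bool = False,
) -> RankedPredictions:
    """Score every unordered non-adjacent pair and rank by descending score.

    Parameters
    ----------
    predictor
        A registered predictor name (see :data:`PREDICTORS`).
    seed
        Seeds both the tie-breaking shuffle and the ``rand`` predictor.
    l3_only
        Fast path for L3-family predictors: only pairs joined by at least
        one P4 are scored; every other candidate carries score 0 and ranks
        after all positive-score pairs (in tie-shuffled order).

    Raises
    ------
    ValueError
        On an unknown predictor name or a graph with fewer than two nodes.
    """
    if predictor not in PREDICTORS:
        raise ValueError(f"unknown predictor {predictor!r}; known: {sorted(PREDICTORS)}")
    if len(net) < 2:
        raise ValueError("need at least 2 nodes to enumerate candidate pairs")
    if l3_only and predictor not in L3_FAMILY:
        raise ValueError(f"l3_only restriction applies to L3-family predictors, not {predictor!r}")

    rng = random.Random(seed)
    candidates = list(net.candidate_pairs())

    if predictor == "rand":
        scored = [(pair, rng.random()) for pair in candidates]
    else:
        fn = PREDICTORS[predictor]
        if l3_only:
            positive = _p4_reachable_pairs(net)
            scored = [
                (pair, fn(net, *pair) if pair in positive else 0.0) for pair in candidates
            ]
        else:
            scored = [(pair, fn(net, *pair)) for pair in candidates]

    rng.shuffle(scored)  # seeded tie-break, then stable sort on score only
    scored.sort(key=lambda ps: -ps[1])
    return RankedPredictions(predictor=predictor, ordering=tuple(scored), tie_seed=seed)


def _p4_reachable_pairs(net: PPINetwork) -> set[tuple[str, str]]:
    """Unordered non-adjacent pairs joined by at least one P4 (sorted tuples)."""
    out: set[tuple[str, str]] = set()
    for x in net.nodes:
        # nodes at exactly 3 hops along some walk x-a-b-y with y != x, y not adjacent
        nx_ = net.neighbors(x)
        for a in nx_:
            for b in net.neighbors(a):
                if b == x:
                    continue
                for y in net.neighbors(b):
                    if y == x or y in nx_ or y == a:
                        continue
                    out.add((x, y) if x < y else (y, x))
    return out
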