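"""Ideal-L3-graph sensitivity simulations and synthetic network generators.

An *ideal L3 graph* is the maximal-evidence configuration for one candidate
edge {x, y}: a complete bipartite graph on parts U and V, with x attached
to every node of U and y to every node of V (and x, y non-adjacent).  A
predictor that faithfully implements the L3 principle should react sharply
when this structure is perturbed.  Two perturbation protocols are provided:

* **removal**: delete *compatible* edges {u_i, v_j}, i ≠ j, one per
  iteration, uniformly at random; the |U| matched edges {u_i, v_i} are
  protected so the L3-elements (x, y, U, V) never change;
* **insertion**: insert *incompatible* edges ({u_i, u_j}, {v_i, v_j},
  {x, v_i}, {y, u_i}) one per iteration, uniformly at random.

Each trajectory records the candidate score of every requested predictor at
iteration 0 (the ideal graph) and after each edit.  Traces are normalized
per-trajectory to [0, 1] for cross-predictor comparison, summarised by
trapezoidal AUC (full or partial-from-minimum), and optionally smoothed
with a Savitzky-Golay filter for display.

A duplication-mutation-with-complementarity generator is also provided to
grow synthetic interactomes for end-to-end fixtures.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

from .graph import PPINetwork
from .predictors import PREDICTORS

__all__ = [
    "IdealL3Graph",
    "SimulationTrace",
    "build_ideal_l3",
    "classify_edges",
    "run_removal_sim",
    "run_insertion_sim",
    "normalize_trace",
    "trace_auc",
    "smooth_trace",
    "generate_dmc_network",
    "build_gadget_network",
]


@dataclass(frozen=True)
class IdealL3Graph:
    """An ideal L3 graph plus the bookkeeping the simulations need."""

    net: PPINetwork
    x: str
    y: str
    U: tuple[str, ...]
    V: tuple[str, ...]
    #: index-paired protected edges {u_i, v_i}, i < min(|U|, |V|)
    matching: tuple[tuple[str, str], ...]


def build_ideal_l3(nU: int, nV: int) -> IdealL3Graph:
    """Construct the ideal L3 graph with ``nU`` u-nodes and ``nV`` v-nodes.

    The result has ``nU + nV + 2`` nodes and ``nU·nV + nU + nV`` edges.
    Rectangular shapes are allowed; the protected matching pairs
    ``min(nU, nV)`` nodes under their indices.
    """
    if nU < 1 or nV < 1:
        raise ValueError(f"part sizes must be >= 1, got nU={nU}, nV={nV}")
    U = tuple(f"u{i}" for i in range(nU))
    V = tuple(f"v{j}" for j in range(nV))
    net = PPINetwork()
    for u in U:
        net.add_edge("x", u)
    for v in V:
        net.add_edge("y", v)
    for u in U:
        for v in V:
            net.add_edge(u, v)
    matching = tuple((U[i], V[i]) for i in range(min(nU, nV)))
    return IdealL3Graph(net=net, x="x", y="y", U=U, V=V, matching=matching)


def classify_edges(g: IdealL3Graph) -> tuple[set[frozenset[str]], set[frozenset[str]]]:
    """Partition the perturbation universe of an ideal L3 graph.

    Returns ``(compatible, incompatible)`` where compatible edges are the
    removable cross edges {u_i, v_j} with i ≠ j (the protected matching is
    excluded), and incompatible edges are the insertable corruptions:
    within-U, within-V, {x, v} and {y, u} edges.  {x, y} itself belongs to
    neither set.
    """
    matching = {frozenset(e) for e in g.matching}
    compatible = {
        frozenset((u, v)) for u in g.U for v in g.V if frozenset((u, v)) not in matching
    }
    incompatible: set[frozenset[str]] = set()
    incompatible.update(frozenset(p) for p in itertools.combinations(g.U, 2))
    incompatible.update(frozenset(p) for p in itertools.combinations(g.V, 2))
    incompatible.update(frozenset((g.x, v)) for v in g.V)
    incompatible.update(frozenset((g.y, u)) for u in g.U)
    return compatible, incompatible


@dataclass(frozen=True)
class SimulationTrace:
    """Per-iteration predictor scores along a perturbation trajectory.

    ``raw[name]`` is a (repeats, T+1) array: row r is repeat r, column t the
    score after t edits (column 0 is the unperturbed ideal graph).
    ``normalized`` holds the same trajectories divided by their own maxima.
    """

    kind: str  # "removal" | "insertion"
    iterations: np.ndarray
    raw: dict[str, np.ndarray]
    seed: int
    normalized: dict[str, np.ndarray] | None = None

    @property
    def predictors(self) -> list[str]:
        return list(self.raw)

    def band(self, predictor: str, normalized: bool = True):
        """Per-iteration (min, median, max) across repeats."""
        data = self._select(predictor, normalized)
        return data.min(axis=0), np.median(data, axis=0), data.max(axis=0)

    def _select(self, predictor: str, normalized: bool) -> np.ndarray:
        if normalized:
            if self.normalized is None:
                raise ValueError("trace is not normalized; call normalize_trace first")
            return self.normalized[predictor]
        return self.raw[predictor]

    def to_tsv(self, path) -> None:
        """Long-format TSV: iteration, predictor, repeat, raw, normalized."""
        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind}\tseed={self.seed}\n")
            fh.write("iteration\tpredictor\trepeat\traw\tnormalized\n")
            for name, arr in self.raw.items():
                norm = self.normalized[name] if self.normalized else None
                for r in range(arr.shape[0]):
                    for t in range(arr.shape[1]):
                        nval = "" if norm is None else f"{norm[r, t]:.12g}"
                        fh.write(f"{t}\t{name}\t{r}\t{arr[r, t]:.12g}\t{nval}\n")


def _derive_seed(root: int, stream: int, repeat: int) -> int:
    """Deterministic per-repeat seed below 2**31 (string hashing is process-
    salted in Python, so only integer arithmetic is used)."""
    return (root * 1_000_003 + stream * 524_287 + repeat) % (2**31 - 1)


def _check_predictors(predictors) -> list[str]:
    names = list(predictors)
    if not names:
        raise ValueError("predictors list must not be empty")
    for name in names:
        if name not in PREDICTORS or name == "rand":
            raise ValueError(f"predictor {name!r} cannot be traced (must be a scoring predictor)")
    return names


def run_removal_sim(
    g: IdealL3Graph,
    predictors,
    repeats: int = 10,
    seed: int = 0,
) -> SimulationTrace:
    """Remove compatible edges one at a time, uniformly at random.

    The matching edges are never removed, so (x, y, U, V) stay fixed along
    the whole trajectory; this is asserted at every step.  T equals the
    number of compatible edges; each repeat draws its own removal order from
    a seed derived from ``seed``.
    """
    names = _check_predictors(predictors)
    compatible, _ = classify_edges(g)
    order0 = sorted(tuple(sorted(e)) for e in compatible)
    T = len(order0)
    raw = {n: np.empty((repeats, T + 1)) for n in names}
    Uset, Vset = frozenset(g.U), frozenset(g.V)
    for r in range(repeats):
        rng = random.Random(_derive_seed(seed, 0, r))
        order = order0[:]
        rng.shuffle(order)
        net = g.net.copy()
        for n in names:
            raw[n][r, 0] = PREDICTORS[n](net, g.x, g.y)
        for t, (a, b) in enumerate(order, start=1):
            net.remove_edge(a, b)
            _assert_elements_fixed(net, g, Uset, Vset)
            for n in names:
                raw[n][r, t] = PREDICTORS[n](net, g.x, g.y)
    return SimulationTrace(
        kind="removal", iterations=np.arange(T + 1), raw=raw, seed=seed
    )


def _assert_elements_fixed(net, g, Uset, Vset):
    from .graph import l3_elements

    elems = l3_elements(net, g.x, g.y)
    assert elems.U == Uset and elems.V == Vset, "removal protocol changed the L3-elements"


def run_insertion_sim(
    g: IdealL3Graph,
    predictors,
    repeats: int = 10,
    seed: int = 0,
    freeze_elements: bool = False,
) -> SimulationTrace:
    """Insert incompatible edges one at a time, uniformly at random.

    By default the L3-elements are recomputed from the current graph at
    every iteration, so insertions of {x, v} / {y, u} edges move nodes
    between roles exactly as the set definitions dictate.
    ``freeze_elements=True`` instead scores against the ideal-graph U and V
    throughout (the alternative protocol reading).
    """
    names = _check_predictors(predictors)
    _, incompatible = classify_edges(g)
    order0 = sorted(tuple(sorted(e)) for e in incompatible)
    T = len(order0)
    raw = {n: np.empty((repeats, T + 1)) for n in names}
    score = _frozen_scorer(g) if freeze_elements else (
        lambda net, name: PREDICTORS[name](net, g.x, g.y)
    )
    for r in range(repeats):
        rng = random.Random(_derive_seed(seed, 1, r))
        order = order0[:]
        rng.shuffle(order)
        net = g.net.copy()
        for n in names:
            raw[n][r, 0] = score(net, n)
        for t, (a, b) in enumerate(order, start=1):
            net.add_edge(a, b)
            for n in names:
                raw[n][r, t] = score(net, n)
    return SimulationTrace(
        kind="insertion", iterations=np.arange(T + 1), raw=raw, seed=seed
    )


def _frozen_scorer(g: IdealL3Graph):
    """Score with U, V pinned to the ideal-graph parts (freeze_elements).

    Implemented by temporarily swapping the element extractor in both the
    graph and predictors modules; single-threaded use only.
    """
    from . import graph as G
    from . import predictors as P
    from .graph import L3Neighborhood

    Uset, Vset = frozenset(g.U), frozenset(g.V)

    def pinned(net_, x_, y_):
        return L3Neighborhood(x=x_, y=y_, U=Uset, V=Vset)

    def score(net, name):
        orig_p, orig_g = P.l3_elements, G.l3_elements
        try:
            P.l3_elements = pinned
            G.l3_elements = pinned
            return PREDICTORS[name](net, g.x, g.y)
        finally:
            P.l3_elements = orig_p
            G.l3_elements = orig_g

    return score


def normalize_trace(t: SimulationTrace) -> SimulationTrace:
    """Scale every repeat-trajectory by its own maximum into [0, 1].

    All scores here are non-negative, and the ideal-graph start point is the
    maximum along a removal trajectory, so removal traces start at exactly 1.
    An all-zero trajectory maps to all zeros.
    """
    normalized: dict[str, np.ndarray] = {}
    for name, arr in t.raw.items():
        peaks = arr.max(axis=1, keepdims=True)
        safe = np.where(peaks > 0, peaks, 1.0)
        normalized[name] = arr / safe
    return replace(t, normalized=normalized)


def trace_auc(t: SimulationTrace, mode: str = "full") -> dict[str, float]:
    """Trapezoidal AUC of each predictor's median normalized trajectory.

    The x-axis is rescaled to [0, 1].  ``mode="partial-from-min"``
    integrates from the argmin of the median trajectory to the end, with x
    rescaled over that window (the insertion-protocol summary: how fast the
    score rebounds after its dip).
    """
    if mode not in ("full", "partial-from-min"):
        raise ValueError(f"unknown mode {mode!r}")
    if t.iterations.size < 2:
        raise ValueError("trace must have at least 2 points")
    out: dict[str, float] = {}
    for name in t.raw:
        _, med, _ = t.band(name, normalized=True)
        if mode == "partial-from-min":
            start = int(np.argmin(med))
            med = med[start:]
            if med.size < 2:  # minimum at the last point: zero-width window
                out[name] = 0.0
                continue
        x = np.linspace(0.0, 1.0, med.size)
        out[name] = float(np.trapezoid(med, x))
    return out


def smooth_trace(t: SimulationTrace, window: int = 21, polyorder: int = 3) -> SimulationTrace:
    """Savitzky-Golay smoothing of every trajectory (presentation only).

    AUC statistics are computed on unsmoothed data unless a caller smooths
    explicitly first.
    """
    n_points = t.iterations.size
    if window % 2 == 0 or window <= polyorder or window > n_points:
        raise ValueError(
            f"window must be odd, > polyorder and <= trace length; "
            f"got window={window}, polyorder={polyorder}, length={n_points}"
        )
    smooth_raw = {n: savgol_filter(a, window, polyorder, axis=1) for n, a in t.raw.items()}
    smooth_norm = None
    if t.normalized is not None:
        smooth_norm = {
            n: savgol_filter(a, window, polyorder, axis=1) for n, a in t.normalized.items()
        }
    return replace(t, raw=smooth_raw, normalized=smooth_norm)


# ---------------------------------------------------------------------------
# synthetic interactome generators


def generate_dmc_network(
    n_final: int,
    p_keep: float = 0.7,
    p_anchor: float = 0.1,
    seed: int = 0,
) -> PPINetwork:
    """Grow a synthetic interactome by duplication-mutation-with-
    complementarity.

    Starting from a triangle, each step duplicates a uniformly chosen
    parent node: the duplicate inherits each parent edge independently with
    probability ``p_keep`` and gains an anchor edge to its parent with
    probability ``p_anchor``.  A duplicate that would end up isolated is
    anchored to its parent so the network stays connected-ish.  Gene
    duplication followed by divergent edge loss is the standard null model
    for the heavy-tailed, P4-rich structure of real interactomes.
    """
    if not (0.0 <= p_keep <= 1.0 and 0.0 <= p_anchor <= 1.0):
        raise ValueError(f"probabilities must be in [0, 1], got p_keep={p_keep}, p_anchor={p_anchor}")
    if n_final < 3:
        raise ValueError(f"n_final must be >= 3, got {n_final}")
    rng = random.Random(seed)
    net = PPINetwork([("g0", "g1"), ("g1", "g2"), ("g0", "g2")])
    names = ["g0", "g1", "g2"]
    while len(net) < n_final:
        parent = names[rng.randrange(len(names))]
        child = f"g{len(names)}"
        names.append(child)
        net.add_node(child)
        for nbr in sorted(net.neighbors(parent)):
            if rng.random() < p_keep:
                net.add_edge(child, nbr)
        if rng.random() < p_anchor or net.degree(child) == 0:
            net.add_edge(child, parent)
    return net


def build_gadget_network(
    n_gadgets: int = 6,
    n_side: int = 4,
    extra_edges: int = 0,
    seed: int = 0,
) -> tuple[PPINetwork, set[frozenset[str]]]:
    """Union of ideal-L3 gadgets, each completed with its true {x, y} edge.

    Returns the full network and the set of gadget {x, y} edges — the
    ground truth for end-to-end recovery experiments (hide these edges,
    rank all candidates, check that an L3 predictor recovers them).
    ``extra_edges`` uniformly random cross-gadget edges can be sprinkled in
    as noise.
    """
    net = PPINetwork()
    truth: set[frozenset[str]] = set()
    for k in range(n_gadgets):
        g = build_ideal_l3(n_side, n_side)
        rename = {n: f"G{k}_{n}" for n in g.net.nodes}
        for a, b in g.net.edges():
            net.add_edge(rename[a], rename[b])
        xk, yk = rename[g.x], rename[g.y]
        net.add_edge(xk, yk)
        truth.add(frozenset((xk, yk)))
    rng = random.Random(seed)
    nodes = sorted(net.nodes)
    added = 0
    while added < extra_edges:
        a, b = rng.sample(nodes, 2)
        if not net.has_edge(a, b) and frozenset((a, b)) not in truth:
            net.add_edge(a, b)
            added += 1
    return net, truth
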