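"""Cross-validation harness for edge predictors.

The evaluation protocol hides a fraction of a network's edges, scores and
ranks every remaining candidate pair, and walks the ranking against the
hidden set to produce a precision-recall curve:

    precision = tp / (tp + fp)        recall = tp / (tp + fn)

with tp/fp updated candidate by candidate and fn = |hidden| - tp.  The
summary statistic is the trapezoidal area under that curve (PR AUC),
optionally capped at a fixed recall (e.g. 10%) to focus on the head of the
ranking, where experimental validation effort would actually be spent.

Splits come from Monte-Carlo sampling (remove a fraction uniformly at
random, repeatedly) or k-fold cross-validation over edges.  Negative-PPI
injection replaces a fraction of the training edges with sampled non-edges
of the full network, holding the edge count fixed, to probe robustness to
false information.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .graph import PPINetwork
from .predictors import RankedPredictions

__all__ = [
    "EvalSplit",
    "PRCurve",
    "monte_carlo_split",
    "kfold_split",
    "inject_negatives",
    "pr_curve",
    "top_k_predictions",
    "overlap_ratio",
    "delta_pr_auc",
    "moving_mean",
    "compare_auc_ttest",
]

Edge = frozenset


@dataclass(frozen=True)
class EvalSplit:
    """One train/hidden split of a network.

    ``removed`` is the hidden ground-truth positive set; ``full`` keeps a
    reference to the unsplit network so negative injection can sample true
    non-edges.
    """

    train: PPINetwork
    removed: frozenset[Edge]
    full: PPINetwork
    seed: int
    injected_negatives: frozenset[Edge] = field(default_factory=frozenset)


def _edges_sorted(net: PPINetwork) -> list[tuple[str, str]]:
    return list(net.edges())


def _make_split(net: PPINetwork, removed_edges, seed: int) -> EvalSplit:
    train = net.copy()
    for a, b in removed_edges:
        train.remove_edge(a, b)
    return EvalSplit(
        train=train,
        removed=frozenset(Edge(e) for e in removed_edges),
        full=net,
        seed=seed,
    )


def monte_carlo_split(
    net: PPINetwork, fraction: float, repeats: int = 10, seed: int = 0
) -> list[EvalSplit]:
    """Remove ``round(fraction·m)`` edges uniformly at random, ``repeats``
    independent times (each repeat from a derived seed)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    edges = _edges_sorted(net)
    n_remove = round(fraction * len(edges))
    splits = []
    for r in range(repeats):
        sub_seed = (seed * 1_000_003 + r) % (2**31 - 1)
        rng = random.Random(sub_seed)
        removed = rng.sample(edges, n_remove)
        splits.append(_make_split(net, removed, sub_seed))
    return splits


def kfold_split(net: PPINetwork, k: int, seed: int = 0) -> list[EvalSplit]:
    """Partition edges into k folds; split i hides fold i and trains on the
    rest.  Folds are disjoint and exhaustive."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    edges = _edges_sorted(net)
    if k > len(edges):
        raise ValueError(f"k={k} exceeds edge count m={len(edges)}")
    rng = random.Random(seed)
    rng.shuffle(edges)
    folds = [edges[i::k] for i in range(k)]
    return [_make_split(net, fold, seed) for fold in folds]


def inject_negatives(split: EvalSplit, ratio: float, seed: int = 0) -> EvalSplit:
    """Replace ``round(ratio·train_m)`` training edges with uniformly
    sampled non-edges of the original full network.

    The train edge count is preserved.  Corrupted (replaced) true edges do
    *not* join the hidden ground-truth set: the harness scores recovery of
    the originally removed edges only.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"ratio must be in [0, 1], got {ratio}")
    if ratio == 0.0:
        return split
    train = split.train.copy()
    edges = _edges_sorted(train)
    n_swap = round(ratio * len(edges))
    rng = random.Random(seed)
    to_drop = rng.sample(edges, n_swap)
    for a, b in to_drop:
        train.remove_edge(a, b)

    nodes = sorted(split.full.nodes)
    n = len(nodes)
    max_non_edges = n * (n - 1) // 2 - split.full.edge_count
    if n_swap > max_non_edges:
        raise ValueError(f"cannot sample {n_swap} non-edges; only {max_non_edges} exist")
    negatives: set[Edge] = set()
    attempts = 0
    while len(negatives) < n_swap:
        attempts += 1
        if attempts > 200 * n_swap + 1000:
            raise RuntimeError("non-edge rejection sampling failed to converge")
        a, b = rng.sample(nodes, 2)
        e = Edge((a, b))
        if split.full.has_edge(a, b) or e in negatives or train.has_edge(a, b):
            continue
        negatives.add(e)
        train.add_edge(a, b)
    return EvalSplit(
        train=train,
        removed=split.removed,
        full=split.full,
        seed=split.seed,
        injected_negatives=frozenset(negatives),
    )


@dataclass(frozen=True)
class PRCurve:
    """Precision/recall sequence walked down a ranking, with trapezoidal AUC.

    The walk starts from an implicit (recall 0, precision of the first
    step) anchor so a perfect ranking integrates to exactly the recall span
    covered.
    """

    precision: np.ndarray
    recall: np.ndarray
    tp: int
    fp: int
    fn: int
    auc: float
    recall_cap: float | None = None

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# auc={self.auc:.12g}\trecall_cap={self.recall_cap}\n")
            fh.write("recall\tprecision\n")
            for r, p in zip(self.recall, self.precision):
                fh.write(f"{r:.12g}\t{p:.12g}\n")


def pr_curve(
    ranking: RankedPredictions,
    truth: set[Edge] | frozenset[Edge],
    recall_cap: float | None = None,
) -> PRCurve:
    """Walk a ranking against a hidden edge set.

    Every ranked candidate is classified in order (tp if in ``truth``, else
    fp); the walk stops once recall reaches ``recall_cap`` if one is set.
    AUC is the trapezoidal area over the recall range actually walked.
    """
    if not truth:
        raise ValueError("ground-truth edge set must be non-empty")
    truth = {Edge(e) for e in truth}
    n_truth = len(truth)
    tp = fp = 0
    precisions: list[float] = []
    recalls: list[float] = []
    for pair, _score in ranking.ordering:
        if Edge(pair) in truth:
            tp += 1
        else:
            fp += 1
        precisions.append(tp / (tp + fp))
        recalls.append(tp / n_truth)
        if recall_cap is not None and recalls[-1] >= recall_cap:
            break
    precision = np.array(precisions)
    recall = np.array(recalls)
    # anchor at recall 0 with the precision of the first step
    x = np.concatenate(([0.0], recall))
    ycurve = np.concatenate(([precision[0]], precision))
    auc = float(np.trapezoid(ycurve, x))
    return PRCurve(
        precision=precision,
        recall=recall,
        tp=tp,
        fp=fp,
        fn=n_truth - tp,
        auc=auc,
        recall_cap=recall_cap,
    )


def top_k_predictions(ranking: RankedPredictions, k: int) -> set[Edge]:
    """First k pairs of the ranking (ties already seeded-shuffled)."""
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if k > len(ranking):
        warnings.warn(
            f"k={k} exceeds the {len(ranking)} ranked candidates; returning all",
            stacklevel=2,
        )
        k = len(ranking)
    return {Edge(pair) for pair, _ in ranking.ordering[:k]}


def overlap_ratio(predA: set[Edge], predB: set[Edge]) -> float:
    """|A ∩ B| / k for two size-k prediction sets."""
    if len(predA) != len(predB):
        raise ValueError(f"prediction sets must have equal size, got {len(predA)} vs {len(predB)}")
    if not predA:
        return 1.0
    return len(predA & predB) / len(predA)


def delta_pr_auc(auc_by_ratio: dict[float, list[float]]) -> float:
    """Mean relative change of mean PR AUC across consecutive negative-PPI
    ratios; negative values mean degradation as corruption grows."""
    if len(auc_by_ratio) < 2:
        raise ValueError("need AUCs for at least two ratios")
    ratios = sorted(auc_by_ratio)
    means = [float(np.mean(auc_by_ratio[r])) for r in ratios]
    deltas = []
    for prev, nxt in zip(means, means[1:]):
        if prev == 0.0:
            raise ValueError("zero baseline AUC: relative change undefined")
        deltas.append((nxt - prev) / prev)
    return float(np.mean(deltas))


def moving_mean(values, window: int = 100, step: int = 10) -> np.ndarray:
    """Mean over sliding windows advancing ``step`` positions per output."""
    values = np.asarray(values, dtype=float)
    if window > values.size:
        raise ValueError(f"window={window} exceeds sequence length {values.size}")
    starts = range(0, values.size - window + 1, step)
    return np.array([values[s : s + window].mean() for s in starts])


def compare_auc_ttest(aucsA, aucsB) -> float:
    """Two-tailed independent two-sample t-test p-value on PR-AUC samples.

    Two identical zero-variance samples return p = 1 by convention.
    """
    a = np.asarray(aucsA, dtype=float)
    b = np.asarray(aucsB, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    if a.std() == 0.0 and b.std() == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    p = stats.ttest_ind(a, b).pvalue
    return float(p)
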