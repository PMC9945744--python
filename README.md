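# l3npred

Link prediction for protein–protein interaction (PPI) networks based on the
**L3 principle**, including the **NormalizedL3 (L3N / L3N′)** family of
predictors, the classical baselines, sensitivity simulations on ideal L3
graphs, and a Monte-Carlo precision–recall evaluation harness.

## The problem

High-throughput interactome maps are incomplete: many true PPIs are missing
from every curated database. Link prediction ranks the non-adjacent protein
pairs of a known network by how strongly the surrounding topology suggests a
direct interaction. Two competing topological principles exist:

* **Triadic closure (CN):** many shared neighbors ⇒ likely edge. For PPIs
  this is biologically suspect — two proteins with near-identical
  interaction interfaces usually *cannot* dock with each other.
* **L3 principle:** many paths of length three (P4 subgraphs `x–u–v–y`) and
  few paths of length two ⇒ likely edge, because `x` then resembles the
  known partners of `y` (interface complementarity).

For a candidate pair `{x, y}` define the L3-elements
`U = N(x) ∩ N(N(y))` and `V = N(y) ∩ N(N(x))`. The classical L3 score
penalises high-degree intermediates empirically:

    L3:   P_xy = Σ_{(u,v) ∈ E, u∈U, v∈V}  1 / √(|N(u)|·|N(v)|)

## NormalizedL3

L3N instead scores each P4 by how closely the neighborhood of the pair
matches an *ideal L3 graph* — the maximal-evidence configuration: a complete
bipartite graph on `U, V` with `x` attached to all of `U` and `y` to all of
`V`. With a set-similarity metric `f` (simple ratio `f1(A,B) = |A∩B|/|A|`
or Jaccard `f2(A,B) = |A∩B|/|A∪B|`) and `N¬b(a) = N(a)\{b}`:

    L3N(f):  P_xy = f(N(x),U) · f(N(y),V) ·
                    Σ_{(u,v)} f(N¬x(u),V) · f(N¬y(v),U) · f(N(x),N¬y(v)) · f(N(y),N¬x(u))

`L3N′` is the variant using the full neighborhoods `N(u), N(v)` inside the
sum, which offsets every factor by one and rewards larger interfaces. On an
ideal L3 graph with `|U| = |V| = n` these identities hold exactly:
`L3N(f1) = L3N(f2) = n²`, `L3 = n²/(n+1)`, `L3N′(f1) = n²·(n/(n+1))²`.

Implemented predictors: `cn`, `ra`, `aa`, `cra` (CN-based); `l3`, `ch2`,
`sim`, `l3n_f1`, `l3n_f2`, `l3n_prime_f1`, `l3n_prime_f2` (L3-based);
`p4` (raw path-count control) and `rand` (uniform-random control).

## Worked example

Hide the true `{x, y}` edges of a small synthetic network assembled from
ideal-L3 gadgets, then rank all candidate pairs with L3N′(f1):

```python
import l3npred as L

net, truth = L.build_gadget_network(n_gadgets=4, n_side=3, extra_edges=8, seed=7)
train = net.copy()
for e in truth:
    train.remove_edge(*tuple(e))

ranking = L.score_all_candidates(train, "l3n_prime_f1", seed=1, l3_only=True)
for (a, b), s in ranking.ordering[:6]:
    print(a, b, round(s, 4), "*" if frozenset((a, b)) in truth else "")
print("PR AUC:", L.pr_curve(ranking, truth).auc)
```

prints

```
G3_x G3_y 4.095 *
G2_x G2_y 2.6578 *
G1_x G1_y 2.4806 *
G0_x G0_y 1.7719 *
G0_v1 G3_u1 0.1684
G0_v0 G3_u2 0.1684
PR AUC: 1.0
```

All four hidden interactions rank above every one of the 1607 other
candidates (starred rows), so the precision–recall curve walked down this
ranking has area 1.0 — perfect recovery. The score of each recovered pair
grows with how intact its L3 neighborhood is: gadget 3, least damaged by
the random noise edges, scores highest.

The same workflow is available from the shell:

```sh
l3npred generate --dmc 500 --seed 1 --out net.tsv
l3npred predict  --input net.tsv --predictor l3n_prime_f1 --out ranked.tsv
l3npred simulate --removal --nu 50 --nv 50 --out trace.tsv
l3npred evaluate --input net.tsv --predictors l3n_prime_f1,l3,cn \
                 --fraction 0.5 --repeats 10 --seed 7 --out aucs.tsv
```

Edge lists are two-column TSV/CSV files; loading collapses directional
duplicates, drops repeated evidence lines and (by default) removes
self-interacting proteins, reporting the exact accounting in a manifest.

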