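# pilesort

Tools for **network-based theme elicitation** from independent card sorts —
the computational core of participatory qualitative analysis methods in
which several analysts (for example, researchers with lived experience
working alongside academic researchers) each sort a shared deck of quote
cards into labelled piles, and the combined sorting pattern is turned into
quote groupings by community detection.

The pipeline:

1. **Sorting table** — a long-format, three-column table
   `(researcher, quote, pile)`; each researcher's piles must partition the
   quote set into at least two piles (no "miscellaneous" pile).
2. **Co-sort network** — quotes are nodes; an edge joins two quotes if at
   least one researcher co-placed them, with integer weight
   `w_ij = #{r : pile_r(i) = pile_r(j)}`.
3. **Groupings** — communities found by maximising weighted
   Newman–Girvan modularity

   `Q = (1/2m) Σ_ij [w_ij − γ k_i k_j / 2m] δ(c_i, c_j)`

   with the Louvain heuristic (seeded, deterministic, resolution γ = 1 by
   default), plus an exhaustive small-graph optimum used as a test oracle.
4. **Congruence statistics** — per human-curated theme, the dominant
   grouping and the percentage of theme quotes carrying it (ties report the
   full count breakdown); adjusted Rand index between whole partitions;
   Jaccard best-matching between two theme sets.
5. **Synthetic studies** — a seeded generator with planted theme structure
   (per-quote move noise, pile splits/merges) for recovery experiments.

The clustering core is also exposed as scikit-learn estimators
(`CoSortTransformer`, `LouvainClusterer`) that compose with
`sklearn.pipeline`.

## Worked example

```python
from pilesort import (SyntheticConfig, generate_study, build_cosort_network,
                      louvain, modularity, adjusted_rand_index)

cfg = SyntheticConfig(n_quotes=89, n_researchers=4, n_themes=4,
                      p_move=0.1, seed=7)
study, truth = generate_study(cfg)          # 4 researchers sort 89 quotes
net = build_cosort_network(study)           # weighted co-occurrence graph
groups = louvain(net, seed=0)               # quote -> grouping label (1..K)
print(max(groups.values()),                 # 4     detected groupings
      round(modularity(net, groups), 3),    # 0.519 partition quality
      round(adjusted_rand_index(groups, truth), 3))  # 0.969 vs planted truth
```

Output: `4 0.519 0.969` — with 10% per-quote sorting noise the four planted
themes are recovered almost exactly; at zero noise recovery is exact
(ARI = 1.0).

The same pathway from the shell:

```sh
pte simulate --out sim --quotes 89 --researchers 4 --themes 4 --p-move 0.1
pte validate sim/sorting_table.csv
pte run sim/sorting_table.csv --out out     # network.graphml, network.dot,
                                            # assignment.csv, groups.txt
pte congruence themes.txt out/assignment.csv --rounding one_decimal
pte compare themes_groupA.txt themes_groupB.txt
```

`groups.txt` is the grouped-quote sheet (one block of canonical quote IDs
per grouping) that analysts discuss when turning groupings into themes.

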