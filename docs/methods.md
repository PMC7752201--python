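# Methods

## The procedure

The package operates on *open card sorts*: R analysts each partition the
same N quote cards into piles of their own devising, independently, with
two protocol rules — at least two piles, and every quote sorted exactly
once (no "miscellaneous" pile). Sorting data arrive as a long-format table
of `(researcher, quote, pile)` records. Pile labels are opaque and carry
meaning only within one researcher's sort; two researchers' pile "3" are
unrelated.

From the sorts we build the **co-sort network**: nodes are quotes, and the
weight of edge {i, j} counts the researchers who co-placed i and j, so
0 ≤ w_ij ≤ R and an edge exists iff w_ij ≥ 1. Quotes never co-placed with
anything remain as isolated nodes, because every quote must appear in the
grouped output handed back to analysts. Weights obey a conservation law
used as a validation identity throughout the tests: the total edge weight
equals Σ_r Σ_{piles p of r} C(|p|, 2).

Quote groupings are communities of this network under weighted
Newman–Girvan modularity with a resolution parameter γ:

    Q(c) = (1/2m) Σ_ij [ w_ij − γ k_i k_j / 2m ] δ(c_i, c_j)

where m is the total edge weight and k_i the weighted degree. Optimisation
uses the Louvain heuristic: repeated local moving of single nodes to the
neighbouring community with the largest positive gain, followed by
aggregation of communities into super-nodes, iterated until no level
improves; a final local-moving sweep over the *original* nodes, started
from the aggregated partition, polishes the result (it can only increase
Q). Node visit order is a seeded shuffle, so output is deterministic per
seed; move gains must exceed a tolerance of 1e-12. Community labels are
canonicalised to 1..K by descending size (ties towards the smallest member
quote), so assignments are comparable across runs and analyst groups.

For graphs of at most 10 nodes, `exhaustive_max_modularity` enumerates all
set partitions (Bell-number guard) and returns a true optimum; it exists
purely as an independent oracle for the heuristic and is never part of the
analysis path.

## Congruence statistics

Human themes are ordered, labelled quote lists that may overlap and need
not cover the quote set. For a theme T and an assignment c, the
**dominant grouping** is the unique modal label among {c(q) : q ∈ T}; its
percentage is 100·(modal count)/|T|. When two or more labels tie for the
modal count there is *no* dominant grouping: the percentage is undefined
(rendered `N/A`) and the full breakdown is reported as
`"4 green; 4 pink; 3 blue"` (descending count, then label). Percentages
are carried at full precision; presentation supports integer and
one-decimal rounding because published summaries use both styles. Source
tables can be internally inconsistent (a printed breakdown disagreeing
with the printed quote list); the implementation computes only from its
actual inputs and never reconciles to a printed summary.

Partition-level agreement uses the adjusted Rand index computed from the
pair-count contingency table under the permutation model; the degenerate
case where both partitions are trivial returns 1 by convention, and a
non-trivial partition against the single-community partition scores 0.
Theme-set matching builds the full Jaccard matrix
|A_i ∩ B_j| / |A_i ∪ B_j| and pairs themes greedily, largest Jaccard
first, ties broken towards earlier theme indices, each theme used at most
once. Greedy (rather than optimal-assignment) matching was chosen
deliberately: it mirrors the informal best-match comparison analysts do in
a workshop and is transparent; it is documented as a heuristic.

## Synthetic studies

The generator plants a ground-truth partition of N quotes into K themes
(balanced sizes by default, or explicit sizes) and derives each
researcher's sort from it: optionally one random pile bisection
(probability `p_split`), optionally one merge of two random piles
(`p_merge`, rejected when fewer than three piles exist), then independent
per-quote moves (`p_move`) to a uniformly chosen different pile. A move
that would empty a pile deletes the pile; when the source pile is a
singleton and only two piles remain, no destination can preserve the
two-pile rule, so the move is rejected outright (no resampling can
succeed). Researchers perturb independently — they never see each other's
sorts — via per-researcher substreams spawned deterministically from the
study seed, so studies are exactly reproducible.

Defaults (N=89 quotes, R=4 researchers, K=4 themes, p_move=0.1,
p_split=p_merge=0) emulate a realistic small participatory study; the
noise level is illustrative, since measured move rates for human sorters
are not available. What the generator does **not** model: semantic content
of quotes (noise is structureless, not meaning-driven), researcher
fatigue or ordering effects, correlated errors between similar quotes, or
overlapping latent themes. Passing recovery tests therefore show that the
network-plus-Louvain pathway recovers *structured, independently noised*
partitions — not that it recovers whatever structure human sorters
express.

`recovery_experiment` sweeps a config grid with a fixed replicate count,
reporting mean/sd adjusted Rand index against the planted truth, the mean
detected community count, and the fraction of replicates recovering
exactly K. Replicate seeds are derived arithmetically from the experiment
seed (kept below 2^31).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `resolution` (γ) | 1.0 | modularity resolution; γ→0 favours one community, large γ favours singletons |
| `seed` | 0 | Louvain node-visit shuffle; output deterministic per seed |
| `weighted` | True | use co-placement counts as weights; unweighted treats every edge as 1 |
| gain tolerance | 1e-12 | minimum modularity gain to accept a local move |
| `p_move` | 0.1 | per-quote, per-researcher probability of a random pile reassignment |
| `p_split`, `p_merge` | 0.0 | per-researcher probability of one pile bisection / merge |
| rounding | `one_decimal` | percentage rendering (`integer`, `one_decimal`, `full`) |

Weighted optimisation is the default because the weights encode exactly
the "how many researchers agree" signal; `--unweighted` is exposed because
upstream web tools do not always document their weighting.

## Numerical and design choices

- Quote ids normalise from both written styles (`17`, `ID17`) to one
  integer; canonical rendering is zero-padded (`ID17`). Parsing is strict:
  non-numeric payloads and values < 1 are errors naming the token.
- Complete coverage (every researcher sorts every quote) is enforced by
  default with an `allow_partial` opt-out that simply drops unsorted
  quotes from that researcher's co-occurrence counts; protocols imply
  complete sorting but real tables can be ragged.
- Tie-breaking in Louvain's local moves prefers staying put, then the
  lexicographically smaller community id among equal-gain candidates, so
  runs are reproducible bit-for-bit.
- A zero-edge network makes modularity undefined (error); community
  detection on it degrades gracefully to all-singletons with a warning.
- The exhaustive oracle breaks exact ties towards fewer communities, then
  the lexicographically smallest canonical labelling, making it a
  deterministic reference.
- Graph export writes GraphML/GML via networkx, a plain weighted edge
  list, and a small hand-written subset of the Graphviz DOT language
  (pen widths scale with weight); all formats round-trip through the
  matching importer. Force-directed layout is seeded for deterministic
  diagrams.

## Problem sizes in the test and acceptance runs

The test suite and acceptance script use the study-scale configuration
(89 quotes, 4 researchers, K ∈ {2..6}) with 20 seeds/replicates per
condition, 50 random ≤8-node graphs for the exhaustive comparison, and 100
random studies for the conservation identity — sizes chosen so the whole
verification completes in well under a minute while keeping Monte-Carlo
error small relative to the thresholds checked.

## Known limitations

- Louvain is a heuristic: on small rugged landscapes it occasionally
  returns a slightly sub-optimal partition (it matched the exhaustive
  optimum on 92–96% of random small graphs in our runs, never exceeding
  it). Single-seed determinism is favoured over multi-restart search.
- Exact replication of any particular published grouping requires the raw
  sorts and the original tool's (undocumented) Louvain variant and seed
  policy; the package guarantees its *own* determinism instead.
- The dominant-grouping percentage is undefined on ties by construction;
  downstream code must handle `N/A`.
- Greedy theme matching is order-stable but not globally optimal; for an
  optimal pairing use the Jaccard matrix with an assignment solver.
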