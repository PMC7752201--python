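"""Theme-level congruence statistics.

Given machine-detected quote groupings and human-curated themes, these
operations compute, per theme, which grouping dominates and what share of
the theme's quotes carry it; compare two whole partitions with the adjusted
Rand index; and match two theme sets by Jaccard overlap of their quote
lists.  A theme whose modal grouping count is attained by two or more
groupings has *no* dominant grouping and its percentage is undefined (the
summary prints the full count breakdown instead).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sortdata import PilesortError, QuoteId, ThemeSet, format_quote_id

ROUNDING_POLICIES = ("integer", "one_decimal", "full")


class ThemeCoverageError(PilesortError, ValueError):
    """A theme lists a quote that the grouping assignment does not cover."""


@dataclass
class DominantGroupingResult:
    """Per-theme dominance summary.

    ``dominant`` is ``None`` (and ``percentage`` is ``None``) exactly when
    the maximal count is shared by two or more grouping labels; otherwise
    ``percentage`` = 100 * max count / theme size, carried at full
    precision.
    """

    counts: dict[str, int]
    dominant: str | None
    percentage: float | None

    @property
    def n_quotes(self) -> int:
        return sum(self.counts.values())

    def breakdown(self) -> str:
        """Counts as ``'4 green; 4 pink; 3 blue'`` (descending, then label)."""
        items = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return "; ".join(f"{n} {label}" for label, n in items)

    def render_percentage(self, rounding: str = "one_decimal") -> str:
        """Percentage under a rounding policy, or ``'N/A'`` on a tie."""
        if rounding not in ROUNDING_POLICIES:
            raise PilesortError(f"unknown rounding policy {rounding!r}")
        if self.percentage is None:
            return "N/A"
        if rounding == "integer":
            return f"{round(self.percentage):d}%"
        if rounding == "one_decimal":
            return f"{round(self.percentage, 1):g}%"
        return f"{self.percentage}%"


def dominant_grouping(
    theme_quotes: Sequence[QuoteId], assignment: Mapping[QuoteId, object]
) -> DominantGroupingResult:
    """Dominance summary for one theme against a grouping assignment."""
    missing = [q for q in theme_quotes if q not in assignment]
    if missing:
        raise ThemeCoverageError(
            "assignment does not cover theme quote(s): "
            + ", ".join(format_quote_id(q) for q in missing)
        )
    counts = Counter(str(assignment[q]) for q in theme_quotes)
    top = max(counts.values())
    leaders = [label for label, n in counts.items() if n == top]
    if len(leaders) > 1:
        return DominantGroupingResult(dict(counts), None, None)
    return DominantGroupingResult(
        dict(counts), leaders[0], 100.0 * top / len(theme_quotes)
    )


def theme_congruence_table(
    themes: ThemeSet,
    assignment: Mapping[QuoteId, object],
    rounding: str = "one_decimal",
) -> pd.DataFrame:
    """One summary row per theme, in input order.

    Columns: theme label, canonical quote list, dominant grouping (or the
    tie breakdown string), and the rendered percentage (``'N/A'`` on ties).
    """
    rows = []
    for label, ids in themes:
        res = dominant_grouping(ids, assignment)
        rows.append(
            {
                "theme": label,
                "quotes": ", ".join(format_quote_id(q) for q in ids),
                "n_quotes": len(ids),
                "dominant_grouping": (
                    res.dominant
                    if res.dominant is not None
                    else f"No dominant grouping—{res.breakdown()}"
                ),
                "percentage": res.render_percentage(rounding),
            }
        )
    return pd.DataFrame(rows)


def adjusted_rand_index(
    a: Mapping[QuoteId, object], b: Mapping[QuoteId, object]
) -> float:
    """Chance-corrected agreement between two partitions of the same items.

    Computed from the pair-count contingency table under the permutation
    model:  ARI = (Index - Expected) / (Max - Expected).  Both assignments
    must label exactly the same item set.  The degenerate cases (both
    partitions all-singletons or both one community) return 1.0 by the
    usual convention; comparing a non-trivial partition with a single
    community yields 0.
    """
    if set(a) != set(b):
        diff = sorted(set(a) ^ set(b))
        raise PilesortError(
            "assignments cover different quote sets; symmetric difference: "
            + ", ".join(str(q) for q in diff)
        )
    items = list(a)
    n = len(items)
    table: Counter = Counter((a[x], b[x]) for x in items)
    a_sizes: Counter = Counter(a[x] for x in items)
    b_sizes: Counter = Counter(b[x] for x in items)
    index = sum(comb(nij, 2) for nij in table.values())
    sum_a = sum(comb(ni, 2) for ni in a_sizes.values())
    sum_b = sum(comb(nj, 2) for nj in b_sizes.values())
    total = comb(n, 2)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0  # both trivial partitions: perfect agreement by convention
    return (index - expected) / (max_index - expected)


@dataclass
class ThemeMatch:
    """One greedily matched theme pair with its overlap evidence."""

    index_a: int
    index_b: int
    label_a: str
    label_b: str
    jaccard: float
    shared: list[QuoteId]


@dataclass
class ThemeOverlapReport:
    """Full Jaccard matrix plus the greedy best-match pairing."""

    labels_a: list[str]
    labels_b: list[str]
    jaccard: np.ndarray  # shape (len(a), len(b))
    matches: list[ThemeMatch]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.jaccard, index=self.labels_a, columns=self.labels_b)


def match_theme_sets(a: ThemeSet, b: ThemeSet) -> ThemeOverlapReport:
    """Compare two theme sets by quote overlap.

    Builds the full Jaccard matrix |A_i & B_j| / |A_i | B_j| and pairs
    themes greedily, largest Jaccard first (ties broken by earlier theme
    indices), each theme matched at most once; pairs with zero overlap are
    not matched.
    """
    sets_a = [set(ids) for _, ids in a]
    sets_b = [set(ids) for _, ids in b]
    jac = np.zeros((len(sets_a), len(sets_b)))
    for i, sa in enumerate(sets_a):
        for j, sb in enumerate(sets_b):
            union = sa | sb
            jac[i, j] = len(sa & sb) / len(union) if union else 0.0
    candidates = sorted(
        ((i, j) for i in range(len(sets_a)) for j in range(len(sets_b))),
        key=lambda ij: (-jac[ij], ij[0], ij[1]),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[ThemeMatch] = []
    for i, j in candidates:
        if jac[i, j] <= 0.0 or i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append(
            ThemeMatch(
                index_a=i,
                index_b=j,
                label_a=a.themes[i][0],
                label_b=b.themes[j][0],
                jaccard=float(jac[i, j]),
                shared=sorted(sets_a[i] & sets_b[j]),
            )
        )
    matches.sort(key=lambda m: m.index_a)
    return ThemeOverlapReport(
        labels_a=[lbl for lbl, _ in a],
        labels_b=[lbl for lbl, _ in b],
        jaccard=jac,
        matches=matches,
    )
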