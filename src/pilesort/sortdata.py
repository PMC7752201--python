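"""Domain types and I/O for card-sorting studies.

A sorting study records how each of several analysts ("researchers")
independently partitioned a shared set of quote cards into labelled piles.
Quotes are identified by positive integers with a canonical ``ID``-prefixed,
zero-padded rendering (``ID07``); source tables mix bare (``7``) and
prefixed (``ID07``) styles, and both normalise to the same identifier.

Study validity rules follow the open-sorting protocol: every researcher
sorts every quote exactly once, uses at least two piles, and no pile is
empty.  Pile labels are opaque and compared only within one researcher.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

QuoteId = int  # positive integer; canonical text form is "ID" + zero-padded value


class PilesortError(Exception):
    """Base class for all domain errors raised by this package."""


class QuoteIdParseError(PilesortError, ValueError):
    """A token could not be parsed as a quote identifier."""


class IntegrityError(PilesortError, ValueError):
    """Duplicate (researcher, quote) record: a quote was sorted twice."""


class CoverageError(PilesortError, ValueError):
    """A researcher did not sort a quote that others sorted."""


class ConstraintError(PilesortError, ValueError):
    """A protocol constraint (e.g. the two-pile rule) was violated."""


class ThemeFileError(PilesortError, ValueError):
    """A theme definition file is malformed."""


_QUOTE_RE = re.compile(r"^(?:ID)?(\d+)$", re.IGNORECASE)


def parse_quote_id(text: str | int) -> QuoteId:
    """Parse a quote identifier from either of its two written styles.

    Accepts bare integers (``"17"``, ``17``) and prefixed forms (``"ID17"``,
    case-insensitive), with optional surrounding whitespace; both normalise
    to the same positive integer.

    Raises
    ------
    QuoteIdParseError
        If the payload is non-numeric or the value is < 1.
    """
    if isinstance(text, int) and not isinstance(text, bool):
        value = text
    else:
        token = str(text).strip()
        m = _QUOTE_RE.match(token)
        if m is None:
            raise QuoteIdParseError(f"not a quote identifier: {text!r}")
        value = int(m.group(1))
    if value < 1:
        raise QuoteIdParseError(f"quote identifier must be >= 1, got {text!r}")
    return value


def format_quote_id(value: QuoteId) -> str:
    """Render a quote id canonically: ``ID`` + value zero-padded to 2 digits."""
    if value < 1:
        raise QuoteIdParseError(f"quote identifier must be >= 1, got {value!r}")
    return f"ID{value:02d}"


@dataclass(frozen=True)
class SortRecord:
    """One row of a sorting table: *researcher* placed *quote* on *pile*."""

    researcher: str
    quote: QuoteId
    pile: str


@dataclass
class SortingStudy:
    """All researchers' independent partitions of a shared quote set.

    Attributes
    ----------
    records:
        The long-format records, one per (researcher, quote) pair.
    researchers:
        Researcher identifiers in first-appearance order.
    quotes:
        Sorted list of all quote ids appearing in any record.
    """

    records: list[SortRecord]
    researchers: list[str] = field(init=False)
    quotes: list[QuoteId] = field(init=False)

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        quoteset: set[QuoteId] = set()
        for rec in self.records:
            seen.setdefault(rec.researcher, None)
            quoteset.add(rec.quote)
        self.researchers = list(seen)
        self.quotes = sorted(quoteset)

    def partition_of(self, researcher: str) -> dict[QuoteId, str]:
        """Map quote -> pile label for one researcher."""
        return {r.quote: r.pile for r in self.records if r.researcher == researcher}

    def piles_of(self, researcher: str) -> dict[str, list[QuoteId]]:
        """Map pile label -> sorted quote list for one researcher."""
        piles: dict[str, list[QuoteId]] = {}
        for rec in self.records:
            if rec.researcher == researcher:
                piles.setdefault(rec.pile, []).append(rec.quote)
        return {k: sorted(v) for k, v in piles.items()}

    @property
    def n_researchers(self) -> int:
        return len(self.researchers)

    @property
    def n_quotes(self) -> int:
        return len(self.quotes)


def validate_study(study: SortingStudy, allow_partial: bool = False) -> list[str]:
    """Check the open-sorting invariants; return a list of violation messages.

    With ``allow_partial`` the complete-coverage requirement is waived
    (quotes a researcher left unsorted simply contribute no co-placements);
    duplicates and the two-pile rule are always enforced.
    """
    violations: list[str] = []
    pairs: set[tuple[str, QuoteId]] = set()
    for rec in study.records:
        key = (rec.researcher, rec.quote)
        if key in pairs:
            violations.append(
                f"researcher {rec.researcher!r} sorted quote "
                f"{format_quote_id(rec.quote)} more than once"
            )
        pairs.add(key)
    allq = set(study.quotes)
    for r in study.researchers:
        part = study.partition_of(r)
        piles = set(part.values())
        if len(piles) < 2:
            violations.append(
                f"researcher {r!r} used {len(piles)} pile(s); "
                "the protocol requires at least two piles"
            )
        if not allow_partial:
            missing = allq - set(part)
            if missing:
                ids = ", ".join(format_quote_id(q) for q in sorted(missing)[:5])
                more = "" if len(missing) <= 5 else f" (+{len(missing) - 5} more)"
                violations.append(
                    f"researcher {r!r} did not sort: {ids}{more}"
                )
    return violations


def _raise_for_violations(violations: Sequence[str]) -> None:
    for v in violations:
        if "more than once" in v:
            raise IntegrityError("; ".join(violations))
    for v in violations:
        if "did not sort" in v:
            raise CoverageError("; ".join(violations))
    if violations:
        raise ConstraintError("; ".join(violations))


def make_study(
    rows: Iterable[tuple[str, str | int, str | int]],
    allow_partial: bool = False,
) -> SortingStudy:
    """Build and validate a study from (researcher, quote, pile) triples."""
    records = [
        SortRecord(str(r), parse_quote_id(q), str(p)) for r, q, p in rows
    ]
    if not records:
        raise ConstraintError("sorting table contains no records")
    study = SortingStudy(records)
    _raise_for_violations(validate_study(study, allow_partial=allow_partial))
    return study


def _sniff_delimiter(sample: str) -> str:
    # comma or tab; prefer whichever splits the first non-empty line into 3
    for line in sample.splitlines():
        if line.strip():
            if line.count("\t") >= 2:
                return "\t"
            return ","
    return ","


def read_sorting_table(
    path: str | Path | io.TextIOBase,
    delimiter: str | None = None,
    allow_partial: bool = False,
) -> SortingStudy:
    """Read a three-column long-format sorting table.

    Columns are ``researcher, quote, pile`` in comma- or tab-delimited text.
    A header row is auto-detected: if the quote column of the first row does
    not parse as a quote id, the row is treated as a header.
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text(encoding="utf-8")
    else:
        text = path.read()
    if not text.strip():
        raise ConstraintError("sorting table is empty")
    sep = delimiter or _sniff_delimiter(text)
    df = pd.read_csv(io.StringIO(text), sep=sep, header=None, dtype=str,
                     skip_blank_lines=True)
    if df.shape[1] != 3:
        raise ConstraintError(
            f"expected exactly 3 columns (researcher, quote, pile), "
            f"got {df.shape[1]}"
        )
    try:
        parse_quote_id(df.iloc[0, 1])
    except QuoteIdParseError:
        df = df.iloc[1:]
        if df.empty:
            raise ConstraintError("sorting table holds a header but no data")
    rows = [(r, q, p) for r, q, p in df.itertuples(index=False)]
    return make_study(rows, allow_partial=allow_partial)


def write_sorting_table(
    study: SortingStudy, path: str | Path, delimiter: str = ",", header: bool = True
) -> None:
    """Write a study back out as delimited text with canonical quote ids."""
    lines = []
    if header:
        lines.append(delimiter.join(("researcher", "quote", "pile")))
    for rec in study.records:
        lines.append(
            delimiter.join((rec.researcher, format_quote_id(rec.quote), rec.pile))
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class ThemeSet:
    """An ordered list of human-labelled themes.

    Themes may overlap (the same quote can support several themes) and need
    not cover the whole quote set; duplicate ids *within* one theme are
    rejected at construction.
    """

    themes: list[tuple[str, list[QuoteId]]]

    def __post_init__(self) -> None:
        for label, ids in self.themes:
            if not ids:
                raise ThemeFileError(f"theme {label!r} has an empty quote list")
            if len(set(ids)) != len(ids):
                dupes = sorted({q for q in ids if ids.count(q) > 1})
                raise ThemeFileError(
                    f"theme {label!r} lists duplicate quote(s): "
                    + ", ".join(format_quote_id(q) for q in dupes)
                )

    def __len__(self) -> int:
        return len(self.themes)

    def __iter__(self):
        return iter(self.themes)

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.themes]

    def quote_ids(self, label: str) -> list[QuoteId]:
        for lbl, ids in self.themes:
            if lbl == label:
                return list(ids)
        raise KeyError(label)


def read_theme_file(path: str | Path | io.TextIOBase) -> ThemeSet:
    """Read theme definitions from text.

    Two layouts are accepted:

    * one theme per line, ``label: id, id, ...``;
    * a two-column delimited file ``label,quote`` (one quote per row,
      rows for the same label collected in order; optional header).
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text(encoding="utf-8")
    else:
        text = path.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ThemeFileError("theme file is empty")
    if any(":" in ln for ln in lines):
        themes: list[tuple[str, list[QuoteId]]] = []
        for ln in lines:
            if ":" not in ln:
                raise ThemeFileError(f"line without 'label:' separator: {ln!r}")
            label, _, rest = ln.partition(":")
            ids = [parse_quote_id(tok) for tok in rest.split(",") if tok.strip()]
            themes.append((label.strip(), ids))
        return ThemeSet(themes)
    # two-column layout
    sep = "\t" if lines[0].count("\t") >= 1 else ","
    collected: dict[str, list[QuoteId]] = {}
    order: list[str] = []
    for i, ln in enumerate(lines):
        parts = [p.strip() for p in ln.split(sep)]
        if len(parts) != 2:
            raise ThemeFileError(f"expected 'label{sep}quote' on line {i + 1}: {ln!r}")
        label, tok = parts
        try:
            qid = parse_quote_id(tok)
        except QuoteIdParseError:
            if i == 0:  # header row
                continue
            raise
        collected.setdefault(label, [])
        if label not in order:
            order.append(label)
        collected[label].append(qid)
    return ThemeSet([(lbl, collected[lbl]) for lbl in order])


def write_theme_file(themes: ThemeSet, path: str | Path) -> None:
    """Write themes one per line as ``label: ID01, ID02, ...``."""
    lines = [
        f"{label}: " + ", ".join(format_quote_id(q) for q in ids)
        for label, ids in themes
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_assignment(path: str | Path | io.TextIOBase) -> Mapping[QuoteId, str]:
    """Read a two-column ``quote,group`` file into an assignment mapping."""
    if isinstance(path, (str, Path)):
        text = Path(path).read_text(encoding="utf-8")
    else:
        text = path.read()
    out: dict[QuoteId, str] = {}
    for i, ln in enumerate(ln for ln in text.splitlines() if ln.strip()):
        sep = "\t" if "\t" in ln else ","
        parts = [p.strip() for p in ln.split(sep)]
        if len(parts) != 2:
            raise PilesortError(f"expected 'quote{sep}group': {ln!r}")
        try:
            qid = parse_quote_id(parts[0])
        except QuoteIdParseError:
            if i == 0:
                continue
            raise
        out[qid] = parts[1]
    return out


def write_assignment(assignment: Mapping[QuoteId, object], path: str | Path) -> None:
    """Write an assignment as ``quote,group`` delimited text, sorted by quote."""
    lines = ["quote,group"] + [
        f"{format_quote_id(q)},{assignment[q]}" for q in sorted(assignment)
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
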