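"""Parsing of MCMC trace files into a uniform table.

Supported dialects:

* ``tabular`` — tab-separated traces as emitted by MrBayes (``.p``),
  BEAST (``.log``) and JPrIME/PrIMe: optional comment lines (leading
  ``#``, or a bracketed ``[ID: ...]`` first line), a header row, then one
  sample per line.  Columns are classified per-column as *numeric* (every
  value parses as a decimal number, ``NA``/``NaN`` allowed), *tree*
  (every non-empty value is a Newick string ending in ``;``), or
  *ignored*.  A column named ``Gen``/``state``/``Sample``/``Iteration``
  (case-insensitive) is taken as the iteration counter.
* ``nexus_trees`` — a NEXUS ``trees`` block with an optional ``Translate``
  table (MrBayes ``.t`` files); parsed with dendropy, yielding a single
  tree-valued column with taxon labels substituted.

Fields are separated by tabs only; runs of spaces are not separators,
because Newick strings may legitimately contain spaces.  Sample indexing
is 0-based and intervals are half-open ``[start, end)`` throughout the
package.
"""

from __future__ import annotations

import math
import os
import re
from dataclasses import dataclass, field, replace
from typing import Literal

import dendropy
import numpy as np

from .summary_stats import NumericSeries

__all__ = [
    "TraceTable",
    "IntervalSelection",
    "TraceParseError",
    "parse_trace",
    "extract_interval",
]

ColumnKind = Literal["numeric", "tree", "ignored"]

#: header names (lower-cased) recognised as the iteration-number column
GENERATION_NAMES = {"gen", "state", "sample", "iteration"}

_NA_TOKENS = {"na", "nan", "-nan", "n/a"}


class TraceParseError(ValueError):
    """Raised when a trace file cannot be parsed."""


@dataclass
class IntervalSelection:
    """Half-open sample interval [start, end), 0-based."""

    start: int
    end: int

    def validate(self, n_samples: int) -> None:
        if not (0 <= self.start < self.end <= n_samples):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) "
                f"for {n_samples} samples"
            )


@dataclass
class TraceTable:
    """A parsed MCMC trace.

    ``columns`` lists every non-generation column in file order with its
    classification.  Numeric columns live in ``numeric_data`` (values may
    contain NaN where the file said ``NA``); tree columns are ordered
    Newick-string lists in ``tree_data``.
    """

    source_path: str
    n_samples: int
    columns: list[tuple[str, ColumnKind]]
    numeric_data: dict[str, NumericSeries] = field(default_factory=dict)
    tree_data: dict[str, list[str]] = field(default_factory=dict)
    generation: np.ndarray | None = None

    def numeric_names(self) -> list[str]:
        return [n for n, k in self.columns if k == "numeric"]

    def tree_names(self) -> list[str]:
        return [n for n, k in self.columns if k == "tree"]


def _try_float(token: str) -> float | None:
    t = token.strip()
    if t.lower() in _NA_TOKENS:
        return math.nan
    try:
        return float(t)
    except ValueError:
        return None


def _is_newick(token: str) -> bool:
    t = token.strip()
    if not t.endswith(";"):
        return False
    try:
        dendropy.Tree.get(data=t, schema="newick")
    except Exception:
        return False
    return True


def _read_source(path_or_text: "str | os.PathLike[str]") -> tuple[str, str]:
    """Return (text, source_path). A string containing a newline, or one
    that is not an existing file, is treated as literal trace content."""
    s = os.fspath(path_or_text)
    if "\n" not in s and os.path.exists(s):
        with open(s, "r", encoding="utf-8") as fh:
            return fh.read(), s
    return s, "<string>"


def parse_trace(
    path_or_text: "str | os.PathLike[str]",
    dialect: Literal["auto", "tabular", "nexus_trees"] = "auto",
) -> TraceTable:
    """Parse a trace file (or literal text) into a :class:`TraceTable`."""
    text, source = _read_source(path_or_text)
    if dialect == "auto":
        dialect = "nexus_trees" if text.lstrip()[:6].upper() == "#NEXUS" else "tabular"
    if dialect == "nexus_trees":
        return _parse_nexus(text, source)
    return _parse_tabular(text, source)


def _parse_tabular(text: str, source: str) -> TraceTable:
    header: list[str] | None = None
    rows: list[list[str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        stripped = line.lstrip()
        if stripped.startswith("#"):
            continue
        # MrBayes-style "[ID: 1234]" preamble before the header
        if header is None and stripped.startswith("[") and stripped.rstrip().endswith("]"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            continue
        if len(fields) != len(header):
            raise TraceParseError(
                f"{source}: line {lineno}: expected {len(header)} fields, "
                f"got {len(fields)}"
            )
        rows.append([f.strip() for f in fields])
    if header is None or not rows:
        raise TraceParseError(f"{source}: no samples")

    n = len(rows)
    gen_idx = None
    for i, name in enumerate(header):
        if name.lower() in GENERATION_NAMES:
            gen_idx = i
            break

    generation = None
    if gen_idx is not None:
        try:
            generation = np.array([int(float(r[gen_idx])) for r in rows])
        except ValueError as exc:
            raise TraceParseError(
                f"{source}: generation column {header[gen_idx]!r} is not integral"
            ) from exc
        if np.any(np.diff(generation) <= 0):
            raise TraceParseError(
                f"{source}: generation column {header[gen_idx]!r} "
                "is not strictly increasing"
            )

    columns: list[tuple[str, ColumnKind]] = []
    numeric_data: dict[str, NumericSeries] = {}
    tree_data: dict[str, list[str]] = {}
    for i, name in enumerate(header):
        if i == gen_idx:
            continue
        values = [r[i] for r in rows]
        floats = [_try_float(v) for v in values]
        if all(f is not None for f in floats):
            columns.append((name, "numeric"))
            numeric_data[name] = NumericSeries(np.array(floats, dtype=float), name)
        elif all((not v) or _is_newick(v) for v in values):
            columns.append((name, "tree"))
            tree_data[name] = values
        else:
            columns.append((name, "ignored"))
    return TraceTable(
        source_path=source,
        n_samples=n,
        columns=columns,
        numeric_data=numeric_data,
        tree_data=tree_data,
        generation=generation,
    )


_STATE_RE = re.compile(r"(?:STATE|GEN|REP|TREE|T)[_. ]?(\d+)$", re.IGNORECASE)


def _parse_nexus(text: str, source: str) -> TraceTable:
    try:
        trees = dendropy.TreeList.get(data=text, schema="nexus")
    except Exception as exc:
        raise TraceParseError(f"{source}: unparseable NEXUS: {exc}") from exc
    if len(trees) == 0:
        raise TraceParseError(f"{source}: no samples")
    newicks = [
        t.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        for t in trees
    ]
    # recover generation numbers from tree labels like "STATE_1000", if any
    generation = None
    labels = [t.label or "" for t in trees]
    matches = [_STATE_RE.search(lb) for lb in labels]
    if all(m is not None for m in matches):
        gens = np.array([int(m.group(1)) for m in matches])  # type: ignore[union-attr]
        if len(gens) == len(set(gens.tolist())) and np.all(np.diff(gens) > 0):
            generation = gens
    return TraceTable(
        source_path=source,
        n_samples=len(newicks),
        columns=[("tree", "tree")],
        tree_data={"tree": newicks},
        generation=generation,
    )


def extract_interval(table: TraceTable, sel: IntervalSelection) -> TraceTable:
    """Restrict a trace to the samples in ``[sel.start, sel.end)``."""
    sel.validate(table.n_samples)
    s, e = sel.start, sel.end
    return replace(
        table,
        n_samples=e - s,
        numeric_data={
            k: NumericSeries(v.values[s:e], v.name) for k, v in table.numeric_data.items()
        },
        tree_data={k: v[s:e] for k, v in table.tree_data.items()},
        generation=None if table.generation is None else table.generation[s:e],
    )
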