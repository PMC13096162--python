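"""Hierarchical ambiguity-level annotation of Fibonacci-grammar strings.

At the surface level a grammatical string has two deterministic regularities
(a 0 is always followed by a 1; two 1s are always followed by a 0) and one
probabilistic one (a single 1 may be followed by either symbol).  Positions
whose identity is forced by the preceding context are *unambiguous* points;
positions following exactly one 1 are *ambiguous* points.

Because the grammar is self-similar, the surface string can be chunked into
constituents ([01] -> 1, [1] -> 0) that spell out the previous generation,
and the same two determinism rules apply to the constituent labels.  An
ambiguous surface transition always falls on a constituent boundary, so it
can be lifted to the transition between the two adjacent constituents one
level up and re-classified there.  The *ambiguity level* of a position is
the smallest chunking level at which the transition into it becomes
deterministic; level 0 means the position is predictable from the surface
alone.

The module provides the rule-based assignment, the chunk hierarchy with span
bookkeeping, and a brute-force enumeration oracle that decides determinism
by exhaustively matching contexts in a long reference generation instead of
applying the rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grammar import (
    GrammarError,
    SymbolString,
    generate,
    parse_down_spans,
    validate_grammatical,
)

__all__ = [
    "ChunkHierarchy",
    "NO_CONTEXT",
    "UNRESOLVED",
    "annotate_level0",
    "build_chunk_hierarchy",
    "assign_ambiguity_levels",
    "oracle_min_resolving_level",
    "class_at_level",
    "DEFAULT_MAX_LEVEL",
]

logger = logging.getLogger(__name__)

#: Sentinels used wherever a position has no numeric ambiguity level.
NO_CONTEXT = "no_context"
UNRESOLVED = "unresolved"

#: Levels 0..4 are the ones the behavioural analysis conditions on.
DEFAULT_MAX_LEVEL = 5


def _as_text(s) -> str:
    text = s.symbols if isinstance(s, SymbolString) else "".join(str(c) for c in s)
    ok, violations = validate_grammatical(text)
    if not ok:
        raise GrammarError(
            f"ungrammatical string: forbidden substring at positions {violations}"
        )
    return text


def annotate_level0(s) -> list[str]:
    """Surface (level-0) labels: no_context / unambiguous / ambiguous.

    Position i >= 1 is unambiguous iff the prefix ends in '0' or in '11'
    (the two deterministic regularities), ambiguous iff it ends in exactly
    one '1'.  Position 0 has no preceding context.
    """
    text = _as_text(s)
    if len(text) < 2:
        raise GrammarError("need at least two symbols to classify transitions")
    labels = [NO_CONTEXT]
    for i in range(1, len(text)):
        labels.append(_classify(text, i))
    return labels


def _classify(labels: str, j: int) -> str:
    """Classify the transition into label position j by the two rules."""
    if j == 0:
        return NO_CONTEXT
    if labels[j - 1] == "0":
        return "unambiguous"
    if j >= 2 and labels[j - 2] == "1":
        return "unambiguous"
    return "ambiguous"


@dataclass
class ChunkHierarchy:
    """Constituent segmentations of a surface string, one per chunking level.

    ``spans[k]`` tiles the surface string with half-open ``(start, end,
    label)`` spans whose labels concatenate to the level-k label string
    (``labels[k]``); ``labels[0]`` is the surface string itself and
    ``spans[0]`` the single-position spans.  ``chunk_index[k]`` maps a
    level-(k-1) label index to the index of the level-k chunk containing it.
    """

    surface: str
    labels: list[str]
    spans: list[list[tuple[int, int, str]]]
    chunk_index: list[np.ndarray]

    @property
    def depth(self) -> int:
        return len(self.labels) - 1


def build_chunk_hierarchy(s, max_level: int) -> ChunkHierarchy:
    """Repeatedly inverse-rewrite, tracking spans in surface coordinates.

    Stops early (with a logged warning) if ``max_level`` exceeds the number
    of times the string can be parsed down.
    """
    text = _as_text(s)
    labels = [text]
    surface_spans = [[(i, i + 1, c) for i, c in enumerate(text)]]
    chunk_index: list[np.ndarray] = [np.arange(len(text))]
    for k in range(1, max_level + 1):
        prev = labels[-1]
        if len(prev) <= 1:
            logger.warning(
                "hierarchy truncated at level %d: string exhausted", k - 1
            )
            break
        try:
            rel_spans = parse_down_spans(prev)
        except GrammarError:
            logger.warning(
                "hierarchy truncated at level %d: level string not parseable", k - 1
            )
            break
        idx = np.empty(len(prev), dtype=int)
        new_spans = []
        prev_surface = surface_spans[-1]
        for ci, (a, b, lab) in enumerate(rel_spans):
            idx[a:b] = ci
            new_spans.append((prev_surface[a][0], prev_surface[b - 1][1], lab))
        labels.append("".join(lab for _, _, lab in rel_spans))
        surface_spans.append(new_spans)
        chunk_index.append(idx)
    return ChunkHierarchy(text, labels, surface_spans, chunk_index)


def _min_level(hier: ChunkHierarchy, i: int, max_level: int):
    """Rule-based minimal resolving level for position i (or a sentinel)."""
    if i == 0:
        return NO_CONTEXT
    j = i
    for k in range(max_level + 1):
        if k > hier.depth:
            return UNRESOLVED
        if k > 0:
            # an ambiguous transition always sits on a chunk boundary, so
            # lifting to the containing chunk index is well defined
            j = int(hier.chunk_index[k][j])
        cls = _classify(hier.labels[k], j)
        if cls == "unambiguous":
            return k
        if cls == NO_CONTEXT:
            return UNRESOLVED
    return UNRESOLVED


def class_at_level(level, analysis_level: int, pool: bool = False) -> str:
    """Point class at a given analysis level L.

    * ``unambiguous`` – deterministic at the surface (level 0);
    * ``disambiguated`` – resolved exactly at L (or at any level 1..L when
      ``pool`` is set);
    * ``ambiguous`` – still unresolved at L (level > L, or never resolved);
    * ``resolved_below`` – resolved at a positive level below L (only when
      ``pool`` is off);
    * ``no_context`` – first position of a block.
    """
    if level == NO_CONTEXT:
        return NO_CONTEXT
    if level == UNRESOLVED:
        return "ambiguous"
    if level == 0:
        return "unambiguous"
    if level == analysis_level or (pool and level <= analysis_level):
        return "disambiguated"
    if level > analysis_level:
        return "ambiguous"
    return "resolved_below"


def assign_ambiguity_levels(
    s,
    max_level: int = DEFAULT_MAX_LEVEL,
    pool_levels: bool = False,
) -> pd.DataFrame:
    """Annotate every position with its ambiguity level and per-level class.

    Returns a table with columns ``position``, ``symbol``,
    ``ambiguity_level`` (nullable integer; empty for the first position and
    for positions not resolved within ``max_level``), ``status`` and
    ``class_at_level_0`` .. ``class_at_level_{max_level - 1}``.
    """
    text = _as_text(s)
    hier = build_chunk_hierarchy(text, max_level)
    levels = [_min_level(hier, i, max_level) for i in range(len(text))]
    records = []
    for i, (sym, lev) in enumerate(zip(text, levels)):
        rec = {
            "position": i,
            "symbol": int(sym),
            "ambiguity_level": lev if isinstance(lev, int) else pd.NA,
            "status": lev if isinstance(lev, str) else "resolved",
        }
        for L in range(max_level):
            rec[f"class_at_level_{L}"] = class_at_level(lev, L, pool=pool_levels)
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    out["ambiguity_level"] = out["ambiguity_level"].astype("Int64")
    return out


def oracle_min_resolving_level(
    s,
    i: int,
    reference: SymbolString | str | None = None,
    max_level: int = DEFAULT_MAX_LEVEL,
):
    """Brute-force oracle: decide determinism by exhaustive context matching.

    At each chunking level k the transition into position i corresponds to a
    transition between two adjacent constituents; its context is the (at
    most two) constituent labels preceding it.  The oracle scans the level-k
    label string of a long reference generation (default ``generate(15)``)
    for every occurrence of that context and returns the smallest k at which
    all occurrences are followed by the same label.  It never applies the
    after-'0' / after-'11' determinism rules, so it is an independent check
    of the rule-based assignment.
    """
    text = _as_text(s)
    if not 0 <= i < len(text):
        raise GrammarError(f"position {i} outside string of length {len(text)}")
    if i == 0:
        return NO_CONTEXT
    ref_text = _as_text(reference if reference is not None else generate(n=15))
    # label strings of the reference at each level
    ref_levels = [ref_text]
    while len(ref_levels) <= max_level and len(ref_levels[-1]) > 1:
        try:
            spans = parse_down_spans(ref_levels[-1])
        except GrammarError:
            break
        ref_levels.append("".join(lab for _, _, lab in spans))
    hier = build_chunk_hierarchy(text, max_level)
    j = i
    for k in range(max_level + 1):
        if k > hier.depth or k >= len(ref_levels):
            return UNRESOLVED
        if k > 0:
            j = int(hier.chunk_index[k][j])
            if j == 0:
                return UNRESOLVED
        lab = hier.labels[k]
        ctx = lab[max(0, j - 2) : j]
        ref = ref_levels[k]
        followers = {
            ref[m]
            for m in range(len(ctx), len(ref))
            if ref[m - len(ctx) : m] == ctx
        }
        if not followers:
            return UNRESOLVED
        if len(followers) == 1:
            return k
    return UNRESOLVED
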