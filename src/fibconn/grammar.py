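"""Lindenmayer (Fibonacci) grammar: generation, validation, inverse parsing.

The Fibonacci grammar is the two-symbol L-system with rules ``0 -> 1`` and
``1 -> 01``.  All symbols are rewritten simultaneously at each generation, and
there is no distinction between rewritable and terminal symbols.  Starting
from the axiom ``0``, the length of generation *n* is the Fibonacci number
F(n) (with F(0) = F(1) = 1), and for n >= 2 the string of generation n is the
concatenation of generations n-2 and n-1.  Grammatical strings never contain
``00`` or ``111``: a 0 is always followed by a 1, and two 1s are always
followed by a 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "RewriteSystem",
    "SymbolString",
    "GrammarError",
    "ParseError",
    "DEFAULT_SYSTEM",
    "generate",
    "parse_down",
    "parse_down_spans",
    "validate_grammatical",
    "fibonacci",
]


class GrammarError(ValueError):
    """Invalid grammar input (bad symbol, bad generation count...)."""


class ParseError(GrammarError):
    """String cannot be inverse-rewritten; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


@dataclass(frozen=True)
class RewriteSystem:
    """A deterministic parallel rewriting system over a finite alphabet."""

    alphabet: frozenset = frozenset({"0", "1"})
    rules: Mapping[str, str] = field(
        default_factory=lambda: {"0": "1", "1": "01"}
    )
    axiom: str = "0"

    def __post_init__(self):
        if set(self.rules) != set(self.alphabet):
            raise GrammarError("every alphabet symbol needs exactly one rule")
        for sym, repl in self.rules.items():
            if not set(repl) <= set(self.alphabet):
                raise GrammarError(
                    f"rule {sym!r} -> {repl!r} uses symbols outside the alphabet"
                )
        if self.axiom not in self.alphabet:
            raise GrammarError(f"axiom {self.axiom!r} not in alphabet")


DEFAULT_SYSTEM = RewriteSystem()


@dataclass(frozen=True)
class SymbolString:
    """A string over {0,1} with provenance.

    ``generation`` is the number of rewriting passes that produced the string
    from the axiom, or ``None`` for strings of unknown provenance (e.g. the
    pseudo-random training sequence).
    """

    symbols: str
    generation: int | None = None

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return self.symbols

    def __iter__(self):
        return iter(self.symbols)

    def __getitem__(self, i):
        return self.symbols[i]


def fibonacci(n: int) -> int:
    """F(n) with F(0) = F(1) = 1 (the length of grammar generation n)."""
    if n < 0:
        raise GrammarError("n must be non-negative")
    a, b = 1, 1
    for _ in range(n):
        a, b = b, a + b
    return a


def generate(system: RewriteSystem = DEFAULT_SYSTEM, n: int = 0) -> SymbolString:
    """Apply ``n`` simultaneous rewriting passes to the axiom.

    With the default system the result is generation *n* of the Fibonacci
    grammar; generation 11 has 144 symbols.
    """
    if n < 0:
        raise GrammarError(f"generation count must be >= 0, got {n}")
    s = system.axiom
    for _ in range(n):
        s = "".join(system.rules[c] for c in s)
    return SymbolString(s, generation=n)


def validate_grammatical(symbols) -> tuple[bool, list[int]]:
    """Check a sequence for the forbidden substrings ``00`` and ``111``.

    Returns ``(valid, violations)`` where ``violations`` lists the start
    position of every forbidden substring occurrence.  Symbols outside
    {0,1} raise :class:`GrammarError`.
    """
    s = "".join(str(c) for c in symbols)
    bad = set(s) - {"0", "1"}
    if bad:
        raise GrammarError(f"symbols outside alphabet {{0,1}}: {sorted(bad)}")
    violations = []
    for i in range(len(s) - 1):
        if s[i] == "0" and s[i + 1] == "0":
            violations.append(i)
    for i in range(len(s) - 2):
        if s[i : i + 3] == "111":
            violations.append(i)
    violations.sort()
    return (not violations, violations)


def parse_down_spans(s) -> list[tuple[int, int, str]]:
    """Inverse-rewrite one level, returning chunk spans.

    Left-to-right greedy chunking: each ``01`` pair maps to ``1`` (undoing
    ``1 -> 01``) and each remaining lone ``1`` maps to ``0`` (undoing
    ``0 -> 1``).  This is unambiguous because in a grammatical string a ``0``
    can only open a ``01`` chunk.  Returns ``(start, end, label)`` triples
    with half-open 0-based spans tiling the input.
    """
    text = str(s) if not isinstance(s, SymbolString) else s.symbols
    ok, violations = validate_grammatical(text)
    if not ok:
        raise ParseError("ungrammatical input", violations[0])
    spans: list[tuple[int, int, str]] = []
    i = 0
    n = len(text)
    while i < n:
        if text[i] == "0":
            if i + 1 >= n:
                raise ParseError("trailing unpaired '0'", i)
            # grammaticality guarantees text[i + 1] == "1"
            spans.append((i, i + 2, "1"))
            i += 2
        else:
            spans.append((i, i + 1, "0"))
            i += 1
    return spans


def parse_down(s) -> SymbolString:
    """Deterministic inverse rewrite: map a generation onto the previous one.

    ``parse_down(generate(system, n)) == generate(system, n - 1)`` for all
    n >= 1.
    """
    spans = parse_down_spans(s)
    gen = s.generation if isinstance(s, SymbolString) else None
    new_gen = gen - 1 if isinstance(gen, int) and gen >= 1 else None
    return SymbolString("".join(label for _, _, label in spans), generation=new_gen)
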