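"""Formula AST, multiset (aggregate) semantics and the concrete text syntax.

The object language has three operators over opaque molecular species names:

* ``*`` (interaction) — binary, **non-associative**: ``(A*B)*C`` and
  ``A*(B*C)`` are different complexes, and ``A*B*C`` is a syntax error.
  Operands are single molecule types or complexes, never aggregates or
  conditionals.
* ``&`` (conjunction) — associative, commutative, **non-idempotent**: an
  aggregate is a *multiset* of formulas, so ``A & A`` is two molecules of
  type ``A``, not one.  This is what carries reaction stoichiometry.
* ``->`` (conditional, also written ``→``) — an aggregate of type ``A -> B``
  enables the transition from an aggregate of type ``A`` to one of type
  ``B``.  Lowest precedence.

Grammar (EBNF)::

    formula  = conj [ arrow conj ] ;        (* "->" is non-associative *)
    conj     = inter { "&" inter } ;
    inter    = primary [ "*" primary ] ;    (* "A*B*C" must be parenthesized *)
    primary  = ATOM | "(" formula ")" ;
    ATOM     = CHARS [ "(" CHARS ")" ] ;    (* marker atoms like d(TP53) *)
    CHARS    = { A-Z a-z 0-9 _ , . ' - }+ ;
    arrow    = "->" | "→" ;

Whitespace around operators is insignificant.  The atom charset includes
comma and hyphen so that names like ``F1,6P`` and ``TP53-P`` are single
tokens.  The function-style form ``d(TP53)`` is one atom token (a marker for
an event such as degradation), not an operator application.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Union

__all__ = [
    "Atom",
    "Interaction",
    "Conjunction",
    "Conditional",
    "Formula",
    "Multiset",
    "Sequent",
    "ZsyntaxSyntaxError",
    "parse_formula",
    "format_formula",
    "decompose",
    "conjunction_of",
    "atom_leaves",
    "depth",
]


class ZsyntaxSyntaxError(ValueError):
    """Raised on malformed concrete syntax; carries the offending position."""

    def __init__(self, message: str, text: str, pos: int):
        self.pos = pos
        self.text = text
        super().__init__(f"{message} (at position {pos}: {text[:pos]!r} <here> {text[pos:]!r})")


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

_ATOM_CHARS = r"A-Za-z0-9_,.'\-"
_ATOM_RE = re.compile(rf"[{_ATOM_CHARS}]+(?:\([{_ATOM_CHARS}]+\))?$")


@dataclass(frozen=True)
class Atom:
    """A molecular species (or marker event) named by an opaque identifier.

    Two atoms are equal iff their names are byte-identical; all
    disambiguation (species, modification state, gene vs protein) lives in
    the name, e.g. ``TP53`` vs ``TP53-P`` vs ``MDM2_gene``.
    """

    name: str

    def __post_init__(self) -> None:
        if not self.name or not _ATOM_RE.match(self.name):
            raise ValueError(f"invalid atom name: {self.name!r}")

    def __repr__(self) -> str:
        return f"Atom({self.name!r})"


@dataclass(frozen=True)
class Interaction:
    """The complex formed when ``left`` and ``right`` interact.

    Non-associative and (by default) non-commutative: operand order is part
    of the tree.  Operands must be single molecule types or complexes —
    never aggregates (Conjunction) or conditionals.
    """

    left: "Formula"
    right: "Formula"

    def __post_init__(self) -> None:
        for side, operand in (("left", self.left), ("right", self.right)):
            if isinstance(operand, (Conjunction, Conditional)):
                raise ValueError(
                    f"interaction {side} operand may not be a "
                    f"{type(operand).__name__}: {format_formula(operand)}"
                )

    def __repr__(self) -> str:
        return f"Interaction({self.left!r}, {self.right!r})"


@dataclass(frozen=True)
class Conjunction:
    """An aggregate of two or more molecules, i.e. a multiset of parts.

    Always flattened: parts are never themselves conjunctions.  Equality is
    multiset equality, so conjunct order never matters.
    """

    parts: "Multiset"

    def __post_init__(self) -> None:
        if self.parts.total() < 2:
            raise ValueError("a conjunction must aggregate at least two molecules")
        for part in self.parts.distinct():
            if isinstance(part, Conjunction):
                raise ValueError("conjunction parts must be flattened")

    def __repr__(self) -> str:
        return f"Conjunction({self.parts!r})"


@dataclass(frozen=True)
class Conditional:
    """``antecedent -> consequent``: the type of aggregates enabling the path."""

    antecedent: "Formula"
    consequent: "Formula"

    def __repr__(self) -> str:
        return f"Conditional({self.antecedent!r}, {self.consequent!r})"


Formula = Union[Atom, Interaction, Conjunction, Conditional]


# ---------------------------------------------------------------------------
# Multiset
# ---------------------------------------------------------------------------

class Multiset:
    """An immutable bag of formulas with positive integer counts.

    This is the aggregate: the empty multiset is the empty aggregate (zero
    molecules), and counts carry stoichiometry (``A & A`` has count 2).
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, items: Union[Iterable[Formula], Mapping[Formula, int]] = ()):
        counts: dict[Formula, int] = {}
        if isinstance(items, Mapping):
            for f, c in items.items():
                if c < 0:
                    raise ValueError("multiset counts must be non-negative")
                if c:
                    counts[f] = counts.get(f, 0) + c
        else:
            for f in items:
                counts[f] = counts.get(f, 0) + 1
        self._counts = counts
        self._hash: int | None = None

    # -- queries ------------------------------------------------------------
    def count(self, f: Formula) -> int:
        return self._counts.get(f, 0)

    def total(self) -> int:
        return sum(self._counts.values())

    def is_empty(self) -> bool:
        return not self._counts

    def distinct(self) -> Iterator[Formula]:
        return iter(self._counts)

    def items(self) -> Iterator[tuple[Formula, int]]:
        return iter(self._counts.items())

    def sorted_items(self) -> list[tuple[Formula, int]]:
        """Items in canonical order: (formula depth, rendered text)."""
        return sorted(self._counts.items(), key=lambda kv: sort_key(kv[0]))

    def elements(self) -> Iterator[Formula]:
        """Every element, with multiplicity, in canonical order."""
        for f, c in self.sorted_items():
            for _ in range(c):
                yield f

    def __contains__(self, f: Formula) -> bool:
        return f in self._counts

    def __len__(self) -> int:  # number of *distinct* members
        return len(self._counts)

    def __iter__(self) -> Iterator[Formula]:
        return self.distinct()

    # -- algebra ------------------------------------------------------------
    def __le__(self, other: "Multiset") -> bool:
        """Count-wise containment (sub-multiset)."""
        return all(other.count(f) >= c for f, c in self._counts.items())

    def __lt__(self, other: "Multiset") -> bool:
        return self <= other and self != other

    def __add__(self, other: "Multiset") -> "Multiset":
        counts = dict(self._counts)
        for f, c in other._counts.items():
            counts[f] = counts.get(f, 0) + c
        return Multiset(counts)

    def __sub__(self, other: "Multiset") -> "Multiset":
        if not other <= self:
            raise ValueError("multiset subtraction would go negative")
        counts = dict(self._counts)
        for f, c in other._counts.items():
            remaining = counts[f] - c
            if remaining:
                counts[f] = remaining
            else:
                del counts[f]
        return Multiset(counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Multiset):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash(frozenset(self._counts.items()))
        return self._hash

    def __repr__(self) -> str:
        inner = ", ".join(
            f"{format_formula(f)}:{c}" for f, c in self.sorted_items()
        )
        return f"Multiset({{{inner}}})"


@dataclass(frozen=True)
class Sequent:
    """A theorem form: premises (an aggregate) entail a conclusion."""

    premises: Multiset
    conclusion: Formula

    def __str__(self) -> str:
        if self.premises.is_empty():
            lhs = "0"  # the empty aggregate
        else:
            lhs = " & ".join(_render(f, _CTX_CONJ) for f in self.premises.elements())
        return f"{lhs} |- {format_formula(self.conclusion)}"


# ---------------------------------------------------------------------------
# Derived operations
# ---------------------------------------------------------------------------

def depth(f: Formula) -> int:
    if isinstance(f, Atom):
        return 0
    if isinstance(f, Interaction):
        return 1 + max(depth(f.left), depth(f.right))
    if isinstance(f, Conjunction):
        return 1 + max(depth(p) for p in f.parts.distinct())
    return 1 + max(depth(f.antecedent), depth(f.consequent))


def sort_key(f: Formula) -> tuple[int, str]:
    """Canonical ordering key: (depth, rendered text)."""
    return (depth(f), format_formula(f))


def decompose(f: Formula) -> Multiset:
    """The multiset of molecules in an aggregate formula.

    A conjunction decomposes into its parts; any other non-conditional
    formula is a singleton aggregate.  Conditionals are not aggregates of
    molecules and are rejected.
    """
    if isinstance(f, Conditional):
        raise ValueError(f"cannot decompose a conditional: {format_formula(f)}")
    if isinstance(f, Conjunction):
        return f.parts
    return Multiset([f])


def bag_of(f: Formula) -> Multiset:
    """Like :func:`decompose` but treats a conditional as a singleton.

    Used internally where a derivation line's formula must be viewed as a
    resource bag regardless of shape.
    """
    if isinstance(f, Conjunction):
        return f.parts
    return Multiset([f])


def conjunction_of(bag: Multiset) -> Formula:
    """The canonical formula denoting a non-empty aggregate."""
    if bag.is_empty():
        raise ValueError("the empty aggregate has no formula rendering")
    if bag.total() == 1:
        return next(bag.distinct())
    return Conjunction(bag)


def atom_leaves(f: Formula) -> Multiset:
    """The multiset of atoms occurring in ``f``, with multiplicity."""
    if isinstance(f, Atom):
        return Multiset([f])
    if isinstance(f, Interaction):
        return atom_leaves(f.left) + atom_leaves(f.right)
    if isinstance(f, Conjunction):
        out = Multiset()
        for part, c in f.parts.items():
            leaves = atom_leaves(part)
            for _ in range(c):
                out = out + leaves
        return out
    return atom_leaves(f.antecedent) + atom_leaves(f.consequent)


# ---------------------------------------------------------------------------
# Printer
# ---------------------------------------------------------------------------

_CTX_TOP = 0
_CTX_CONJ = 1
_CTX_INTER = 2


def _render(f: Formula, ctx: int) -> str:
    if isinstance(f, Atom):
        return f.name
    if isinstance(f, Interaction):
        left = _render(f.left, _CTX_INTER)
        right = _render(f.right, _CTX_INTER)
        text = f"{left}*{right}"
        return f"({text})" if ctx == _CTX_INTER else text
    if isinstance(f, Conjunction):
        parts = " & ".join(_render(p, _CTX_CONJ) for p in f.parts.elements())
        return f"({parts})" if ctx != _CTX_TOP else parts
    # Conditional
    ante = _render(f.antecedent, _CTX_TOP)
    if isinstance(f.antecedent, Conditional):
        ante = f"({ante})"
    cons = _render(f.consequent, _CTX_TOP)
    if isinstance(f.consequent, Conditional):
        cons = f"({cons})"
    text = f"{ante} -> {cons}"
    return f"({text})" if ctx != _CTX_TOP else text


def format_formula(f: Formula) -> str:
    """Canonical text for a formula.

    Conjuncts are emitted in canonical (depth, lexicographic) order, with
    the minimal parenthesization the grammar requires; ``parse_formula``
    inverts this exactly.
    """
    return _render(f, _CTX_TOP)


# ---------------------------------------------------------------------------
# Lexer / parser
# ---------------------------------------------------------------------------

_TOK_ATOM = "ATOM"
_TOK_AMP = "&"
_TOK_STAR = "*"
_TOK_ARROW = "->"
_TOK_LPAREN = "("
_TOK_RPAREN = ")"
_TOK_EOF = "EOF"

_atom_char = re.compile(rf"[{_ATOM_CHARS}]")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "&":
            tokens.append((_TOK_AMP, ch, i))
            i += 1
        elif ch == "*":
            tokens.append((_TOK_STAR, ch, i))
            i += 1
        elif ch == "(":
            tokens.append((_TOK_LPAREN, ch, i))
            i += 1
        elif ch == ")":
            tokens.append((_TOK_RPAREN, ch, i))
            i += 1
        elif ch == "→":
            tokens.append((_TOK_ARROW, ch, i))
            i += 1
        elif ch == "-" and i + 1 < n and text[i + 1] == ">":
            tokens.append((_TOK_ARROW, "->", i))
            i += 2
        elif _atom_char.match(ch):
            start = i
            while i < n and _atom_char.match(text[i]):
                # lone "-" may start an arrow, not an atom char run
                if text[i] == "-" and i + 1 < n and text[i + 1] == ">":
                    break
                i += 1
            name = text[start:i]
            # function-style marker atom, e.g. d(TP53): the "(" must follow
            # the name immediately (no whitespace) and enclose a bare name.
            if i < n and text[i] == "(":
                j = i + 1
                k = j
                while k < n and _atom_char.match(text[k]) and not (
                    text[k] == "-" and k + 1 < n and text[k + 1] == ">"
                ):
                    k += 1
                if k > j and k < n and text[k] == ")":
                    name = text[start:k + 1]
                    i = k + 1
            tokens.append((_TOK_ATOM, name, start))
        else:
            raise ZsyntaxSyntaxError(f"unexpected character {ch!r}", text, i)
    tokens.append((_TOK_EOF, "", n))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self) -> tuple[str, str, int]:
        return self.tokens[self.pos]

    def advance(self) -> tuple[str, str, int]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def error(self, message: str, at: int | None = None) -> ZsyntaxSyntaxError:
        pos = self.peek()[2] if at is None else at
        return ZsyntaxSyntaxError(message, self.text, pos)

    def parse(self) -> Formula:
        f = self.conditional()
        kind, value, pos = self.peek()
        if kind != _TOK_EOF:
            raise self.error(f"unexpected {value!r}")
        return f

    def conditional(self) -> Formula:
        left = self.conjunction()
        if self.peek()[0] == _TOK_ARROW:
            self.advance()
            right = self.conjunction()
            if self.peek()[0] == _TOK_ARROW:
                raise self.error("chained '->' must be parenthesized")
            return Conditional(left, right)
        return left

    def conjunction(self) -> Formula:
        parts = [self.interaction()]
        while self.peek()[0] == _TOK_AMP:
            self.advance()
            parts.append(self.interaction())
        if len(parts) == 1:
            return parts[0]
        bag = Multiset()
        for p in parts:
            bag = bag + (p.parts if isinstance(p, Conjunction) else Multiset([p]))
        return Conjunction(bag)

    def interaction(self) -> Formula:
        left = self.primary()
        if self.peek()[0] != _TOK_STAR:
            return left
        star_pos = self.advance()[2]
        right = self.primary()
        if self.peek()[0] == _TOK_STAR:
            raise self.error(
                "'*' is non-associative: nested interactions must be parenthesized"
            )
        try:
            return Interaction(left, right)
        except ValueError as exc:
            raise self.error(str(exc), at=star_pos) from None

    def primary(self) -> Formula:
        kind, value, pos = self.advance()
        if kind == _TOK_ATOM:
            return Atom(value)
        if kind == _TOK_LPAREN:
            inner = self.conditional()
            kind2, value2, _ = self.advance()
            if kind2 != _TOK_RPAREN:
                raise self.error("unbalanced parenthesis", at=pos)
            return inner
        if kind == _TOK_EOF:
            raise self.error("unexpected end of input", at=pos)
        raise self.error(f"unexpected {value!r}", at=pos)


def parse_formula(text: str) -> Formula:
    """Parse the concrete syntax (grammar in the module docstring).

    ``->`` and ``→`` are interchangeable; whitespace is insignificant.
    Raises :class:`ZsyntaxSyntaxError` with the offending position on
    unbalanced parentheses, dangling operators, or unparenthesized nested
    ``*``.
    """
    if not text or not text.strip():
        raise ZsyntaxSyntaxError("empty formula", text, 0)
    return _Parser(text).parse()


def parse_aggregate(text: str) -> Multiset:
    """Parse an aggregate (conditional-free formula) into its multiset."""
    return decompose(parse_formula(text))
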