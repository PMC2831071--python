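"""Natural-deduction derivations and the proof checker.

A derivation is a numbered sequence of lines, each a formula with a
justification:

* ``IA`` — an initial-aggregate (premise) line;
* ``EVF:<id>`` — a knowledge-base reaction rule, asserted as an axiom;
* ``AndE:<src>`` — conjunction elimination: the line's bag is extracted
  from the aggregate on line ``src``;
* ``AndI:<a>,<b>`` — conjunction introduction: the line merges the bags of
  lines ``a`` and ``b``;
* ``ArrowE:<cond>,<minor>`` — modus ponens: line ``cond`` is a conditional,
  line ``minor`` matches its antecedent, the line is its consequent;
* ``ArrowI:<i>,<s>-<e>`` — conditional introduction over the span ``s``–``e``,
  discharging premise line ``i``: the line is ``formula(i) -> formula(e)``.

The checker enforces the *linearity restriction*: resources are consumed.
Every line may be consumed (cited as an AndI or ArrowE operand) at most
once.  The one multi-citation exception is conjunction elimination: a line
may serve as the source of several ``AndE`` extractions, as long as the
union of the extracted bags stays within the source's own bag — partial
decomposition of an aggregate is legal, using it twice is not.  A line
consumed by AndI/ArrowE cannot additionally be an AndE source.  Unused
lines (leftover products such as a released enzyme or ADP) are permitted.

EVF lines are resources too: re-using a reaction requires introducing its
rule on a second line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .formula import (
    Conditional,
    Formula,
    Multiset,
    Sequent,
    bag_of,
    format_formula,
    parse_formula,
)
from .kb import KnowledgeBase

__all__ = [
    "IA",
    "EvfRef",
    "AndE",
    "AndI",
    "ArrowE",
    "ArrowI",
    "Justification",
    "DerivationLine",
    "Derivation",
    "Violation",
    "CheckReport",
    "check_derivation",
    "extract_theorem",
    "load_derivation",
    "loads_derivation",
    "dump_derivation",
    "render_derivation",
]


# ---------------------------------------------------------------------------
# Justifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IA:
    """Initial aggregate (premise) line."""

    def __str__(self) -> str:
        return "IA"


@dataclass(frozen=True)
class EvfRef:
    evf_id: str

    def __str__(self) -> str:
        return f"EVF:{self.evf_id}"


@dataclass(frozen=True)
class AndE:
    source: int

    def __str__(self) -> str:
        return f"AndE:{self.source}"


@dataclass(frozen=True)
class AndI:
    line_a: int
    line_b: int

    def __str__(self) -> str:
        return f"AndI:{self.line_a},{self.line_b}"


@dataclass(frozen=True)
class ArrowE:
    conditional_line: int
    minor_line: int

    def __str__(self) -> str:
        return f"ArrowE:{self.conditional_line},{self.minor_line}"


@dataclass(frozen=True)
class ArrowI:
    discharged_line: int
    span: tuple[int, int]

    def __str__(self) -> str:
        return f"ArrowI:{self.discharged_line},{self.span[0]}-{self.span[1]}"


Justification = Union[IA, EvfRef, AndE, AndI, ArrowE, ArrowI]


def parse_justification(text: str) -> Justification:
    text = text.strip()
    if text == "IA":
        return IA()
    if ":" not in text:
        raise ValueError(f"malformed justification: {text!r}")
    kind, _, args = text.partition(":")
    kind = kind.strip()
    args = args.strip()
    try:
        if kind == "EVF":
            if not args:
                raise ValueError("EVF justification needs an id")
            return EvfRef(args)
        if kind == "AndE":
            return AndE(int(args))
        if kind == "AndI":
            a, b = args.split(",")
            return AndI(int(a), int(b))
        if kind == "ArrowE":
            c, m = args.split(",")
            return ArrowE(int(c), int(m))
        if kind == "ArrowI":
            i, span = args.split(",")
            s, e = span.split("-")
            return ArrowI(int(i), (int(s), int(e)))
    except ValueError as exc:
        raise ValueError(f"malformed justification {text!r}: {exc}") from None
    raise ValueError(f"unknown justification kind: {kind!r}")


# ---------------------------------------------------------------------------
# Derivation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DerivationLine:
    number: int
    formula: Formula
    justification: Justification
    label: Optional[str] = None

    def __str__(self) -> str:
        return f"{self.number}. {format_formula(self.formula)}\t{self.justification}"


@dataclass
class Derivation:
    lines: list[DerivationLine]
    claimed_theorem: Optional[Sequent] = None

    def __post_init__(self) -> None:
        if not self.lines:
            raise ValueError("a derivation must have at least one line")
        for i, line in enumerate(self.lines, start=1):
            if line.number != i:
                raise ValueError(
                    f"line numbers must be 1..n consecutive; got {line.number} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.lines)

    def __getitem__(self, number: int) -> DerivationLine:
        """1-based access by line number."""
        return self.lines[number - 1]


# ---------------------------------------------------------------------------
# Checker
# ---------------------------------------------------------------------------

BAD_REF = "BAD_REF"
EVF_NOT_IN_KB = "EVF_NOT_IN_KB"
LINEARITY = "LINEARITY"
BAD_EXTRACTION = "BAD_EXTRACTION"
BAD_COMBINE = "BAD_COMBINE"
BAD_MODUS_PONENS = "BAD_MODUS_PONENS"
BAD_DISCHARGE = "BAD_DISCHARGE"


@dataclass(frozen=True)
class Violation:
    line: int
    code: str
    message: str

    def __str__(self) -> str:
        return f"line {self.line}: {self.code}: {self.message}"


@dataclass
class CheckReport:
    valid: bool
    theorem: Optional[Sequent]
    violations: list[Violation]
    consumption: dict[int, list[int]] = field(default_factory=dict)

    def __bool__(self) -> bool:
        return self.valid


def check_derivation(d: Derivation, kb: KnowledgeBase) -> CheckReport:
    """Verify every line's justification and the linearity restriction.

    Returns a report with the extracted theorem (undischarged premises
    entail the final formula) when valid, or the list of violations when
    not.  The consumption map records, per line, which later lines consumed
    it (AndI/ArrowE operands and AndE extractions).
    """
    violations: list[Violation] = []
    consumption: dict[int, list[int]] = {}
    extracted: dict[int, Multiset] = {}  # AndE source -> union of extracted bags
    hard_consumed: dict[int, int] = {}  # line -> the single AndI/ArrowE consumer
    discharged: set[int] = set()

    def bad(line: int, code: str, message: str) -> None:
        violations.append(Violation(line, code, message))

    def consume(target: int, consumer: int) -> None:
        """Record a hard (AndI/ArrowE operand) consumption of ``target``."""
        consumption.setdefault(target, []).append(consumer)
        if target in hard_consumed:
            bad(
                consumer,
                LINEARITY,
                f"line {target} already consumed by line {hard_consumed[target]}",
            )
            return
        if target in extracted:
            bad(
                consumer,
                LINEARITY,
                f"line {target} already partially consumed by AndE extraction",
            )
            return
        hard_consumed[target] = consumer

    def ref_ok(ref: int, current: int) -> bool:
        if not (1 <= ref < current):
            bad(current, BAD_REF, f"reference to line {ref} is out of range")
            return False
        return True

    n = len(d.lines)
    for line in d.lines:
        num, f, just = line.number, line.formula, line.justification

        if isinstance(just, IA):
            if isinstance(f, Conditional):
                bad(num, BAD_REF, "an initial-aggregate line may not be a conditional")
            continue

        if isinstance(just, EvfRef):
            evf = kb.get(just.evf_id)
            if evf is None:
                bad(num, EVF_NOT_IN_KB, f"no EVF with id {just.evf_id!r} in the knowledge base")
            elif evf.rule != f:
                bad(
                    num,
                    EVF_NOT_IN_KB,
                    f"formula differs from EVF {just.evf_id!r}: "
                    f"expected {format_formula(evf.rule)}",
                )
            continue

        if isinstance(just, AndE):
            if not ref_ok(just.source, num):
                continue
            src = d[just.source]
            if isinstance(src.formula, Conditional) or isinstance(f, Conditional):
                bad(num, BAD_EXTRACTION, "AndE applies only to aggregates, not conditionals")
                continue
            if just.source in hard_consumed:
                bad(
                    num,
                    LINEARITY,
                    f"line {just.source} already consumed by line {hard_consumed[just.source]}",
                )
                continue
            union = extracted.get(just.source, Multiset()) + bag_of(f)
            if not union <= bag_of(src.formula):
                bad(
                    num,
                    BAD_EXTRACTION,
                    f"extractions from line {just.source} exceed its aggregate "
                    f"{format_formula(src.formula)}",
                )
                continue
            extracted[just.source] = union
            consumption.setdefault(just.source, []).append(num)
            continue

        if isinstance(just, AndI):
            if not (ref_ok(just.line_a, num) and ref_ok(just.line_b, num)):
                continue
            if just.line_a == just.line_b:
                bad(num, LINEARITY, "AndI may not cite the same line twice")
                continue
            merged = bag_of(d[just.line_a].formula) + bag_of(d[just.line_b].formula)
            if bag_of(f) != merged:
                bad(
                    num,
                    BAD_COMBINE,
                    f"formula is not the conjunction of lines "
                    f"{just.line_a} and {just.line_b}",
                )
                continue
            consume(just.line_a, num)
            consume(just.line_b, num)
            continue

        if isinstance(just, ArrowE):
            if not (ref_ok(just.conditional_line, num) and ref_ok(just.minor_line, num)):
                continue
            cond = d[just.conditional_line].formula
            minor = d[just.minor_line].formula
            if not isinstance(cond, Conditional):
                bad(
                    num,
                    BAD_MODUS_PONENS,
                    f"line {just.conditional_line} is not a conditional",
                )
                continue
            if minor != cond.antecedent:
                bad(
                    num,
                    BAD_MODUS_PONENS,
                    f"line {just.minor_line} does not match the antecedent "
                    f"{format_formula(cond.antecedent)}",
                )
                continue
            if f != cond.consequent:
                bad(
                    num,
                    BAD_MODUS_PONENS,
                    f"formula differs from the consequent {format_formula(cond.consequent)}",
                )
                continue
            consume(just.conditional_line, num)
            consume(just.minor_line, num)
            continue

        if isinstance(just, ArrowI):
            i = just.discharged_line
            s, e = just.span
            if not (ref_ok(i, num) and ref_ok(e, num)):
                continue
            if not (s <= i <= e):
                bad(num, BAD_DISCHARGE, f"discharged line {i} outside span {s}-{e}")
                continue
            if not isinstance(d[i].justification, IA):
                bad(num, BAD_DISCHARGE, f"line {i} is not a premise (IA) line")
                continue
            if i in discharged:
                bad(num, BAD_DISCHARGE, f"line {i} already discharged")
                continue
            expected = Conditional(d[i].formula, d[e].formula)
            if f != expected:
                bad(
                    num,
                    BAD_DISCHARGE,
                    f"formula should be {format_formula(expected)}",
                )
                continue
            discharged.add(i)
            continue

        bad(num, BAD_REF, f"unknown justification {just!r}")  # pragma: no cover

    valid = not violations
    theorem: Optional[Sequent] = None
    if valid:
        premises = Multiset()
        for line in d.lines:
            if isinstance(line.justification, IA) and line.number not in discharged:
                premises = premises + bag_of(line.formula)
        theorem = Sequent(premises, d.lines[-1].formula)
    return CheckReport(valid=valid, theorem=theorem, violations=violations, consumption=consumption)


def extract_theorem(d: Derivation, kb: KnowledgeBase) -> Sequent:
    """The sequent established by a valid derivation.

    Premises are the undischarged IA-line bags; the conclusion is the final
    line's formula.  Invalid derivations are rejected.
    """
    report = check_derivation(d, kb)
    if not report.valid:
        raise ValueError(
            "cannot extract a theorem from an invalid derivation: "
            + "; ".join(str(v) for v in report.violations[:3])
        )
    assert report.theorem is not None
    return report.theorem


# ---------------------------------------------------------------------------
# .zdx IO
# ---------------------------------------------------------------------------

def loads_derivation(text: str, name: str = "<string>") -> Derivation:
    """Parse the ``.zdx`` TSV dialect: ``number<TAB>formula<TAB>justification``
    with an optional fourth label column; ``#`` starts a comment line.

    A label may alternatively be attached inline as ``formula : label``.
    """
    lines: list[DerivationLine] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{name}:{lineno}: expected number<TAB>formula<TAB>justification"
            )
        try:
            number = int(fields[0].strip())
        except ValueError:
            raise ValueError(f"{name}:{lineno}: bad line number {fields[0]!r}") from None
        formula_text = fields[1].strip()
        label: Optional[str] = fields[3].strip() if len(fields) > 3 and fields[3].strip() else None
        if label is None and " : " in formula_text:
            formula_text, _, label_text = formula_text.partition(" : ")
            label = label_text.strip()
        try:
            formula = parse_formula(formula_text)
            just = parse_justification(fields[2])
        except ValueError as exc:
            raise ValueError(f"{name}:{lineno}: {exc}") from None
        lines.append(DerivationLine(number, formula, just, label))
    return Derivation(lines)


def load_derivation(path: Union[str, Path]) -> Derivation:
    path = Path(path)
    return loads_derivation(path.read_text(encoding="utf-8"), name=str(path))


def dump_derivation(d: Derivation) -> str:
    rows = []
    for line in d.lines:
        row = f"{line.number}\t{format_formula(line.formula)}\t{line.justification}"
        if line.label is not None:
            row += f"\t{line.label}"
        rows.append(row)
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# Renderer
# ---------------------------------------------------------------------------

def _justification_prose(just: Justification) -> str:
    if isinstance(just, IA):
        return "IA"
    if isinstance(just, EvfRef):
        return f"EVF ({just.evf_id})"
    if isinstance(just, AndE):
        return f"From {just.source} by &E"
    if isinstance(just, AndI):
        return f"From {just.line_a},{just.line_b} by &I"
    if isinstance(just, ArrowE):
        return f"From {just.minor_line},{just.conditional_line} by ->E"
    if isinstance(just, ArrowI):
        return f"From {just.span[0]}-{just.span[1]} by ->I"
    return str(just)  # pragma: no cover


def render_derivation(d: Derivation) -> str:
    """A human-readable three-column proof table."""
    rows = [
        (
            f"{line.number}.",
            format_formula(line.formula)
            + (f" : {line.label}" if line.label is not None else ""),
            _justification_prose(line.justification),
        )
        for line in d.lines
    ]
    w0 = max(len(r[0]) for r in rows)
    w1 = max(len(r[1]) for r in rows)
    return "\n".join(f"{r[0]:>{w0}}  {r[1]:<{w1}}  {r[2]}" for r in rows)
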