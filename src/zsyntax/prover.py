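"""Forward-chaining proof search over the EVF knowledge base.

Deciding whether an initial aggregate entails a goal is a multiset
reachability question: the state is the bag of conditional-free formulas
currently available, and applying an EVF replaces its antecedent bag with
its consequent bag.  The four logical rules are compiled away — conjunction
elimination/introduction are bag bookkeeping, modus ponens is EVF
application — which is faithful because the logical rules are
content-independent and conditionals occur in pathway derivations only as
EVFs (plus the optional final discharge into theorem form).

The default breadth-first strategy returns a proof with a minimal number of
EVF applications.  Tie-breaks are fully deterministic: EVFs are tried in
knowledge-base order and states are expanded in insertion order, so
identical inputs always yield identical proofs.  Visited states are
memoized by a canonical bag encoding (sorted rendered-formula/count pairs).

On success the search path is replayed into a detailed natural-deduction
derivation — premise introduction, conjunction eliminations, EVF lines,
conjunction introductions and modus ponens steps — which always passes
:func:`~zsyntax.derivation.check_derivation`.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

from .derivation import (
    AndE,
    AndI,
    ArrowE,
    ArrowI,
    Derivation,
    DerivationLine,
    EvfRef,
    IA,
)
from .formula import (
    Conditional,
    Formula,
    Multiset,
    bag_of,
    conjunction_of,
    decompose,
    format_formula,
)
from .kb import Context, EVF, KnowledgeBase, applicable_evfs

__all__ = [
    "ProverConfig",
    "ProofResult",
    "prove",
    "check_validity",
    "simplify",
    "apply_evf",
    "encode_state",
]

PROVED = "proved"
NOT_PROVED = "not_proved"
BOUND_EXCEEDED = "bound_exceeded"


@dataclass(frozen=True)
class ProverConfig:
    """Search bounds and strategy.

    ``max_states`` caps the number of distinct bags memoized; ``max_depth``
    caps EVF applications along one path.  ``consume_all`` switches the goal
    test from bag containment (leftover products allowed, the default) to
    bag equality (every initial resource must end up in the goal).
    """

    max_states: int = 10**6
    max_depth: int = 64
    strategy: Literal["bfs", "dfs"] = "bfs"
    context: Context = field(default_factory=Context)
    consume_all: bool = False

    def __post_init__(self) -> None:
        if self.max_states <= 0 or self.max_depth <= 0:
            raise ValueError("search bounds must be positive")
        if self.strategy not in ("bfs", "dfs"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


_DEFAULT = ProverConfig()


@dataclass
class ProofResult:
    status: str  # proved | not_proved | bound_exceeded
    derivation: Optional[Derivation]
    evf_applications: list[str]
    states_explored: int

    @property
    def proved(self) -> bool:
        return self.status == PROVED


def encode_state(bag: Multiset) -> tuple[tuple[str, int], ...]:
    """Canonical, hashable encoding of a search state."""
    return tuple(
        (format_formula(f), c) for f, c in sorted(
            bag.items(), key=lambda kv: format_formula(kv[0])
        )
    )


def apply_evf(bag: Multiset, evf: EVF) -> Multiset:
    """The successor bag after firing ``evf`` (antecedent out, consequent in)."""
    return (bag - evf.antecedent_bag) + evf.consequent_bag


def _goal_satisfied(bag: Multiset, goal_bag: Multiset, consume_all: bool) -> bool:
    if consume_all:
        return bag == goal_bag
    return goal_bag <= bag


def prove(
    kb: KnowledgeBase,
    ia: Multiset,
    goal: Formula,
    cfg: ProverConfig = _DEFAULT,
    theorem_form: bool = False,
) -> ProofResult:
    """Decide whether the initial aggregate entails the goal over ``kb``.

    The goal must be conditional-free (for conditional goals use
    :func:`check_validity`).  ``status`` distinguishes an exhaustively
    closed search (``not_proved``) from one truncated by the bounds
    (``bound_exceeded``).  With ``theorem_form`` the reconstructed
    derivation ends with a conditional-introduction line discharging the
    premise, so the theorem needs no initial aggregate.
    """
    if isinstance(goal, Conditional):
        raise ValueError("goal must be conditional-free; use check_validity")
    for f in ia.distinct():
        if isinstance(f, Conditional):
            raise ValueError("initial aggregate must be conditional-free")
    goal_bag = decompose(goal)

    start_key = encode_state(ia)
    visited = {start_key}
    frontier: deque[tuple[Multiset, tuple[int, ...]]] = deque([(ia, ())])
    truncated = False
    pop = frontier.popleft if cfg.strategy == "bfs" else frontier.pop

    while frontier:
        bag, path = pop()
        if _goal_satisfied(bag, goal_bag, cfg.consume_all):
            evf_seq = [kb.evfs[i] for i in path]
            derivation = _reconstruct(ia, evf_seq, goal, theorem_form)
            return ProofResult(
                status=PROVED,
                derivation=derivation,
                evf_applications=[e.id for e in evf_seq],
                states_explored=len(visited),
            )
        if len(path) >= cfg.max_depth:
            truncated = True
            continue
        successors = []
        for index, evf in enumerate(kb.evfs):
            if not cfg.context.admits(evf):
                continue
            if evf.antecedent_bag <= bag:
                nxt = apply_evf(bag, evf)
                key = encode_state(nxt)
                if key in visited:
                    continue
                if len(visited) >= cfg.max_states:
                    truncated = True
                    continue
                visited.add(key)
                successors.append((nxt, path + (index,)))
        if cfg.strategy == "dfs":
            successors.reverse()  # keep KB order as the first branch explored
        frontier.extend(successors)

    return ProofResult(
        status=BOUND_EXCEEDED if truncated else NOT_PROVED,
        derivation=None,
        evf_applications=[],
        states_explored=len(visited),
    )


def check_validity(
    kb: KnowledgeBase, f: Conditional, cfg: ProverConfig = _DEFAULT
) -> Optional[bool]:
    """Is the conditional valid, i.e. derivable from the empty aggregate?

    By the deduction property, the empty aggregate is of type ``A -> B``
    exactly when ``A`` entails ``B``; so the antecedent is decomposed into
    an initial aggregate and the consequent is proved from it.  Returns
    ``True``/``False``, or ``None`` when the search hit its bounds
    (indeterminate, deliberately distinct from false).
    """
    if not isinstance(f, Conditional):
        raise ValueError("check_validity expects a conditional formula")
    result = prove(kb, decompose(f.antecedent), f.consequent, cfg)
    if result.status == BOUND_EXCEEDED:
        return None
    return result.proved


def simplify(d: Derivation) -> list[Conditional]:
    """The demonstration view: EVF rules in application order.

    Line order equals application order in checker-valid derivations, since
    a rule line must precede the modus ponens that consumes it.
    """
    return [
        line.formula  # type: ignore[misc]
        for line in d.lines
        if isinstance(line.justification, EvfRef)
    ]


# ---------------------------------------------------------------------------
# Derivation reconstruction
# ---------------------------------------------------------------------------

class _Builder:
    """Accumulates derivation lines, tracking one available (unconsumed)
    line per resource instance."""

    def __init__(self) -> None:
        self.lines: list[DerivationLine] = []
        self.available: dict[Formula, deque[int]] = {}

    def add(self, formula: Formula, just) -> int:
        number = len(self.lines) + 1
        self.lines.append(DerivationLine(number, formula, just))
        return number

    def offer(self, formula: Formula, number: int) -> None:
        self.available.setdefault(formula, deque()).append(number)

    def take(self, formula: Formula) -> int:
        queue = self.available.get(formula)
        if not queue:  # pragma: no cover - search guarantees availability
            raise RuntimeError(f"no available line for {format_formula(formula)}")
        number = queue.popleft()
        if not queue:
            del self.available[formula]
        return number

    def last_number(self) -> int:
        return len(self.lines)


def _explode(b: _Builder, source_line: int, bag: Multiset, last: Optional[Formula]) -> None:
    """Extract every element of ``bag`` from ``source_line`` via AndE,
    putting one instance of ``last`` (when given) on the final line."""
    order = list(bag.elements())
    if last is not None:
        order.remove(last)
        order.append(last)
    for f in order:
        n = b.add(f, AndE(source_line))
        b.offer(f, n)


def _reconstruct(
    ia: Multiset, evf_seq: list[EVF], goal: Formula, theorem_form: bool
) -> Derivation:
    b = _Builder()
    goal_bag = decompose(goal)

    ia_formula: Optional[Formula] = None
    ia_line: Optional[int] = None
    if not ia.is_empty():
        ia_formula = conjunction_of(ia)
        ia_line = b.add(ia_formula, IA())
        if ia.total() == 1:
            b.offer(ia_formula, ia_line)
        else:
            # put a goal element last so that an EVF-free proof ends on goal
            last = None
            if not evf_seq and goal_bag.total() == 1 and ia != goal_bag:
                last = next(goal_bag.distinct())
            _explode(b, ia_line, ia, last)

    for position, evf in enumerate(evf_seq):
        rule_line = b.add(evf.rule, EvfRef(evf.id))
        # assemble the minor premise from available resource lines
        ante = evf.antecedent_bag
        instances = [b.take(f) for f in ante.elements()]
        if len(instances) == 1:
            minor_line = instances[0]
        else:
            minor_line = instances[0]
            acc = bag_of(b.lines[minor_line - 1].formula)
            for inst in instances[1:]:
                acc = acc + bag_of(b.lines[inst - 1].formula)
                minor_line = b.add(conjunction_of(acc), AndI(minor_line, inst))
        result_line = b.add(evf.rule.consequent, ArrowE(rule_line, minor_line))
        cons = evf.consequent_bag
        if cons.total() == 1:
            b.offer(evf.rule.consequent, result_line)
        else:
            last = None
            if position == len(evf_seq) - 1 and goal_bag.total() == 1:
                g = next(goal_bag.distinct())
                if g in cons:
                    last = g
            _explode(b, result_line, cons, last)

    # final line must carry exactly the goal formula
    if not (b.lines and b.lines[-1].formula == goal and goal in b.available
            and b.available[goal][-1] == b.last_number()):
        if goal_bag.total() == 1:
            # the goal line exists but is not last (EVF-free extraction from
            # an aggregate already ends on it; this branch covers odd orders)
            instances = [b.take(f) for f in goal_bag.elements()]
            if instances[-1] != b.last_number():  # pragma: no cover - defensive
                raise RuntimeError("goal line could not be placed last")
        else:
            instances = [b.take(f) for f in goal_bag.elements()]
            current = instances[0]
            acc = bag_of(b.lines[current - 1].formula)
            for inst in instances[1:]:
                acc = acc + bag_of(b.lines[inst - 1].formula)
                current = b.add(conjunction_of(acc), AndI(current, inst))

    if theorem_form:
        if ia_line is None or ia_formula is None:
            raise ValueError("theorem form requires a non-empty initial aggregate")
        end = b.last_number()
        b.add(Conditional(ia_formula, b.lines[end - 1].formula), ArrowI(ia_line, (ia_line, end)))

    return Derivation(b.lines)
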