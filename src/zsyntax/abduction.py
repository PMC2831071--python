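"""Abductive reasoning: what is missing when a deduction fails?

When the prover cannot establish a goal, three backward-looking questions
arise, mirroring how a bench scientist reasons about a failed pathway
reconstruction:

* **Missing resources** — is the initial aggregate simply short of some
  molecules?  :func:`abduce_resources` searches addition bags of increasing
  cardinality and returns the minimal ones that make the goal provable.
* **Missing reactions** — is a reaction absent from the knowledge base?
  :func:`abduce_evfs` enumerates candidate binding rules (``X & Y -> X*Y``)
  and release/transformation rules (``X*Y -> ...``) connecting what is
  reachable forward from the initial aggregate to what the goal requires
  backward, and returns those that close the gap.
* **Candidate endpoints** — given an anchoring complex, what final
  aggregates could a hypothetical pathway produce?  :func:`enumerate_goals`
  applies hypothetical pairwise interaction events to the post-anchor bag
  and emits every resulting aggregate as a candidate theorem, under the
  full-consumption convention: every initial resource is used exactly once
  and none is invented, which :func:`validate_candidate` checks by
  comparing atom-leaf multisets.

Pruning of biologically implausible candidates is a plugin interface (a
list of predicates); the built-in pruner drops candidates that introduced
hypothetical interaction events yet whose conclusion is already reachable
with known reactions alone — those are deductions, not hypotheses.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from .derivation import Derivation
from .formula import (
    Atom,
    Conditional,
    Conjunction,
    Formula,
    Interaction,
    Multiset,
    Sequent,
    atom_leaves,
    conjunction_of,
    decompose,
    format_formula,
    sort_key,
)
from .kb import EVF, KnowledgeBase
from .prover import BOUND_EXCEEDED, ProverConfig, prove

__all__ = [
    "ResourceHypothesis",
    "EvfHypothesis",
    "CandidateGoal",
    "abduce_resources",
    "abduce_evfs",
    "enumerate_goals",
    "validate_candidate",
    "prune_known_pathways",
]

_DEFAULT = ProverConfig()


@dataclass
class ResourceHypothesis:
    """Additional resources that make the goal provable, with the proof."""

    additions: Multiset
    proof: Derivation

    def __str__(self) -> str:
        return " & ".join(format_formula(f) for f in self.additions.elements())


@dataclass
class EvfHypothesis:
    """A hypothesized reaction rule that closes the deductive gap."""

    rule: Conditional
    proof: Derivation

    def __str__(self) -> str:
        return format_formula(self.rule)


@dataclass
class CandidateGoal:
    """A candidate theorem for a hypothetical pathway endpoint."""

    sequent: Sequent
    hypothetical_events: list[Interaction]

    def __str__(self) -> str:
        return str(self.sequent)


# ---------------------------------------------------------------------------
# Missing resources
# ---------------------------------------------------------------------------

def abduce_resources(
    kb: KnowledgeBase,
    ia: Multiset,
    goal: Formula,
    vocabulary: Optional[Sequence[Atom]] = None,
    max_additions: int = 2,
    cfg: ProverConfig = _DEFAULT,
) -> list[ResourceHypothesis]:
    """Minimal addition bags making the goal provable.

    Deepens over addition cardinality 1..``max_additions`` drawing from
    ``vocabulary`` (default: every atom mentioned in the KB).  A bag that
    contains an already-returned smaller solution is redundant and skipped,
    so no returned bag is a super-multiset of another.  Order is
    deterministic (cardinality, then canonical formula order).
    """
    baseline = prove(kb, ia, goal, cfg)
    if baseline.proved:
        warnings.warn("goal is already provable; nothing to abduce", stacklevel=2)
        return []
    vocab: list[Atom] = (
        sorted(set(vocabulary), key=sort_key) if vocabulary is not None else kb.atoms()
    )
    hypotheses: list[ResourceHypothesis] = []
    for k in range(1, max_additions + 1):
        for combo in itertools.combinations_with_replacement(vocab, k):
            additions = Multiset(combo)
            if any(h.additions <= additions for h in hypotheses):
                continue
            result = prove(kb, ia + additions, goal, cfg)
            if result.proved:
                assert result.derivation is not None
                hypotheses.append(ResourceHypothesis(additions, result.derivation))
    return hypotheses


# ---------------------------------------------------------------------------
# Missing reactions
# ---------------------------------------------------------------------------

def _forward_reachable_formulas(
    kb: KnowledgeBase, ia: Multiset, cfg: ProverConfig, max_states: int = 20000
) -> list[Formula]:
    """Every conditional-free formula occurring in any bag reachable from ``ia``."""
    from .prover import apply_evf, encode_state

    seen_states = {encode_state(ia)}
    frontier = [ia]
    formulas: set[Formula] = set(ia.distinct())
    while frontier and len(seen_states) < max_states:
        bag = frontier.pop(0)
        for evf in kb.evfs:
            if cfg.context.admits(evf) and evf.antecedent_bag <= bag:
                nxt = apply_evf(bag, evf)
                key = encode_state(nxt)
                if key not in seen_states:
                    seen_states.add(key)
                    formulas.update(nxt.distinct())
                    frontier.append(nxt)
    return sorted(formulas, key=sort_key)


def _backward_relevant_formulas(kb: KnowledgeBase, goal: Formula) -> list[Formula]:
    """Formulas from which the goal could be assembled, by reverse rule chaining:
    start with the goal's constituents and repeatedly pull in the antecedent
    bags of rules producing anything already in the set."""
    relevant: set[Formula] = set(decompose(goal).distinct())
    changed = True
    while changed:
        changed = False
        for evf in kb.evfs:
            if any(f in relevant for f in evf.consequent_bag.distinct()):
                for f in evf.antecedent_bag.distinct():
                    if f not in relevant:
                        relevant.add(f)
                        changed = True
    return sorted(relevant, key=sort_key)


def _interaction_leaves(f: Formula) -> list[Formula]:
    """The molecule-level components of a complex (subcomplexes and atoms)."""
    out: list[Formula] = []

    def walk(g: Formula) -> None:
        out.append(g)
        if isinstance(g, Interaction):
            walk(g.left)
            walk(g.right)

    if isinstance(f, Interaction):
        walk(f.left)
        walk(f.right)
    return out


def _candidate_rules(
    kb: KnowledgeBase, ia: Multiset, goal: Formula, cfg: ProverConfig
) -> list[Conditional]:
    forward = _forward_reachable_formulas(kb, ia, cfg)
    backward = _backward_relevant_formulas(kb, goal)
    candidates: list[Conditional] = []
    seen: set[Conditional] = set()

    def emit(rule: Conditional) -> None:
        if rule not in seen and not kb.has_rule(rule):
            seen.add(rule)
            candidates.append(rule)

    interactable = [f for f in forward if not isinstance(f, (Conjunction, Conditional))]
    backward_set = set(backward)
    # binding hypotheses X & Y -> X*Y whose complex the goal plausibly needs
    for x in interactable:
        for y in interactable:
            complex_ = Interaction(x, y)
            if complex_ in backward_set:
                ante = conjunction_of(Multiset([x, y]))
                emit(Conditional(ante, complex_))
    # release/transformation hypotheses X*Y -> C (& D): consequents drawn from
    # backward-relevant formulas and the complex's own components
    complexes = [f for f in forward if isinstance(f, Interaction)]
    for z in complexes:
        pool = sorted(set(backward) | set(_interaction_leaves(z)), key=sort_key)
        pool = [p for p in pool if not isinstance(p, (Conjunction, Conditional))]
        for c in pool:
            emit(Conditional(z, c))
        for c, d in itertools.combinations_with_replacement(pool, 2):
            emit(Conditional(z, conjunction_of(Multiset([c, d]))))
    return candidates


def abduce_evfs(
    kb: KnowledgeBase,
    ia: Multiset,
    goal: Formula,
    max_new_rules: int = 1,
    cfg: ProverConfig = _DEFAULT,
) -> list[EvfHypothesis]:
    """Hypothesized reaction rules that make the goal provable.

    Candidate rules keep the two canonical shapes — binding
    (``X & Y -> X*Y``) and complex transformation/release
    (``X*Y -> C`` or ``X*Y -> C & D``) — which keeps the space finite.
    Singleton rule sets are tried first; pairs only when ``max_new_rules``
    allows and no single rule suffices.  Each hypothesis carries the proof
    obtained with the rule added.
    """
    baseline = prove(kb, ia, goal, cfg)
    if baseline.proved:
        warnings.warn("goal is already provable; nothing to abduce", stacklevel=2)
        return []
    candidates = _candidate_rules(kb, ia, goal, cfg)
    hypotheses: list[EvfHypothesis] = []
    for rule in candidates:
        extended = kb.extended(EVF(id="hyp", rule=rule))
        result = prove(extended, ia, goal, cfg)
        if result.proved:
            assert result.derivation is not None
            hypotheses.append(EvfHypothesis(rule, result.derivation))
    if hypotheses or max_new_rules < 2:
        return hypotheses
    # no single rule closes the gap: regenerate candidates against each
    # singleton extension and try pairs
    for first in candidates:
        kb1 = kb.extended(EVF(id="hypA", rule=first))
        for second in _candidate_rules(kb1, ia, goal, cfg):
            extended = kb1.extended(EVF(id="hypB", rule=second))
            result = prove(extended, ia, goal, cfg)
            if result.proved:
                assert result.derivation is not None
                hypotheses.append(EvfHypothesis(second, result.derivation))
                hypotheses.append(EvfHypothesis(first, result.derivation))
                return hypotheses
    return hypotheses


# ---------------------------------------------------------------------------
# Candidate endpoint enumeration
# ---------------------------------------------------------------------------

def validate_candidate(ia: Multiset, candidate: Formula) -> bool:
    """Stoichiometric validity of a hypothesis endpoint.

    True iff the candidate's atom-leaf multiset equals the initial
    aggregate's: every initial molecule is used exactly once and none is
    invented.
    """
    if isinstance(candidate, Conditional):
        raise ValueError("candidate must be conditional-free")
    ia_leaves = Multiset()
    for f in ia.elements():
        ia_leaves = ia_leaves + atom_leaves(f)
    return atom_leaves(candidate) == ia_leaves


def prune_known_pathways(
    kb: KnowledgeBase, ia: Multiset, cfg: ProverConfig = _DEFAULT
) -> Callable[[CandidateGoal], bool]:
    """The built-in pruner: keep only candidates with genuinely hypothetical
    content.

    A join event is *known* when the KB already contains the binding rule
    forming that exact complex from its operands.  A candidate all of whose
    events are known is a deduction dressed up as a hypothesis and is
    dropped.  The zero-event candidate is always kept: it is the baseline
    "the anchor plays no further role" hypothesis, and candidates with at
    least one genuinely novel event survive even if other events are known.
    """

    def event_known(event: Interaction) -> bool:
        operands = Multiset([event.left, event.right])
        return kb.has_rule(Conditional(conjunction_of(operands), event))

    def keep(candidate: CandidateGoal) -> bool:
        if not candidate.hypothetical_events:
            return True
        return not all(event_known(e) for e in candidate.hypothetical_events)

    return keep


def enumerate_goals(
    kb: KnowledgeBase,
    ia: Multiset,
    anchor: Interaction,
    max_events: int = 2,
    pruners: Optional[Iterable[Callable[[CandidateGoal], bool]]] = None,
    cfg: ProverConfig = _DEFAULT,
) -> list[CandidateGoal]:
    """Candidate theorems reachable by hypothetical interaction events.

    The anchor complex must be derivable from the initial aggregate via the
    KB; the starting bag is the aggregate after forming it.  Each event
    joins two bag members into an interaction (both operand orders are
    hypothesized, since operand order is part of the complex).  Every
    resulting bag, rendered as a conjunction, is a candidate conclusion for
    the sequent ``ia |- conclusion``; by construction all initial resources
    are consumed exactly once.  Candidates are deduplicated by conclusion
    (keeping the fewest-events version) and emitted in deterministic order:
    event count, then canonical conclusion text.
    """
    if not isinstance(anchor, Interaction):
        raise ValueError("anchor must be an interaction complex")
    anchored = prove(kb, ia, anchor, cfg)
    if not anchored.proved:
        raise ValueError(
            f"anchor {format_formula(anchor)} is not derivable from the initial aggregate"
        )
    # replay the anchoring proof's EVF applications to obtain the post-anchor bag
    from .prover import apply_evf

    bag = ia
    for evf_id in anchored.evf_applications:
        bag = apply_evf(bag, kb[evf_id])

    frontier: list[tuple[Multiset, tuple[Interaction, ...]]] = [(bag, ())]
    by_conclusion: dict[Formula, CandidateGoal] = {}
    ordered: list[CandidateGoal] = []
    for depth_level in range(max_events + 1):
        next_frontier: list[tuple[Multiset, tuple[Interaction, ...]]] = []
        for state, events in frontier:
            conclusion = conjunction_of(state)
            if conclusion not in by_conclusion:
                cand = CandidateGoal(
                    sequent=Sequent(ia, conclusion),
                    hypothetical_events=list(events),
                )
                by_conclusion[conclusion] = cand
                ordered.append(cand)
            if depth_level == max_events:
                continue
            members = [
                f
                for f in sorted(state.distinct(), key=sort_key)
                if not isinstance(f, (Conjunction, Conditional))
            ]
            for i, x in enumerate(members):
                for y in members[i:]:
                    if x == y and state.count(x) < 2:
                        continue
                    joins = [Interaction(x, y)]
                    if x != y:
                        joins.append(Interaction(y, x))
                    for joined in joins:
                        nxt = (state - Multiset([x, y])) + Multiset([joined])
                        next_frontier.append((nxt, events + (joined,)))
        frontier = next_frontier

    pruner_list = list(pruners) if pruners is not None else [prune_known_pathways(kb, ia, cfg)]
    kept = [c for c in ordered if all(p(c) for p in pruner_list)]
    kept.sort(
        key=lambda c: (len(c.hypothetical_events), format_formula(c.sequent.conclusion))
    )
    return kept
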