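"""Packaged worked-example pathways, a seeded random-pathway generator and
an independent brute-force reachability oracle.

The packaged bundles are small curated pathways: glycolysis (D-Glucose to
Fructose-1,6-bisphosphate), the TP53/MDM2 regulatory loop and its
degradation sub-routine, an abstract feed-forward loop, TP53
phosphorylation, and the NUMB/MDM2 setting for hypothesis generation.
Each bundle couples a knowledge base with an initial aggregate, a goal and
(where a detailed proof exists) a checkable derivation.

:func:`random_pathway` emulates the same anatomy at arbitrary size:
enzyme-catalysis chains (substrate binds enzyme, the complex transforms
into the next substrate releasing the enzyme), optional stoichiometric
double-consumption of a cofactor, and decoy branch reactions.  It can
delete one needed resource or rule and record it as the planted answer for
parameter-recovery tests of the abduction module.

:func:`brute_force_reachable` is a deliberately naive exhaustive closure
with its own state encoding, used in tests as the ground-truth oracle for
the prover; it shares no search code with :mod:`zsyntax.prover`.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Union

import yaml

from .derivation import Derivation, loads_derivation
from .formula import Atom, Formula, Multiset, parse_formula, decompose
from .kb import EVF, KnowledgeBase, loads_kb

__all__ = [
    "PathwayFixture",
    "fixture_names",
    "load_fixture_kb",
    "load_fixture_derivation",
    "load_bundle",
    "load_candidate_conclusions",
    "random_pathway",
    "brute_force_reachable",
]

BUNDLES = ("glycolysis", "tp53_loop", "tp53_degradation", "ffl", "phospho", "numb")


def _data(name: str) -> str:
    return (resources.files("zsyntax.data") / name).read_text(encoding="utf-8")


def fixture_names() -> tuple[str, ...]:
    return BUNDLES


def load_fixture_kb(name: str) -> KnowledgeBase:
    """Load a packaged knowledge base by bundle name (e.g. ``"glycolysis"``)."""
    return loads_kb(_data(f"{name}.kb"), name=f"{name}.kb")


def load_fixture_derivation(name: str) -> Derivation:
    """Load a packaged detailed derivation (``glycolysis``, ``tp53_loop``, ``ffl``)."""
    return loads_derivation(_data(f"{name}_detailed.zdx"), name=f"{name}_detailed.zdx")


def load_candidate_conclusions() -> list[Formula]:
    """The eight curated hypothetical endpoints for the NUMB/TP53/MDM2 loop."""
    out = []
    for line in _data("numb_candidates.tsv").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        _, _, formula_text = line.partition("\t")
        out.append(parse_formula(formula_text.strip()))
    return out


@dataclass
class PathwayFixture:
    """A pathway instance: KB, initial aggregate, goal, and ground truth."""

    kb: KnowledgeBase
    ia: Multiset
    goal: Formula
    reachable: bool
    planted_answer: Optional[Union[Multiset, EVF]] = None
    seed: int = 0
    derivation: Optional[Derivation] = None


def load_bundle(name: str) -> PathwayFixture:
    """Load a packaged pathway bundle (KB + manifest + optional derivation)."""
    manifest = yaml.safe_load(_data(f"{name}.yaml"))
    derivation = None
    if manifest.get("derivation"):
        derivation = loads_derivation(
            _data(manifest["derivation"]), name=manifest["derivation"]
        )
    return PathwayFixture(
        kb=loads_kb(_data(manifest["kb"]), name=manifest["kb"]),
        ia=decompose(parse_formula(manifest["ia"])),
        goal=parse_formula(manifest["goal"]),
        reachable=bool(manifest["reachable"]),
        planted_answer=None,
        seed=int(manifest.get("seed") or 0),
        derivation=derivation,
    )


# ---------------------------------------------------------------------------
# Random pathway generator
# ---------------------------------------------------------------------------

def random_pathway(
    n_atoms: int,
    chain_len: int,
    branching: int = 0,
    require_stoich: bool = False,
    seed: int = 0,
    delete: Optional[str] = None,
) -> PathwayFixture:
    """Deterministically generate an enzyme-catalysis chain pathway.

    The core chain has ``chain_len`` steps: substrate ``S{i}`` binds enzyme
    ``E{i}`` and the complex transforms into ``S{i+1}``, releasing the
    enzyme (the hexokinase pattern).  With ``require_stoich`` one seeded
    step additionally consumes two copies of a cofactor ``X``, so a single
    copy in the aggregate leaves the goal unreachable.  ``branching`` adds
    decoy binding reactions among ``n_atoms`` distractor species (present
    in the aggregate, leading nowhere).  ``delete`` removes one needed
    resource (``"resource"``) or one chain rule (``"rule"``), recording it
    as ``planted_answer`` for abduction-recovery tests.

    Identical ``seed`` and parameters always produce the identical fixture.
    """
    if not (n_atoms >= chain_len >= 1):
        raise ValueError("need n_atoms >= chain_len >= 1")
    if delete not in (None, "resource", "rule"):
        raise ValueError(f"unknown deletion mode {delete!r}")
    rng = random.Random(seed)

    subs = [Atom(f"S{i}") for i in range(chain_len + 1)]
    enzymes = [Atom(f"E{i}") for i in range(1, chain_len + 1)]
    cofactor = Atom("X")
    spent = Atom("Y")

    evfs: list[EVF] = []
    stoich_step = rng.randrange(chain_len) if require_stoich else -1
    for i in range(chain_len):
        s, e, nxt = subs[i], enzymes[i], subs[i + 1]
        bind = parse_formula(f"{s.name} & {e.name} -> {s.name}*{e.name}")
        evfs.append(EVF(id=f"bind{i}", rule=bind))
        if i == stoich_step:
            # the transformation consumes two cofactor molecules
            load = parse_formula(
                f"({s.name}*{e.name}) & {cofactor.name} & {cofactor.name} "
                f"-> ({s.name}*{e.name})*{cofactor.name}"
            )
            evfs.append(EVF(id=f"load{i}", rule=load))
            trans = parse_formula(
                f"({s.name}*{e.name})*{cofactor.name} "
                f"-> {nxt.name} & {e.name} & {spent.name} & {spent.name}"
            )
        else:
            trans = parse_formula(
                f"{s.name}*{e.name} -> {nxt.name} & {e.name}"
            )
        evfs.append(EVF(id=f"trans{i}", rule=trans))

    decoys = [Atom(f"D{i}") for i in range(min(n_atoms, 6))]
    seen_pairs: set[frozenset[str]] = set()
    for b in range(branching):
        if len(decoys) < 2:
            break
        x, y = rng.sample(decoys, 2)
        pair = frozenset((x.name, y.name))
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        rule = parse_formula(f"{x.name} & {y.name} -> {x.name}*{y.name}")
        evfs.append(EVF(id=f"decoy{b}", rule=rule))

    ia_items: list[Atom] = [subs[0]] + enzymes + decoys[: min(2, len(decoys))]
    if require_stoich:
        ia_items += [cofactor, cofactor]
    ia = Multiset(ia_items)
    goal: Formula = subs[-1]

    planted: Optional[Union[Multiset, EVF]] = None
    reachable = True
    if delete == "resource":
        # drop one chain-critical resource (a substrate copy, enzyme or cofactor)
        critical = [subs[0]] + enzymes + ([cofactor] if require_stoich else [])
        victim = rng.choice(critical)
        ia = ia - Multiset([victim])
        planted = Multiset([victim])
        reachable = False
    elif delete == "rule":
        # only delete rules of the two canonical shapes (binding, two-product
        # transformation): those are the shapes abduction hypothesizes over
        excluded = {f"load{stoich_step}", f"trans{stoich_step}"}
        chain_ids = [
            e.id
            for e in evfs
            if (e.id.startswith("bind") or e.id.startswith("trans"))
            and e.id not in excluded
        ]
        victim_id = rng.choice(chain_ids)
        planted = next(e for e in evfs if e.id == victim_id)
        evfs = [e for e in evfs if e.id != victim_id]
        reachable = False

    return PathwayFixture(
        kb=KnowledgeBase(evfs),
        ia=ia,
        goal=goal,
        reachable=reachable,
        planted_answer=planted,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Independent oracle
# ---------------------------------------------------------------------------

def brute_force_reachable(
    kb: KnowledgeBase,
    ia: Multiset,
    goal: Formula,
    max_states: int = 10**5,
) -> bool:
    """Exhaustive breadth-first closure over bags; ground truth for tests.

    States are encoded naively as sorted tuples of rendered formulas with
    repetition; no heuristics, no shared machinery with the prover.  Raises
    if the closure exceeds ``max_states``.
    """
    from .formula import format_formula

    def encode(bag: Multiset) -> tuple[str, ...]:
        names = []
        for f, c in bag.items():
            names.extend([format_formula(f)] * c)
        return tuple(sorted(names))

    goal_bag = decompose(goal)

    def satisfied(bag: Multiset) -> bool:
        return all(bag.count(f) >= c for f, c in goal_bag.items())

    seen = {encode(ia)}
    queue = [ia]
    while queue:
        bag = queue.pop(0)
        if satisfied(bag):
            return True
        for evf in kb.evfs:
            ante = evf.antecedent_bag
            if all(bag.count(f) >= c for f, c in ante.items()):
                nxt = (bag - ante) + evf.consequent_bag
                key = encode(nxt)
                if key not in seen:
                    if len(seen) >= max_states:
                        raise RuntimeError(
                            f"brute-force closure exceeded {max_states} states"
                        )
                    seen.add(key)
                    queue.append(nxt)
    return False
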