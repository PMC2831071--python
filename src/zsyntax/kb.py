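"""Empirically valid formulas (EVFs) and the knowledge base holding them.

An EVF is a laboratory-established reaction written as a conditional,
e.g. ``Glc & HK -> Glc*HK`` (binding) or ``(Glc*HK)*ATP -> G6P & HK & ADP``
(transformation).  EVFs are the non-logical axioms of a pathway theory:
their validity is content-dependent and they are simply asserted, never
derived.  The knowledge base is an ordered collection of EVFs; file order
is the deterministic tie-break used by the prover and by abduction.

The on-disk ``.kb`` dialect is tab-separated with columns
``id, rule, interaction_class, compartment, citation`` (trailing empty
columns may be omitted; ``#`` starts a comment line).  A JSON array of
objects with the same fields is supported for programmatic use.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from .formula import (
    Conditional,
    Formula,
    Multiset,
    decompose,
    format_formula,
    parse_formula,
)

__all__ = ["EVF", "KnowledgeBase", "Context", "load_kb", "loads_kb", "applicable_evfs"]


class KBError(ValueError):
    """Raised on malformed knowledge-base input."""


@dataclass(frozen=True)
class EVF:
    """An empirically valid formula with its metadata.

    ``interaction_class`` tags the kind of experimental evidence behind a
    binding claim (in vitro binding, two-hybrid, co-IP, FRET, ...);
    ``compartment`` localizes the reaction (nucleus, cytoplasm, ...).  Both
    are optional opaque strings; an untagged EVF applies in every context.
    """

    id: str
    rule: Conditional
    interaction_class: Optional[str] = None
    compartment: Optional[str] = None
    citation: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise KBError("EVF id must be non-empty")
        if not isinstance(self.rule, Conditional):
            raise KBError(f"EVF {self.id!r}: rule must be a conditional")
        for side in (self.rule.antecedent, self.rule.consequent):
            try:
                decompose(side)
            except ValueError:
                raise KBError(
                    f"EVF {self.id!r}: nested conditionals are not allowed in "
                    f"{format_formula(self.rule)}"
                ) from None

    @property
    def antecedent_bag(self) -> Multiset:
        return decompose(self.rule.antecedent)

    @property
    def consequent_bag(self) -> Multiset:
        return decompose(self.rule.consequent)

    def __str__(self) -> str:
        return f"{self.id}: {format_formula(self.rule)}"


@dataclass(frozen=True)
class Context:
    """Optional filters restricting which EVFs may fire.

    A tagged EVF requires the matching context field to be unset or to
    match (compartment: equality; interaction class: membership in the
    allowed set).  Untagged EVFs are universally applicable.
    """

    compartment: Optional[str] = None
    allowed_interaction_classes: Optional[frozenset[str]] = None

    def admits(self, evf: EVF) -> bool:
        if (
            evf.compartment is not None
            and self.compartment is not None
            and evf.compartment != self.compartment
        ):
            return False
        if (
            evf.interaction_class is not None
            and self.allowed_interaction_classes is not None
            and evf.interaction_class not in self.allowed_interaction_classes
        ):
            return False
        return True


_UNIVERSAL = Context()


class KnowledgeBase:
    """An ordered, id-indexed collection of EVFs."""

    def __init__(self, evfs: Iterable[EVF] = ()):
        self.evfs: list[EVF] = []
        self._by_id: dict[str, EVF] = {}
        self._by_rule: dict[Conditional, list[EVF]] = {}
        for evf in evfs:
            self.add(evf)

    def add(self, evf: EVF) -> None:
        if evf.id in self._by_id:
            raise KBError(f"duplicate EVF id {evf.id!r}")
        if evf.rule in self._by_rule:
            warnings.warn(
                f"EVF {evf.id!r} duplicates the rule of "
                f"{self._by_rule[evf.rule][0].id!r}: {format_formula(evf.rule)}",
                stacklevel=2,
            )
        self.evfs.append(evf)
        self._by_id[evf.id] = evf
        self._by_rule.setdefault(evf.rule, []).append(evf)

    def __len__(self) -> int:
        return len(self.evfs)

    def __iter__(self) -> Iterator[EVF]:
        return iter(self.evfs)

    def __contains__(self, evf_id: str) -> bool:
        return evf_id in self._by_id

    def get(self, evf_id: str) -> Optional[EVF]:
        return self._by_id.get(evf_id)

    def __getitem__(self, evf_id: str) -> EVF:
        return self._by_id[evf_id]

    def has_rule(self, rule: Conditional) -> bool:
        return rule in self._by_rule

    def atoms(self) -> list:
        """All atoms mentioned anywhere in the KB, in canonical order."""
        from .formula import atom_leaves, sort_key

        seen = set()
        for evf in self.evfs:
            for side in (evf.rule.antecedent, evf.rule.consequent):
                seen.update(atom_leaves(side).distinct())
        return sorted(seen, key=sort_key)

    def without(self, *evf_ids: str) -> "KnowledgeBase":
        """A copy lacking the given EVFs (for ablation experiments)."""
        return KnowledgeBase(e for e in self.evfs if e.id not in evf_ids)

    def extended(self, *evfs: EVF) -> "KnowledgeBase":
        """A copy with extra EVFs appended (preserving order)."""
        return KnowledgeBase(list(self.evfs) + list(evfs))

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "id": e.id,
                    "rule": format_formula(e.rule),
                    "interaction_class": e.interaction_class,
                    "compartment": e.compartment,
                    "citation": e.citation,
                }
                for e in self.evfs
            ],
            indent=2,
        )

    def to_tsv(self) -> str:
        lines = ["# id\trule\tinteraction_class\tcompartment\tcitation"]
        for e in self.evfs:
            lines.append(
                "\t".join(
                    [
                        e.id,
                        format_formula(e.rule),
                        e.interaction_class or "",
                        e.compartment or "",
                        e.citation,
                    ]
                ).rstrip("\t")
            )
        return "\n".join(lines) + "\n"


def _evf_from_fields(
    fields: list[str], where: str
) -> EVF:
    if len(fields) < 2:
        raise KBError(f"{where}: expected at least columns id<TAB>rule")
    id_, rule_text = fields[0].strip(), fields[1].strip()
    try:
        rule = parse_formula(rule_text)
    except ValueError as exc:
        raise KBError(f"{where}: {exc}") from None
    if not isinstance(rule, Conditional):
        raise KBError(f"{where}: EVF {id_!r} is not a conditional: {rule_text}")
    opt = [f.strip() for f in fields[2:5]] + ["", "", ""]
    try:
        return EVF(
            id=id_,
            rule=rule,
            interaction_class=opt[0] or None,
            compartment=opt[1] or None,
            citation=opt[2],
        )
    except KBError as exc:
        raise KBError(f"{where}: {exc}") from None


def loads_kb(text: str, name: str = "<string>") -> KnowledgeBase:
    """Parse the `.kb` TSV dialect from a string."""
    kb = KnowledgeBase()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        where = f"{name}:{lineno}"
        evf = _evf_from_fields(line.split("\t"), where)
        try:
            kb.add(evf)
        except KBError as exc:
            raise KBError(f"{where}: {exc}") from None
    return kb


def load_kb(path: Union[str, Path]) -> KnowledgeBase:
    """Load a knowledge base from a ``.kb`` TSV file or a ``.json`` file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix == ".json":
        kb = KnowledgeBase()
        for i, obj in enumerate(json.loads(text)):
            where = f"{path}[{i}]"
            evf = _evf_from_fields(
                [
                    obj.get("id", ""),
                    obj.get("rule", ""),
                    obj.get("interaction_class") or "",
                    obj.get("compartment") or "",
                    obj.get("citation") or "",
                ],
                where,
            )
            kb.add(evf)
        return kb
    return loads_kb(text, name=str(path))


def applicable_evfs(
    kb: KnowledgeBase,
    state: Multiset,
    ctx: Context = _UNIVERSAL,
) -> list[tuple[EVF, Multiset]]:
    """All EVFs that can fire on ``state`` under ``ctx``, with remainders.

    An EVF can fire when its antecedent bag is a sub-multiset of the state
    (count-wise, so stoichiometry is respected) and its tags are compatible
    with the context.  The remainder is the state minus the antecedent.
    Results follow KB order.
    """
    out: list[tuple[EVF, Multiset]] = []
    for evf in kb.evfs:
        if not ctx.admits(evf):
            continue
        ante = evf.antecedent_bag
        if ante <= state:
            out.append((evf, state - ante))
    return out
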