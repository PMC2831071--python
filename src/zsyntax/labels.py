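"""Labeled formulas and label propagation through modus ponens.

A labeled formula ``A : α`` carries, next to the logical content ``A``, an
opaque record ``α`` of empirical quantities — a stoichiometric fraction, a
confidence grade, a concentration snapshot.  Labels never change the
logical structure: stripping them from a labeled derivation leaves a valid
plain derivation.  What they add is a *propagation* semantics: when modus
ponens fires a rule ``(A -> B) : α`` on a minor premise ``A : β``, the
conclusion ``B`` receives ``combine(α, β)`` for a user-chosen label
algebra.

One algebra ships built in: :data:`FRACTION`, whose labels are fractions in
[0, 1] combined by multiplication — the label of a chain of reaction steps
is the product of the per-step fractions, modeling compounding reaction
stoichiometry/yield.  Other propagation semantics (equilibrium binding with
concentration and time parameters, evidence grading, ...) are supplied as
user algebras; conjunction introduction/elimination copy labels unchanged,
a documented convention rather than a law of the calculus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable

from .formula import Conditional, Formula, format_formula

__all__ = ["LabeledFormula", "LabelAlgebra", "labeled_arrow_e", "FRACTION"]


@dataclass(frozen=True)
class LabeledFormula:
    formula: Formula
    label: Any

    def __str__(self) -> str:
        return f"{format_formula(self.formula)} : {self.label}"


@dataclass(frozen=True)
class LabelAlgebra:
    """A label domain with a total combine operation and its identity.

    ``contains`` is an optional domain membership check; labels outside the
    domain are rejected before propagation.
    """

    name: str
    combine: Callable[[Any, Any], Any]
    identity: Any
    contains: Callable[[Any], bool] = lambda label: True

    def check(self, label: Any) -> None:
        if not self.contains(label):
            raise ValueError(f"label {label!r} is outside the {self.name!r} algebra")


FRACTION = LabelAlgebra(
    name="fraction",
    combine=lambda a, b: a * b,
    identity=1.0,
    contains=lambda label: isinstance(label, (int, float)) and 0.0 <= label <= 1.0,
)
"""Stoichiometric-fraction labels in [0, 1], combined multiplicatively."""


def labeled_arrow_e(
    cond: LabeledFormula, minor: LabeledFormula, algebra: LabelAlgebra
) -> LabeledFormula:
    """Labeled modus ponens.

    The unlabeled step is exactly plain conditional elimination — the minor
    premise must match the conditional's antecedent and the result is its
    consequent — while the labels are combined by the algebra.  The logical
    backbone is thus kept separate from the empirical labeling module.
    """
    if not isinstance(cond.formula, Conditional):
        raise ValueError(
            f"major premise is not a conditional: {format_formula(cond.formula)}"
        )
    if minor.formula != cond.formula.antecedent:
        raise ValueError(
            f"minor premise {format_formula(minor.formula)} does not match the "
            f"antecedent {format_formula(cond.formula.antecedent)}"
        )
    algebra.check(cond.label)
    algebra.check(minor.label)
    return LabeledFormula(
        formula=cond.formula.consequent,
        label=algebra.combine(cond.label, minor.label),
    )
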