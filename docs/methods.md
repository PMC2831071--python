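# Methods

## The calculus and its assumptions

The engine implements a substructural (resource-aware) natural-deduction
calculus over three operators: a non-associative interaction `*`, a
multiset-forming conjunction `&`, and a conditional `->`.  The semantic
commitments, and where they come from, are:

* **Aggregates are multisets.** `&` is associative and commutative but not
  idempotent; `A & A` is two molecules.  Conjunctions are therefore stored
  flattened as bags with counts, and equality of conjunctions is multiset
  equality.  Conjunct order never carries information.
* **Complexes are trees.** `*` is non-associative — `(A*B)*C` and
  `A*(B*C)` are different species — and, by default, non-commutative:
  `A*B ≠ B*A`.  Whether operand order denotes the same physical complex is
  genuinely open; we keep the distinction because worked pathway material
  writes complexes in fixed conventional order, and a canonicalization pass
  would silently merge species a curator meant to keep apart.  Interaction
  operands are single molecule types or complexes, never aggregates or
  conditionals.
* **Reactions are axioms.** EVFs (empirically valid formulas) are
  conditionals whose antecedent and consequent are conditional-free.  No
  chemistry is checked: an EVF such as `(Glc*HK)*ATP -> G6P & HK & ADP` is
  an opaque empirical fact; atom balance is not enforced.
* **Linearity.** Each derivation line may be consumed at most once.
  Consumers are conjunction-introduction operands and the two operands of
  modus ponens.  Conjunction *elimination* is the one multi-citation
  exception: a line may source several extractions as long as the union of
  extracted bags stays within its own bag — partial decomposition is legal.
  A line already consumed cannot also source extractions.  EVF lines are
  resources too: applying a reaction twice requires introducing its rule on
  two lines (the feed-forward fixture does exactly this).  Unused lines —
  leftover products such as released enzymes or ADP — are permitted.
* **Discharge.** Conditional introduction may discharge any premise (IA)
  line over a stated span, producing `premise -> last-line` and removing
  the premise from the extracted theorem.  All packaged examples discharge
  the single IA line at the end; the checker implements the general form.

## Proof checking

`check_derivation` verifies each line's justification locally (references
strictly backward, formula shapes as above) and the linearity bookkeeping
globally, then extracts the theorem: undischarged premises ⊢ final
formula.  Violations carry machine-readable codes (`BAD_REF`,
`EVF_NOT_IN_KB`, `LINEARITY`, `BAD_EXTRACTION`, `BAD_COMBINE`,
`BAD_MODUS_PONENS`, `BAD_DISCHARGE`) and the offending line, so a corrupted
proof fails at the corruption, not with a generic rejection.

## Proof search

`prove` compiles the logical rules away: a search state is the bag of
available conditional-free formulas, and the only transition is EVF
application (antecedent bag out, consequent bag in).  This is faithful
because the logical rules are content-independent bookkeeping — `&E`/`&I`
regroup bags, `->E` is exactly EVF firing — and conditionals occur in
pathway derivations only as EVF lines, plus the optional final discharge.
The goal test is bag containment, so leftover products are allowed; a
`consume_all` switch changes it to bag equality for full-consumption
questions.

Search is breadth-first by default (guaranteeing a minimal number of EVF
applications), with depth-first available.  Determinism is absolute: EVFs
are tried in knowledge-base file order, states expanded in insertion
order, and visited states are memoized under a canonical encoding (sorted
rendered-formula/count pairs).  There is no randomness anywhere in the
engine.  Bounds — `max_states` (default 10^6) and `max_depth` (default
64) — separate an honest `not_proved` (exhaustive closure completed) from
`bound_exceeded` (truncated search); validity checks propagate the latter
as indeterminate rather than false.  Combinatorial explosion is handled
only by memoization and these bounds; no macrostate abstraction is
attempted.

On success the EVF application sequence is replayed into a detailed
derivation: premise line, full conjunction-elimination explosion, then per
reaction an EVF line, conjunction introductions assembling the antecedent,
modus ponens, and explosion of the consequent; goal elements are placed (or
reassembled) last so the final line is the goal.  Every reconstructed
derivation passes the checker — a property exercised on all packaged
pathways and on seeded random fixtures.

## Knowledge bases and context

`.kb` files are tab-separated (`id, rule, interaction_class, compartment,
citation`).  The two tag columns contextualize a rule: the interaction
class records the kind of evidence behind a binding claim (in vitro
binding, two-hybrid, co-IP, FRET, ...) and the compartment localizes the
reaction.  Matching is deliberately minimal — an untagged EVF applies
everywhere; a tagged EVF requires the corresponding context field to be
unset or to match exactly — because nothing firmer than "an index running
over classes" is established for these tags; a reliability partial order
over interaction classes is noted as future work, not guessed at.
Duplicate rule texts under distinct ids are allowed (with a warning): they
support holding the same reaction at different evidence grades.

## Abduction

* **Missing resources** (`abduce_resources`): iterative deepening over
  addition bags drawn from a vocabulary (default: all KB atoms), cardinality
  1 to `max_additions`.  Returned bags are minimal — none contains another —
  and each carries the proof found with the additions present.  The
  enumeration is exhaustive within the bound, so the trivially sufficient
  "add the goal itself" hypothesis appears alongside informative ones;
  ranking is left to the user.
* **Missing reactions** (`abduce_evfs`): candidate rules keep the two
  canonical shapes, binding `X & Y -> X*Y` and transformation
  `X*Y -> C (& D)`, which keeps the space finite.  Binding operands range
  over formulas reachable forward from the initial aggregate, filtered to
  complexes the goal plausibly needs (a backward relevance closure over
  consequent/antecedent bags); transformation consequents are drawn from
  that backward-relevant set plus the complex's own components.  Each
  surviving candidate is verified by an actual proof with the rule added.
* **Candidate endpoints** (`enumerate_goals`): from the bag left after
  forming an anchoring complex, 0 to `max_events` hypothetical pairwise
  join events are applied; each event joins two bag members into an
  interaction, in both operand orders, since order is part of the species.
  Every resulting bag is a candidate conclusion with the full initial
  aggregate as premises.  Full consumption is the chosen semantics here
  (each initial molecule used exactly once, none invented) — the question
  these candidates answer is precisely "what if *everything* in the
  aggregate plays a role?" — and `validate_candidate` checks it by
  atom-leaf multiset equality.  The prover's default remains
  leftovers-allowed; the two conventions serve different questions.

Pruning is a plugin interface (a list of predicates on candidates) because
the biological knowledge that eliminates implausible endpoints is not
formalizable in the calculus.  The single built-in pruner drops candidates
whose every join event is already a known binding rule in the KB — those
are deductions dressed as hypotheses — while always keeping the zero-event
baseline (the "anchor plays no further role" case).  The built-in pruner is
approximate by design: it does not attempt to reproduce any hand-curated
shortlist exactly, only to guarantee that curated candidate sets appear
within its output.

## Labels

Labeled formulas `A : α` attach empirical records to lines.  Only modus
ponens propagates labels, through a pluggable algebra (combine function +
identity + domain check); conjunction introduction/elimination copy labels
unchanged — a documented convention, since no propagation law exists for
partial extraction.  One algebra ships built in: fractions in [0, 1] under
multiplication, modeling compounding stoichiometric yield along a chain.
An equilibrium-binding algebra (concentration/time parameters) is
deliberately not built in: its propagation function is empirical and must
come from the user.  Labels never affect checking; erasure yields the
plain derivation.

## Synthetic pathway generator

`random_pathway` emulates the anatomy of the worked examples: chains of
enzyme catalysis (substrate binds enzyme; the complex transforms into the
next substrate, releasing the enzyme), an optional step that consumes two
copies of a cofactor (so single-copy aggregates are unreachable — the
stoichiometry regime), and decoy binding rules among distractor species
that lead nowhere (the branching regime).  It can delete one needed
resource or one chain rule and record it as the planted answer.  Generation
is a pure function of seed and parameters.

What the generator does *not* emulate: reversible reactions, competing
productive branches, kinetic rates, and complexes deeper than the chain
pattern produces.  Passing tests on these fixtures therefore demonstrate
correctness of the search and abduction machinery on acyclic
catalysis-like rule systems, not performance or discovery power on
realistic genome-scale networks.

## Numerical and testing choices

There are no floating-point computations in the engine (labels excepted);
all comparisons are exact structural equality, so no tolerances arise.
Canonical print order (formula depth, then lexicographic text) makes every
output byte-deterministic and diff-friendly.

Oracle testing compares `prove` against `brute_force_reachable`, an
independent exhaustive closure with its own naive state encoding, across
500 seeded fixtures spanning four pathway shapes (plain chains, stoichiometric
chains with decoys, deleted-resource and deleted-rule variants), with small
vocabularies (≤ 8 decoy atoms, chains of length ≤ 4) chosen so each closure
stays well under 10^5 states; the whole sweep runs in under a second.
Abduction recovery is verified on bounded fixtures (chain length 3,
single deletions), where the planted item must always be among the
returned hypotheses.  Property tests (round-trip parsing, structural laws
of derivability) use derandomized hypothesis strategies.

## Known limitations

* Forward search is exponential in the worst case; no macrostate or
  symmetry reduction is implemented beyond state memoization.
* Tag matching is exact; no evidence-reliability hierarchy.
* `abduce_evfs` cannot hypothesize rules outside the two canonical shapes
  (e.g. three-reactant transformations), and pair-search over rules is a
  first-found heuristic rather than an exhaustive minimal-set enumeration.
* The calculus is atemporal: no kinetics, no ODE coupling, no equilibrium
  parameters.  These belong to a different representational layer than the
  inferential backbone formalized here.
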