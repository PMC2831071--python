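# zsyntax

A resource-aware logical calculus for molecular biology, implemented as a
deduction engine.  Biochemical pathways are treated as *proofs*: the
reactants form a multiset of premises (the initial aggregate), each
laboratory-established reaction is a non-logical axiom (an *empirically
valid formula*, EVF), and a small set of resource-sensitive inference rules
carries the aggregate from reactants to products.  The package is for
systems biologists and computational logicians who want to check pathway
derivations mechanically, decide reachability questions with exact
stoichiometry, and generate testable hypotheses when a deduction fails.

## The calculus

Formulas are built from opaque molecular species names with three operators:

| operator | reading | algebraic behavior |
|---|---|---|
| `A*B` | the complex formed when A and B interact | binary, **non-associative**: `(A*B)*C ≠ A*(B*C)` |
| `A & B` | an aggregate (bag) of molecules | associative, commutative, **non-idempotent**: `A & A ≠ A` |
| `A -> B` | an aggregate enabling the path from A to B | lowest precedence |

Because `&` is non-idempotent, an aggregate is a **multiset** and counts
carry stoichiometry: a reaction needing two ATP will not fire on one.  A
pathway claim is a sequent Γ ⊢ B — conclusion B is derivable from the
aggregate Γ using EVFs plus four logical rules (conjunction
introduction/elimination, conditional introduction/elimination), under the
**linearity restriction**: any formula occurring on a derivation line may
be consumed at most once.  Resources are spent, not copied; enzymes persist
only because the EVFs that invoke them return them among the products.  A
conditional `A -> B` is *valid* when it is derivable from the empty
aggregate, i.e. when A ⊢ B.

There are no logical rules for `*`: complexes are formed and dissolved only
through EVFs of the shapes `A & B -> A*B` (binding) and
`A*B -> C & D` (transformation/release), plus general transformations —
their validity is an empirical matter, not a formal one.

### Concrete syntax

```ebnf
formula  = conj [ ("->" | "→") conj ] ;    (* "->" is non-associative *)
conj     = inter { "&" inter } ;
inter    = primary [ "*" primary ] ;       (* "A*B*C" must be parenthesized *)
primary  = ATOM | "(" formula ")" ;
ATOM     = CHARS [ "(" CHARS ")" ] ;       (* marker atoms like d(TP53) *)
CHARS    = { A-Z | a-z | 0-9 | "_" | "," | "." | "'" | "-" }+ ;
```

Species disambiguation lives entirely in atom names: `TP53`, its
phosphorylated form `TP53-P`, and the gene `MDM2_gene` are distinct atoms,
which is how post-translational modifications, gene-vs-protein distinctions
and allosteric states are expressed.

## Worked example

The TP53 degradation pathway: MDM2 binds the tumor suppressor TP53 and,
acting as a ubiquitin ligase, hands it to the proteasome (U = ubiquitin,
P = proteasome, `d(TP53)` = the degradation event).  The packaged knowledge
base `tp53_degradation.kb` holds the five reactions; the prover finds the
proof of `TP53 & MDM2 & U & P ⊢ d(TP53)`:

```sh
$ zsyntax prove --kb src/zsyntax/data/tp53_degradation.kb \
    --ia "TP53 & MDM2 & U & P" --goal "d(TP53)" --simple
1. MDM2 & TP53 -> MDM2*TP53
2. U & MDM2*TP53 -> (MDM2*TP53)*U
3. (MDM2*TP53)*U -> MDM2 & TP53*U
4. P & TP53*U -> (TP53*U)*P
5. (TP53*U)*P -> P & U & d(TP53)
```

Five EVF applications, in order — the "demonstration" view.  With
`--detail` the full 23-line natural-deduction derivation is printed, each
line justified (`IA`, `EVF`, `From 2,4 by &I`, `From 7,6 by ->E`, ...), and
the same object can be re-checked independently:

```sh
$ zsyntax prove --kb src/zsyntax/data/tp53_degradation.kb \
    --ia "TP53 & MDM2 & U & P" --goal "d(TP53)" --out proof.zdx --simple
$ zsyntax check --kb src/zsyntax/data/tp53_degradation.kb proof.zdx
valid, 23 lines
theorem: MDM2 & P & TP53 & U |- d(TP53)
```

Stoichiometry is respected exactly: glycolysis from D-glucose to
fructose-1,6-bisphosphate consumes two ATP, so

```sh
$ zsyntax prove --kb src/zsyntax/data/glycolysis.kb \
    --ia "Glc & HK & GPI & PFK & ATP" --goal "F1,6P"
not proved
```

exits with status 1, while the same command with `ATP & ATP` proves the
goal in eight reaction steps.

When deduction fails, `zsyntax abduce` proposes the missing resources
(here, the second ATP) or missing reaction rules, and
`zsyntax hypothesize` enumerates candidate endpoint theorems around an
anchoring complex — e.g. the eight hypothetical regulatory-loop endpoints
for NUMB/TP53/MDM2 obtained with

```sh
$ zsyntax hypothesize --kb src/zsyntax/data/numb.kb \
    --ia "TP53 & MDM2 & NUMB & U & P" --anchor "MDM2*NUMB" --max-events 2
```

Library use mirrors the CLI: `parse_formula`, `load_kb`, `prove`,
`check_derivation`, `abduce_resources`, `enumerate_goals`, etc.; see the
module docstrings.

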