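# Methods

## Molecular graphs

Structures are parsed with RDKit (SMILES or MDL Molfile), then converted to a
plain labeled graph: atoms carry element and formal charge, bonds carry order
1, 2, 3 or aromatic.  Hydrogens are explicit nodes — rule element balance must
include them, and hydrogen movement is part of most reaction centers.
Aromatic bonds are kept as a distinct order rather than kekulized, so
resonance-equivalent atoms receive equal labels; one fixed perception model
(RDKit's default) is used throughout.  Protonation states are taken verbatim
from the input — the formation energies consumed downstream already embed
pH 7.0, so no re-protonation is attempted.  Disconnected records (salts) are
accepted; signatures are additive over components.

## Canonical labeling and moiety size

The base invariant of an atom is (element, formal charge, sorted incident
bond orders).  Each refinement round replaces an atom's key by (own prime,
sorted multiset of (bond order, neighbor prime)); every distinct key is mapped
to a fresh prime by a session-global registry, drawn in increasing order after
lexicographic sorting of the unseen keys, so labeling is deterministic and
isomorphism-invariant.  Sorted-tuple keys give the same order-independence a
product of primes would, without multiplicity collisions (one neighbor at
bond order 2 and two equal neighbors at order 1 must not merge).

A *size-λ moiety* is the radius λ−1 ball around the center with typed
boundary atoms, i.e. 2λ−1 refinement rounds.  The extra typing matters: with
plain radius-(λ−1) balls, two reactions that exchange the same group but
differ one shell further out produce identical change vectors one λ later
than they should.  With this definition the bundled decarboxylase pair
behaves canonically: one shared rule at λ=1, two distinct rules at λ=2.
Supported sizes are λ ∈ {1, 2, 3}; stereochemistry is outside the label (no
stereo-descriptors, no tautomer handling).

The registry serializes with outputs (`registry.json`), keeping primes — and
hence signatures and rule vectors — comparable across runs.  λ values are
never mixed within one rule set or one design run.

## Rules

`derive_rule` computes T^λ_m = Σ_i S_ij C^λ_mi exactly (integer arithmetic),
drops zeros, and rejects any reaction whose rule is not elementally balanced —
an unbalanced reaction would poison every design that invokes its rule.
Balance is audited from the rule vector itself: each moiety carries its center
element, and each atom is the center of exactly one moiety, so per-element
sums of (change × center element) must vanish.  Deduplication groups
identical change maps; rule ids `R1..Rn` follow the sorted order of the
change maps, making extraction independent of database order.  Transport
reactions are skipped; per-reaction failures are collected and reported
without aborting the run.  Every rule is reversible by default; a design run
may pin or disable directions per step.

## The design MILP

Variables (all integer): split fluxes p_s, n_s ≥ 0 with direction binaries
d⁺_s, d⁻_s for every known reaction and rule step (v_s = p_s − n_s, at most
one direction active, d ≤ flux ≤ M·d in both directions so an active
indicator implies a nonzero flux); imbalance fluxes v^imb_i for database
metabolites; exchange fluxes v^EX_i for the declared exchange set (all other
metabolites are sealed).

Constraint families:

1. **Component balance** — v^imb_i = Σ_j S_ij v_j: the known network's net
   production of each metabolite, handed to the rule layer.
2. **Moiety balance** — Σ_{I_ex} C^λ v^EX = Σ_R T^λ v_r + Σ_I C^λ v^imb for
   every moiety observed in the signatures or rules.
3. **Rule-layer activity linkage** — ρ_i = v^EX_i − v^imb_i is forced to zero
   unless at least one rule step is active (big-M on Σ_r(d⁺_r + d⁻_r)).
   Without this family, coarse moiety vectors (λ=1 especially) admit
   degenerate designs in which the *idle* rule network converts metabolites
   whose moiety sums coincide — e.g. running a decarboxylase twice against a
   phantom supply of its substrate.  With it, a rule-free design collapses to
   v^EX = v^imb, the ordinary known-network pathway balance.
4. **Thermodynamics** — Σ Δ_f G'°_i v^EX_i ≤ −ε over exchange fluxes
   (kcal/mol at pH 7.0, ionic strength 0.1 M).  ε defaults to 0.5 kcal.  The
   row can be disabled to inspect infeasible-but-instructive designs; the
   validator then still reports the (positive) ΔG.
5. **Design criteria** — exchange bounds and bans, Σ rule indicators ≤
   max_rules, Σ all indicators ≤ max_steps, organism/pathway selection
   (a step is usable only if annotated to a selected label; rules inherit the
   union of their member reactions' annotations), per-step direction pins.

Objectives: `min_total_steps` (Σ indicators), `min_rules` (Σ rule
indicators), `max_profit` (Σ price_i · v^EX_i, requiring finite exchange
bounds).  A step used at flux 2 counts one indicator — one enzyme to engineer;
flux-weighted counts can be read off the solution directly.

Solved with HiGHS through `scipy.optimize.milp`.  Alternatives are enumerated
by re-solving after adding an integer cut that excludes the exact active
(step, direction) pattern — supersets and the same steps in other directions
remain discoverable, which is what makes the two-decarboxylase enumeration
yield its four designs.  Returned solutions are sorted by (objective, sorted
active-step list) so ties are reproducible across solvers.  Every solution is
re-validated from scratch in exact integer arithmetic (component rows, moiety
rows, ΔG, counts, element balance of the net conversion); the validator is
shared with no solver code.

Default big-M / flux bound is 10 mol per mol of conversion (configurable; the
bundled studies use 2, which keeps enumeration exhaustive and fast).
v^imb bounds are derived from the stoichiometry (flux bound × Σ_j |S_ij|).

## Exhaustive reference enumeration

On small networks the whole design space is enumerated directly: every
integer step-flux vector within bounds, v^imb by stoichiometric summation,
v^EX by solving the moiety system exactly (the exchange signature matrix must
have full column rank, which generation guarantees; rank deficiency raises
rather than silently under-enumerating), then bounds, caps, annotations,
ρ-linkage and thermodynamics as plain arithmetic filters.  This enumerator
shares no code with the MILP and serves as ground truth: the test suite and
the acceptance script assert exact agreement of feasible design sets and
min-step optima on 50 seeded networks (3–9 steps, |flux| ≤ 2; the largest
instances enumerate ~2·10⁶ vectors).

## Fixtures

The toy system is the smallest complete exercise: 2-hydroxyisophthalate and
salicylate decarboxylase over 2hipa/sal/CO2/phenol, drawn as neutral acids
(a mono-anion variant exercises charge-sensitive labeling).  Its design run
converts one source to one target with CO2 free and at most two active steps
— the configuration under which enumeration returns exactly the four
documented designs.  Formation energies are synthetic but ordered so both
decarboxylations are exergonic (≈ −52 kcal/mol each); the reverse
carboxylation (+52 kcal) is the bundled positive-ΔG cautionary case.

Planted networks emulate the combinatorics of a real database at a size where
exhaustive search is possible: a scaffold (benzene, pyridine, furan,
thiophene, cyclohexane, cyclopentane) carrying k carboxyls is decarboxylated
k times to the bare scaffold; decoys are the same chemistry on other
scaffolds, so they can never shorten the route — certified at generation by
breadth-first search over the conversion graph, with every reaction audited
for element balance.  Generation is seed-deterministic byte-for-byte.  What
these fixtures do *not* emulate: cofactor pairs, multi-substrate reactions,
heteroatom-rich chemistry, thermodynamic noise — so passing tests certify the
algebra and the optimizer, not coverage of real-database curation issues.
Route certification is done with rules disabled: at λ=1 all decarboxylations
collapse to one rule, and a single rule step at flux k legitimately shortcuts
any k-step route (that is a feature of rule-based design, not an error).

## Rule instantiation

`match_sites` locates candidate reaction centers: the rule's base-type
projection (sums of changes grouped by the centers' element/charge/bond-order
type) says how many atoms of each type genuinely change bonding; consumed
λ-level moieties beyond that are ripple relabelings and are not matched.
Center selections must be connected within each substrate.  `apply_rule` then
searches bond-order edits over the center and its neighbors (never touching
aromatic bonds), requiring each atom's total incident bond order to be
conserved (closed-shell chemistry: hydrogens move, radicals never form),
sanitizing survivors with RDKit, and accepting only candidates whose
recomputed signature difference equals the rule exactly.  If no edit within
the budget (4 by default) succeeds, single partner atoms from co-substrates
are adjoined to the search and the application is flagged unrealizable when
the search still fails.  At λ=3 the residual check pins the product
essentially uniquely; at λ=1 all residual-zero candidates are returned ranked
by edit count.  Ring-forming/breaking chemistry through aromatic systems is a
known limitation of the edit vocabulary.  Pathway design never depends on
this module; it is post-processing.

## Numerical choices and degenerate inputs

Coefficients are normalized to smallest integers at load time (rationals
accepted).  Solver outputs are rounded to integers and then re-verified
exactly — a solution is never reported on solver arithmetic alone.  An
identity reaction yields an empty change map; an empty database is a valid
(infeasible-design) input; a design whose source equals its target admits the
empty pathway, flagged "empty design".  Missing formation energies are
errors, never assumed zero.  Time-limited enumeration returns the partial
list and marks the status on the model.

## Scope

Database curation and atom-mapping reconciliation, stereo-descriptors,
computation of formation energies (component-contribution/eQuilibrator are
upstream), flux-balance yield analysis, host selection, and ranking by enzyme
performance/toxicity/orthogonality are all out of scope.  Problem sizes in
the bundled tests (≤ 9 steps, |flux| ≤ 2, 50 networks) were chosen so the
exhaustive oracle remains exact; the MILP itself has no such structural
limits.
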