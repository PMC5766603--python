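# moietypath

Retrosynthetic pathway design for metabolic engineering: prime-encoded moiety
signatures, elementally balanced reaction rules, and a mixed-integer linear
program that designs mass-, moiety- and energy-balanced bioconversion routes
blending cataloged enzymatic reactions with de novo rule steps.

## The problem

Engineering a microbe to make (or degrade) a target molecule means finding a
route from a source metabolite through a sequence of enzymatic steps.  Known
reactions alone often cannot close the route; enzymes with promiscuous or
engineered activity can fill the gaps, but each novel step must still conserve
every atom, balance its cofactors, and keep the overall conversion
thermodynamically downhill.  This package is for computational biologists and
metabolic engineers who want those guarantees imposed *during* the search, not
checked afterwards.

## The method

**Signatures.** Every atom of every metabolite (cofactors included) is labeled
by a prime number encoding its size-λ moiety — the atom environment of radius
λ−1, for λ ∈ {1, 2, 3}.  A metabolite *i* becomes a sparse nonnegative vector
C^λ_mi counting its moieties *m*.  Identical environments receive the same
prime across all molecules, so the vectors are directly comparable.

**Rules.** A reaction *j* with stoichiometry S_ij induces the moiety-change
vector

    T^λ_mj = Σ_i S_ij · C^λ_mi

which captures exactly what happens at the reaction center (everything far
from it cancels).  Rules from elementally balanced reactions are themselves
elementally balanced; deduplicating identical change vectors yields the unique
rule set R^λ.  Two different decarboxylases collapse to one rule at λ=1 and
separate again at λ=2 — specificity is tunable.

**Design.** The MILP selects integer fluxes v_j (known reactions), v_r
(rules), exchange fluxes v^EX_i, and the linkage fluxes
v^imb_i = Σ_j S_ij v_j that hand metabolites between the known network and the
rule network, subject to

    Σ_{i∈I_ex} C^λ_mi v^EX_i = Σ_{r∈R^λ} T^λ_mr v_r + Σ_{i∈I} C^λ_mi v^imb_i   (moiety balance, every m)
    Σ_i Δ_f G'°_i v^EX_i ≤ −ε                                                  (thermodynamic feasibility)

plus step/rule caps, exchange bounds and bans, organism/pathway selection, and
direction pins.  Objectives: fewest total steps, fewest rule steps, or maximum
profit margin.  Alternative designs are enumerated with integer cuts over the
active (step, direction) pattern, and every solution is re-validated with
exact integer arithmetic independent of the solver (HiGHS, via SciPy).

**Instantiation.**  A designed rule step can be turned back into candidate
product structures: a bounded bond-edit search around the matched reaction
center, accepting only valence-legal candidates whose recomputed signature
difference equals the rule exactly.

## Worked example

The bundled two-reaction system — 2-hydroxyisophthalate decarboxylase (2HIPD)
and salicylate decarboxylase (SLD) over the metabolites 2hipa, sal, CO2 and
phenol — exercises the whole stack:

```bash
python examples/02_design_toy_pathways.py
```

```
4 designs from 2hipa to phnl

design 1: steps=1 rules=1 ΔG'°=-104.5 kcal  valid=True
  [rule ] R1           v = +2   (novel step from moiety-change template)
  net: 2hipa -> 2 co2 + phnl   (ΔG'° = -104.5 kcal)

design 2: steps=2 rules=1 ΔG'°=-104.5 kcal  valid=True
  [known] 2HIPD        v = +1   2hipa -> co2 + sal
  [rule ] R1           v = +1   (novel step from moiety-change template)
  net: 2hipa -> 2 co2 + phnl   (ΔG'° = -104.5 kcal)

design 3: steps=2 rules=0 ΔG'°=-104.5 kcal  valid=True
  [known] 2HIPD        v = +1   2hipa -> co2 + sal
  [known] SLD          v = +1   sal -> co2 + phnl
  net: 2hipa -> 2 co2 + phnl   (ΔG'° = -104.5 kcal)

design 4: steps=2 rules=1 ΔG'°=-104.5 kcal  valid=True
  [rule ] R1           v = +1   (novel step from moiety-change template)
  [known] SLD          v = +1   sal -> co2 + phnl
  net: 2hipa -> 2 co2 + phnl   (ΔG'° = -104.5 kcal)
```

All four designs realize the same net conversion (one 2hipa to one phenol plus
two CO2, 104.5 kcal downhill): the purely known two-step pathway (design 3),
two hybrids that replace one enzyme with the generic decarboxylation rule
(designs 2 and 4), and a single-rule design that applies the rule twice —
one enzyme candidate, counted as one novel step (design 1).  In design 2 the
imbalance fluxes are v^imb_2hipa = −1 (the source is handed to the known
network) and v^imb_sal = +1 (salicylate handed back to the rule network).

The other examples show signature/rule extraction (`01`), certification of the
MILP against exhaustive enumeration on randomized planted-route networks
(`03`), and structure-level rule instantiation, including the reverse
carboxylation of phenol + CO2 that recovers salicylate (`04`).

A thin CLI mirrors the library for file-based workflows:

```bash
moietypath extract-rules --db reactions.tsv --structures mols.smi --lam 1 --lam 2 --out rules/
moietypath design --db reactions.tsv --structures mols.smi --thermo dg.tsv \
    --lam 1 --source 2hipa --target phnl --config design.yaml --out out/
```

Exit codes: 0 solutions found, 3 infeasible, 4 input error.

## Layout

- `src/moietypath/chemgraph.py` — molecular graphs, SMILES/Molfile I/O (RDKit-backed)
- `src/moietypath/signatures.py` — prime registry, canonical labeling, C^λ vectors
- `src/moietypath/rules.py` — rule derivation T^λ, deduplication, JSON persistence
- `src/moietypath/reactiondb.py` — reaction tables, balance audits, Δ_f G'° tables
- `src/moietypath/design.py` — the design MILP, enumeration, independent validation
- `src/moietypath/ruleapply.py` — rule instantiation on structures
- `src/moietypath/exhaustive.py` — brute-force reference enumeration (ground truth for tests)
- `src/moietypath/fixtures.py` — toy system and planted-route network generator
- `src/moietypath/cli.py` — the `moietypath` command

See `docs/methods.md` for the model's assumptions, parameter choices and
limitations.
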