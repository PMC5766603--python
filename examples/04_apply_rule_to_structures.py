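"""Instantiate the decarboxylation rule on concrete structures.

Pathway design works purely on signatures; this post-processing step proposes
actual product structures for a rule step.  Forward: salicylate loses its
carboxyl as CO2.  Reverse: phenol + CO2 is carboxylated, and among the
candidates (all signature-exact at λ=1) sits salicylate itself — identified
by comparing signatures at λ=3.
"""

import moietypath as mp

db, structures = mp.toy_decarboxylase_db()
registry = mp.PrimeRegistry()
sigs = mp.signature_index(structures, 1, registry)
rules = mp.extract_rules(list(db), sigs, 1)
rule = rules.by_id("R1")
sal = structures["sal"]

centers = mp.match_sites(rule, [sal], registry)
print(f"reaction centers on salicylate: {len(centers)}")
app = mp.apply_rule(rule, [sal], centers[0], registry)
for cand in app.candidates:
    print(f"  forward products: {' + '.join(cand.smiles)}  ({cand.n_edits} bond edits)")

rev = rule.negated()
subs = [structures["phnl"], structures["co2"]]
sal_lam3 = mp.signature(sal, 3, registry)
print("\nreverse (carboxylation of phenol + CO2):")
for center in mp.match_sites(rev, subs, registry):
    for cand in mp.apply_rule(rev, subs, center, registry).candidates:
        mark = ""
        if len(cand.molecules) == 1 and mp.signature(cand.molecules[0], 3, registry) == sal_lam3:
            mark = "   <- λ=3-identical to salicylate"
        print(f"  {' + '.join(cand.smiles)}{mark}")
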