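"""Rule instantiation on concrete structures."""

import moietypath as mp


def test_decarboxylation_centers_on_salicylate(toy):
    rule = toy["rules"][1].by_id("R1")
    centers = mp.match_sites(rule, [toy["structures"]["sal"]], toy["registry"])
    assert len(centers) == 1
    elems = {toy["structures"]["sal"].atoms[idx].element for _, idx in centers[0]}
    assert elems == {"C", "O"}  # the carboxyl carbon and its hydroxyl oxygen


def test_two_symmetric_carboxyls_give_two_centers(toy):
    rule = toy["rules"][1].by_id("R1")
    centers = mp.match_sites(rule, [toy["structures"]["2hipa"]], toy["registry"])
    assert len(centers) == 2


def test_absent_moiety_gives_empty_center_list(toy):
    rule = toy["rules"][1].by_id("R1")
    assert mp.match_sites(rule, [toy["structures"]["phnl"]], toy["registry"]) == []


def test_forward_decarboxylation_yields_phenol_and_co2(toy):
    rule = toy["rules"][1].by_id("R1")
    sal = toy["structures"]["sal"]
    center = mp.match_sites(rule, [sal], toy["registry"])[0]
    app = mp.apply_rule(rule, [sal], center, toy["registry"])
    assert app.realized
    assert sorted(app.candidates[0].smiles) == ["O=C=O", "Oc1ccccc1"]
    assert app.signature_residual == {}


def test_identity_rule_returns_substrates_unchanged(toy):
    ident = mp.ReactionRule(id="I", lam=1, changes={})
    sal = toy["structures"]["sal"]
    centers = mp.match_sites(ident, [sal], toy["registry"])
    app = mp.apply_rule(ident, [sal], centers[0], toy["registry"])
    assert app.candidates[0].smiles == [mp.to_smiles(sal)]
    assert app.candidates[0].n_edits == 0


def test_reverse_rule_recovers_salicylate_signature_at_lambda3(toy):
    reg = toy["registry"]
    rev = toy["rules"][1].by_id("R1").negated()
    subs = [toy["structures"]["phnl"], toy["structures"]["co2"]]
    sal3 = mp.signature(toy["structures"]["sal"], 3, reg)
    hits = []
    for center in mp.match_sites(rev, subs, reg):
        for cand in mp.apply_rule(rev, subs, center, reg).candidates:
            if len(cand.molecules) == 1 and mp.signature(cand.molecules[0], 3, reg) == sal3:
                hits.append(cand)
    assert hits, "ortho carboxylation product must be among the candidates"


def test_round_trip_rule_then_negation_restores_lambda3_signature(toy):
    """Apply the rule, then its negation on the products: some candidate has
    the original substrate's λ=3 signature."""
    reg = toy["registry"]
    rule = toy["rules"][1].by_id("R1")
    sal = toy["structures"]["sal"]
    sal3 = mp.signature(sal, 3, reg)
    center = mp.match_sites(rule, [sal], reg)[0]
    products = mp.apply_rule(rule, [sal], center, reg).candidates[0].molecules
    rev = rule.negated()
    restored = False
    for c in mp.match_sites(rev, products, reg):
        for cand in mp.apply_rule(rev, products, c, reg).candidates:
            if len(cand.molecules) == 1 and mp.signature(cand.molecules[0], 3, reg) == sal3:
                restored = True
    assert restored


def test_lambda3_application_is_near_unique(toy):
    """At λ=3 the environment constraints pin the edit: SLD's own rule on
    salicylate yields exactly phenol + CO2, and the 2HIPD rule does not
    match salicylate at all."""
    reg = toy["registry"]
    rules3 = toy["rules"][3]
    sal = toy["structures"]["sal"]
    sld = rules3.by_id(rules3.reaction_to_rule["SLD"])
    centers = mp.match_sites(sld, [sal], reg)
    assert len(centers) == 1
    app = mp.apply_rule(sld, [sal], centers[0], reg)
    assert [sorted(c.smiles) for c in app.candidates] == [["O=C=O", "Oc1ccccc1"]]
    hipd = rules3.by_id(rules3.reaction_to_rule["2HIPD"])
    assert mp.match_sites(hipd, [sal], reg) == []


def test_products_elementally_balanced_against_substrates(toy):
    rule = toy["rules"][1].by_id("R1")
    for met in ("sal", "2hipa"):
        mol = toy["structures"][met]
        for center in mp.match_sites(rule, [mol], toy["registry"]):
            app = mp.apply_rule(rule, [mol], center, toy["registry"])
            for cand in app.candidates:
                got = {}
                for p in cand.molecules:
                    for e, c in mp.element_counts(p).items():
                        got[e] = got.get(e, 0) + c
                assert got == mp.element_counts(mol)


def test_unrealizable_center_is_flagged(toy):
    # a rule demanding an impossible transformation: negate only the CO2 side
    rule = toy["rules"][1].by_id("R1")
    co2 = toy["structures"]["co2"]
    rev = rule.negated()
    centers = mp.match_sites(rev, [co2], toy["registry"])
    if centers:  # no partner molecule present: nothing to carboxylate
        app = mp.apply_rule(rev, [co2], centers[0], toy["registry"])
        assert not app.realized
        assert app.flag == "unrealizable at this center"
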