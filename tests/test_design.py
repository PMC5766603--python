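"""Pathway-design MILP: balances, enumeration, constraint semantics."""

import pytest

import moietypath as mp
from moietypath.design import ModelBuildError


def test_toy_enumeration_returns_four_distinct_designs(toy_solutions):
    sols = toy_solutions["solutions"]
    patterns = {tuple(s.active_steps()) for s in sols}
    assert len(sols) == 4 and len(patterns) == 4
    assert (("2HIPD", 1), ("SLD", 1)) in patterns  # the all-known pathway
    assert (("R1", 1),) in patterns  # the rule applied twice, one indicator


def test_worked_solution_imbalance_fluxes(toy_solutions):
    """Known 2HIPD plus a rule step for sal → phnl: the source is handed to
    the known network (deficit −1) and salicylate handed back (surplus +1)."""
    sol = next(
        s for s in toy_solutions["solutions"]
        if s.v_known.get("2HIPD") == 1 and s.v_rules.get("R1") == 1
    )
    assert sol.v_imb["2hipa"] == -1
    assert sol.v_imb["sal"] == 1


def test_all_solutions_validate_with_zero_residuals(toy, toy_solutions):
    for sol in toy_solutions["solutions"]:
        report = mp.validate_solution(
            sol, toy["db"], toy["rules"][1], toy["sigs"][1], toy["thermo"],
            toy_solutions["problem"], toy["structures"],
        )
        assert report.ok, report.violations
        assert report.component_residuals == {}
        assert report.moiety_residuals == {}
        assert report.net_element_residuals == {}


def test_net_conversion_of_toy_solution(toy_solutions):
    sol = toy_solutions["solutions"][0]
    conv = mp.net_conversion(sol, "phnl")
    assert conv == {"2hipa": -1, "phnl": 1, "co2": 2}


def test_net_conversion_scale_invariant(toy_solutions):
    sol = toy_solutions["solutions"][0]
    doubled = mp.PathwaySolution(
        v_known={k: 2 * v for k, v in sol.v_known.items()},
        v_rules={k: 2 * v for k, v in sol.v_rules.items()},
        v_imb={k: 2 * v for k, v in sol.v_imb.items()},
        v_ex={k: 2 * v for k, v in sol.v_ex.items()},
        objective_value=sol.objective_value,
        deltaG_overall=None,
        step_count=sol.step_count,
        rule_count=sol.rule_count,
    )
    assert mp.net_conversion(doubled, "phnl") == mp.net_conversion(sol, "phnl")
    with pytest.raises(ValueError):
        mp.net_conversion(sol, "sal")  # zero target flux


def test_max_rules_zero_leaves_only_known_reaction_designs(toy):
    problem = mp.toy_design_problem(max_rules=0)
    model = mp.build_model(problem, toy["db"], toy["rules"][1], toy["sigs"][1], toy["thermo"])
    sols = mp.solve_enumerate(model, k=10)
    assert len(sols) == 1
    assert tuple(sols[0].active_steps()) == (("2HIPD", 1), ("SLD", 1))


def test_empty_rule_set_reduces_to_known_only_search(toy):
    empty = mp.RuleSet(lam=1, rules=[], reaction_to_rule={})
    problem = mp.toy_design_problem()
    model = mp.build_model(problem, toy["db"], empty, toy["sigs"][1], toy["thermo"])
    sols = mp.solve_enumerate(model, k=10)
    assert {tuple(s.active_steps()) for s in sols} == {(("2HIPD", 1), ("SLD", 1))}


def test_banned_exchange_removes_exactly_the_designs_using_it(toy):
    base = mp.toy_design_problem()
    model = mp.build_model(base, toy["db"], toy["rules"][1], toy["sigs"][1], toy["thermo"])
    all_sols = mp.solve_enumerate(model, k=20)
    banned = mp.toy_design_problem(banned_exchanges={"co2"}, use_thermo=False)
    model_b = mp.build_model(banned, toy["db"], toy["rules"][1], toy["sigs"][1], toy["thermo"])
    banned_sols = mp.solve_enumerate(model_b, k=20)
    survivors = {tuple(s.active_steps()) for s in all_sols if s.v_ex["co2"] == 0}
    assert {tuple(s.active_steps()) for s in banned_sols} == survivors
    assert survivors == set()  # every toy design must export the CO2


def test_thermo_row_toggles_positive_deltaG_pathway(toy):
    """Carboxylating phenol back to salicylate has ΔG'° > 0: admitted only
    with the thermodynamic row disabled (the cautionary-output behavior)."""
    kwargs = dict(
        source="phnl",
        target="sal",
        exchange_bounds={"phnl": (-1, -1), "sal": (1, 1), "co2": (-2, 0)},
        max_steps=2,
        flux_bound=2,
    )
    relaxed = mp.DesignProblem(lam=1, use_thermo=False, **kwargs)
    model = mp.build_model(relaxed, toy["db"], toy["rules"][1], toy["sigs"][1], toy["thermo"])
    sols = mp.solve_enumerate(model, k=10)
    assert sols, "reverse pathway should be admitted without the ΔG row"
    assert all(s.deltaG_overall > 0 for s in sols)
    strict = mp.DesignProblem(lam=1, use_thermo=True, **kwargs)
    model_s = mp.build_model(strict, toy["db"], toy["rules"][1], toy["sigs"][1], toy["thermo"])
    assert mp.solve_enumerate(model_s, k=10) == []


def test_every_solution_meets_thermo_threshold(toy, toy_solutions):
    eps = toy_solutions["problem"].deltaG_epsilon
    for sol in toy_solutions["solutions"]:
        assert sol.deltaG_overall <= -eps


def test_organism_selection_constrains_reaction_usage(toy):
    # 2HIPD is annotated to orgA, SLD to orgB; the rule inherits both
    problem = mp.toy_design_problem(organism_select={"orgA"})
    model = mp.build_model(problem, toy["db"], toy["rules"][1], toy["sigs"][1], toy["thermo"])
    sols = mp.solve_enumerate(model, k=10)
    assert sols
    for s in sols:
        assert s.v_known.get("SLD", 0) == 0


def test_pathway_selection_requires_matching_annotation(toy):
    ok = mp.toy_design_problem(pathway_select={"decarboxylation"})
    model = mp.build_model(ok, toy["db"], toy["rules"][1], toy["sigs"][1], toy["thermo"])
    assert len(mp.solve_enumerate(model, k=10)) == 4
    none = mp.toy_design_problem(pathway_select={"unrelated"})
    model_n = mp.build_model(none, toy["db"], toy["rules"][1], toy["sigs"][1], toy["thermo"])
    assert mp.solve_enumerate(model_n, k=10) == []


def test_direction_override_pins_rule_direction(toy):
    problem = mp.toy_design_problem(direction_overrides={"R1": "off"})
    model = mp.build_model(problem, toy["db"], toy["rules"][1], toy["sigs"][1], toy["thermo"])
    sols = mp.solve_enumerate(model, k=10)
    assert {tuple(s.active_steps()) for s in sols} == {(("2HIPD", 1), ("SLD", 1))}


def test_infeasible_problem_returns_empty_with_certificate(toy):
    problem = mp.toy_design_problem(max_steps=0)
    model = mp.build_model(problem, toy["db"], toy["rules"][1], toy["sigs"][1], toy["thermo"])
    assert mp.solve_enumerate(model, k=5) == []
    assert "infeasible" in model.enumeration_status


def test_lambda_mismatch_rejected(toy):
    problem = mp.toy_design_problem()  # lam=1
    with pytest.raises(ModelBuildError, match="λ"):
        mp.build_model(problem, toy["db"], toy["rules"][2], toy["sigs"][1], toy["thermo"])


def test_missing_signature_named_in_error(toy):
    problem = mp.toy_design_problem()
    sigs = {k: v for k, v in toy["sigs"][1].items() if k != "sal"}
    with pytest.raises(ModelBuildError, match="sal"):
        mp.build_model(problem, toy["db"], toy["rules"][1], sigs, toy["thermo"])


def test_validator_reports_single_perturbed_moiety_row(toy, toy_solutions):
    sol = toy_solutions["solutions"][0]
    bad = mp.PathwaySolution(
        v_known=dict(sol.v_known), v_rules=dict(sol.v_rules),
        v_imb=dict(sol.v_imb), v_ex=dict(sol.v_ex),
        objective_value=sol.objective_value, deltaG_overall=sol.deltaG_overall,
        step_count=sol.step_count, rule_count=sol.rule_count,
    )
    bad.v_imb["phnl"] = bad.v_imb.get("phnl", 0) + 1  # corrupt one linkage flux
    report = mp.validate_solution(
        bad, toy["db"], toy["rules"][1], toy["sigs"][1], toy["thermo"],
        toy_solutions["problem"], toy["structures"],
    )
    assert not report.ok
    assert report.component_residuals == {"phnl": 1}


def test_empty_design_flagged(toy):
    zero = mp.PathwaySolution(
        v_known={r.id: 0 for r in toy["db"]}, v_rules={"R1": 0},
        v_imb={m: 0 for m in toy["db"].metabolites},
        v_ex={"2hipa": 0, "phnl": 0, "co2": 0},
        objective_value=0.0, deltaG_overall=0.0, step_count=0, rule_count=0,
    )
    report = mp.validate_solution(zero, toy["db"], toy["rules"][1], toy["sigs"][1])
    assert "empty design" in report.flags


def test_min_steps_on_linear_chain_equals_chain_length():
    """Rules removed, known network a linear source→target chain of length L."""
    for L in (1, 2, 3):
        net = mp.planted_network(L + 3, L, L, seed=100 + L)
        reg = mp.PrimeRegistry()
        sigs = mp.signature_index(net.structures, 1, reg)
        rules = mp.extract_rules(list(net.db), sigs, 1)
        prob = mp.planted_problem(net, max_rules=0)
        model = mp.build_model(prob, net.db, rules, sigs, net.thermo)
        sols = mp.solve_enumerate(model, k=1)
        assert sols and sols[0].step_count == L


def test_tightening_max_rules_never_improves_min_steps(toy):
    best = {}
    for cap in (2, 1, 0):
        problem = mp.toy_design_problem(max_rules=cap)
        model = mp.build_model(problem, toy["db"], toy["rules"][1], toy["sigs"][1], toy["thermo"])
        sols = mp.solve_enumerate(model, k=1)
        best[cap] = sols[0].step_count if sols else float("inf")
    assert best[2] <= best[1] <= best[0]


def test_enlarging_exchange_set_never_worsens_max_profit(toy):
    prices = {"2hipa": 1.0, "sal": 3.0, "phnl": 5.0, "co2": 0.0}
    base_bounds = {"2hipa": (-2, -1), "phnl": (1, 2), "co2": (-4, 4)}
    small = mp.toy_design_problem(
        objective="max_profit", prices=prices, exchange_bounds=dict(base_bounds)
    )
    model_s = mp.build_model(small, toy["db"], toy["rules"][1], toy["sigs"][1], toy["thermo"])
    sols_s = mp.solve_enumerate(model_s, k=1)
    larger = mp.toy_design_problem(
        objective="max_profit", prices=prices,
        exchange_bounds={**base_bounds, "sal": (0, 1)},
    )
    model_l = mp.build_model(larger, toy["db"], toy["rules"][1], toy["sigs"][1], toy["thermo"])
    sols_l = mp.solve_enumerate(model_l, k=1)
    assert sols_s and sols_l
    profit_small = sum(prices[m] * v for m, v in sols_s[0].v_ex.items())
    profit_large = sum(prices[m] * v for m, v in sols_l[0].v_ex.items())
    assert profit_large >= profit_small


def test_max_profit_requires_prices_and_finite_bounds(toy):
    with pytest.raises(ModelBuildError, match="price"):
        mp.build_model(
            mp.toy_design_problem(objective="max_profit"),
            toy["db"], toy["rules"][1], toy["sigs"][1], toy["thermo"],
        )


def test_solutions_ordered_by_objective_then_lexicographic(toy_solutions):
    sols = toy_solutions["solutions"]
    keys = [(s.objective_value, s.active_steps()) for s in sols]
    assert keys == sorted(keys)
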