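import pytest

import moietypath as mp


@pytest.fixture(scope="session")
def toy():
    """Toy decarboxylase system with signatures and rules at every λ."""
    db, structures = mp.toy_decarboxylase_db()
    registry = mp.PrimeRegistry()
    sigs = {lam: mp.signature_index(structures, lam, registry) for lam in (1, 2, 3)}
    rules = {lam: mp.extract_rules(list(db), sigs[lam], lam) for lam in (1, 2, 3)}
    return {
        "db": db,
        "structures": structures,
        "registry": registry,
        "sigs": sigs,
        "rules": rules,
        "thermo": mp.toy_thermo(),
    }


@pytest.fixture(scope="session")
def toy_solutions(toy):
    """The four enumerated designs of the 2hipa → phnl run."""
    problem = mp.toy_design_problem()
    model = mp.build_model(problem, toy["db"], toy["rules"][1], toy["sigs"][1], toy["thermo"])
    sols = mp.solve_enumerate(model, k=10)
    return {"problem": problem, "model": model, "solutions": sols}
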