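"""Reaction-table loading, balance audits, thermodynamics."""

import pytest

import moietypath as mp
from moietypath.reactiondb import ReactionLoadError

TOY_TSV = """reaction\tmetabolite\tcoefficient\treversible\tpathways\torganisms
2HIPD\t2hipa\t-1\tfalse\tdecarboxylation\torgA
2HIPD\tsal\t1\tfalse\t\t
2HIPD\tco2\t1\tfalse\t\t
SLD\tsal\t-1\tfalse\tdecarboxylation\torgB
SLD\tphnl\t1\tfalse\t\t
SLD\tco2\t1\tfalse\t\t
"""


def _write(tmp_path, text, name="rxns.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


def test_load_toy_table(tmp_path):
    db = mp.load_reactions(_write(tmp_path, TOY_TSV))
    assert len(db) == 2
    assert db.metabolites == ["2hipa", "co2", "phnl", "sal"]
    assert db["2HIPD"].stoich == {"2hipa": -1, "sal": 1, "co2": 1}
    assert db["2HIPD"].pathways == {"decarboxylation"}
    assert db["SLD"].organisms == {"orgB"}


def test_empty_table_loads_as_empty_database(tmp_path):
    db = mp.load_reactions(
        _write(tmp_path, "reaction\tmetabolite\tcoefficient\treversible\n")
    )
    assert len(db) == 0


def test_zero_coefficient_row_rejected(tmp_path):
    bad = TOY_TSV + "SLD2\tsal\t0\tfalse\t\t\n"
    with pytest.raises(ReactionLoadError, match="zero coefficient"):
        mp.load_reactions(_write(tmp_path, bad))


def test_duplicate_reaction_metabolite_row_rejected(tmp_path):
    bad = TOY_TSV + "SLD\tsal\t-2\tfalse\t\t\n"
    with pytest.raises(ReactionLoadError, match="duplicate metabolite"):
        mp.load_reactions(_write(tmp_path, bad))


def test_missing_column_and_bad_coefficient_errors(tmp_path):
    with pytest.raises(ReactionLoadError, match="missing columns"):
        mp.load_reactions(_write(tmp_path, "reaction\tmetabolite\tcoefficient\nR\ta\t1\n"))
    bad = "reaction\tmetabolite\tcoefficient\treversible\nR\ta\tabc\tfalse\n"
    with pytest.raises(ReactionLoadError, match="non-numeric"):
        mp.load_reactions(_write(tmp_path, bad))


def test_rational_coefficients_normalized_to_smallest_integers(tmp_path):
    text = (
        "reaction\tmetabolite\tcoefficient\treversible\n"
        "R\ta\t-1/2\ttrue\nR\tb\t3/2\ttrue\n"
    )
    db = mp.load_reactions(_write(tmp_path, text))
    assert db["R"].stoich == {"a": -1, "b": 3}


def test_json_round_trip(tmp_path, toy):
    path = str(tmp_path / "db.json")
    toy["db"].save(path)
    back = mp.load_reactions(path)
    assert back.to_json() == toy["db"].to_json()


def test_balance_report_sld_all_zero(toy):
    report = mp.check_reaction_balance(toy["db"]["SLD"], toy["structures"])
    assert report.balanced is True
    assert report.residuals == {}


def test_balance_report_detects_missing_co2():
    corrupt = mp.Reaction(id="SLDx", stoich={"sal": -1, "phnl": 1}, reversible=False)
    _, structures = mp.toy_decarboxylase_db()
    report = mp.check_reaction_balance(corrupt, structures)
    assert report.balanced is False
    assert report.residuals == {"C": -1, "O": -2}


def test_balance_report_detects_wrong_hydrogen_count():
    structures = {
        "h2o": mp.parse_structure("O", "smiles", mol_id="h2o"),
        "o2": mp.parse_structure("O=O", "smiles", mol_id="o2"),
        "h2": mp.parse_structure("[H][H]", "smiles", mol_id="h2"),
    }
    bad = mp.Reaction(id="WS", stoich={"h2o": -2, "o2": 1, "h2": 1}, reversible=False)
    report = mp.check_reaction_balance(bad, structures)
    assert report.residuals.get("H") == -2


def test_balance_report_flags_missing_structure(toy):
    rxn = mp.Reaction(id="X", stoich={"sal": -1, "mystery": 1}, reversible=False)
    report = mp.check_reaction_balance(rxn, toy["structures"])
    assert report.balanced is None
    assert report.missing_structures == ["mystery"]


def test_overall_deltaG_arithmetic():
    thermo = mp.ThermoTable({"a": -100.0, "b": -60.0})
    assert mp.overall_deltaG({}, thermo) == 0.0
    assert mp.overall_deltaG({"a": 1, "b": -1}, thermo) == pytest.approx(-40.0)
    assert mp.overall_deltaG({"a": -1, "b": 1}, thermo) == pytest.approx(40.0)


def test_overall_deltaG_missing_entry_is_an_error():
    thermo = mp.ThermoTable({"a": -100.0})
    with pytest.raises(KeyError, match="b"):
        mp.overall_deltaG({"a": -1, "b": 1}, thermo)
    # zero-flux metabolites need no entry
    assert mp.overall_deltaG({"a": 1, "b": 0}, thermo) == pytest.approx(-100.0)


def test_thermo_table_tsv_round_trip(tmp_path):
    table = mp.toy_thermo()
    path = str(tmp_path / "dg.tsv")
    table.save(path)
    back = mp.ThermoTable.load(path)
    assert dict(back.items()) == dict(table.items())
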