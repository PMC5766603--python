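"""Canonical prime labeling and molecular signatures."""

import random

import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

import moietypath as mp
from moietypath.signatures import assign_primes

POOL = [
    "O=C=O",
    "c1ccccc1O",
    "OC(=O)c1ccccc1O",
    "OC(=O)c1cccc(C(O)=O)c1O",
    "CC(N)C(O)=O",
    "OCC(O)CO",
    "C1CCOC1",
    "N",
    "O",
    "CC(=O)OC",
]


def _permuted(smiles: str, seed: int) -> mp.Molecule:
    base = Chem.MolFromSmiles(smiles)
    order = list(range(base.GetNumAtoms()))
    random.Random(seed).shuffle(order)
    text = Chem.MolToSmiles(Chem.RenumberAtoms(base, order), canonical=False)
    return mp.parse_structure(text, "smiles")


def test_co2_has_two_distinct_labels_at_lambda1():
    reg = mp.PrimeRegistry()
    mol = mp.parse_structure("O=C=O", "smiles", mol_id="co2")
    labels = assign_primes(mol, 1, reg)
    primes = sorted(set(l.prime for l in labels.values()))
    assert len(primes) == 2  # the carbon and the two equivalent oxygens
    sig = mp.signature(mol, 1, reg)
    assert sorted(sig.counts.values()) == [1, 2]


def test_lambda_out_of_range_rejected():
    reg = mp.PrimeRegistry()
    mol = mp.parse_structure("O", "smiles")
    with pytest.raises(ValueError):
        assign_primes(mol, 4, reg)
    with pytest.raises(ValueError):
        assign_primes(mol, 0, reg)


def test_signature_total_equals_node_count_at_every_lambda():
    reg = mp.PrimeRegistry()
    for smiles in POOL:
        mol = mp.parse_structure(smiles, "smiles")
        for lam in (1, 2, 3):
            assert mp.signature(mol, lam, reg).total() == mol.n_atoms


@pytest.mark.parametrize("lam", [1, 2, 3])
def test_label_multiset_invariant_under_atom_permutation(lam):
    reg = mp.PrimeRegistry()
    for smiles in POOL:
        ref = mp.signature(mp.parse_structure(smiles, "smiles"), lam, reg)
        for seed in range(20):
            assert mp.signature(_permuted(smiles, seed), lam, reg) == ref


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    a=st.sampled_from(POOL),
    b=st.sampled_from(POOL),
    lam=st.sampled_from([1, 2, 3]),
)
def test_signature_additive_over_disconnected_components(a, b, lam):
    """sig(A ∪ B) = sig(A) + sig(B): brute-force addition oracle."""
    reg = mp.PrimeRegistry()
    ma = mp.parse_structure(a, "smiles", mol_id="a")
    mb = mp.parse_structure(b, "smiles", mol_id="b")
    union = mp.combine("ab", [ma, mb])
    expected = mp.signature(ma, lam, reg) + mp.signature(mb, lam, reg)
    assert mp.signature(union, lam, reg) == expected


def test_symmetric_carboxyl_carbons_share_label_in_2hipa():
    """The two mirror-equivalent carboxyl carbons get one label; the ring
    carbon between them gets another, at λ=2 and λ=3."""
    reg = mp.PrimeRegistry()
    mol = mp.parse_structure("OC(=O)c1cccc(C(O)=O)c1O", "smiles", mol_id="2hipa")
    for lam in (2, 3):
        labels = assign_primes(mol, lam, reg)
        carboxyl = [
            i for i, a in enumerate(mol.atoms)
            if a.element == "C" and mol.incident_orders(i) == (1.0, 1.0, 2.0)
        ]
        assert len(carboxyl) == 2
        assert labels[carboxyl[0]] == labels[carboxyl[1]]
        ring_c = [
            i for i, a in enumerate(mol.atoms)
            if a.element == "C" and 1.5 in mol.incident_orders(i)
        ]
        assert labels[carboxyl[0]] not in {labels[i] for i in ring_c}


def test_specificity_grows_with_lambda():
    reg = mp.PrimeRegistry()
    mol = mp.parse_structure("OC(=O)c1cccc(C(O)=O)c1O", "smiles", mol_id="2hipa")
    n_distinct = [len(mp.signature(mol, lam, reg).counts) for lam in (1, 2, 3)]
    assert n_distinct[0] <= n_distinct[1] <= n_distinct[2]
    assert n_distinct[0] < n_distinct[2]


def test_registry_round_trip_preserves_primes():
    reg = mp.PrimeRegistry()
    mol = mp.parse_structure("OC(=O)c1ccccc1O", "smiles", mol_id="sal")
    sig = mp.signature(mol, 2, reg)
    restored = mp.PrimeRegistry.from_json(reg.to_json())
    assert mp.signature(mol, 2, restored) == sig


def test_same_environment_same_prime_across_molecules():
    reg = mp.PrimeRegistry()
    water = mp.parse_structure("O", "smiles")
    methanol = mp.parse_structure("CO", "smiles")
    lw = set(assign_primes(water, 1, reg).values())
    lm = set(assign_primes(methanol, 1, reg).values())
    # the hydroxyl-type H(single bond) label is shared
    h_labels_w = {l for l in lw if l.element == "H"}
    h_labels_m = {l for l in lm if l.element == "H"}
    assert h_labels_w & h_labels_m
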