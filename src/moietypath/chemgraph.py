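"""Molecular graphs with explicit hydrogens.

Everything downstream — canonical labeling, moiety signatures, reaction-rule
derivation, balance audits and rule application — consumes the :class:`Molecule`
defined here: a plain labeled graph of atoms (element, formal charge) and bonds
(order 1, 2, 3 or aromatic).  RDKit does the heavy lifting for parsing SMILES and
MDL Molfiles, aromaticity perception and canonical SMILES output; the graph itself
is deliberately independent of RDKit so that graph edits and labeling stay simple
integer/tuple manipulations.

Conventions:

* hydrogens are explicit nodes (element balance of rules must include H);
* aromatic bonds keep a distinct order (``1.5``) rather than being kekulized, so
  resonance-equivalent atoms receive equal labels;
* formal charges are taken verbatim from the input structure — no pH-dependent
  re-protonation;
* disconnected structures (salts) are accepted; signatures are additive over
  components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from rdkit import Chem
from rdkit import RDLogger

# RDKit is chatty on stderr for recoverable parse problems; errors are raised
# as exceptions below, so the log stream is silenced.
RDLogger.DisableLog("rdApp.*")

AROMATIC_ORDER = 1.5

_RDKIT_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: AROMATIC_ORDER,
}
_TO_RDKIT_ORDER = {
    1.0: Chem.BondType.SINGLE,
    2.0: Chem.BondType.DOUBLE,
    3.0: Chem.BondType.TRIPLE,
    AROMATIC_ORDER: Chem.BondType.AROMATIC,
}


class StructureParseError(ValueError):
    """Raised when a SMILES/Molfile cannot be turned into a valid molecule."""


@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    charge: int


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: float  # 1, 2, 3 or AROMATIC_ORDER

    def other(self, idx: int) -> int:
        return self.j if idx == self.i else self.i


@dataclass
class Molecule:
    """A labeled molecular graph with explicit hydrogens.

    ``atoms`` are indexed 0..n-1; ``bonds`` reference those indices.  The graph
    may be disconnected (multi-component records are legal inputs).
    """

    id: str
    atoms: List[Atom]
    bonds: List[Bond]
    provenance: str = ""
    _adj: Optional[Dict[int, List[Bond]]] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if sorted(a.index for a in self.atoms) != list(range(n)):
            raise ValueError(f"{self.id}: atom indices must be 0..{n - 1} and unique")
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise ValueError(f"{self.id}: bond ({b.i},{b.j}) references invalid atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> Dict[int, List[Bond]]:
        if self._adj is None:
            adj: Dict[int, List[Bond]] = {a.index: [] for a in self.atoms}
            for b in self.bonds:
                adj[b.i].append(b)
                adj[b.j].append(b)
            self._adj = adj
        return self._adj

    def incident_orders(self, idx: int) -> Tuple[float, ...]:
        """Sorted bond orders incident to atom ``idx`` (part of the λ=1 label)."""
        return tuple(sorted(b.order for b in self.adjacency()[idx]))

    def components(self) -> List[List[int]]:
        """Connected components as sorted atom-index lists, in deterministic order."""
        seen = set()
        comps = []
        adj = self.adjacency()
        for start in range(self.n_atoms):
            if start in seen:
                continue
            stack, comp = [start], []
            seen.add(start)
            while stack:
                v = stack.pop()
                comp.append(v)
                for b in adj[v]:
                    w = b.other(v)
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            comps.append(sorted(comp))
        return comps


# ---------------------------------------------------------------------------
# RDKit bridge


def _from_rdkit(mol: Chem.Mol, mol_id: str, provenance: str) -> Molecule:
    atoms = [
        Atom(a.GetIdx(), a.GetSymbol(), a.GetFormalCharge()) for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        try:
            order = _RDKIT_ORDER[b.GetBondType()]
        except KeyError:
            raise StructureParseError(
                f"{mol_id}: unsupported bond type {b.GetBondType()}"
            ) from None
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return Molecule(id=mol_id, atoms=atoms, bonds=bonds, provenance=provenance)


def to_rdkit(mol: Molecule, sanitize: bool = True) -> Chem.Mol:
    """Rebuild an RDKit molecule (used for canonical SMILES and valence checks).

    Raises :class:`StructureParseError` if the graph does not sanitize (illegal
    valence, un-kekulizable aromatic system, ...).
    """
    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.charge)
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    for b in mol.bonds:
        rw.AddBond(b.i, b.j, _TO_RDKIT_ORDER[b.order])
        if b.order == AROMATIC_ORDER:
            rw.GetAtomWithIdx(b.i).SetIsAromatic(True)
            rw.GetAtomWithIdx(b.j).SetIsAromatic(True)
            rw.GetBondBetweenAtoms(b.i, b.j).SetIsAromatic(True)
    out = rw.GetMol()
    if sanitize:
        try:
            Chem.SanitizeMol(out)
        except Exception as exc:  # rdkit raises several exception types
            raise StructureParseError(f"{mol.id}: graph does not sanitize: {exc}") from exc
    return out


def parse_structure(text: str, dialect: str = "smiles", mol_id: str = "") -> Molecule:
    """Parse one structure record into a :class:`Molecule` with explicit hydrogens.

    Parameters
    ----------
    text:
        The structure, either a SMILES string or a full MDL Molfile block.
    dialect:
        ``"smiles"`` or ``"molfile"``.
    mol_id:
        Metabolite identifier attached to the result (defaults to the record's
        own name for Molfiles, else the SMILES text).
    """
    if dialect == "smiles":
        rd = Chem.MolFromSmiles(text, sanitize=True)
        if rd is None:
            raise StructureParseError(f"malformed SMILES: {text!r}")
        default_id = text.strip()
    elif dialect == "molfile":
        rd = Chem.MolFromMolBlock(text, sanitize=True, removeHs=False)
        if rd is None:
            raise StructureParseError("malformed Molfile block")
        default_id = (rd.GetProp("_Name") if rd.HasProp("_Name") else "").strip()
    else:
        raise ValueError(f"unknown structure dialect {dialect!r}")
    rd = Chem.AddHs(rd)
    # One fixed aromaticity perception model throughout (RDKit default).
    Chem.SetAromaticity(rd)
    return _from_rdkit(rd, mol_id or default_id or "mol", provenance=text)


def to_smiles(mol: Molecule) -> str:
    """Canonical SMILES (hydrogens folded back in) for reporting."""
    rd = to_rdkit(mol)
    return Chem.MolToSmiles(Chem.RemoveHs(rd))


# ---------------------------------------------------------------------------
# Element bookkeeping


def element_counts(mol: Molecule) -> Dict[str, int]:
    """Element → count over all nodes (hydrogens included).

    Counts sum to the node count and are invariant under any permutation of
    atom indices.
    """
    out: Dict[str, int] = {}
    for a in mol.atoms:
        out[a.element] = out.get(a.element, 0) + 1
    return out


def combine(mol_id: str, parts: Iterable[Molecule]) -> Molecule:
    """Disjoint union of molecules as a single (multi-component) Molecule."""
    atoms: List[Atom] = []
    bonds: List[Bond] = []
    offset = 0
    for p in parts:
        for a in p.atoms:
            atoms.append(Atom(a.index + offset, a.element, a.charge))
        for b in p.bonds:
            bonds.append(Bond(b.i + offset, b.j + offset, b.order))
        offset += p.n_atoms
    return Molecule(id=mol_id, atoms=atoms, bonds=bonds, provenance="union")


def read_smiles_file(path: str) -> Dict[str, Molecule]:
    """Read a ``.smi`` file (``SMILES<whitespace>id`` per line) into an index."""
    out: Dict[str, Molecule] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise StructureParseError(
                    f"{path}:{lineno}: expected 'SMILES id', got {line!r}"
                )
            smiles, mol_id = parts[0], parts[1].strip()
            if mol_id in out:
                raise StructureParseError(f"{path}:{lineno}: duplicate id {mol_id!r}")
            out[mol_id] = parse_structure(smiles, "smiles", mol_id=mol_id)
    return out


def read_sdf_file(path: str) -> Dict[str, Molecule]:
    """Read an SDF; each record's title line is its metabolite id."""
    out: Dict[str, Molecule] = {}
    supplier = Chem.SDMolSupplier(path, sanitize=True, removeHs=False)
    for k, rd in enumerate(supplier):
        if rd is None:
            raise StructureParseError(f"{path}: record {k} failed to parse")
        mol_id = (rd.GetProp("_Name") if rd.HasProp("_Name") else "").strip() or f"mol{k}"
        rd = Chem.AddHs(rd)
        Chem.SetAromaticity(rd)
        out[mol_id] = _from_rdkit(rd, mol_id, provenance=f"{path}#{k}")
    return out
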