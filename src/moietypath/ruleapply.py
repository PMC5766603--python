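"""Instantiate a reaction rule on concrete substrates to propose product
structures.

Pathway design itself never depends on this module — the MILP works purely on
signatures — but a designed route that invokes a rule implies novel
intermediates, and this module proposes candidate structures for them.  The
verifiable contract is signature-level: a candidate product set is accepted
only if the recomputed signature difference against the substrates equals the
rule's change map exactly (zero residual) and the structures are
valence-legal.

Generation is best-effort and λ-guided: candidate reaction centers are the
atoms carrying the rule's consumed moieties; around each center a bounded
search over bond-order edits is run.  Two structural filters keep the search
sharp: (i) edits never touch aromatic bonds, and (ii) each atom's total
incident bond order is conserved across the edit (closed-shell chemistry —
explicit hydrogens move, radicals are never formed).  Survivors are
re-validated by RDKit sanitization.  At λ=3 the environment constraints make
edits near-unique; at λ=1 several residual-zero candidates are expected and
all are returned, ranked by fewest graph edits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .chemgraph import AROMATIC_ORDER, Bond, Molecule, StructureParseError, combine, to_rdkit, to_smiles
from .rules import ReactionRule
from .signatures import MoietyLabel, PrimeRegistry, assign_primes, signature

Center = Tuple[Tuple[int, int], ...]  # ((molecule index, atom index), ...)


def match_sites(
    rule: ReactionRule,
    substrates: Sequence[Molecule],
    registry: PrimeRegistry,
    max_centers: int = 500,
) -> List[Center]:
    """Candidate reaction centers: atom selections covering the rule's
    consumed moieties at the required multiplicities.

    Within one substrate, a multi-atom selection must be connected (a moiety
    neighborhood cannot straddle disconnected atoms); selections may span
    several substrates.  Centers are returned in deterministic sorted order.
    An absent required moiety yields an empty list, not an error.
    """
    negatives = {m: -c for m, c in rule.changes.items() if c < 0}
    if not negatives:
        return [tuple()]  # identity-like rule: one empty center
    labels_per_mol = [assign_primes(mol, rule.lam, registry) for mol in substrates]
    # The reaction center is where bonding actually changes.  The rule's
    # *base-type* projection (element, charge, bond-order pattern of the
    # moiety centers) says how many atoms of each base type truly change
    # bonding; consumed λ-level moieties beyond that are ripple effects of
    # the environment relabeling.  Pick the required number of atoms per
    # base type from the carriers of consumed moieties of that type.
    base_proj: Dict[Tuple, int] = {}
    for m, c in rule.changes.items():
        base_proj[m.base_type] = base_proj.get(m.base_type, 0) + c
    requirements: List[Tuple[int, List[Tuple[int, int]]]] = []
    if any(v < 0 for v in base_proj.values()):
        for base, net in sorted(base_proj.items(), key=lambda kv: repr(kv[0])):
            if net >= 0:
                continue
            carriers = sorted(
                (k, idx)
                for k, labels in enumerate(labels_per_mol)
                for idx, lab in labels.items()
                if lab in negatives and lab.base_type == base
            )
            requirements.append((-net, carriers))
    else:  # pure ripple rule: fall back to matching every consumed moiety
        for label, need in sorted(negatives.items()):
            carriers = sorted(
                (k, idx)
                for k, labels in enumerate(labels_per_mol)
                for idx, lab in labels.items()
                if lab == label
            )
            requirements.append((need, carriers))
    pools: List[List[Tuple[Tuple[int, int], ...]]] = []
    for need, carriers in requirements:
        if len(carriers) < need:
            return []
        pools.append([tuple(sel) for sel in itertools.combinations(carriers, need)])
    centers: List[Center] = []
    for combo in itertools.product(*pools):
        atoms: Set[Tuple[int, int]] = set()
        clash = False
        for sel in combo:
            for a in sel:
                if a in atoms:
                    clash = True
                    break
                atoms.add(a)
            if clash:
                break
        if clash:
            continue
        center = tuple(sorted(atoms))
        if _center_connected(center, substrates) and center not in centers:
            centers.append(center)
            if len(centers) >= max_centers:
                break
    return sorted(centers)


def _center_connected(center: Center, substrates: Sequence[Molecule]) -> bool:
    by_mol: Dict[int, List[int]] = {}
    for k, idx in center:
        by_mol.setdefault(k, []).append(idx)
    for k, atoms in by_mol.items():
        if len(atoms) == 1:
            continue
        chosen = set(atoms)
        adj = substrates[k].adjacency()
        seen = {atoms[0]}
        stack = [atoms[0]]
        while stack:
            v = stack.pop()
            for b in adj[v]:
                w = b.other(v)
                if w in chosen and w not in seen:
                    seen.add(w)
                    stack.append(w)
        if seen != chosen:
            return False
    return True


@dataclass
class ProductCandidate:
    molecules: List[Molecule]
    smiles: List[str]
    n_edits: int


@dataclass
class RuleApplication:
    rule_id: str
    substrate_ids: List[str]
    center: Center
    candidates: List[ProductCandidate] = field(default_factory=list)
    signature_residual: Dict[MoietyLabel, int] = field(default_factory=dict)
    flag: str = ""

    @property
    def realized(self) -> bool:
        return bool(self.candidates)


def apply_rule(
    rule: ReactionRule,
    substrates: Sequence[Molecule],
    center: Center,
    registry: PrimeRegistry,
    max_edits: int = 4,
    partner_search: bool = True,
    max_candidates: int = 20,
) -> RuleApplication:
    """Search bond edits around ``center`` realizing the rule's moiety changes.

    Returns all residual-zero, valence-legal product sets found within the
    edit budget, deduplicated by canonical SMILES and ranked by fewest edits.
    If no candidate survives, the application is flagged
    ``"unrealizable at this center"``.
    """
    app = RuleApplication(
        rule_id=rule.id,
        substrate_ids=[m.id for m in substrates],
        center=center,
    )
    if not rule.changes:  # identity rule: substrates returned unchanged
        app.candidates = [
            ProductCandidate(
                molecules=list(substrates),
                smiles=[to_smiles(m) for m in substrates],
                n_edits=0,
            )
        ]
        return app

    union = combine("substrate_union", substrates)
    offsets = []
    off = 0
    for m in substrates:
        offsets.append(off)
        off += m.n_atoms
    center_atoms = sorted(offsets[k] + idx for k, idx in center)
    base_sig = signature(union, rule.lam, registry)
    target_counts: Dict[MoietyLabel, int] = dict(base_sig.counts)
    for label, change in rule.changes.items():
        target_counts[label] = target_counts.get(label, 0) + change
        if target_counts[label] < 0:
            app.flag = "rule not applicable: moiety deficit"
            return app
        if target_counts[label] == 0:
            del target_counts[label]

    found: Dict[Tuple[str, ...], ProductCandidate] = {}

    def _search(atom_set: List[int]) -> None:
        _edit_search(
            union, rule, atom_set, center_atoms, target_counts, registry,
            max_edits, found, max_candidates,
        )

    adj = union.adjacency()
    base_atoms = sorted(
        set(center_atoms)
        | {b.other(a) for a in center_atoms for b in adj[a]}
    )
    _search(base_atoms)
    if not found and partner_search:
        heavy = [a.index for a in union.atoms if a.element != "H" and a.index not in base_atoms]
        for q in heavy:
            if len(found) >= max_candidates:
                break
            extra = [q]
            for b in adj[q]:
                w = b.other(q)
                if union.atoms[w].element == "H":
                    extra.append(w)
                    break
            _search(sorted(set(base_atoms) | set(extra)))

    app.candidates = sorted(found.values(), key=lambda c: (c.n_edits, c.smiles))
    if not app.candidates:
        app.flag = "unrealizable at this center"
    return app


def _edit_search(
    union: Molecule,
    rule: ReactionRule,
    atom_set: List[int],
    center_atoms: List[int],
    target_counts: Mapping[MoietyLabel, int],
    registry: PrimeRegistry,
    max_edits: int,
    found: Dict[Tuple[str, ...], ProductCandidate],
    max_candidates: int,
) -> None:
    bond_map: Dict[Tuple[int, int], float] = {}
    for b in union.bonds:
        bond_map[(min(b.i, b.j), max(b.i, b.j))] = b.order
    atoms = union.atoms
    # candidate pairs: within the atom set, never an aromatic bond, never H-H
    pairs: List[Tuple[int, int]] = []
    for i, j in itertools.combinations(sorted(atom_set), 2):
        cur = bond_map.get((i, j), 0.0)
        if cur == AROMATIC_ORDER:
            continue
        if atoms[i].element == "H" and atoms[j].element == "H":
            continue
        pairs.append((i, j))
    center_set = set(center_atoms)
    total_order = {a: sum(b.order for b in union.adjacency()[a]) for a in atom_set}

    for n_edits in range(1, max_edits + 1):
        for chosen in itertools.combinations(pairs, n_edits):
            touched = {i for p in chosen for i in p}
            if center_set and not (center_set & touched):
                continue
            current = [bond_map.get(p, 0.0) for p in chosen]
            options = [[o for o in (0.0, 1.0, 2.0, 3.0) if o != c] for c in current]
            for new_orders in itertools.product(*options):
                # closed-shell filter: per-atom total bond order conserved
                delta: Dict[int, float] = {}
                for (i, j), old, new in zip(chosen, current, new_orders):
                    d = new - old
                    delta[i] = delta.get(i, 0.0) + d
                    delta[j] = delta.get(j, 0.0) + d
                if any(abs(v) > 1e-9 for v in delta.values()):
                    continue
                candidate = _apply_edits(union, bond_map, chosen, new_orders)
                if candidate is None:
                    continue
                sig = signature(candidate, rule.lam, registry)
                if sig.counts != dict(target_counts):
                    continue
                products = _split_products(candidate)
                if products is None:
                    continue
                smiles = tuple(sorted(to_smiles(p) for p in products))
                if smiles not in found or found[smiles].n_edits > n_edits:
                    found[smiles] = ProductCandidate(
                        molecules=products, smiles=list(smiles), n_edits=n_edits
                    )
                if len(found) >= max_candidates:
                    return


def _apply_edits(
    union: Molecule,
    bond_map: Mapping[Tuple[int, int], float],
    chosen: Sequence[Tuple[int, int]],
    new_orders: Sequence[float],
) -> Optional[Molecule]:
    edited = dict(bond_map)
    for p, o in zip(chosen, new_orders):
        if o == 0.0:
            edited.pop(p, None)
        else:
            edited[p] = o
    bonds = [Bond(i, j, o) for (i, j), o in sorted(edited.items())]
    mol = Molecule(id="edited", atoms=list(union.atoms), bonds=bonds, provenance="edit")
    # a bare neutral H/C/N/O atom would be a radical, never a product
    adj = mol.adjacency()
    for a in mol.atoms:
        if not adj[a.index] and a.charge == 0 and a.element in {"H", "C", "N", "O"}:
            return None
    try:
        to_rdkit(mol, sanitize=True)
    except StructureParseError:
        return None
    return mol


def _split_products(candidate: Molecule) -> Optional[List[Molecule]]:
    comps = candidate.components()
    products: List[Molecule] = []
    for k, comp in enumerate(comps):
        remap = {old: new for new, old in enumerate(comp)}
        atoms = [
            type(candidate.atoms[0])(remap[i], candidate.atoms[i].element, candidate.atoms[i].charge)
            for i in comp
        ]
        bonds = [
            Bond(remap[b.i], remap[b.j], b.order)
            for b in candidate.bonds
            if b.i in remap and b.j in remap
        ]
        try:
            mol = Molecule(id=f"prod{k + 1}", atoms=atoms, bonds=bonds, provenance="ruleapply")
            to_rdkit(mol, sanitize=True)
        except (StructureParseError, ValueError):
            return None
        products.append(mol)
    return products
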