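"""Self-contained test inputs: the two-decarboxylase toy system and random
planted-route networks.

The toy system is the smallest complete exercise of the whole stack: two
decarboxylase reactions — 2-hydroxyisophthalate decarboxylase (2HIPD) and
salicylate decarboxylase (SLD) — over four metabolites (2hipa, sal, CO2,
phnl).  Both reactions shed a carboxyl group as CO2, so they collapse to one
rule at λ=1 but separate at λ=2, and the design from 2hipa to phnl admits
exactly four distinct step/direction patterns under a two-step cap.

Planted networks are randomized databases with a certified source→target
route: a scaffold carrying k carboxyl groups is decarboxylated k times down to
the bare scaffold, while decoy reactions act on other scaffolds and can never
shorten the route.  Every generated network is audited for element balance and
its optimal route length is certified by exhaustive search (reachability plus,
on small instances, full flux-vector enumeration) before being returned.
Structures are encoded as neutral acids; a charged variant of the toy set is
provided to exercise charge-sensitive labeling.
"""

from __future__ import annotations

import json
import os
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .chemgraph import Molecule, parse_structure
from .design import DesignProblem
from .reactiondb import (
    Reaction,
    ReactionDatabase,
    ThermoTable,
    check_reaction_balance,
)

CO2_DFG = -92.26  # kcal/mol, standard transformed formation energy scale used in fixtures

TOY_SMILES = {
    "2hipa": "OC(=O)c1cccc(C(O)=O)c1O",
    "sal": "OC(=O)c1ccccc1O",
    "co2": "O=C=O",
    "phnl": "Oc1ccccc1",
}

# mono-anions instead of the neutral acids: exercises charge-sensitive labels
# (the anionic site follows the leaving carboxyl so both reactions stay balanced)
TOY_SMILES_CHARGED = {
    "2hipa": "[O-]C(=O)c1cccc(C(O)=O)c1O",
    "sal": "[O-]C(=O)c1ccccc1O",
    "co2": "O=C=O",
    "phnl": "[O-]c1ccccc1",
}


def fixture_path(name: str) -> str:
    """Absolute path of a bundled fixture file (``toy_reactions.tsv``,
    ``toy_structures.smi``, ``toy_thermo.tsv``) for file-based workflows."""
    from importlib.resources import files

    return str(files("moietypath").joinpath("data", name))


def toy_structures(charged: bool = False) -> Dict[str, Molecule]:
    source = TOY_SMILES_CHARGED if charged else TOY_SMILES
    return {mid: parse_structure(smi, "smiles", mol_id=mid) for mid, smi in source.items()}


def toy_decarboxylase_db(charged: bool = False) -> Tuple[ReactionDatabase, Dict[str, Molecule]]:
    """The two-reaction fixture: 2HIPD (2hipa → sal + CO2), SLD (sal → phnl + CO2)."""
    db = ReactionDatabase()
    db.add(
        Reaction(
            id="2HIPD",
            stoich={"2hipa": -1, "sal": 1, "co2": 1},
            reversible=False,
            pathways={"decarboxylation"},
            organisms={"orgA"},
        )
    )
    db.add(
        Reaction(
            id="SLD",
            stoich={"sal": -1, "phnl": 1, "co2": 1},
            reversible=False,
            pathways={"decarboxylation"},
            organisms={"orgB"},
        )
    )
    structures = toy_structures(charged=charged)
    for rxn in db:
        report = check_reaction_balance(rxn, structures)
        assert report.balanced, f"toy fixture reaction {rxn.id} unbalanced: {report.residuals}"
    return db, structures


def toy_thermo() -> ThermoTable:
    """Synthetic formation energies making both decarboxylations exergonic."""
    return ThermoTable({"2hipa": -140.0, "sal": -100.0, "phnl": -60.0, "co2": CO2_DFG})


def toy_design_problem(**overrides) -> DesignProblem:
    """The design run of the illustrative example: 2hipa → phnl, CO2 free.

    One mol of source is converted to one mol of target with CO2 freely
    exchanged; at most two steps may be active, which is the configuration
    under which the enumeration returns exactly the four documented patterns.
    """
    defaults = dict(
        lam=1,
        source="2hipa",
        target="phnl",
        exchange_bounds={"2hipa": (-1, -1), "phnl": (1, 1), "co2": (-4, 4)},
        max_steps=2,
        flux_bound=2,
        objective="min_total_steps",
    )
    defaults.update(overrides)
    return DesignProblem(**defaults)


# ---------------------------------------------------------------------------
# Planted networks

# aromatic/aliphatic cores; each admits up to three carboxyl substituents
_CORES: List[Tuple[str, str]] = [
    ("bz", "c1ccccc1"),
    ("pyr", "c1ccncc1"),
    ("fur", "c1ccoc1"),
    ("thi", "c1ccsc1"),
    ("chx", "C1CCCCC1"),
    ("cpn", "C1CCCC1"),
]


def _core_acid_smiles(core_smiles: str, k: int) -> str:
    """Core with k carboxyl groups (k ≤ 3), substituted at successive ring atoms."""
    if k == 0:
        return core_smiles
    # place substituents by rewriting the first k ring atoms with branches
    out = []
    placed = 0
    i = 0
    while i < len(core_smiles):
        ch = core_smiles[i]
        out.append(ch)
        if ch in "cC" and placed < k:
            # attach after the atom (and after a ring-closure digit if present)
            j = i + 1
            if j < len(core_smiles) and core_smiles[j].isdigit():
                out.append(core_smiles[j])
                i = j
            out.append("(C(O)=O)")
            placed += 1
        i += 1
    if placed < k:
        raise ValueError(f"core {core_smiles!r} cannot carry {k} substituents")
    return "".join(out)


@dataclass
class PlantedNetwork:
    """A reaction database with a certified source→target route."""

    db: ReactionDatabase
    structures: Dict[str, Molecule]
    thermo: ThermoTable
    source: str
    target: str
    route: List[str]  # ordered reaction ids along the planted route
    decoys: List[str] = field(default_factory=list)
    seed: int = 0

    def to_json(self) -> dict:
        return {
            "seed": self.seed,
            "source": self.source,
            "target": self.target,
            "route": list(self.route),
            "decoys": list(self.decoys),
            "reactions": self.db.to_json()["reactions"],
            "structures": {mid: m.provenance for mid, m in sorted(self.structures.items())},
            "thermo": dict(self.thermo.items()),
        }

    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "network.json"), "w") as fh:
            json.dump(self.to_json(), fh, indent=1, sort_keys=True)
        with open(os.path.join(outdir, "structures.smi"), "w") as fh:
            for mid, mol in sorted(self.structures.items()):
                fh.write(f"{mol.provenance}\t{mid}\n")
        self.thermo.save(os.path.join(outdir, "thermo.tsv"))


class PlantedGenerationError(RuntimeError):
    pass


def _route_reachable_length(db: ReactionDatabase, source: str, target: str) -> Optional[int]:
    """Exhaustive shortest known-reaction route via breadth-first search.

    Treats every reaction as a conversion between its non-CO2 participants
    (the planted moves are unimolecular up to the CO2 carrier), traversing
    reversible reactions both ways.
    """
    from collections import deque

    adj: Dict[str, List[str]] = {}
    for rxn in db:
        mets = [m for m in rxn.stoich if m != "co2"]
        subs = [m for m in mets if rxn.stoich[m] < 0]
        prods = [m for m in mets if rxn.stoich[m] > 0]
        for s in subs:
            for p in prods:
                adj.setdefault(s, []).append(p)
                if rxn.reversible:
                    adj.setdefault(p, []).append(s)
    seen = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        if v == target:
            return seen[v]
        for w in adj.get(v, []):
            if w not in seen:
                seen[w] = seen[v] + 1
                queue.append(w)
    return seen.get(target)


def planted_network(
    n_mets: int,
    n_rxns: int,
    route_len: int,
    seed: int,
    reversible: bool = True,
    max_retries: int = 20,
) -> PlantedNetwork:
    """Generate a random balanced network with a planted route of exact length.

    The route scaffold carries ``route_len`` carboxyl groups and loses one per
    step down to the bare scaffold (the target); decoys are decarboxylations
    on other scaffolds.  Requires ``route_len <= n_rxns`` and
    ``n_mets >= route_len + 2`` (route metabolites plus CO2).
    """
    if route_len > n_rxns:
        raise PlantedGenerationError("route_len cannot exceed n_rxns")
    if n_mets < route_len + 2:
        raise PlantedGenerationError("need n_mets >= route_len + 2")
    if route_len > 3:
        raise PlantedGenerationError("planted routes support route_len <= 3")
    rng = random.Random(seed)
    for _attempt in range(max_retries):
        cores = _CORES[:]
        rng.shuffle(cores)
        route_core = cores.pop()
        structures: Dict[str, Molecule] = {}
        thermo_vals: Dict[str, float] = {"co2": CO2_DFG}
        db = ReactionDatabase()

        def add_series(core_name: str, core_smiles: str, length: int, tag: str, base_dfg: float) -> List[str]:
            """Molecules core_k .. core_0 and the decarboxylation chain between them."""
            mets = []
            for k in range(length, -1, -1):
                mid = f"{core_name}_{k}" if k else core_name
                if mid not in structures:
                    smi = _core_acid_smiles(core_smiles, k)
                    structures[mid] = parse_structure(smi, "smiles", mol_id=mid)
                    thermo_vals[mid] = base_dfg + 30.0 * k
                mets.append(mid)
            rids = []
            for step, (sub, prod) in enumerate(zip(mets, mets[1:]), start=1):
                rid = f"{tag}{core_name}{step}"
                db.add(
                    Reaction(
                        id=rid,
                        stoich={sub: -1, prod: 1, "co2": 1},
                        reversible=reversible,
                        pathways={tag.rstrip("_") or "route"},
                        organisms={"orgRoute" if tag == "rt_" else "orgDecoy"},
                    )
                )
                rids.append(rid)
            return rids

        base = -50.0 - 10.0 * rng.randrange(8)
        route_ids = add_series(route_core[0], route_core[1], route_len, "rt_", base)
        structures["co2"] = parse_structure(TOY_SMILES["co2"], "smiles", mol_id="co2")

        # decoys on other scaffolds within the metabolite/reaction budget
        decoy_ids: List[str] = []
        rxn_budget = n_rxns - route_len
        met_budget = n_mets - (route_len + 2)
        while rxn_budget > 0 and met_budget >= 2 and cores:
            core = cores.pop()
            length = min(rng.randint(1, 2), rxn_budget, met_budget - 1)
            if length < 1:
                break
            decoy_ids += add_series(core[0], core[1], length, "dk_", base - 5.0 * len(decoy_ids) - 7.0)
            rxn_budget -= length
            met_budget -= length + 1

        source = f"{route_core[0]}_{route_len}" if route_len else route_core[0]
        target = route_core[0]

        # audits: every reaction elementally balanced; route length certified
        balanced = all(
            check_reaction_balance(rxn, structures).balanced for rxn in db
        )
        certified = (
            _route_reachable_length(db, source, target) == route_len if route_len else True
        )
        if balanced and certified:
            net = PlantedNetwork(
                db=db,
                structures=structures,
                thermo=ThermoTable(thermo_vals),
                source=source,
                target=target,
                route=route_ids,
                decoys=decoy_ids,
                seed=seed,
            )
            return net
    raise PlantedGenerationError(
        f"could not generate a certified network for (n_mets={n_mets}, "
        f"n_rxns={n_rxns}, route_len={route_len}, seed={seed})"
    )


def planted_problem(net: PlantedNetwork, **overrides) -> DesignProblem:
    """Default design run on a planted network: 1 source → 1 target, CO2 free."""
    if net.source == net.target:
        defaults = dict(
            lam=1,
            source=net.source,
            target=net.target,
            exchange_bounds={net.source: (0, 0), "co2": (-2, 2)},
            use_thermo=False,
            flux_bound=2,
            objective="min_total_steps",
        )
    else:
        defaults = dict(
            lam=1,
            source=net.source,
            target=net.target,
            exchange_bounds={
                net.source: (-1, -1),
                net.target: (1, 1),
                "co2": (-2 * max(len(net.route), 1), 2 * max(len(net.route), 1)),
            },
            flux_bound=2,
            objective="min_total_steps",
        )
    defaults.update(overrides)
    return DesignProblem(**defaults)
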