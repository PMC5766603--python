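"""Known-reaction network: stoichiometry, annotations, thermodynamics.

The reaction table is consumed in long TSV format (one row per reaction ×
metabolite) or as JSON.  Coefficients are rationals normalized per reaction to
the smallest integer representation, because pathway fluxes downstream are
integers.  Pathway/subsystem and organism/genus annotations are plain label
sets used by the design module's selection constraints.  The thermodynamic
table stores standard transformed formation energies Δ_f G'° in kcal/mol at
pH 7.0 and ionic strength 0.1 M — values are consumed, never computed here.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd, isfinite, lcm
from typing import Dict, Iterator, List, Mapping, Optional, Set

from .chemgraph import Molecule, element_counts


class ReactionLoadError(ValueError):
    pass


@dataclass
class Reaction:
    id: str
    stoich: Dict[str, int]  # metabolite id -> signed integer coefficient
    reversible: bool = False
    pathways: Set[str] = field(default_factory=set)
    organisms: Set[str] = field(default_factory=set)
    transport: bool = False

    def __post_init__(self) -> None:
        signs = {c > 0 for c in self.stoich.values() if c != 0}
        if signs != {True, False}:
            raise ReactionLoadError(
                f"reaction {self.id!r} must consume and produce at least one metabolite"
            )

    @property
    def substrates(self) -> List[str]:
        return sorted(m for m, c in self.stoich.items() if c < 0)

    @property
    def products(self) -> List[str]:
        return sorted(m for m, c in self.stoich.items() if c > 0)


@dataclass
class ReactionDatabase:
    reactions: Dict[str, Reaction] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reactions)

    def __iter__(self) -> Iterator[Reaction]:
        for rid in sorted(self.reactions):
            yield self.reactions[rid]

    def __getitem__(self, rid: str) -> Reaction:
        return self.reactions[rid]

    def add(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ReactionLoadError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn

    @property
    def metabolites(self) -> List[str]:
        mets: Set[str] = set()
        for rxn in self.reactions.values():
            mets.update(rxn.stoich)
        return sorted(mets)

    # -- persistence --------------------------------------------------------

    def to_json(self) -> dict:
        return {
            "reactions": [
                {
                    "id": r.id,
                    "stoich": dict(sorted(r.stoich.items())),
                    "reversible": r.reversible,
                    "pathways": sorted(r.pathways),
                    "organisms": sorted(r.organisms),
                    "transport": r.transport,
                }
                for r in self
            ]
        }

    @classmethod
    def from_json(cls, payload: dict) -> "ReactionDatabase":
        db = cls()
        for r in payload["reactions"]:
            db.add(
                Reaction(
                    id=r["id"],
                    stoich={m: int(c) for m, c in r["stoich"].items()},
                    reversible=bool(r.get("reversible", False)),
                    pathways=set(r.get("pathways", [])),
                    organisms=set(r.get("organisms", [])),
                    transport=bool(r.get("transport", False)),
                )
            )
        return db

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1, sort_keys=True)


def _normalize_integer(stoich: Mapping[str, Fraction]) -> Dict[str, int]:
    """Scale rational coefficients to the smallest integer representation."""
    denoms = [c.denominator for c in stoich.values() if c != 0]
    scale = lcm(*denoms) if denoms else 1
    ints = {m: int(c * scale) for m, c in stoich.items() if c != 0}
    g = 0
    for v in ints.values():
        g = gcd(g, abs(v))
    if g > 1:
        ints = {m: v // g for m, v in ints.items()}
    return ints


def load_reactions(path: str) -> ReactionDatabase:
    """Load a long-format reaction table.

    ``.json`` files use :meth:`ReactionDatabase.from_json`; anything else is
    read as TSV with required columns ``reaction``, ``metabolite``,
    ``coefficient``, ``reversible`` and optional ``pathways``, ``organisms``
    (comma-separated) and ``transport``.  Zero coefficients and duplicate
    (reaction, metabolite) rows are load errors, reported with row numbers.
    """
    if path.endswith(".json"):
        with open(path) as fh:
            return ReactionDatabase.from_json(json.load(fh))
    rows: Dict[str, Dict[str, Fraction]] = {}
    meta: Dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"reaction", "metabolite", "coefficient", "reversible"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ReactionLoadError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            rid = (row["reaction"] or "").strip()
            met = (row["metabolite"] or "").strip()
            if not rid or not met:
                raise ReactionLoadError(f"{path}:{lineno}: empty reaction/metabolite id")
            try:
                coef = Fraction(row["coefficient"].strip())
            except (ValueError, ZeroDivisionError, AttributeError):
                raise ReactionLoadError(
                    f"{path}:{lineno}: non-numeric coefficient {row['coefficient']!r}"
                ) from None
            if coef == 0:
                raise ReactionLoadError(f"{path}:{lineno}: zero coefficient for {met!r}")
            stoich = rows.setdefault(rid, {})
            if met in stoich:
                raise ReactionLoadError(
                    f"{path}:{lineno}: duplicate metabolite {met!r} in reaction {rid!r}"
                )
            stoich[met] = coef
            info = meta.setdefault(
                rid, {"reversible": False, "pathways": set(), "organisms": set(), "transport": False}
            )
            info["reversible"] = _parse_bool(row["reversible"], path, lineno)
            for col, key in (("pathways", "pathways"), ("organisms", "organisms")):
                if row.get(col):
                    info[key].update(x.strip() for x in row[col].split(",") if x.strip())
            if row.get("transport"):
                info["transport"] = _parse_bool(row["transport"], path, lineno)
    db = ReactionDatabase()
    for rid in sorted(rows):
        db.add(
            Reaction(
                id=rid,
                stoich=_normalize_integer(rows[rid]),
                reversible=meta[rid]["reversible"],
                pathways=meta[rid]["pathways"],
                organisms=meta[rid]["organisms"],
                transport=meta[rid]["transport"],
            )
        )
    return db


def _parse_bool(text: str, path: str, lineno: int) -> bool:
    t = (text or "").strip().lower()
    if t in {"1", "true", "yes", "y"}:
        return True
    if t in {"0", "false", "no", "n", ""}:
        return False
    raise ReactionLoadError(f"{path}:{lineno}: cannot parse boolean {text!r}")


# ---------------------------------------------------------------------------
# Balance audit


@dataclass
class BalanceReport:
    reaction_id: str
    residuals: Dict[str, int]
    missing_structures: List[str]

    @property
    def balanced(self) -> Optional[bool]:
        """True/False when all structures were available, None otherwise."""
        if self.missing_structures:
            return None
        return not self.residuals


def check_reaction_balance(
    rxn: Reaction, structures: Mapping[str, Molecule]
) -> BalanceReport:
    """Per-element residual Σ_i S_ij · element_counts(i); zero vector ⇔ balanced."""
    residuals: Dict[str, int] = {}
    missing: List[str] = []
    for met, coef in sorted(rxn.stoich.items()):
        mol = structures.get(met)
        if mol is None:
            missing.append(met)
            continue
        for elem, cnt in element_counts(mol).items():
            residuals[elem] = residuals.get(elem, 0) + coef * cnt
    return BalanceReport(
        reaction_id=rxn.id,
        residuals={e: v for e, v in sorted(residuals.items()) if v != 0},
        missing_structures=missing,
    )


# ---------------------------------------------------------------------------
# Thermodynamics


class ThermoTable:
    """Metabolite id → Δ_f G'° (kcal/mol, pH 7.0, I = 0.1 M)."""

    def __init__(self, values: Mapping[str, float]):
        for met, v in values.items():
            if not isfinite(v):
                raise ValueError(f"non-finite formation energy for {met!r}")
        self._values = dict(values)

    def __contains__(self, met: str) -> bool:
        return met in self._values

    def __getitem__(self, met: str) -> float:
        return self._values[met]

    def get(self, met: str, default: Optional[float] = None) -> Optional[float]:
        return self._values.get(met, default)

    def items(self):
        return sorted(self._values.items())

    @classmethod
    def load(cls, path: str) -> "ThermoTable":
        values: Dict[str, float] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            for lineno, row in enumerate(reader, start=1):
                if not row or row[0].startswith("#"):
                    continue
                if len(row) < 2:
                    raise ReactionLoadError(f"{path}:{lineno}: expected 'metabolite\\tvalue'")
                if lineno == 1 and row[0].strip().lower() in {"metabolite", "met", "id"}:
                    continue
                try:
                    values[row[0].strip()] = float(row[1])
                except ValueError:
                    raise ReactionLoadError(
                        f"{path}:{lineno}: non-numeric formation energy {row[1]!r}"
                    ) from None
        return cls(values)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("metabolite\tdfG_prime_kcal\n")
            for met, v in self.items():
                fh.write(f"{met}\t{v}\n")


def overall_deltaG(exchange_fluxes: Mapping[str, int], thermo: ThermoTable) -> float:
    """Overall standard Gibbs energy change Σ_i Δ_f G'°_i · v^EX_i in kcal.

    Every metabolite with nonzero exchange flux must have a formation energy —
    a missing entry is an error, never assumed zero.
    """
    total = 0.0
    for met, flux in sorted(exchange_fluxes.items()):
        if flux == 0:
            continue
        if met not in thermo:
            raise KeyError(f"no formation energy for exchanged metabolite {met!r}")
        total += thermo[met] * flux
    return total
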