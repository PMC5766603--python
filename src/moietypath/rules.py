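"""Reaction rules: net moiety changes of a reaction, deduplicated into a rule set.

A rule T^λ is the stoichiometry-weighted sum of participant signatures,
T^λ_m = Σ_i S_ij · C^λ_mi, with zero entries dropped.  Because every atom is the
center of exactly one moiety and the source reaction is elementally balanced,
the rule is elementally balanced too: for each element, summing (change ×
center-element indicator) over moieties gives zero.  Two reactions that induce
the same change map at a given λ are the same rule; the unique set R^λ is what
the pathway-design MILP searches alongside known reactions.  Every rule is
treated as reversible by default (directions can be pinned per design run).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from .signatures import MoietyLabel, MolecularSignature, PrimeRegistry


class RuleDerivationError(ValueError):
    pass


@dataclass
class ReactionRule:
    """Sparse integer vector of net moiety changes, elementally balanced."""

    id: str
    lam: int
    changes: Dict[MoietyLabel, int]
    member_reactions: List[str] = field(default_factory=list)
    reversible: bool = True

    def element_residuals(self) -> Dict[str, int]:
        """Per-element residual of the rule (zero map ⇔ balanced)."""
        res: Dict[str, int] = {}
        for label, change in self.changes.items():
            res[label.element] = res.get(label.element, 0) + change
        return {e: v for e, v in res.items() if v != 0}

    def is_balanced(self) -> bool:
        return not self.element_residuals()

    def negated(self) -> "ReactionRule":
        return ReactionRule(
            id=f"{self.id}_rev",
            lam=self.lam,
            changes={m: -c for m, c in self.changes.items()},
            member_reactions=list(self.member_reactions),
            reversible=self.reversible,
        )

    def change_key(self) -> Tuple[Tuple[int, int], ...]:
        """Canonical hashable form of the change map (prime, change), sorted."""
        return tuple(sorted((m.prime, c) for m, c in self.changes.items()))


def derive_rule(
    stoich: Mapping[str, int],
    sigs: Mapping[str, MolecularSignature],
    lam: int,
    rule_id: str = "rule",
    reaction_id: Optional[str] = None,
) -> ReactionRule:
    """Derive the rule of one reaction from its stoichiometry and signatures.

    ``stoich`` maps metabolite id → signed coefficient (negative = consumed).
    Raises if a participant lacks a signature at this λ or if the resulting
    rule is not elementally balanced (i.e. the reaction itself was unbalanced —
    such reactions must never enter the rule database).
    """
    changes: Dict[MoietyLabel, int] = {}
    for met, coef in sorted(stoich.items()):
        if coef == 0:
            continue
        sig = sigs.get(met)
        if sig is None:
            raise RuleDerivationError(f"no molecular signature for metabolite {met!r}")
        if sig.lam != lam:
            raise RuleDerivationError(
                f"signature of {met!r} is at λ={sig.lam}, expected λ={lam}"
            )
        for label, count in sig.counts.items():
            changes[label] = changes.get(label, 0) + coef * count
    changes = {m: c for m, c in changes.items() if c != 0}
    rule = ReactionRule(
        id=rule_id,
        lam=lam,
        changes=changes,
        member_reactions=[reaction_id] if reaction_id else [],
    )
    residuals = rule.element_residuals()
    if residuals:
        raise RuleDerivationError(
            f"reaction {reaction_id or rule_id!r} is not elementally balanced "
            f"(rule residuals {residuals}); unbalanced reactions are rejected"
        )
    return rule


@dataclass
class RuleSet:
    """Unique rules R^λ plus the reaction→rule mapping and per-reaction errors."""

    lam: int
    rules: List[ReactionRule]
    reaction_to_rule: Dict[str, str]
    errors: Dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rules)

    def by_id(self, rule_id: str) -> ReactionRule:
        for r in self.rules:
            if r.id == rule_id:
                return r
        raise KeyError(rule_id)

    # -- persistence --------------------------------------------------------

    def to_json(self) -> dict:
        return {
            "lambda": self.lam,
            "rules": [
                {
                    "id": r.id,
                    "lambda": r.lam,
                    "reversible": r.reversible,
                    "changes": [
                        {
                            "prime": m.prime,
                            "element": m.element,
                            "charge": m.charge,
                            "orders": list(m.orders),
                            "change": c,
                        }
                        for m, c in sorted(r.changes.items())
                    ],
                    "member_reactions": sorted(r.member_reactions),
                }
                for r in self.rules
            ],
            "reaction_to_rule": dict(sorted(self.reaction_to_rule.items())),
            "errors": dict(sorted(self.errors.items())),
        }

    @classmethod
    def from_json(cls, payload: dict) -> "RuleSet":
        lam = payload["lambda"]
        rules = [
            ReactionRule(
                id=r["id"],
                lam=r["lambda"],
                reversible=r["reversible"],
                changes={
                    MoietyLabel(
                        lam=r["lambda"],
                        prime=ch["prime"],
                        element=ch["element"],
                        charge=ch["charge"],
                        orders=tuple(ch.get("orders", [])),
                    ): ch["change"]
                    for ch in r["changes"]
                },
                member_reactions=list(r["member_reactions"]),
            )
            for r in payload["rules"]
        ]
        return cls(
            lam=lam,
            rules=rules,
            reaction_to_rule=dict(payload["reaction_to_rule"]),
            errors=dict(payload.get("errors", {})),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "RuleSet":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


def extract_rules(
    reactions: Iterable,
    sigs: Mapping[str, MolecularSignature],
    lam: int,
) -> RuleSet:
    """Derive and deduplicate rules for a whole reaction database.

    Transport reactions are skipped; per-reaction failures (missing structures,
    unbalanced stoichiometry) are collected in ``errors`` and the run continues.
    Rule ids ``R1..Rn`` are assigned deterministically by sorting the distinct
    change maps, so shuffling the database yields the same rule set.
    """
    per_reaction: Dict[str, ReactionRule] = {}
    errors: Dict[str, str] = {}
    for rxn in reactions:
        if getattr(rxn, "transport", False):
            continue
        try:
            per_reaction[rxn.id] = derive_rule(
                rxn.stoich, sigs, lam, rule_id=rxn.id, reaction_id=rxn.id
            )
        except RuleDerivationError as exc:
            errors[rxn.id] = str(exc)
    grouped: Dict[Tuple[Tuple[int, int], ...], List[str]] = {}
    for rid in sorted(per_reaction):
        grouped.setdefault(per_reaction[rid].change_key(), []).append(rid)
    rules: List[ReactionRule] = []
    reaction_to_rule: Dict[str, str] = {}
    for k, key in enumerate(sorted(grouped), start=1):
        members = grouped[key]
        template = per_reaction[members[0]]
        rule = ReactionRule(
            id=f"R{k}",
            lam=lam,
            changes=dict(template.changes),
            member_reactions=list(members),
            reversible=True,
        )
        rules.append(rule)
        for rid in members:
            reaction_to_rule[rid] = rule.id
    return RuleSet(lam=lam, rules=rules, reaction_to_rule=reaction_to_rule, errors=errors)
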