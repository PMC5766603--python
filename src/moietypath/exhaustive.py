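"""Exhaustive enumeration of feasible designs on small networks.

This is a reference checker, deliberately independent of the MILP: it walks
every integer step-flux vector within bounds, derives the imbalance fluxes by
direct stoichiometric summation, solves the moiety balance for the exchange
fluxes by exact linear algebra, and filters on bounds, caps, annotations and
thermodynamics with plain integer arithmetic.  On networks small enough to
enumerate (a handful of steps, |flux| ≤ 2) its feasible-design set must match
what the MILP enumeration finds — that equivalence is asserted in the test
suite and at planted-network generation time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Set, Tuple

import numpy as np

from .design import DesignProblem
from .reactiondb import ReactionDatabase, ThermoTable
from .rules import RuleSet
from .signatures import MolecularSignature

Pattern = Tuple[Tuple[str, int], ...]


@dataclass
class ExhaustiveResult:
    feasible: List[Dict[str, Dict[str, int]]]
    patterns: Set[Pattern]
    min_steps: Optional[int]


def _allowed_range(
    step_id: str,
    db: ReactionDatabase,
    rules: RuleSet,
    problem: DesignProblem,
) -> Tuple[int, int]:
    b = problem.flux_bound
    if step_id in db.reactions:
        rxn = db.reactions[step_id]
        fwd, bwd = True, rxn.reversible
        pathways, organisms = rxn.pathways, rxn.organisms
    else:
        rule = rules.by_id(step_id)
        fwd, bwd = True, rule.reversible
        pathways, organisms = set(), set()
        for rid in rule.member_reactions:
            if rid in db.reactions:
                pathways |= db.reactions[rid].pathways
                organisms |= db.reactions[rid].organisms
    override = problem.direction_overrides.get(step_id)
    if override == "+":
        fwd, bwd = True, False
    elif override == "-":
        fwd, bwd = False, True
    elif override == "both":
        fwd, bwd = True, True
    elif override == "off":
        fwd, bwd = False, False
    if problem.organism_select is not None and not (organisms & problem.organism_select):
        fwd, bwd = False, False
    if problem.pathway_select is not None and not (pathways & problem.pathway_select):
        fwd, bwd = False, False
    return (-b if bwd else 0), (b if fwd else 0)


def enumerate_designs(
    db: ReactionDatabase,
    rules: RuleSet,
    sigs: Mapping[str, MolecularSignature],
    problem: DesignProblem,
    thermo: Optional[ThermoTable] = None,
    chunk: int = 200_000,
    max_combos: int = 30_000_000,
) -> ExhaustiveResult:
    """Enumerate every feasible (v_j, v_r, v^EX) assignment within bounds.

    The exchange fluxes are uniquely determined by the moiety balance for a
    given step-flux vector whenever the exchange signature matrix has full
    column rank; rank deficiency raises, since the enumeration would then be
    incomplete.
    """
    rxn_ids = sorted(db.reactions)
    rule_ids = sorted(r.id for r in rules.rules)
    step_ids = rxn_ids + rule_ids
    ex_mets = problem.exchange_metabolites
    known_mets = db.metabolites

    moieties = set()
    for met in set(known_mets) | set(ex_mets):
        moieties.update(sigs[met].counts)
    for rule in rules.rules:
        moieties.update(rule.changes)
    moieties = sorted(moieties)
    m_index = {m: k for k, m in enumerate(moieties)}

    S = np.zeros((len(known_mets), len(rxn_ids)), dtype=np.int64)
    for j, rid in enumerate(rxn_ids):
        for met, c in db.reactions[rid].stoich.items():
            S[known_mets.index(met), j] = c
    C_I = np.zeros((len(moieties), len(known_mets)), dtype=np.int64)
    for i, met in enumerate(known_mets):
        for label, c in sigs[met].counts.items():
            C_I[m_index[label], i] = c
    T = np.zeros((len(moieties), len(rule_ids)), dtype=np.int64)
    rule_by_id = {r.id: r for r in rules.rules}
    for r, rid in enumerate(rule_ids):
        for label, c in rule_by_id[rid].changes.items():
            T[m_index[label], r] = c
    C_ex = np.zeros((len(moieties), len(ex_mets)), dtype=np.int64)
    for i, met in enumerate(ex_mets):
        for label, c in sigs[met].counts.items():
            C_ex[m_index[label], i] = c
    if ex_mets and np.linalg.matrix_rank(C_ex.astype(float)) < len(ex_mets):
        raise ValueError(
            "exchange signature matrix is rank-deficient; exhaustive enumeration "
            "cannot uniquely reconstruct exchange fluxes"
        )
    pinv = np.linalg.pinv(C_ex.astype(float)) if ex_mets else None

    ranges = [
        np.arange(lo, hi + 1, dtype=np.int64)
        for lo, hi in (_allowed_range(sid, db, rules, problem) for sid in step_ids)
    ]
    n_combos = int(np.prod([len(r) for r in ranges])) if ranges else 1
    if n_combos > max_combos:
        raise ValueError(f"{n_combos} flux combinations exceed the enumeration cap")

    ex_lb = np.array([problem.exchange_bounds[m][0] for m in ex_mets], dtype=np.int64)
    ex_ub = np.array([problem.exchange_bounds[m][1] for m in ex_mets], dtype=np.int64)
    dg = None
    if problem.use_thermo:
        if thermo is None:
            raise ValueError("thermodynamic filtering requested but no table given")
        dg = np.array([thermo[m] for m in ex_mets])

    # rule-layer handoff bookkeeping: rho_i = v_ex_i - v_imb_i over all metabolites
    union_mets = sorted(set(known_mets) | set(ex_mets))
    E_map = np.zeros((len(union_mets), len(ex_mets)), dtype=np.int64)
    K_map = np.zeros((len(union_mets), len(known_mets)), dtype=np.int64)
    for u, met in enumerate(union_mets):
        if met in ex_mets:
            E_map[u, ex_mets.index(met)] = 1
        if met in known_mets:
            K_map[u, known_mets.index(met)] = 1

    n_rxn = len(rxn_ids)
    feasible: List[Dict[str, Dict[str, int]]] = []
    patterns: Set[Pattern] = set()
    min_steps: Optional[int] = None

    def _emit(V: np.ndarray, X: np.ndarray) -> None:
        nonlocal min_steps
        for v_row, x_row in zip(V, X):
            v_known = {rid: int(v_row[j]) for j, rid in enumerate(rxn_ids)}
            v_rules = {rid: int(v_row[n_rxn + r]) for r, rid in enumerate(rule_ids)}
            v_ex = {met: int(x_row[i]) for i, met in enumerate(ex_mets)}
            feasible.append({"v_known": v_known, "v_rules": v_rules, "v_ex": v_ex})
            pattern = tuple(
                sorted(
                    [(sid, 1 if v > 0 else -1) for sid, v in {**v_known, **v_rules}.items() if v]
                )
            )
            patterns.add(pattern)
            steps = len(pattern)
            if min_steps is None or steps < min_steps:
                min_steps = steps

    # chunked cartesian product over step fluxes
    sizes = [len(r) for r in ranges]
    total = n_combos
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total))
        V = np.zeros((len(idx), len(step_ids)), dtype=np.int64)
        rem = idx.copy()
        for col in range(len(step_ids) - 1, -1, -1):
            V[:, col] = ranges[col][rem % sizes[col]]
            rem //= sizes[col]
        IMB = V[:, :n_rxn] @ S.T if n_rxn else np.zeros((len(idx), len(known_mets)), dtype=np.int64)
        B = IMB @ C_I.T
        if rule_ids:
            B = B + V[:, n_rxn:] @ T.T
        if ex_mets:
            X = np.rint(B @ pinv.T).astype(np.int64)
            ok = np.all(X @ C_ex.T == B, axis=1)
            ok &= np.all((X >= ex_lb) & (X <= ex_ub), axis=1)
        else:
            X = np.zeros((len(idx), 0), dtype=np.int64)
            ok = np.all(B == 0, axis=1)
        # without an active rule step, the rule layer may not hand off anything
        rho = X @ E_map.T - IMB @ K_map.T
        rules_active = (
            np.any(V[:, n_rxn:] != 0, axis=1) if rule_ids else np.zeros(len(idx), dtype=bool)
        )
        ok &= rules_active | np.all(rho == 0, axis=1)
        nz = V != 0
        steps = nz.sum(axis=1)
        if problem.max_steps is not None:
            ok &= steps <= problem.max_steps
        if problem.max_rules is not None:
            ok &= nz[:, n_rxn:].sum(axis=1) <= problem.max_rules
        if dg is not None and ex_mets:
            ok &= (X @ dg) <= -problem.deltaG_epsilon
        if np.any(ok):
            _emit(V[ok], X[ok])

    return ExhaustiveResult(feasible=feasible, patterns=patterns, min_steps=min_steps)
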