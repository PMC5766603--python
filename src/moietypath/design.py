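"""Pathway design as a mixed-integer linear program.

The designed conversion is described by four integer flux families:

* ``v_j`` — flux through known reaction *j* (signed if reversible);
* ``v_r`` — flux through de novo rule *r* (rules are reversible by default);
* ``v^imb_i = Σ_j S_ij v_j`` — net production of metabolite *i* by the known
  network: the linkage variable handing surplus/deficit over to the rule
  network (component balance);
* ``v^EX_i`` — net export (+) or uptake (−) of exchange metabolite *i* across
  the whole conversion.

The moiety balance ties them together for every moiety *m* at the chosen λ:

    Σ_{i∈I_ex} C^λ_mi v^EX_i  =  Σ_{r∈R^λ} T^λ_mr v_r  +  Σ_{i∈I} C^λ_mi v^imb_i

so that every moiety consumed somewhere is produced somewhere, whether by a
cataloged reaction or a novel rule step.  A linkage family keeps the rule
layer honest: the per-metabolite handoff ρ_i = v^EX_i − v^imb_i may be nonzero
only while at least one rule step is active (otherwise coarse moiety vectors
would let an idle rule network transmute metabolites whose moiety sums happen
to coincide).  Thermodynamic feasibility is imposed
on the exchange fluxes, Σ_i Δ_f G'°_i v^EX_i ≤ −ε.  Each step carries a pair of
direction binaries linked to the split flux by big-M rows in both directions, so
step counts, step caps, organism/pathway selection and integer-cut enumeration
of alternatives are all linear.

Solved with HiGHS through :func:`scipy.optimize.milp`.  All reported solutions
are re-validated with exact integer arithmetic, independent of the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import LinearConstraint, Bounds, milp

from .chemgraph import Molecule, element_counts
from .reactiondb import ReactionDatabase, ThermoTable, overall_deltaG
from .rules import RuleSet
from .signatures import MolecularSignature

OBJECTIVES = ("min_total_steps", "min_rules", "max_profit")


class ModelBuildError(ValueError):
    pass


@dataclass
class DesignProblem:
    """Configuration of one pathway-design run.

    ``exchange_bounds`` lists the allowed exchange metabolites with integer
    (lb, ub) on v^EX in mol per mol of designed conversion; metabolites absent
    from it are sealed (v^EX = 0).  The source defaults to (−flux_bound, −1)
    and the target to (+1, flux_bound) when no explicit bounds are given.
    ``organism_select`` / ``pathway_select`` of ``None`` means the respective
    selection mode is off; a set (possibly empty) activates it: a step is then
    usable only if it carries at least one selected annotation (rules inherit
    the union of their member reactions' annotations).
    """

    lam: int
    source: str
    target: str
    exchange_bounds: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    prices: Optional[Dict[str, float]] = None
    max_steps: Optional[int] = None
    max_rules: Optional[int] = None
    banned_exchanges: Set[str] = field(default_factory=set)
    organism_select: Optional[Set[str]] = None
    pathway_select: Optional[Set[str]] = None
    use_thermo: bool = True
    deltaG_epsilon: float = 0.5
    objective: str = "min_total_steps"
    flux_bound: int = 10
    # step id -> "+" | "-" | "both" | "off": pin or free a direction
    direction_overrides: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVES:
            raise ValueError(f"objective must be one of {OBJECTIVES}")
        if self.deltaG_epsilon <= 0:
            raise ValueError("deltaG_epsilon must be positive")
        if self.flux_bound < 1:
            raise ValueError("flux_bound must be >= 1")
        self.exchange_bounds = dict(self.exchange_bounds)
        self.exchange_bounds.setdefault(self.source, (-self.flux_bound, -1))
        self.exchange_bounds.setdefault(self.target, (1, self.flux_bound))
        for met, (lb, ub) in self.exchange_bounds.items():
            if lb > ub:
                raise ValueError(f"exchange bounds for {met!r} have lb > ub")
        for met in self.banned_exchanges:
            self.exchange_bounds[met] = (0, 0)

    @property
    def exchange_metabolites(self) -> List[str]:
        return sorted(self.exchange_bounds)


@dataclass
class PathwaySolution:
    """One balanced design: integer fluxes plus derived bookkeeping."""

    v_known: Dict[str, int]
    v_rules: Dict[str, int]
    v_imb: Dict[str, int]
    v_ex: Dict[str, int]
    objective_value: float
    deltaG_overall: Optional[float]
    step_count: int
    rule_count: int

    def active_steps(self) -> List[Tuple[str, int]]:
        """(step id, direction ±1) pairs of the steps in use, sorted by id."""
        out = [(j, 1 if v > 0 else -1) for j, v in self.v_known.items() if v != 0]
        out += [(r, 1 if v > 0 else -1) for r, v in self.v_rules.items() if v != 0]
        return sorted(out)

    def is_empty(self) -> bool:
        return self.step_count == 0 and all(v == 0 for v in self.v_ex.values())


class DesignModel:
    """Assembled MILP plus the bookkeeping needed for enumeration/validation."""

    def __init__(
        self,
        problem: DesignProblem,
        db: ReactionDatabase,
        rules: RuleSet,
        sigs: Mapping[str, MolecularSignature],
        thermo: Optional[ThermoTable],
    ):
        self.problem = problem
        self.db = db
        self.rules = rules
        self.sigs = sigs
        self.thermo = thermo
        self.reaction_ids: List[str] = sorted(db.reactions)
        self.rule_ids: List[str] = sorted(r.id for r in rules.rules)
        self.step_ids: List[str] = self.reaction_ids + self.rule_ids
        self.known_mets: List[str] = db.metabolites
        self.ex_mets: List[str] = problem.exchange_metabolites
        self._cuts: List[Tuple[np.ndarray, float]] = []
        self._build()

    # -- variable layout ----------------------------------------------------
    # per step s: [p_s, n_s, dp_s, dn_s]; then v_imb per known metabolite;
    # then v_ex per exchange metabolite.

    def _p(self, s: int) -> int:
        return 4 * s

    def _n(self, s: int) -> int:
        return 4 * s + 1

    def _dp(self, s: int) -> int:
        return 4 * s + 2

    def _dn(self, s: int) -> int:
        return 4 * s + 3

    def _imb(self, k: int) -> int:
        return 4 * len(self.step_ids) + k

    def _ex(self, k: int) -> int:
        return 4 * len(self.step_ids) + len(self.known_mets) + k

    @property
    def n_vars(self) -> int:
        return 4 * len(self.step_ids) + len(self.known_mets) + len(self.ex_mets)

    # -- construction -------------------------------------------------------

    def _step_allowed_directions(self, step_id: str) -> Tuple[bool, bool]:
        """(forward allowed, backward allowed) after reversibility + overrides
        + annotation selection."""
        if step_id in self.db.reactions:
            rxn = self.db.reactions[step_id]
            fwd, bwd = True, rxn.reversible
            pathways, organisms = rxn.pathways, rxn.organisms
        else:
            rule = self.rules.by_id(step_id)
            fwd, bwd = True, rule.reversible
            pathways: Set[str] = set()
            organisms: Set[str] = set()
            for rid in rule.member_reactions:
                if rid in self.db.reactions:
                    pathways |= self.db.reactions[rid].pathways
                    organisms |= self.db.reactions[rid].organisms
        override = self.problem.direction_overrides.get(step_id)
        if override == "+":
            fwd, bwd = True, False
        elif override == "-":
            fwd, bwd = False, True
        elif override == "both":
            fwd, bwd = True, True
        elif override == "off":
            fwd, bwd = False, False
        if self.problem.organism_select is not None and not (
            organisms & self.problem.organism_select
        ):
            fwd, bwd = False, False
        if self.problem.pathway_select is not None and not (
            pathways & self.problem.pathway_select
        ):
            fwd, bwd = False, False
        return fwd, bwd

    def _build(self) -> None:
        prob = self.problem
        if self.rules.lam != prob.lam:
            raise ModelBuildError(
                f"rule set is at λ={self.rules.lam}, design asks λ={prob.lam}"
            )
        needed = set(self.known_mets) | set(self.ex_mets)
        for met in sorted(needed):
            sig = self.sigs.get(met)
            if sig is None:
                raise ModelBuildError(f"no molecular signature for metabolite {met!r}")
            if sig.lam != prob.lam:
                raise ModelBuildError(
                    f"signature of {met!r} at λ={sig.lam}, design asks λ={prob.lam}"
                )
        if prob.use_thermo:
            if self.thermo is None:
                raise ModelBuildError("thermodynamic constraint enabled but no table given")
            for met in self.ex_mets:
                if met not in self.thermo:
                    raise ModelBuildError(f"no formation energy for exchange metabolite {met!r}")
        M = prob.flux_bound
        nS = len(self.step_ids)

        lb = np.zeros(self.n_vars)
        ub = np.zeros(self.n_vars)
        for s, sid in enumerate(self.step_ids):
            fwd, bwd = self._step_allowed_directions(sid)
            ub[self._p(s)] = M if fwd else 0
            ub[self._n(s)] = M if bwd else 0
            ub[self._dp(s)] = 1 if fwd else 0
            ub[self._dn(s)] = 1 if bwd else 0
        for k, met in enumerate(self.known_mets):
            cap = M * sum(
                abs(self.db.reactions[rid].stoich.get(met, 0)) for rid in self.reaction_ids
            )
            lb[self._imb(k)], ub[self._imb(k)] = -cap, cap
        for k, met in enumerate(self.ex_mets):
            lo, hi = prob.exchange_bounds[met]
            lb[self._ex(k)], ub[self._ex(k)] = lo, hi
        self.bounds = Bounds(lb, ub)

        rows: List[np.ndarray] = []
        row_lb: List[float] = []
        row_ub: List[float] = []

        def add_row(coefs: Mapping[int, float], lo: float, hi: float) -> None:
            row = np.zeros(self.n_vars)
            for idx, c in coefs.items():
                row[idx] += c
            rows.append(row)
            row_lb.append(lo)
            row_ub.append(hi)

        # component balance: v_imb_i - sum_j S_ij (p_j - n_j) = 0
        for k, met in enumerate(self.known_mets):
            coefs: Dict[int, float] = {self._imb(k): 1.0}
            for s, rid in enumerate(self.reaction_ids):
                S = self.db.reactions[rid].stoich.get(met, 0)
                if S:
                    coefs[self._p(s)] = coefs.get(self._p(s), 0.0) - S
                    coefs[self._n(s)] = coefs.get(self._n(s), 0.0) + S
            add_row(coefs, 0.0, 0.0)

        # moiety balance rows: union of moieties over signatures and rules
        moieties = set()
        for met in needed:
            moieties.update(self.sigs[met].counts)
        for rule in self.rules.rules:
            moieties.update(rule.changes)
        self.moieties = sorted(moieties)
        rule_by_id = {r.id: r for r in self.rules.rules}
        for m in self.moieties:
            coefs = {}
            for k, met in enumerate(self.ex_mets):
                c = self.sigs[met].counts.get(m, 0)
                if c:
                    coefs[self._ex(k)] = coefs.get(self._ex(k), 0.0) + c
            for s, rid in enumerate(self.rule_ids, start=len(self.reaction_ids)):
                T = rule_by_id[rid].changes.get(m, 0)
                if T:
                    coefs[self._p(s)] = coefs.get(self._p(s), 0.0) - T
                    coefs[self._n(s)] = coefs.get(self._n(s), 0.0) + T
            for k, met in enumerate(self.known_mets):
                c = self.sigs[met].counts.get(m, 0)
                if c:
                    coefs[self._imb(k)] = coefs.get(self._imb(k), 0.0) - c
            if coefs:
                add_row(coefs, 0.0, 0.0)

        # rule-layer activity linkage: the per-metabolite handoff to the rule
        # network, rho_i = v_ex_i - v_imb_i, must vanish when no rule step is
        # active.  Without it, coarse moiety vectors (notably at λ=1) admit
        # degenerate designs in which the idle rule network silently
        # transmutes metabolites whose moiety sums happen to coincide.
        known_index = {met: k for k, met in enumerate(self.known_mets)}
        rule_steps = range(len(self.reaction_ids), nS)
        for met in sorted(set(self.known_mets) | set(self.ex_mets)):
            coefs_hi: Dict[int, float] = {}
            cap = M * (
                1
                + sum(
                    abs(self.db.reactions[rid].stoich.get(met, 0))
                    for rid in self.reaction_ids
                )
            )
            if met in prob.exchange_bounds:
                coefs_hi[self._ex(self.ex_mets.index(met))] = 1.0
            if met in known_index:
                coefs_hi[self._imb(known_index[met])] = -1.0
            coefs_lo = {idx: -c for idx, c in coefs_hi.items()}
            for s in rule_steps:
                coefs_hi[self._dp(s)] = coefs_hi.get(self._dp(s), 0.0) - cap
                coefs_hi[self._dn(s)] = coefs_hi.get(self._dn(s), 0.0) - cap
                coefs_lo[self._dp(s)] = coefs_lo.get(self._dp(s), 0.0) - cap
                coefs_lo[self._dn(s)] = coefs_lo.get(self._dn(s), 0.0) - cap
            add_row(coefs_hi, -np.inf, 0.0)  # rho_i <= cap * sum(y_r)
            add_row(coefs_lo, -np.inf, 0.0)  # -rho_i <= cap * sum(y_r)

        # indicator linkage in both directions: dp <= p <= M dp (same for n)
        for s in range(nS):
            add_row({self._p(s): 1.0, self._dp(s): -M}, -np.inf, 0.0)
            add_row({self._n(s): 1.0, self._dn(s): -M}, -np.inf, 0.0)
            add_row({self._dp(s): 1.0, self._p(s): -1.0}, -np.inf, 0.0)
            add_row({self._dn(s): 1.0, self._n(s): -1.0}, -np.inf, 0.0)
            add_row({self._dp(s): 1.0, self._dn(s): 1.0}, -np.inf, 1.0)

        # thermodynamic feasibility on exchange fluxes
        if prob.use_thermo:
            coefs = {
                self._ex(k): self.thermo[met]
                for k, met in enumerate(self.ex_mets)
            }
            add_row(coefs, -np.inf, -prob.deltaG_epsilon)

        # caps
        if prob.max_rules is not None:
            coefs = {}
            for s in range(len(self.reaction_ids), nS):
                coefs[self._dp(s)] = 1.0
                coefs[self._dn(s)] = 1.0
            add_row(coefs, -np.inf, float(prob.max_rules))
        if prob.max_steps is not None:
            coefs = {}
            for s in range(nS):
                coefs[self._dp(s)] = 1.0
                coefs[self._dn(s)] = 1.0
            add_row(coefs, -np.inf, float(prob.max_steps))

        self._A = np.array(rows) if rows else np.zeros((0, self.n_vars))
        self._row_lb = np.array(row_lb)
        self._row_ub = np.array(row_ub)

        # objective (scipy minimizes)
        c = np.zeros(self.n_vars)
        if prob.objective == "min_total_steps":
            for s in range(nS):
                c[self._dp(s)] = c[self._dn(s)] = 1.0
        elif prob.objective == "min_rules":
            for s in range(len(self.reaction_ids), nS):
                c[self._dp(s)] = c[self._dn(s)] = 1.0
        else:  # max_profit
            if not prob.prices:
                raise ModelBuildError("max_profit objective requires a price map")
            for k, met in enumerate(self.ex_mets):
                if not np.isfinite(self.bounds.lb[self._ex(k)]) or not np.isfinite(
                    self.bounds.ub[self._ex(k)]
                ):
                    raise ModelBuildError(
                        f"max_profit requires finite exchange bounds for {met!r}"
                    )
                c[self._ex(k)] = -float(prob.prices.get(met, 0.0))
        self._c = c

    # -- enumeration --------------------------------------------------------

    def add_pattern_cut(self, pattern: Mapping[str, int]) -> None:
        """Exclude the exact active (step, direction) set of a found solution.

        ``pattern`` maps step id → ±1 for active steps.  The cut
        Σ_{active} d − Σ_{inactive} d ≤ |active| − 1 removes only assignments
        whose direction binaries match the pattern exactly, so the same step
        set used in a different direction — and any strict superset — remains
        a distinct discoverable solution.
        """
        row = np.zeros(self.n_vars)
        n_active = 0
        for s, sid in enumerate(self.step_ids):
            d = pattern.get(sid, 0)
            if d > 0:
                row[self._dp(s)] = 1.0
                row[self._dn(s)] = -1.0
                n_active += 1
            elif d < 0:
                row[self._dn(s)] = 1.0
                row[self._dp(s)] = -1.0
                n_active += 1
            else:
                row[self._dp(s)] = -1.0
                row[self._dn(s)] = -1.0
        self._cuts.append((row, float(n_active - 1)))

    def _solve_once(self, time_limit: Optional[float]):
        A = self._A
        lo, hi = self._row_lb, self._row_ub
        if self._cuts:
            A = np.vstack([A] + [r for r, _ in self._cuts])
            lo = np.concatenate([lo, np.full(len(self._cuts), -np.inf)])
            hi = np.concatenate([hi, np.array([u for _, u in self._cuts])])
        constraints = LinearConstraint(A, lo, hi) if A.shape[0] else ()
        options = {"presolve": True}
        if time_limit is not None:
            options["time_limit"] = time_limit
        return milp(
            c=self._c,
            constraints=constraints,
            integrality=np.ones(self.n_vars),
            bounds=self.bounds,
            options=options,
        )

    def _extract(self, x: np.ndarray) -> PathwaySolution:
        xi = np.rint(x).astype(int)
        v_known = {
            rid: int(xi[self._p(s)] - xi[self._n(s)])
            for s, rid in enumerate(self.reaction_ids)
        }
        v_rules = {
            rid: int(xi[self._p(s)] - xi[self._n(s)])
            for s, rid in enumerate(self.rule_ids, start=len(self.reaction_ids))
        }
        v_imb = {met: int(xi[self._imb(k)]) for k, met in enumerate(self.known_mets)}
        v_ex = {met: int(xi[self._ex(k)]) for k, met in enumerate(self.ex_mets)}
        step_count = sum(1 for v in v_known.values() if v) + sum(
            1 for v in v_rules.values() if v
        )
        rule_count = sum(1 for v in v_rules.values() if v)
        dG = overall_deltaG(v_ex, self.thermo) if self.thermo is not None else None
        if self.problem.objective == "max_profit":
            obj = sum(self.problem.prices.get(m, 0.0) * v for m, v in v_ex.items())
        elif self.problem.objective == "min_rules":
            obj = float(rule_count)
        else:
            obj = float(step_count)
        return PathwaySolution(
            v_known=v_known,
            v_rules=v_rules,
            v_imb=v_imb,
            v_ex=v_ex,
            objective_value=obj,
            deltaG_overall=dG,
            step_count=step_count,
            rule_count=rule_count,
        )


def build_model(
    problem: DesignProblem,
    db: ReactionDatabase,
    rules: RuleSet,
    sigs: Mapping[str, MolecularSignature],
    thermo: Optional[ThermoTable] = None,
) -> DesignModel:
    """Assemble the design MILP (see module docstring for the formulation)."""
    return DesignModel(problem, db, rules, sigs, thermo)


def solve_enumerate(
    model: DesignModel,
    k: int = 10,
    time_limit: Optional[float] = None,
) -> List[PathwaySolution]:
    """Enumerate up to ``k`` distinct designs by repeated solving with
    integer cuts over the active (step, direction) pattern.

    Solutions come back in non-worsening objective order (a cut can only
    remove solutions); ties at equal objective are ordered lexicographically by
    their sorted active-step lists for reproducibility across solvers.  An
    infeasible model yields an empty list; the reason is recorded on
    ``model.enumeration_status``.
    """
    solutions: List[PathwaySolution] = []
    model.enumeration_status = "ok"
    while len(solutions) < k:
        res = model._solve_once(time_limit)
        if res.status == 1:  # iteration/time limit
            model.enumeration_status = f"solver timeout: {res.message}"
            break
        if not res.success:
            if not solutions:
                model.enumeration_status = f"infeasible: {res.message}"
            break
        sol = model._extract(res.x)
        report = validate_solution(
            sol, model.db, model.rules, model.sigs, model.thermo, model.problem
        )
        if not report.ok:
            model.enumeration_status = (
                f"solver returned an invalid solution: {report.violations}"
            )
            break
        solutions.append(sol)
        model.add_pattern_cut(dict(sol.active_steps()))
    solutions.sort(key=lambda s: (s.objective_value, s.active_steps()))
    return solutions


# ---------------------------------------------------------------------------
# Independent validation (exact integer arithmetic, no solver involved)


@dataclass
class ValidationReport:
    ok: bool
    violations: List[str]
    component_residuals: Dict[str, int]
    moiety_residuals: Dict[int, int]  # prime -> residual
    deltaG_overall: Optional[float]
    step_count: int
    rule_count: int
    net_element_residuals: Dict[str, int]
    flags: List[str] = field(default_factory=list)


def validate_solution(
    sol: PathwaySolution,
    db: ReactionDatabase,
    rules: RuleSet,
    sigs: Mapping[str, MolecularSignature],
    thermo: Optional[ThermoTable] = None,
    problem: Optional[DesignProblem] = None,
    structures: Optional[Mapping[str, Molecule]] = None,
) -> ValidationReport:
    """Recompute both balance families, the ΔG row and the counts from scratch.

    Violated rows are listed with their residuals; the report never raises.
    """
    violations: List[str] = []
    flags: List[str] = []

    # component balance residual: v_imb_i - sum_j S_ij v_j
    comp_res: Dict[str, int] = {}
    for met in db.metabolites:
        produced = sum(
            db.reactions[rid].stoich.get(met, 0) * v for rid, v in sol.v_known.items()
        )
        r = sol.v_imb.get(met, 0) - produced
        if r != 0:
            comp_res[met] = r
            violations.append(f"component balance of {met!r}: residual {r}")

    # moiety balance residual per moiety
    rule_by_id = {r.id: r for r in rules.rules}
    moiety_res: Dict[int, int] = {}
    acc: Dict[int, int] = {}
    for met, flux in sol.v_ex.items():
        if flux == 0:
            continue
        for label, c in sigs[met].counts.items():
            acc[label.prime] = acc.get(label.prime, 0) + c * flux
    for rid, flux in sol.v_rules.items():
        if flux == 0:
            continue
        for label, t in rule_by_id[rid].changes.items():
            acc[label.prime] = acc.get(label.prime, 0) - t * flux
    for met, flux in sol.v_imb.items():
        if flux == 0:
            continue
        for label, c in sigs[met].counts.items():
            acc[label.prime] = acc.get(label.prime, 0) - c * flux
    for prime, r in sorted(acc.items()):
        if r != 0:
            moiety_res[prime] = r
            violations.append(f"moiety balance of prime {prime}: residual {r}")

    # rule-layer activity: handoffs v_ex - v_imb require an active rule step
    if all(v == 0 for v in sol.v_rules.values()):
        for met in sorted(set(sol.v_ex) | set(sol.v_imb)):
            rho = sol.v_ex.get(met, 0) - sol.v_imb.get(met, 0)
            if rho != 0:
                violations.append(
                    f"rule-layer handoff of {met!r} is {rho} with no active rule step"
                )

    step_count = sum(1 for v in sol.v_known.values() if v) + sum(
        1 for v in sol.v_rules.values() if v
    )
    rule_count = sum(1 for v in sol.v_rules.values() if v)
    if step_count != sol.step_count:
        violations.append(f"step count mismatch: {sol.step_count} vs {step_count}")
    if rule_count != sol.rule_count:
        violations.append(f"rule count mismatch: {sol.rule_count} vs {rule_count}")

    dG: Optional[float] = None
    if thermo is not None:
        try:
            dG = overall_deltaG(sol.v_ex, thermo)
        except KeyError as exc:
            violations.append(str(exc))
        if dG is not None and problem is not None and problem.use_thermo:
            if dG > -problem.deltaG_epsilon:
                violations.append(
                    f"thermodynamic row violated: ΔG = {dG:+.3f} kcal "
                    f"> -ε = {-problem.deltaG_epsilon}"
                )

    net_elem: Dict[str, int] = {}
    if structures is not None:
        for met, flux in sol.v_ex.items():
            if flux == 0 or met not in structures:
                continue
            for e, c in element_counts(structures[met]).items():
                net_elem[e] = net_elem.get(e, 0) + flux * c
        net_elem = {e: v for e, v in net_elem.items() if v != 0}
        if net_elem:
            violations.append(f"net conversion not elementally balanced: {net_elem}")

    if sol.is_empty():
        flags.append("empty design")

    return ValidationReport(
        ok=not violations,
        violations=violations,
        component_residuals=comp_res,
        moiety_residuals=moiety_res,
        deltaG_overall=dG,
        step_count=step_count,
        rule_count=rule_count,
        net_element_residuals=net_elem,
        flags=flags,
    )


def net_conversion(sol: PathwaySolution, target: str) -> Dict[str, Fraction]:
    """Nonzero exchange fluxes normalized so the target's coefficient is +1.

    Scaling all fluxes by an integer leaves the result unchanged.  A zero
    target flux is an error.
    """
    t = sol.v_ex.get(target, 0)
    if t == 0:
        raise ValueError(f"target {target!r} has zero exchange flux")
    return {
        met: Fraction(v, t) for met, v in sorted(sol.v_ex.items()) if v != 0
    }


def format_route(
    sol: PathwaySolution, db: ReactionDatabase, target: str
) -> str:
    """Human-readable route table: known steps by reaction id, novel steps by
    rule id (the R# convention), plus the net conversion."""
    lines = []
    for sid, direction in sol.active_steps():
        if sid in sol.v_known:
            flux = sol.v_known[sid]
            kind = "known"
            rxn = db.reactions[sid]
            arrow = " -> " if flux > 0 else " <- "
            eq = (
                " + ".join(f"{-c} {m}" if c != -1 else m for m, c in sorted(rxn.stoich.items()) if c < 0)
                + arrow
                + " + ".join(f"{c} {m}" if c != 1 else m for m, c in sorted(rxn.stoich.items()) if c > 0)
            )
        else:
            flux = sol.v_rules[sid]
            kind = "rule "
            eq = "(novel step from moiety-change template)"
        lines.append(f"  [{kind}] {sid:12s} v = {flux:+d}   {eq}")
    conv = net_conversion(sol, target)
    left = " + ".join(
        f"{-c} {m}" if c != -1 else m for m, c in sorted(conv.items()) if c < 0
    )
    right = " + ".join(
        f"{c} {m}" if c != 1 else m for m, c in sorted(conv.items()) if c > 0
    )
    dg = "" if sol.deltaG_overall is None else f"   (ΔG'° = {sol.deltaG_overall:+.1f} kcal)"
    lines.append(f"  net: {left} -> {right}{dg}")
    return "\n".join(lines)
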