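"""The coupled two-condition consistency MILP.

Two direction-split copies of the same stoichiometric model — condition 1
("wild") and condition 2 ("mutant") — are solved jointly.  Each omics-derived
differential constraint gets a binary B_i: when B_i = 1 the constraint is
enforced (up to a slack of eps), when B_i = 0 it is relaxed by a big-M term.
The objective maximizes sum(B_i); its optimum is the maximum consistency
score (MCS) for a single data type and the global consistency score (GCS)
when expression and metabolite constraints are combined.

Per regulated reaction i with ratio p (mutant/wild):

    v_i^mut  >= eps * B_i              (basal flux, both conditions)
    v_i^wild >= eps * B_i
    up:   v_i^mut >= p * v_i^wild - eps - (1 - B_i) * M' * max(1, p)
    down: v_i^mut <= p * v_i^wild + eps + (1 - B_i) * M' * max(1, p)

where v_i is the flux magnitude (sum of the split children, one of which is
zero by direction exclusivity).  The relaxation term is scaled by max(1, p)
so that B_i = 0 truly deactivates the up-constraint for any ratio; eps plays
the role of the enforced-state slack.

Per regulated metabolite i with ratio p', the turnover sums
phi_p = sum(producing split fluxes) and phi_c = sum(consuming split fluxes)
(equal at steady state) are constrained through a branch binary Y_i choosing
between the production and consumption alternative, gated by B_i.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import swiglpk as glp
from optlang.glpk_interface import (
    _GLPK_STATUS_TO_STATUS,
    Constraint,
    Model as LPModel,
    Objective,
    Variable,
)

from .model_core import BACKWARD, FORWARD, MetabolicModel, SplitModel, split_reversible
from .omics import RegulationSet
from .thermo import ThermoData

__all__ = [
    "RemiParams",
    "RemiProblem",
    "Solution",
    "MappingError",
    "InfeasibleModelError",
    "SolverError",
    "build_remi_problem",
    "solve_consistency",
    "WILD",
    "MUTANT",
]

logger = logging.getLogger(__name__)

WILD = "wild"
MUTANT = "mutant"
CONDITIONS = (WILD, MUTANT)


class MappingError(KeyError):
    pass


class InfeasibleModelError(RuntimeError):
    pass


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class RemiParams:
    """Numerical parameters of the consistency MILP.

    eps: basal-flux / slack tolerance (flux units); big_M: flux cap on split
    reactions; growth_min: lower bound on both biomass fluxes; eps_thermo:
    strictness of the DrG' sign requirement (kJ/mol); met_form: "mirrored"
    (consumption branch uses the reciprocal ratio and relaxing slack signs)
    or "literal" (ratio and signs exactly as the printed branch form).
    """

    eps: float = 1e-5
    big_M: float = 1000.0
    growth_min: float = 0.1
    eps_thermo: float = 1e-6
    met_form: str = "mirrored"
    solver_timeout: float | None = None

    def __post_init__(self):
        if self.eps <= 0 or self.big_M <= 0:
            raise ValueError("eps and big_M must be positive")
        if self.eps >= self.big_M:
            raise ValueError("eps must be smaller than big_M")
        if self.met_form not in ("mirrored", "literal"):
            raise ValueError(f"unknown met_form {self.met_form!r}")


def _sane(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]", "_", name)


@dataclass
class Solution:
    """Outcome of a consistency maximization."""

    score: int
    active: frozenset[str]
    binaries: dict[str, int]
    status: str
    tmcs: int
    fluxes: dict[str, dict[str, float]] | None = None  # condition -> rxn -> net flux

    def __post_init__(self):
        assert self.score == sum(self.binaries.values())


class RemiProblem:
    """Holds the optlang MILP plus registries mapping semantic ids to variables.

    Constraint ids are ``"rxn:<reaction id>"`` for expression constraints and
    ``"met:<metabolite id>"`` for metabolite constraints.
    """

    def __init__(self, model: MetabolicModel, split: SplitModel, params: RemiParams,
                 regulation: RegulationSet, thermo: ThermoData | None,
                 use_gex: bool, use_met: bool, use_thermo: bool):
        self.model = model
        self.split = split
        self.params = params
        self.regulation = regulation
        self.thermo = thermo
        self.use_gex = use_gex
        self.use_met = use_met
        self.use_thermo = use_thermo
        self.lp = LPModel(name=f"remi_{model.id}")
        # eps (1e-5) must sit well above the solver's integrality/feasibility
        # tolerances or eps-scale basal fluxes can hide behind rounded binaries;
        # GLPK's MIP presolver rounds away implied binary bounds of order
        # eps/M', so it must stay off (the exact branch-and-bound remains)
        self.lp.configuration.presolve = False
        # feasibility stays at the simplex default: tightening it below 1e-7
        # makes GLPK's branch-and-bound prune feasible nodes as infeasible
        self.lp.configuration.tolerances.feasibility = 1e-7
        self.lp.configuration.tolerances.integrality = 1e-9
        if params.solver_timeout is not None:
            self.lp.configuration.timeout = params.solver_timeout
        self.v: dict[tuple[str, str], Variable] = {}
        self.z: dict[tuple[str, str], Variable] = {}
        self.B: dict[str, Variable] = {}
        self.Y: dict[str, Variable] = {}
        self.lnx: dict[tuple[str, str], Variable] = {}
        self.constraint_ratio: dict[str, float] = {}
        self.constraint_direction: dict[str, str] = {}
        self.skipped_metabolites: list[str] = []

    # -- expression helpers -------------------------------------------------

    @property
    def constraint_ids(self) -> list[str]:
        return sorted(self.B)

    @property
    def tmcs(self) -> int:
        return len(self.B)

    def flux_magnitude(self, condition: str, reaction_id: str):
        """sum of split-children fluxes == |net flux| under direction exclusivity."""
        kids = self.split.children_of(reaction_id)
        expr = 0
        for sid in kids.values():
            expr = expr + self.v[(condition, sid)]
        return expr

    def net_flux_expr(self, condition: str, reaction_id: str):
        kids = self.split.children_of(reaction_id)
        expr = 0
        for direction, sid in kids.items():
            term = self.v[(condition, sid)]
            expr = expr + (term if direction == FORWARD else -term)
        return expr

    def net_fluxes(self) -> dict[str, dict[str, float]]:
        """Read net fluxes per condition from the current solver primals."""
        out: dict[str, dict[str, float]] = {}
        for cond in CONDITIONS:
            vals = {s.id: self.v[(cond, s.id)].primal for s in self.split.split_reactions}
            out[cond] = {r.id: self.split.net_flux(r.id, vals) for r in self.model.reactions}
        return out

    def binary_values(self) -> dict[str, int]:
        return {cid: int(round(var.primal)) for cid, var in self.B.items()}

    def fix_binaries(self, active: Iterable[str]) -> None:
        """Pin every consistency binary: 1 for ids in ``active``, else 0."""
        active = set(active)
        unknown = active - set(self.B)
        if unknown:
            raise MappingError(f"unknown constraint ids: {sorted(unknown)}")
        for cid, var in self.B.items():
            val = 1 if cid in active else 0
            var.lb = val
            var.ub = val

    def release_binaries(self) -> None:
        for var in self.B.values():
            var.lb = 0
            var.ub = 1

    def set_consistency_objective(self) -> None:
        expr = 0
        for var in self.B.values():
            expr = expr + var
        self.lp.objective = Objective(expr, direction="max")

    def optimize(self) -> str:
        """Solve the MILP with one consistent feasibility notion.

        GLPK's stock MIP paths are not trustworthy on this problem class
        (eps = 1e-5 basal rows against M' = 1000 big-M terms): warm-started
        re-solves misreport feasibility, the plain branch-and-bound
        intermittently prunes a feasible tree to "no solution", and the MIP
        presolver fabricates optima on infeasible problems.  The primary
        solver is therefore an in-package branch-and-bound over the integer
        columns in which GLPK only solves LPs (which are sound); GLPK's own
        modes remain as verified fallbacks for a node-budget overrun.
        """
        status = self._own_branch_and_bound()
        if status is not None:
            return status
        status = self.lp.optimize()
        if status == "optimal" and self._mip_point_feasible():
            return status
        status_a = self._scratch_solve(mip_presolve=False)
        if status_a == "optimal" and self._polish() and self._mip_point_feasible():
            return "optimal"
        status_b = self._scratch_solve(mip_presolve=True)
        if status_b == "optimal" and self._polish() and self._mip_point_feasible():
            return "optimal"
        if "infeasible" in (status, status_a, status_b):
            return "infeasible"
        return status_b

    def _own_branch_and_bound(self, max_nodes: int = 20000,
                              int_tol: float = 1e-7) -> str | None:
        """Depth-first branch-and-bound on the integer columns.

        Every node is a pure LP solved from scratch with the simplex
        presolver.  Returns "optimal" (with the incumbent written into the
        MIP solution store via a pinned re-solve), "infeasible" when the tree
        is exhausted without an integer point, or None if the node budget ran
        out.
        """
        self.lp.update()
        p = self.lp.problem
        maximize = glp.glp_get_obj_dir(p) == glp.GLP_MAX
        int_cols = [j for j in range(1, glp.glp_get_num_cols(p) + 1)
                    if glp.glp_get_col_kind(p, j) != glp.GLP_CV]
        saved = {j: (glp.glp_get_col_type(p, j), glp.glp_get_col_lb(p, j),
                     glp.glp_get_col_ub(p, j)) for j in int_cols}
        smcp = glp.glp_smcp()
        glp.glp_init_smcp(smcp)
        smcp.msg_lev = glp.GLP_MSG_OFF
        smcp.presolve = glp.GLP_ON
        smcp.tm_lim = 10_000
        smcp_plain = glp.glp_smcp()
        glp.glp_init_smcp(smcp_plain)
        smcp_plain.msg_lev = glp.GLP_MSG_OFF
        smcp_plain.presolve = glp.GLP_OFF
        # dual simplex: the primal stalls on the heavily degenerate vertices
        # these razor-thin feasible sets produce
        smcp_plain.meth = glp.GLP_DUALP
        smcp_plain.tm_lim = 2_000
        best: list = [None, None]  # objective, {col: value}
        nodes = [0]

        def node_lp():
            """Solve the node LP; None = infeasible, False = abort.

            Degenerate slivers of the feasible set sit at the edge of double
            precision, and GLPK's presolved and plain simplex can disagree
            there; a node counts as infeasible only if both paths agree.
            """
            ret = glp.glp_simplex(p, smcp)
            if ret == 0 and glp.glp_get_status(p) == glp.GLP_OPT:
                return glp.glp_get_obj_val(p)
            first_infeasible = ret == glp.GLP_ENOPFS
            glp.glp_adv_basis(p, 0)
            ret = glp.glp_simplex(p, smcp_plain)
            if ret == 0 and glp.glp_get_status(p) == glp.GLP_OPT:
                return glp.glp_get_obj_val(p)
            if first_infeasible or glp.glp_get_status(p) == glp.GLP_NOFEAS:
                return None
            return False

        def set_bounds(j, lo, hi):
            kind = glp.GLP_FX if lo == hi else glp.GLP_DB
            glp.glp_set_col_bnds(p, j, kind, lo, hi)

        def explore() -> bool:
            nodes[0] += 1
            if nodes[0] > max_nodes:
                return False
            obj = node_lp()
            if obj is None:
                return True
            if obj is False:
                return False
            if best[0] is not None:
                # bound pruning
                if maximize and obj <= best[0] + 1e-9:
                    return True
                if not maximize and obj >= best[0] - 1e-9:
                    return True
            # branch until every integer column is pinned exactly; a point
            # that is integral only to within LP tolerance can sit on the
            # wrong side of the exact feasible set, and accepting it would
            # give pinned and free solves different feasibility notions
            branch_col = None
            branch_val = None
            for j in int_cols:
                lo, hi = glp.glp_get_col_lb(p, j), glp.glp_get_col_ub(p, j)
                if lo == hi:
                    continue
                v = glp.glp_get_col_prim(p, j)
                if abs(v - round(v)) > int_tol:
                    branch_col, branch_val = j, v
                    break
                if branch_col is None:
                    branch_col, branch_val = j, v
            if branch_col is None:
                best[0] = obj
                best[1] = {j: glp.glp_get_col_lb(p, j) for j in int_cols}
                return True
            j, v = branch_col, branch_val
            lo, hi = glp.glp_get_col_lb(p, j), glp.glp_get_col_ub(p, j)
            nearest = min(max(round(v), lo), hi)
            branches = [(nearest, nearest)]
            if lo <= nearest - 1:
                branches.append((lo, nearest - 1))
            if nearest + 1 <= hi:
                branches.append((nearest + 1, hi))
            for blo, bhi in branches:
                set_bounds(j, blo, bhi)
                done = explore()
                set_bounds(j, lo, hi)
                if not done:
                    return False
            return True

        try:
            complete = explore()
        finally:
            for j, (kind, lo, hi) in saved.items():
                glp.glp_set_col_bnds(p, j, kind, lo, hi)
        if not complete:
            return None
        if best[0] is None:
            return "infeasible"
        # pin the incumbent and re-solve so the MIP solution store holds it;
        # the integer part is exact either way, so the presolver variant is
        # an acceptable fallback for boundary points the plain pass rejects
        for j, val in best[1].items():
            glp.glp_set_col_bnds(p, j, glp.GLP_FX, val, val)
        try:
            status = self._scratch_solve(mip_presolve=False)
            if status != "optimal":
                status = self._scratch_solve(mip_presolve=True)
        finally:
            for j, (kind, lo, hi) in saved.items():
                glp.glp_set_col_bnds(p, j, kind, lo, hi)
        return status if status == "optimal" else None

    def _polish(self) -> bool:
        """Re-solve with the incumbent integer assignment pinned.

        Candidate optima can carry solver sloppiness of order eps on the
        continuous part; pinning the integers and re-running the (sound)
        simplex presolver plus a trivial integer pass yields an exact point
        for the same assignment — or exposes the assignment as infeasible.
        """
        p = self.lp.problem
        saved = []
        for j in range(1, glp.glp_get_num_cols(p) + 1):
            if glp.glp_get_col_kind(p, j) == glp.GLP_CV:
                continue
            saved.append((j, glp.glp_get_col_type(p, j),
                          glp.glp_get_col_lb(p, j), glp.glp_get_col_ub(p, j)))
            val = round(glp.glp_mip_col_val(p, j))
            glp.glp_set_col_bnds(p, j, glp.GLP_FX, val, val)
        try:
            status = self._scratch_solve(mip_presolve=False)
        finally:
            for j, kind, lb, ub in saved:
                glp.glp_set_col_bnds(p, j, kind, lb, ub)
        return status == "optimal"

    def _scratch_solve(self, mip_presolve: bool) -> str:
        """Cold solve via the simplex presolver, mapping its infeasibility
        return code (which the interface layer loses as "undefined")."""
        self.lp.update()
        p = self.lp.problem
        glp.glp_scale_prob(p, glp.GLP_SF_AUTO)
        smcp = glp.glp_smcp()
        glp.glp_init_smcp(smcp)
        smcp.msg_lev = glp.GLP_MSG_OFF
        smcp.presolve = glp.GLP_ON
        ret = glp.glp_simplex(p, smcp)
        if ret == glp.GLP_ENOPFS:
            return "infeasible"
        if ret != 0 or glp.glp_get_status(p) != glp.GLP_OPT:
            return _GLPK_STATUS_TO_STATUS[glp.glp_get_status(p)]
        if glp.glp_get_num_int(p) == 0:
            return "optimal"
        iocp = glp.glp_iocp()
        glp.glp_init_iocp(iocp)
        iocp.msg_lev = glp.GLP_MSG_OFF
        iocp.presolve = glp.GLP_ON if mip_presolve else glp.GLP_OFF
        ret = glp.glp_intopt(p, iocp)
        if ret == glp.GLP_ENOPFS:
            return "infeasible"
        return _GLPK_STATUS_TO_STATUS[glp.glp_mip_status(p)]

    def _mip_point_feasible(self, tol: float = 2e-7) -> bool:
        p = self.lp.problem
        if glp.glp_get_num_int(p) == 0:
            return True

        def ok(val, lb, ub, kind, lo_kinds, up_kinds):
            slack = tol * max(1.0, abs(val))  # relative on big-M-scale rows
            if kind in lo_kinds and val < lb - slack:
                return False
            if kind in up_kinds and val > ub + slack:
                return False
            return True

        lo = (glp.GLP_LO, glp.GLP_DB, glp.GLP_FX)
        up = (glp.GLP_UP, glp.GLP_DB, glp.GLP_FX)
        for i in range(1, glp.glp_get_num_rows(p) + 1):
            if not ok(glp.glp_mip_row_val(p, i), glp.glp_get_row_lb(p, i),
                      glp.glp_get_row_ub(p, i), glp.glp_get_row_type(p, i), lo, up):
                return False
        for j in range(1, glp.glp_get_num_cols(p) + 1):
            val = glp.glp_mip_col_val(p, j)
            if not ok(val, glp.glp_get_col_lb(p, j), glp.glp_get_col_ub(p, j),
                      glp.glp_get_col_type(p, j), lo, up):
                return False
            if glp.glp_get_col_kind(p, j) != glp.GLP_CV:
                if abs(val - round(val)) > tol:
                    return False
        return True


def _add_structural_layer(problem: RemiProblem) -> None:
    p = problem.params
    for cond in CONDITIONS:
        for s in problem.split.split_reactions:
            v = Variable(f"v__{cond}__{_sane(s.id)}", lb=s.lower_bound, ub=s.upper_bound)
            z = Variable(f"z__{cond}__{_sane(s.id)}", type="binary")
            problem.v[(cond, s.id)] = v
            problem.z[(cond, s.id)] = z
            # Eq: v_r <= ub * z_r (ub <= M'); z is a use indicator
            problem.lp.add(Constraint(v - s.upper_bound * z, ub=0,
                                      name=f"use__{cond}__{_sane(s.id)}"))
        # direction exclusivity for reversible pairs
        for r in problem.model.reactions:
            kids = problem.split.children_of(r.id)
            if len(kids) == 2:
                za = problem.z[(cond, kids[FORWARD])]
                zb = problem.z[(cond, kids[BACKWARD])]
                problem.lp.add(Constraint(za + zb, lb=1, ub=1,
                                          name=f"excl__{cond}__{_sane(r.id)}"))
        # steady-state mass balance on net fluxes
        for m in problem.model.metabolites:
            expr = 0
            nonzero = False
            for s in problem.split.split_reactions:
                c = problem.split.stoich_coefficient(m.id, s.id)
                if c:
                    expr = expr + c * problem.v[(cond, s.id)]
                    nonzero = True
            if nonzero:
                problem.lp.add(Constraint(expr, lb=0, ub=0,
                                          name=f"mb__{cond}__{_sane(m.id)}"))
        # growth requirement
        if problem.model.biomass_reaction_id is not None:
            growth = problem.net_flux_expr(cond, problem.model.biomass_reaction_id)
            problem.lp.add(Constraint(growth, lb=p.growth_min,
                                      name=f"growth__{cond}"))


def _add_thermo_layer(problem: RemiProblem) -> None:
    thermo = problem.thermo
    p = problem.params
    assert thermo is not None
    g0_vars: dict[str, Variable] = {}
    for r in problem.model.reactions:
        if not thermo.covers(r.id):
            continue  # reactions without a known DrG'0 carry no constraint
        lo, hi = thermo.drg_interval(problem.model, r.id)
        g0, unc = thermo.drg0[r.id]
        g0_var = Variable(f"g0__{_sane(r.id)}", lb=g0 - unc, ub=g0 + unc)
        g0_vars[r.id] = g0_var
        stoich = problem.model.reaction_stoichiometry(r.id)
        for cond in CONDITIONS:
            drg = g0_var
            for mid, n in stoich.items():
                key = (cond, mid)
                if key not in problem.lnx:
                    llo, lhi = thermo.log_conc_bounds(mid)
                    problem.lnx[key] = Variable(f"lnx__{cond}__{_sane(mid)}", lb=llo, ub=lhi)
                drg = drg + thermo.RT * n * problem.lnx[key]
            kids = problem.split.children_of(r.id)
            if FORWARD in kids:
                # z_fwd = 1  =>  DrG' <= -eps_thermo
                mg = hi + p.eps_thermo + 1.0
                z = problem.z[(cond, kids[FORWARD])]
                problem.lp.add(Constraint(drg + mg * z, ub=mg - p.eps_thermo,
                                          name=f"thermo_f__{cond}__{_sane(r.id)}"))
            if BACKWARD in kids:
                # z_bwd = 1  =>  DrG' >= +eps_thermo
                mg = -lo + p.eps_thermo + 1.0
                z = problem.z[(cond, kids[BACKWARD])]
                problem.lp.add(Constraint(drg - mg * z, lb=p.eps_thermo - mg,
                                          name=f"thermo_b__{cond}__{_sane(r.id)}"))


def add_expression_constraints(problem: RemiProblem, reg: RegulationSet) -> None:
    """Attach the relative-expression constraint family (one B_i per reaction)."""
    p = problem.params
    for direction, table in (("up", reg.up_reactions), ("down", reg.down_reactions)):
        for rid in sorted(table):
            ratio = table[rid]
            if ratio <= 0:
                raise ValueError(f"reaction {rid!r}: ratio must be positive, got {ratio}")
            if not problem.model.has_reaction(rid):
                raise MappingError(f"regulated reaction {rid!r} not in model")
            cid = f"rxn:{rid}"
            B = Variable(f"B__rxn__{_sane(rid)}", type="binary")
            scale = p.big_M * max(1.0, ratio)
            problem.B[cid] = B
            problem.constraint_ratio[cid] = ratio
            problem.constraint_direction[cid] = direction
            v_wild = problem.flux_magnitude(WILD, rid)
            v_mut = problem.flux_magnitude(MUTANT, rid)
            # basal flux in both conditions when enforced; stated in eps
            # units (v/eps >= B) so the eps-scale coefficient cannot be
            # dropped as noise by solver presolve tolerances
            problem.lp.add(Constraint(v_mut / p.eps - B, lb=0,
                                      name=f"basal_m__{_sane(rid)}"))
            problem.lp.add(Constraint(v_wild / p.eps - B, lb=0,
                                      name=f"basal_w__{_sane(rid)}"))
            # valid inequality: basal flux needs an active direction; stating
            # it on the binaries keeps branch-and-bound numerically honest
            # (the implied bound z >= eps/M' is otherwise rounded away)
            for cond in CONDITIONS:
                zsum = 0
                for sid in problem.split.children_of(rid).values():
                    zsum = zsum + problem.z[(cond, sid)]
                problem.lp.add(Constraint(B - zsum, ub=0,
                                          name=f"link_{cond[0]}__{_sane(rid)}"))
            # ratio constraint with the slack eliminated: the slack box pins
            # sigma to [0, eps] when B = 1 and to at most eps + M'*max(1,p)
            # when B = 0, so the net effect is a direct big-M gate at
            # tolerance eps (a free sigma squeezed into an eps-wide box is
            # numerically fragile at M' scale)
            if direction == "up":
                # B=1: v_mut >= p*v_wild - eps;  B=0: vacuous over the box
                problem.lp.add(Constraint(v_mut - ratio * v_wild - scale * B,
                                          lb=-p.eps - scale,
                                          name=f"up__{_sane(rid)}"))
            else:
                # B=1: v_mut <= p*v_wild + eps;  B=0: vacuous over the box
                problem.lp.add(Constraint(v_mut - ratio * v_wild + scale * B,
                                          ub=scale + p.eps,
                                          name=f"down__{_sane(rid)}"))


def add_metabolite_constraints(problem: RemiProblem, reg: RegulationSet) -> None:
    """Attach the relative-metabolite constraint family (one B_i per metabolite).

    For each regulated metabolite the turnover sums phi_p (production) and
    phi_c (consumption) over split fluxes are compared across conditions.  A
    branch binary Y_i = 1 selects the production alternative, Y_i = 0 the
    consumption alternative; B_i gates whether the selected branch is
    enforced.  Metabolites lacking producers or consumers are skipped with a
    warning (turnover undefined).
    """
    p = problem.params
    for direction, table in (("up", reg.up_metabolites), ("down", reg.down_metabolites)):
        for mid in sorted(table):
            ratio = table[mid]
            if ratio <= 0:
                raise ValueError(f"metabolite {mid!r}: ratio must be positive, got {ratio}")
            if not problem.model.has_metabolite(mid):
                raise MappingError(f"regulated metabolite {mid!r} not in model")
            producers: list[tuple[str, float]] = []
            consumers: list[tuple[str, float]] = []
            for s in problem.split.split_reactions:
                c = problem.split.stoich_coefficient(mid, s.id)
                if c > 0:
                    producers.append((s.id, c))
                elif c < 0:
                    consumers.append((s.id, -c))
            if not producers or not consumers:
                logger.warning("metabolite %s has no %s; constraint skipped", mid,
                               "producers" if not producers else "consumers")
                problem.skipped_metabolites.append(mid)
                continue
            cid = f"met:{mid}"
            B = Variable(f"B__met__{_sane(mid)}", type="binary")
            Y = Variable(f"Y__met__{_sane(mid)}", type="binary")
            problem.B[cid] = B
            problem.Y[cid] = Y
            problem.constraint_ratio[cid] = ratio
            problem.constraint_direction[cid] = direction
            phi_max = max(sum(c * problem.split.split(sid).upper_bound for sid, c in producers),
                          sum(c * problem.split.split(sid).upper_bound for sid, c in consumers))
            mrel = max(1.0, ratio, 1.0 / ratio) * phi_max + p.eps + 1.0

            def total(cond, pairs):
                expr = 0
                for sid, c in pairs:
                    expr = expr + c * problem.v[(cond, sid)]
                return expr

            pp_w, pp_m = total(WILD, producers), total(MUTANT, producers)
            pc_w, pc_m = total(WILD, consumers), total(MUTANT, consumers)
            if problem.params.met_form == "mirrored":
                cons_ratio, cons_eps = 1.0 / ratio, p.eps
            else:
                cons_ratio, cons_eps = ratio, 0.0
            if direction == "up":
                # production branch (B=1, Y=1): phi_p^mut >= p'*phi_p^wild - eps
                problem.lp.add(Constraint(
                    pp_m - ratio * pp_w - mrel * B - mrel * Y,
                    lb=-p.eps - 2 * mrel, name=f"met_up_p__{_sane(mid)}"))
                # consumption branch (B=1, Y=0): phi_c^mut <= phi_c^wild*cons_ratio + eps
                problem.lp.add(Constraint(
                    pc_m - cons_ratio * pc_w + mrel * B - mrel * Y,
                    ub=cons_eps + mrel, name=f"met_up_c__{_sane(mid)}"))
            else:
                # production branch (B=1, Y=1): phi_p^mut <= p'*phi_p^wild + eps
                problem.lp.add(Constraint(
                    pp_m - ratio * pp_w + mrel * B + mrel * Y,
                    ub=p.eps + 2 * mrel, name=f"met_dn_p__{_sane(mid)}"))
                # consumption branch: phi_c^mut >= phi_c^wild*cons_ratio - eps
                problem.lp.add(Constraint(
                    pc_m - cons_ratio * pc_w - mrel * B + mrel * Y,
                    lb=-cons_eps - mrel, name=f"met_dn_c__{_sane(mid)}"))
            # basal turnover in both conditions when enforced (eps units,
            # see the expression-constraint basal rows)
            problem.lp.add(Constraint(pp_m / p.eps - B, lb=0,
                                      name=f"met_basal_m__{_sane(mid)}"))
            problem.lp.add(Constraint(pp_w / p.eps - B, lb=0,
                                      name=f"met_basal_w__{_sane(mid)}"))
            # valid inequality: basal turnover needs an active producer and
            # (by the steady state) an active consumer in each condition
            for cond in CONDITIONS:
                for tag, pairs in (("p", producers), ("c", consumers)):
                    zsum = 0
                    for sid, _c in pairs:
                        zsum = zsum + problem.z[(cond, sid)]
                    problem.lp.add(Constraint(B - zsum, ub=0,
                                              name=f"met_link_{tag}_{cond[0]}__{_sane(mid)}"))


def build_remi_problem(
    model: MetabolicModel,
    regulation: RegulationSet | None = None,
    thermo: ThermoData | None = None,
    use_gex: bool | None = None,
    use_met: bool | None = None,
    use_thermo: bool | None = None,
    params: RemiParams = RemiParams(),
    check_base_feasibility: bool = True,
) -> RemiProblem:
    """Assemble the coupled two-condition MILP.

    Variant flags default to whatever the supplied data allow: expression
    constraints if the regulation set has reaction calls, metabolite
    constraints if it has metabolite calls, thermodynamics if ``thermo`` is
    given.  The base (pre-omics) model is solved once to report infeasibility
    before any omics constraint is added.
    """
    regulation = regulation or RegulationSet()
    if use_gex is None:
        use_gex = regulation.n > 0
    if use_met is None:
        use_met = regulation.n_met > 0
    if use_thermo is None:
        use_thermo = thermo is not None
    if use_thermo and thermo is None:
        raise ValueError("use_thermo requires thermo data")
    model.validate()
    split = split_reversible(model, params.big_M)
    problem = RemiProblem(model, split, params, regulation, thermo,
                          use_gex=use_gex, use_met=use_met, use_thermo=use_thermo)
    _add_structural_layer(problem)
    if use_thermo:
        _add_thermo_layer(problem)
    if check_base_feasibility:
        problem.lp.objective = Objective(0, direction="max")
        status = problem.lp.optimize()
        if status != "optimal":
            layer = "thermodynamic base model" if use_thermo else "base model"
            raise InfeasibleModelError(
                f"{layer} infeasible before omics constraints "
                f"(growth >= {params.growth_min}); solver status: {status}"
            )
    if use_gex:
        add_expression_constraints(problem, regulation)
    if use_met:
        add_metabolite_constraints(problem, regulation)
    problem.set_consistency_objective()
    return problem


def solve_consistency(problem: RemiProblem, with_fluxes: bool = False) -> Solution:
    """Maximize sum(B_i); the optimum is the MCS (single data type) or GCS."""
    problem.set_consistency_objective()
    status = problem.optimize()
    if status == "infeasible":
        layer = "thermodynamic" if problem.use_thermo else "structural"
        raise InfeasibleModelError(
            f"consistency MILP infeasible at the {layer} layer "
            "(the all-relaxed state should be feasible; check growth bound and bounds)"
        )
    if status not in ("optimal",):
        raise SolverError(f"solver returned status {status!r}")
    binaries = problem.binary_values()
    score = sum(binaries.values())
    active = frozenset(cid for cid, b in binaries.items() if b)
    fluxes = problem.net_fluxes() if with_fluxes else None
    return Solution(score=score, active=active, binaries=binaries,
                    status=status, tmcs=problem.tmcs, fluxes=fluxes)
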