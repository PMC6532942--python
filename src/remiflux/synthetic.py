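"""Toy metabolic networks, planted two-condition omics, and brute-force oracles.

The toy generator emulates the study setting at desk scale: small networks
with exchange reactions and a biomass sink, expression/metabolite tables for
a "wild" and a "mutant" condition with a controlled number of planted up- and
downregulated entries, and optional reaction Gibbs energies.  The brute-force
oracle enumerates all consistency-binary assignments by feasibility testing,
providing the independent ground truth for the MILP and the integer-cut
enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


import numpy as np
import pandas as pd
from optlang.glpk_interface import Objective

from .milp import RemiParams, RemiProblem, build_remi_problem
from .model_core import MetabolicModel, Metabolite, Reaction, parse_gpr
from .omics import RegulationSet
from .thermo import ThermoData

__all__ = [
    "ToySpec",
    "SimulatedOmics",
    "toy_model",
    "simulate_omics",
    "brute_force_mcs",
    "random_regulated_problem",
]

TOPOLOGIES = ("chain", "diamond", "isoenzyme", "hub")


@dataclass(frozen=True)
class ToySpec:
    """Recipe for a deterministic toy model.

    topology: "chain" (linear pathway), "diamond" (two parallel branches),
    "isoenzyme" (chain with OR / AND GPRs), "hub" (one metabolite with two
    producers and two consumers).  ``length`` is the number of internal
    reactions for chain-like topologies.  ``reversible`` lists internal
    reaction ids to make reversible.  ``uptake`` bounds the substrate intake.
    """

    topology: str = "chain"
    length: int = 3
    reversible: tuple[str, ...] = ()
    uptake: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        minimum = {"chain": 1, "isoenzyme": 3, "diamond": 0, "hub": 0}[self.topology]
        if self.topology in ("chain", "isoenzyme") and self.length < minimum:
            raise ValueError(f"{self.topology} requires length >= {minimum}")
        if self.uptake <= 0:
            raise ValueError("uptake must be positive")


def _assemble(spec: ToySpec, mets: list[str], rxns: list[dict]) -> MetabolicModel:
    metabolites = [Metabolite(id=m, name=m, compartment="c") for m in mets]
    reactions = []
    stoich: dict[tuple[str, str], float] = {}
    for r in rxns:
        lb = -spec.uptake if r["id"] in spec.reversible else r.get("lb", 0.0)
        reactions.append(Reaction(
            id=r["id"], name=r["id"], lower_bound=lb,
            upper_bound=r.get("ub", spec.uptake),
            gpr=parse_gpr(r.get("gpr", "")), gpr_text=r.get("gpr", ""),
            subsystem=r.get("subsystem", ""),
        ))
        for mid, c in r["stoich"].items():
            stoich[(mid, r["id"])] = float(c)
    genes = sorted({g for r in rxns if r.get("gpr")
                    for g in parse_gpr(r["gpr"]).genes()})
    model = MetabolicModel(
        metabolites=metabolites, reactions=reactions, stoichiometry=stoich,
        genes=genes, biomass_reaction_id="BIOMASS",
        id=f"toy_{spec.topology}_{spec.seed}",
    )
    model.validate()
    return model


def toy_model(spec: ToySpec) -> MetabolicModel:
    """Build the toy model described by ``spec`` (deterministic per spec)."""
    u = spec.uptake
    if spec.topology in ("chain", "isoenzyme"):
        L = spec.length
        mets = [f"m{i}" for i in range(L + 1)]
        rxns = [{"id": "EX_in", "stoich": {"m0": 1.0}, "ub": u, "subsystem": "exchange"}]
        for i in range(1, L + 1):
            gpr = f"g{i}"
            if spec.topology == "isoenzyme":
                if i == 2:
                    gpr = f"g{i}a or g{i}b"
                elif i == 3:
                    gpr = f"g{i}a and g{i}b"
            rxns.append({"id": f"R{i}", "stoich": {f"m{i-1}": -1.0, f"m{i}": 1.0},
                         "ub": u, "gpr": gpr, "subsystem": "pathway"})
        rxns.append({"id": "EX_out", "stoich": {mets[-1]: -1.0}, "ub": u,
                     "subsystem": "exchange"})
        rxns.append({"id": "BIOMASS", "stoich": {mets[-1]: -1.0}, "ub": u,
                     "subsystem": "biomass"})
        return _assemble(spec, mets, rxns)
    if spec.topology == "diamond":
        mets = ["m0", "ma", "mb", "m3"]
        rxns = [
            {"id": "EX_in", "stoich": {"m0": 1.0}, "ub": u, "subsystem": "exchange"},
            {"id": "RA1", "stoich": {"m0": -1.0, "ma": 1.0}, "ub": u,
             "gpr": "ga1", "subsystem": "branch_a"},
            {"id": "RA2", "stoich": {"ma": -1.0, "m3": 1.0}, "ub": u,
             "gpr": "ga2", "subsystem": "branch_a"},
            {"id": "RB1", "stoich": {"m0": -1.0, "mb": 1.0}, "ub": u,
             "gpr": "gb1", "subsystem": "branch_b"},
            {"id": "RB2", "stoich": {"mb": -1.0, "m3": 1.0}, "ub": u,
             "gpr": "gb2", "subsystem": "branch_b"},
            {"id": "EX_out", "stoich": {"m3": -1.0}, "ub": u, "subsystem": "exchange"},
            {"id": "BIOMASS", "stoich": {"m3": -1.0}, "ub": u, "subsystem": "biomass"},
        ]
        return _assemble(spec, mets, rxns)
    # hub: metabolite M produced by v1, v2 and consumed by v3, v4
    mets = ["A", "B", "M", "C", "D"]
    rxns = [
        {"id": "EX_A", "stoich": {"A": 1.0}, "ub": u, "subsystem": "exchange"},
        {"id": "EX_B", "stoich": {"B": 1.0}, "ub": u, "subsystem": "exchange"},
        {"id": "v1", "stoich": {"A": -1.0, "M": 1.0}, "ub": u, "gpr": "g1",
         "subsystem": "production"},
        {"id": "v2", "stoich": {"B": -1.0, "M": 1.0}, "ub": u, "gpr": "g2",
         "subsystem": "production"},
        {"id": "v3", "stoich": {"M": -1.0, "C": 1.0}, "ub": u, "gpr": "g3",
         "subsystem": "consumption"},
        {"id": "v4", "stoich": {"M": -1.0, "D": 1.0}, "ub": u, "gpr": "g4",
         "subsystem": "consumption"},
        {"id": "EX_D", "stoich": {"D": -1.0}, "ub": u, "subsystem": "exchange"},
        {"id": "EX_C", "stoich": {"C": -1.0}, "ub": u, "subsystem": "exchange"},
        {"id": "BIOMASS", "stoich": {"C": -1.0}, "ub": u, "subsystem": "biomass"},
    ]
    return _assemble(spec, mets, rxns)


@dataclass
class SimulatedOmics:
    """Two-condition tables plus the planted ground truth."""

    expr_wild: pd.Series
    expr_mutant: pd.Series
    met_wild: pd.Series
    met_mutant: pd.Series
    up_genes: dict[str, float]
    down_genes: dict[str, float]
    up_metabolites: dict[str, float]
    down_metabolites: dict[str, float]


def simulate_omics(
    model: MetabolicModel,
    n_up: int = 0,
    n_down: int = 0,
    n_up_met: int = 0,
    n_down_met: int = 0,
    ratio_range: tuple[float, float] = (2.0, 4.0),
    noise_range: tuple[float, float] = (0.9, 1.1),
    seed: int = 0,
) -> SimulatedOmics:
    """Plant up/down-regulated genes and metabolites with known ratios.

    Up entities get ratios drawn uniformly from ``ratio_range`` (> 1), down
    entities the reciprocal band; everything else gets log-uniform noise in
    ``noise_range`` so fold-change calling at 2 recovers exactly the planted
    sets.  Deterministic for a fixed seed.
    """
    if not (1 < ratio_range[0] <= ratio_range[1]):
        raise ValueError("ratio_range must satisfy 1 < lo <= hi")
    rng = np.random.default_rng(seed)
    genes = sorted(model.genes)
    mets = sorted(m.id for m in model.metabolites)
    if n_up + n_down > len(genes):
        raise ValueError(f"{n_up}+{n_down} regulated genes exceed {len(genes)} available")
    if n_up_met + n_down_met > len(mets):
        raise ValueError(
            f"{n_up_met}+{n_down_met} regulated metabolites exceed {len(mets)} available")

    def plant(ids: list[str], k_up: int, k_down: int):
        chosen = list(rng.choice(ids, size=k_up + k_down, replace=False)) if k_up + k_down else []
        up = {str(g): float(rng.uniform(*ratio_range)) for g in chosen[:k_up]}
        down = {str(g): 1.0 / float(rng.uniform(*ratio_range)) for g in chosen[k_up:]}
        base = pd.Series(rng.uniform(50, 150, size=len(ids)), index=ids)
        lo, hi = math.log(noise_range[0]), math.log(noise_range[1])
        ratios = pd.Series(np.exp(rng.uniform(lo, hi, size=len(ids))), index=ids)
        for g, r in {**up, **down}.items():
            ratios[g] = r
        return base, base * ratios, up, down

    expr_w, expr_m, up_g, down_g = plant(genes, n_up, n_down)
    met_w, met_m, up_m, down_m = plant(mets, n_up_met, n_down_met)
    return SimulatedOmics(expr_wild=expr_w, expr_mutant=expr_m,
                          met_wild=met_w, met_mutant=met_m,
                          up_genes=up_g, down_genes=down_g,
                          up_metabolites=up_m, down_metabolites=down_m)


def brute_force_mcs(
    problem: RemiProblem,
    max_binaries: int = 16,
) -> tuple[int, list[frozenset[str]]]:
    """Exhaustive oracle: max consistency score and all maximum-score sets.

    Tests LP/MILP feasibility with the consistency binaries fixed for active
    sets of growing size, pruning by monotonicity (any superset of an
    infeasible active set is infeasible — enforcing more constraints only
    restricts).  Independent of the optimization and integer-cut machinery.
    """
    ids = problem.constraint_ids
    if len(ids) > max_binaries:
        raise ValueError(
            f"{len(ids)} consistency binaries exceed the brute-force cap {max_binaries}")

    def feasible(active: frozenset[str]) -> bool:
        try:
            problem.fix_binaries(active)
            problem.lp.objective = Objective(0, direction="max")
            return problem.optimize() == "optimal"
        finally:
            problem.release_binaries()
            problem.set_consistency_objective()

    if not feasible(frozenset()):
        raise RuntimeError("base problem infeasible even with all constraints relaxed")
    frontier = [frozenset()]
    level = 0
    while True:
        candidates = {f | {e} for f in frontier for e in ids if e not in f}
        nxt = [c for c in sorted(candidates, key=lambda s: tuple(sorted(s)))
               if feasible(c)]
        if not nxt:
            return level, sorted(frontier, key=lambda s: tuple(sorted(s)))
        frontier = nxt
        level += 1


def random_regulated_problem(
    seed: int,
    with_thermo: bool = False,
    with_metabolites: bool = False,
    params: RemiParams = RemiParams(),
    max_binaries: int = 12,
):
    """Generate a random toy consistency problem with <= ``max_binaries`` binaries.

    Returns ``(model, regulation, thermo, problem)``.  Regulation calls are
    planted directly on reactions/metabolites (mixing consistent and
    conflicting directions) so the MILP faces nontrivial trade-offs.  Retries
    deterministically with derived seeds until the base model (with any
    thermodynamic layer) is feasible.
    """
    from .milp import InfeasibleModelError

    rng = np.random.default_rng(seed)
    for _ in range(40):
        topology = str(rng.choice(TOPOLOGIES))
        length = int(rng.integers(3, 6))
        spec = ToySpec(topology=topology, length=length, seed=seed)
        model = toy_model(spec)
        internal = [r.id for r in model.reactions
                    if not r.id.startswith(("EX_", "BIOMASS"))]
        rev = [rid for rid in internal if rng.random() < 0.3]
        spec = ToySpec(topology=topology, length=length, seed=seed,
                       reversible=tuple(rev))
        model = toy_model(spec)
        n_rxn_constraints = int(rng.integers(2, min(6, len(internal)) + 1))
        chosen = list(rng.choice(internal, size=n_rxn_constraints, replace=False))
        up_r, down_r = {}, {}
        for rid in chosen:
            ratio = float(rng.uniform(1.5, 4.0))
            if rng.random() < 0.5:
                up_r[rid] = ratio
            else:
                down_r[rid] = 1.0 / ratio
        up_m, down_m = {}, {}
        if with_metabolites:
            internal_mets = [m.id for m in model.metabolites]
            n_met = int(rng.integers(1, 3))
            n_met = min(n_met, max_binaries - n_rxn_constraints)
            for mid in rng.choice(internal_mets, size=max(n_met, 0), replace=False):
                ratio = float(rng.uniform(1.5, 3.0))
                if rng.random() < 0.5:
                    up_m[str(mid)] = ratio
                else:
                    down_m[str(mid)] = 1.0 / ratio
        regulation = RegulationSet(up_reactions=up_r, down_reactions=down_r,
                                   up_metabolites=up_m, down_metabolites=down_m)
        thermo = None
        if with_thermo:
            drg0 = {}
            for rid in internal:
                if rng.random() < 0.7:
                    drg0[rid] = (float(rng.uniform(-50.0, 45.0)), float(rng.uniform(0, 5)))
            thermo = ThermoData(drg0=drg0)
        try:
            problem = build_remi_problem(model, regulation, thermo=thermo, params=params)
            return model, regulation, thermo, problem
        except InfeasibleModelError:
            rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
            continue
    raise RuntimeError(f"could not generate a feasible random problem from seed {seed}")
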