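"""Integer-cut enumeration of alternative consistency states and flux profiles.

At a fixed consistency score the MILP usually admits many binary assignments.
Each found assignment A is excluded by the integer cut

    sum_{i in A} B_i <= |A| - 1

and the problem re-solved until infeasible (enumeration exhaustive) or a cap
is reached.  Constraints active in every alternative are the high-frequency
constraints (HFC) — the core of the condition-specific regulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from optlang.glpk_interface import Constraint, Objective

from .milp import CONDITIONS, MUTANT, RemiProblem, SolverError, WILD, solve_consistency

__all__ = [
    "AlternativeSet",
    "FluxProfilePair",
    "enumerate_alternatives",
    "high_frequency_constraints",
    "representative_flux",
    "aggregate_profiles",
]


@dataclass
class AlternativeSet:
    """All binary assignments achieving ``score``, as active-constraint id sets."""

    score: int
    assignments: list[frozenset[str]]
    exhaustive: bool

    def __post_init__(self):
        if len(set(self.assignments)) != len(self.assignments):
            raise ValueError("alternative assignments must be distinct")
        for a in self.assignments:
            if len(a) != self.score:
                raise ValueError(
                    f"assignment of size {len(a)} does not achieve score {self.score}"
                )
        # canonical order for reproducible output
        self.assignments = sorted(self.assignments, key=lambda a: tuple(sorted(a)))

    def __len__(self) -> int:
        return len(self.assignments)

    @property
    def hfc(self) -> frozenset[str]:
        return high_frequency_constraints(self, freq=1.0)

    def to_frame(self) -> pd.DataFrame:
        """0/1 matrix, alternatives x constraint ids."""
        ids = sorted(set().union(*self.assignments)) if self.assignments else []
        rows = [[int(c in a) for c in ids] for a in self.assignments]
        return pd.DataFrame(rows, columns=ids)


def enumerate_alternatives(
    problem: RemiProblem,
    score: int | None = None,
    max_count: int = 1000,
) -> AlternativeSet:
    """Enumerate all assignments at ``score`` (default: the MCS) via integer cuts.

    The objective total is fixed to ``score`` as an equality, so sub-optimal
    states (MCS - n) can be enumerated by passing a lower score.
    """
    if max_count < 1:
        raise ValueError("max_count must be >= 1")
    mcs = solve_consistency(problem).score
    if score is None:
        score = mcs
    if score > mcs:
        raise ValueError(f"requested score {score} exceeds MCS {mcs}")
    expr = 0
    for var in problem.B.values():
        expr = expr + var
    fix = Constraint(expr, lb=score, ub=score, name="enum_score_eq")
    cuts: list[Constraint] = []
    problem.lp.add(fix)
    assignments: list[frozenset[str]] = []
    exhaustive = False
    try:
        while len(assignments) < max_count:
            status = problem.optimize()
            if status == "infeasible":
                exhaustive = True
                break
            if status != "optimal":
                break  # solver failure: return the partial set, exhaustive=False
            active = frozenset(cid for cid, b in problem.binary_values().items() if b)
            assignments.append(active)
            if not active:
                exhaustive = True  # score 0 admits exactly one assignment
                break
            cut_expr = 0
            for cid in active:
                cut_expr = cut_expr + problem.B[cid]
            cut = Constraint(cut_expr, ub=len(active) - 1, name=f"cut_{len(cuts)}")
            cuts.append(cut)
            problem.lp.add(cut)
    finally:
        problem.lp.remove([fix, *cuts])
    return AlternativeSet(score=score, assignments=assignments, exhaustive=exhaustive)


def high_frequency_constraints(alts: AlternativeSet, freq: float = 1.0) -> frozenset[str]:
    """Constraint ids active in at least ``freq`` of the alternatives.

    freq = 1.0 gives the classic HFC set (active in *every* alternative).
    """
    if not (0 < freq <= 1.0):
        raise ValueError(f"freq must lie in (0, 1], got {freq}")
    if not alts.assignments:
        raise ValueError("empty alternative set")
    counts: dict[str, int] = {}
    for a in alts.assignments:
        for cid in a:
            counts[cid] = counts.get(cid, 0) + 1
    n = len(alts.assignments)
    return frozenset(cid for cid, c in counts.items() if c / n >= freq - 1e-12)


@dataclass
class FluxProfilePair:
    """Minimum-total-flux representative profiles for one alternative."""

    wild: dict[str, float]
    mutant: dict[str, float]
    total_flux: float
    alternative: frozenset[str]

    def condition(self, cond: str) -> dict[str, float]:
        if cond == WILD:
            return self.wild
        if cond == MUTANT:
            return self.mutant
        raise KeyError(cond)


def representative_flux(problem: RemiProblem, alternative: Iterable[str]) -> FluxProfilePair:
    """Fix the consistency binaries to ``alternative`` and minimize total flux.

    The secondary LP (binaries pinned, direction binaries still free) minimizes
    the sum of all split fluxes over both conditions; the returned profiles
    are net fluxes per parent reaction.
    """
    alternative = frozenset(alternative)
    expr = 0
    for var in problem.v.values():
        expr = expr + var
    try:
        problem.fix_binaries(alternative)
        problem.lp.objective = Objective(expr, direction="min")
        status = problem.optimize()
        if status != "optimal":
            raise SolverError(
                f"fixed-binary minimum-flux model returned {status!r}; "
                "the assignment does not achieve its score"
            )
        total = float(problem.lp.objective.value)
        fluxes = problem.net_fluxes()
    finally:
        problem.release_binaries()
        problem.set_consistency_objective()
    return FluxProfilePair(wild=fluxes[WILD], mutant=fluxes[MUTANT],
                           total_flux=total, alternative=alternative)


def aggregate_profiles(profiles: Sequence[FluxProfilePair]) -> pd.DataFrame:
    """Per-reaction, per-condition mean and SEM across alternative profiles.

    SEM uses the sample standard deviation (ddof=1) over alternatives; a
    single profile yields SEM 0.
    """
    if not profiles:
        raise ValueError("need at least one flux profile")
    rxns = sorted(profiles[0].wild)
    data = {}
    for cond in CONDITIONS:
        arr = np.array([[p.condition(cond)[r] for r in rxns] for p in profiles])
        mean = arr.mean(axis=0)
        if arr.shape[0] > 1:
            sem = arr.std(axis=0, ddof=1) / math.sqrt(arr.shape[0])
        else:
            sem = np.zeros(len(rxns))
        data[(cond, "mean")] = mean
        data[(cond, "sem")] = sem
    return pd.DataFrame(data, index=rxns)
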