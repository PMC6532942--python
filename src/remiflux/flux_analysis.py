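"""Conditional FVA, bidirectional-reaction counting, and relative flexibility.

Conditional flux variability analysis minimizes and maximizes each net
reaction flux while the model is held at (at least) a given consistency
score, yielding per-condition flux ranges.  A reaction is bidirectional
(BDR) in a condition when its range admits both net-flux signs.  Relative
flexibility compares range widths between a target and a reference model;
its average (ARF) over flux-carrying reactions summarizes how much a data
layer shrinks the solution space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from optlang.glpk_interface import Constraint, Objective

from .milp import CONDITIONS, MUTANT, RemiProblem, WILD

__all__ = [
    "FluxRangeReport",
    "FlexibilityReport",
    "conditional_fva",
    "count_bidirectional",
    "relative_flexibility",
]


@dataclass
class FluxRangeReport:
    """Per-condition, per-reaction net-flux intervals [v_min, v_max]."""

    ranges: dict[str, dict[str, tuple[float, float]]]  # condition -> rxn -> (lo, hi)
    score: int | None = None
    # range endpoints are defined up to the enforcement slack eps = 1e-5
    tolerance: float = 2e-5

    def __post_init__(self):
        for cond, table in self.ranges.items():
            for rid, (lo, hi) in table.items():
                if lo > hi + self.tolerance:
                    raise ValueError(f"{cond}/{rid}: v_min {lo} > v_max {hi}")

    @property
    def conditions(self) -> list[str]:
        return sorted(self.ranges)

    def width(self, condition: str, reaction_id: str) -> float:
        lo, hi = self.ranges[condition][reaction_id]
        return hi - lo

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond in self.conditions:
            for rid, (lo, hi) in sorted(self.ranges[cond].items()):
                rows.append({"condition": cond, "reaction": rid,
                             "v_min": lo, "v_max": hi})
        return pd.DataFrame(rows)


def conditional_fva(
    problem: RemiProblem,
    score: int = 0,
    reactions: Iterable[str] | None = None,
    mode: str = "ge",
) -> FluxRangeReport:
    """FVA over net fluxes with sum(B_i) >= score (or == score for mode "eq").

    score = 0 reduces to plain (T)FBA-model FVA.  A score above the MCS makes
    the problem infeasible and raises.
    """
    if mode not in ("ge", "eq"):
        raise ValueError(f"unknown mode {mode!r}")
    rxn_ids = [r.id for r in problem.model.reactions]
    if reactions is not None:
        reactions = list(reactions)
        unknown = [r for r in reactions if not problem.model.has_reaction(r)]
        if unknown:
            raise KeyError(f"unknown reactions: {unknown}")
        rxn_ids = reactions
    expr = 0
    for var in problem.B.values():
        expr = expr + var
    enforce = Constraint(expr, lb=score, ub=score if mode == "eq" else None,
                         name="fva_score")
    problem.lp.add(enforce)
    ranges: dict[str, dict[str, tuple[float, float]]] = {c: {} for c in CONDITIONS}
    try:
        for cond in CONDITIONS:
            for rid in rxn_ids:
                net = problem.net_flux_expr(cond, rid)
                bounds = []
                for direction in ("min", "max"):
                    problem.lp.objective = Objective(net, direction=direction)
                    status = problem.optimize()
                    if status != "optimal":
                        raise RuntimeError(
                            f"conditional FVA at score {score} "
                            f"({cond}/{rid}, {direction}): solver status {status!r}; "
                            "the requested score may exceed the MCS"
                        )
                    bounds.append(float(problem.lp.objective.value))
                ranges[cond][rid] = (bounds[0], bounds[1])
    finally:
        problem.lp.remove(enforce)
        problem.set_consistency_objective()
    return FluxRangeReport(ranges=ranges, score=score)


def count_bidirectional(report: FluxRangeReport, tol: float = 1e-6) -> dict[str, int]:
    """Count bidirectional reactions per condition.

    A reaction is bidirectional in a condition iff v_min < -tol and
    v_max > +tol.  Returns {"n1": mutant count, "n2": wild count, "S": sum}
    following the convention that n1 refers to the mutant model.
    """
    counts = {}
    for cond in (MUTANT, WILD):
        if cond not in report.ranges:
            raise KeyError(f"report lacks condition {cond!r}")
        counts[cond] = sum(
            1 for lo, hi in report.ranges[cond].values() if lo < -tol and hi > tol
        )
    return {"n1": counts[MUTANT], "n2": counts[WILD], "S": counts[MUTANT] + counts[WILD]}


@dataclass
class FlexibilityReport:
    """Per-reaction relative flexibility and its global / subsystem averages."""

    rf: dict[str, float]
    arf: float
    subsystem_arf: dict[str, float] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)
    target_label: str = "target"
    reference_label: str = "reference"


def relative_flexibility(
    target: FluxRangeReport,
    reference: FluxRangeReport,
    subsystems: Mapping[str, str] | None = None,
    tol: float = 1e-6,
    target_label: str = "target",
    reference_label: str = "reference",
) -> FlexibilityReport:
    """Relative flexibility RF_i = target range width / reference range width.

    Widths (v_max - v_min) replace the printed signed differences — the two
    are equal up to sign.  RF_i averages over the conditions shared by both
    reports in which the reference width is nonzero; reactions whose
    reference range is zero in every shared condition are excluded, never
    divided.  The global ARF averages RF_i over reactions that carry flux in
    the reference state (some reference bound exceeding ``tol`` in
    magnitude).
    """
    conds = sorted(set(target.ranges) & set(reference.ranges))
    if not conds:
        raise ValueError("reports share no condition")
    rf: dict[str, float] = {}
    excluded: list[str] = []
    carries_flux: dict[str, bool] = {}
    common = set.intersection(
        *(set(target.ranges[c]) & set(reference.ranges[c]) for c in conds)
    )
    for rid in sorted(common):
        vals = []
        carries = False
        for c in conds:
            ref_lo, ref_hi = reference.ranges[c][rid]
            if abs(ref_lo) > tol or abs(ref_hi) > tol:
                carries = True
            ref_w = ref_hi - ref_lo
            if ref_w > tol:
                vals.append(target.width(c, rid) / ref_w)
        carries_flux[rid] = carries
        if vals:
            rf[rid] = sum(vals) / len(vals)
        else:
            excluded.append(rid)
    qualifying = [rid for rid in rf if carries_flux[rid]]
    arf = sum(rf[r] for r in qualifying) / len(qualifying) if qualifying else float("nan")
    subsystem_arf: dict[str, float] = {}
    if subsystems is not None:
        groups: dict[str, list[float]] = {}
        for rid in qualifying:
            label = subsystems.get(rid, "")
            if label:
                groups.setdefault(label, []).append(rf[rid])
        subsystem_arf = {k: sum(v) / len(v) for k, v in sorted(groups.items())}
    return FlexibilityReport(rf=rf, arf=arf, subsystem_arf=subsystem_arf,
                             excluded=excluded, target_label=target_label,
                             reference_label=reference_label)
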