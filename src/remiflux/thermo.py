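"""Thermodynamic layer: reaction Gibbs energies over metabolite log-concentrations.

The transformed reaction energy is the linear function

    DrG'_i = DrG'0_i + R*T * sum_j n_ij * ln(x_j)

of the log-concentrations ln(x_j), evaluated over per-metabolite concentration
boxes [x_min, x_max].  Energies are consumed as given — no pH or ionic-strength
corrections are applied.  Within the MILP a direction-use binary z couples to
the sign of DrG' so that a direction with no thermodynamic driving force
cannot carry flux; the coupling never forbids the zero-flux state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model_core import MetabolicModel

__all__ = ["ThermoData", "ThermoDataError", "direction_feasibility", "read_thermo_tables"]

#: Gas constant in kJ/(mol*K)
R_KJ = 8.314462618e-3

#: Default metabolite concentration box (mol/L) when none is supplied.
DEFAULT_CONC_BOUNDS = (1e-8, 0.02)


class ThermoDataError(ValueError):
    pass


@dataclass
class ThermoData:
    """Standard reaction energies plus metabolite concentration boxes.

    drg0: reaction id -> (DrG'0 in kJ/mol, uncertainty in kJ/mol).  Reactions
    absent from this map carry no thermodynamic constraint.
    conc_bounds: metabolite id -> (x_min, x_max) in mol/L; metabolites without
    an entry fall back to ``default_conc_bounds``.
    """

    drg0: dict[str, tuple[float, float]] = field(default_factory=dict)
    conc_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    temperature: float = 298.15
    gas_constant: float = R_KJ
    default_conc_bounds: tuple[float, float] = DEFAULT_CONC_BOUNDS

    def __post_init__(self):
        if self.gas_constant * self.temperature <= 0:
            raise ThermoDataError("R*T must be positive")
        for mid, (lo, hi) in self.conc_bounds.items():
            if not (0 < lo <= hi):
                raise ThermoDataError(
                    f"metabolite {mid!r}: concentration bounds must satisfy 0 < min <= max, "
                    f"got [{lo}, {hi}]"
                )
        for rid, (_, unc) in self.drg0.items():
            if unc < 0:
                raise ThermoDataError(f"reaction {rid!r}: negative DrG'0 uncertainty")

    @property
    def RT(self) -> float:
        return self.gas_constant * self.temperature

    def covers(self, reaction_id: str) -> bool:
        return reaction_id in self.drg0

    def log_conc_bounds(self, metabolite_id: str) -> tuple[float, float]:
        lo, hi = self.conc_bounds.get(metabolite_id, self.default_conc_bounds)
        return math.log(lo), math.log(hi)

    def drg_interval(self, model: MetabolicModel, reaction_id: str) -> tuple[float, float]:
        """Interval of DrG' over the concentration box (uncertainty included)."""
        if not self.covers(reaction_id):
            raise ThermoDataError(f"no DrG'0 entry for reaction {reaction_id!r}")
        g0, unc = self.drg0[reaction_id]
        lo = g0 - unc
        hi = g0 + unc
        stoich = model.reaction_stoichiometry(reaction_id)
        if not stoich:
            raise ThermoDataError(f"reaction {reaction_id!r} has empty stoichiometry")
        for mid, n in stoich.items():
            if not model.has_metabolite(mid):
                raise ThermoDataError(f"unknown metabolite id {mid!r}")
            llo, lhi = self.log_conc_bounds(mid)
            term_lo = min(n * llo, n * lhi)
            term_hi = max(n * llo, n * lhi)
            lo += self.RT * term_lo
            hi += self.RT * term_hi
        return lo, hi


def direction_feasibility(
    model: MetabolicModel,
    reaction_id: str,
    thermo: ThermoData,
    eps_thermo: float = 1e-6,
) -> dict[str, bool]:
    """Pre-solve directionality screen from the DrG' interval.

    Forward flux needs DrG' <= -eps_thermo achievable somewhere in the
    concentration box (min of the interval); backward needs DrG' >= +eps_thermo
    (max of the interval).
    """
    lo, hi = thermo.drg_interval(model, reaction_id)
    return {
        "forward_feasible": lo <= -eps_thermo,
        "backward_feasible": hi >= eps_thermo,
    }


def read_thermo_tables(
    drg_path: str | Path,
    conc_path: str | Path | None = None,
    temperature: float = 298.15,
    gas_constant: float = R_KJ,
    default_conc_bounds: tuple[float, float] = DEFAULT_CONC_BOUNDS,
) -> ThermoData:
    """Read delimited thermo tables.

    ``drg_path``: columns reaction_id, drg0_kj_mol[, drg0_uncertainty]
    ``conc_path``: columns metabolite_id, conc_min_M, conc_max_M
    Tab- or comma-separated, header row required.
    """
    drg_df = pd.read_csv(drg_path, sep=None, engine="python")
    drg: dict[str, tuple[float, float]] = {}
    for _, row in drg_df.iterrows():
        unc = float(row["drg0_uncertainty"]) if "drg0_uncertainty" in drg_df.columns else 0.0
        drg[str(row["reaction_id"])] = (float(row["drg0_kj_mol"]), unc)
    conc: dict[str, tuple[float, float]] = {}
    if conc_path is not None:
        conc_df = pd.read_csv(conc_path, sep=None, engine="python")
        for _, row in conc_df.iterrows():
            conc[str(row["metabolite_id"])] = (float(row["conc_min_M"]), float(row["conc_max_M"]))
    return ThermoData(
        drg0=drg,
        conc_bounds=conc,
        temperature=temperature,
        gas_constant=gas_constant,
        default_conc_bounds=default_conc_bounds,
    )
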