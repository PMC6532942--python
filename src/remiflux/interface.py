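"""Pipeline configuration and the end-to-end run.

``run_pipeline`` ties the stages together: load model -> (thermo) -> ratios
-> regulation calls -> build MILP -> maximize consistency -> enumerate
alternatives -> HFC -> representative flux profiles -> conditional FVA ->
BDR / relative flexibility -> benchmark against measured fluxes (when
given).  Every stage logs its counts; all tables are written tab-separated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (
    RegulationSet,
    RemiParams,
    build_remi_problem,
    call_regulation,
    compute_gene_ratios,
    conditional_fva,
    count_bidirectional,
    enumerate_alternatives,
    flux_comparison,
    high_frequency_constraints,
    metabolite_ratios,
    reaction_ratios,
    read_level_table,
    read_model,
    read_thermo_tables,
    relative_flexibility,
    representative_flux,
    aggregate_profiles,
    solve_consistency,
)

__all__ = ["RunConfig", "ConfigError", "ResultBundle", "run_pipeline", "load_config"]

logger = logging.getLogger("remiflux.pipeline")

VARIANTS = ("Gex", "M", "GexM", "TGex", "TM", "TGexM")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Declarative description of one analysis run.

    Paths are condition-1 ("wild") then condition-2 ("mutant") tables.  The
    variant names which data layers are integrated: a leading T adds
    thermodynamics, Gex adds expression constraints, M metabolite
    constraints.
    """

    model_path: str
    variant: str = "Gex"
    expression_cond1: str | None = None
    expression_cond2: str | None = None
    metabolite_cond1: str | None = None
    metabolite_cond2: str | None = None
    thermo_drg: str | None = None
    thermo_conc: str | None = None
    measured_fluxes: str | None = None
    output_dir: str = "remiflux_out"
    regulation_method: str = "quantile"
    q: float = 0.05
    fold: float = 2.0
    eps: float = 1e-5
    big_M: float = 1000.0
    growth_min: float = 0.1
    eps_thermo: float = 1e-6
    met_form: str = "mirrored"
    max_count: int = 1000
    fva_score: int | None = None  # default: the MCS
    bdr_tol: float = 1e-6
    seed: int = 0
    solver_timeout: float | None = None

    @property
    def use_thermo(self) -> bool:
        return self.variant.startswith("T")

    @property
    def use_gex(self) -> bool:
        return "Gex" in self.variant

    @property
    def use_met(self) -> bool:
        return self.variant.removeprefix("T") in ("M", "GexM")

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.use_thermo and not self.thermo_drg:
            raise ConfigError(f"variant {self.variant} requires a thermo table (thermo_drg)")
        if self.use_gex and not (self.expression_cond1 and self.expression_cond2):
            raise ConfigError(f"variant {self.variant} requires both expression tables")
        if self.use_met and not (self.metabolite_cond1 and self.metabolite_cond2):
            raise ConfigError(f"variant {self.variant} requires both metabolite tables")
        if self.regulation_method not in ("quantile", "fold"):
            raise ConfigError(f"unknown regulation method {self.regulation_method!r}")

    def params(self) -> RemiParams:
        return RemiParams(eps=self.eps, big_M=self.big_M, growth_min=self.growth_min,
                          eps_thermo=self.eps_thermo, met_form=self.met_form,
                          solver_timeout=self.solver_timeout)


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a YAML config file; keyword overrides win over file values."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping of config keys")
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


@dataclass
class ResultBundle:
    """Everything the pipeline computed, plus where the tables were written."""

    tmcs: int
    mcs: int
    regulation: RegulationSet
    alternatives: object
    hfc: frozenset[str]
    profile_summary: pd.DataFrame
    fva: object
    bdr: dict[str, int]
    flexibility: object | None = None
    benchmark: pd.Series | None = None
    output_dir: Path | None = None


def _build_regulation(config: RunConfig, model) -> RegulationSet:
    reg = RegulationSet()
    if config.use_gex:
        g1 = read_level_table(config.expression_cond1)
        g2 = read_level_table(config.expression_cond2)
        gene_ratios = compute_gene_ratios(g1, g2)
        logger.info("expression: %d gene ratios (%d excluded)",
                    len(gene_ratios), len(gene_ratios.excluded))
        rxn_ratios = reaction_ratios(model, gene_ratios)
        logger.info("expression: %d reaction ratios via GPR", len(rxn_ratios))
        reg = reg.merge(call_regulation(rxn_ratios, method=config.regulation_method,
                                        q=config.q, fold=config.fold))
    if config.use_met:
        m1 = read_level_table(config.metabolite_cond1)
        m2 = read_level_table(config.metabolite_cond2)
        met_ratios = metabolite_ratios(m1, m2)
        logger.info("metabolites: %d ratios (%d excluded)",
                    len(met_ratios), len(met_ratios.excluded))
        reg = reg.merge(call_regulation(met_ratios, method=config.regulation_method,
                                        q=config.q, fold=config.fold))
    logger.info("regulation: %d reaction + %d metabolite constraints (TMCS %d)",
                reg.n, reg.n_met, reg.tmcs)
    return reg


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute the full analysis described by ``config`` and write all tables."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage load: %s", config.model_path)
    model = read_model(config.model_path)
    logger.info("model %s: %d reactions, %d metabolites, %d genes", model.id,
                len(model.reactions), len(model.metabolites), len(model.genes))
    thermo = None
    if config.use_thermo:
        thermo = read_thermo_tables(config.thermo_drg, config.thermo_conc)
        logger.info("thermo: %d reaction energies, %d concentration boxes",
                    len(thermo.drg0), len(thermo.conc_bounds))
    regulation = _build_regulation(config, model)
    regulation.to_frame().to_csv(outdir / "regulation.tsv", sep="\t", index=False)

    logger.info("stage build: variant %s", config.variant)
    problem = build_remi_problem(model, regulation, thermo=thermo,
                                 use_gex=config.use_gex, use_met=config.use_met,
                                 use_thermo=config.use_thermo, params=config.params())
    solution = solve_consistency(problem)
    logger.info("stage solve: score %d of TMCS %d", solution.score, problem.tmcs)

    alts = enumerate_alternatives(problem, max_count=config.max_count)
    logger.info("stage enumerate: %d alternatives (exhaustive=%s)",
                len(alts), alts.exhaustive)
    alts.to_frame().to_csv(outdir / "alternatives.tsv", sep="\t", index=False)
    hfc = high_frequency_constraints(alts) if len(alts) else frozenset()
    (outdir / "hfc.txt").write_text("\n".join(sorted(hfc)) + "\n")

    profiles = [representative_flux(problem, a) for a in alts.assignments]
    summary = aggregate_profiles(profiles)
    summary.to_csv(outdir / "flux_profiles.tsv", sep="\t")

    fva_score = solution.score if config.fva_score is None else config.fva_score
    fva = conditional_fva(problem, score=fva_score)
    fva.to_frame().to_csv(outdir / "fva.tsv", sep="\t", index=False)
    bdr = count_bidirectional(fva, tol=config.bdr_tol)
    logger.info("stage fva: score >= %d; BDR S=%d (n1=%d, n2=%d)",
                fva_score, bdr["S"], bdr["n1"], bdr["n2"])

    # relative flexibility against the bare (no-data) model
    base_problem = build_remi_problem(model, RegulationSet(), params=config.params())
    base_fva = conditional_fva(base_problem, score=0)
    subsystems = {r.id: r.subsystem for r in model.reactions}
    flexibility = relative_flexibility(fva, base_fva, subsystems=subsystems,
                                       target_label=config.variant,
                                       reference_label="base")
    pd.Series(flexibility.rf, name="RF").to_csv(outdir / "relative_flexibility.tsv", sep="\t")
    logger.info("stage flexibility: global ARF %.4f over %d reactions",
                flexibility.arf, len(flexibility.rf))

    benchmark = None
    if config.measured_fluxes:
        meas = pd.read_csv(config.measured_fluxes, sep=None, engine="python")
        required = {"reaction_id", "flux", "condition"}
        if not required <= set(meas.columns):
            raise ConfigError(f"measured-flux table needs columns {sorted(required)}")
        m1 = dict(zip(meas.loc[meas.condition == "wild", "reaction_id"],
                      meas.loc[meas.condition == "wild", "flux"]))
        m2 = dict(zip(meas.loc[meas.condition == "mutant", "reaction_id"],
                      meas.loc[meas.condition == "mutant", "flux"]))
        mean_profile = {
            "wild": dict(summary[("wild", "mean")]),
            "mutant": dict(summary[("mutant", "mean")]),
        }
        benchmark = flux_comparison(mean_profile["wild"], mean_profile["mutant"], m1, m2)
        benchmark.to_csv(outdir / "benchmark.tsv", sep="\t", header=False)
        logger.info("stage benchmark: r1=%.3f r2=%.3f e=%.3f (N=%d)",
                    benchmark["r_cond1"], benchmark["r_cond2"],
                    benchmark["avg_pct_error"], benchmark["n_reactions"])

    report = {
        "variant": config.variant,
        "tmcs": int(problem.tmcs),
        "mcs": int(solution.score),
        "n_alternatives": len(alts),
        "enumeration_exhaustive": bool(alts.exhaustive),
        "n_hfc": len(hfc),
        "bdr": {k: int(v) for k, v in bdr.items()},
        "global_arf": float(flexibility.arf),
    }
    with open(outdir / "summary.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=False)
    return ResultBundle(tmcs=problem.tmcs, mcs=solution.score, regulation=regulation,
                        alternatives=alts, hfc=hfc, profile_summary=summary,
                        fva=fva, bdr=bdr, flexibility=flexibility,
                        benchmark=benchmark, output_dir=outdir)
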