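# Methods

## Model and constraint formulation

`remiflux` couples two direction-split copies of one stoichiometric model.
Every reversible reaction is decomposed into a forward (α) and backward (β)
child with bounds `[0, min(|bound|, M′)]`; each child carries a binary use
indicator `z` with `v ≤ ub·z`, and each reversible pair satisfies
`z_α + z_β = 1`, so at most one direction carries flux and the magnitude of
a reaction's flux equals the sum of its children.  Irreversible reactions
get a single child in their allowed direction; their `z` stays a free
indicator rather than being pinned to 1, so that a thermodynamically
blocked irreversible reaction can still be silent (the zero-flux state is
never forbidden by the thermodynamic coupling).  Mass balance `S·v = 0` and
a growth floor (biomass flux ≥ `growth_min`) apply to both condition
copies.

**Expression constraints.**  For a regulated reaction with ratio `p`
(condition 2 over condition 1) and consistency binary `B`:

    v_mut ≥ eps·B,  v_wild ≥ eps·B                      (basal flux)
    up:   v_mut ≥ p·v_wild − eps − (1−B)·M′·max(1, p)
    down: v_mut ≤ p·v_wild + eps + (1−B)·M′·max(1, p)

where `v` is the flux magnitude.  The formulation is the net effect of the
slack-variable version (slack pinned to `[0, eps]` when enforced, released
to `eps + M′·max(1,p)` when relaxed): the explicit slack variable is not
materialized because a free variable squeezed into an `eps`-wide box on
rows with `M′`-scale coefficients sits below what a double-precision
simplex can resolve, and made answers depend on solve order.  The
relaxation term is scaled by `max(1, p)` so `B = 0` truly deactivates the
up-constraint for any ratio.  The basal rows are stated in `eps` units
(`v/eps ≥ B`) — mathematically identical, but it prevents solver presolve
routines from discarding the `eps`-scale coefficient as noise.  A valid
inequality `B ≤ Σ z` (per condition, over the reaction's children) makes
the implication "enforced ⇒ some direction active" explicit to the solver.

**Metabolite constraints.**  For a regulated metabolite, production and
consumption turnovers `φ_p` and `φ_c` (sums of producing/consuming split
fluxes weighted by |stoichiometry|; equal at steady state) are constrained
through a branch binary `Y` (1 = production branch, 0 = consumption
branch) gated by the consistency binary `B`, each branch big-M-linearized.
In the default **mirrored** form an up metabolite (`p′ > 1`) requires
`φ_p^mut ≥ p′·φ_p^wild − eps` *or* `φ_c^mut ≤ φ_c^wild/p′ + eps`; down
metabolites mirror both branches.  The consumption branch uses the
reciprocal ratio because "up" via consumption means *less* consumption —
multiplying consumption by `p′ > 1` as the branch form is sometimes
written would make that branch vacuous.  The literal written form (ratio
`p′` on both branches, tightened rather than relaxed by the slack) remains
available via `RemiParams(met_form="literal")` for comparison.  Metabolites
lacking producers or consumers are skipped with a warning (turnover
undefined).  Basal turnover `φ ≥ eps·B` applies in both conditions, with
linking inequalities `B ≤ Σ z` over producers and over consumers.

**Thermodynamic layer.**  For every reaction with a known standard energy,
`ΔrG′ = g0 + RT·Σ n_ij·ln x_j` is linear in per-condition log-concentration
variables bounded by `[ln x_min, ln x_max]`; `g0` is one shared variable in
`ΔrG′° ± uncertainty`.  Direction coupling is `z_fwd = 1 ⇒ ΔrG′ ≤
−eps_thermo` and `z_bwd = 1 ⇒ ΔrG′ ≥ +eps_thermo`, big-M-linearized with a
per-reaction constant from interval arithmetic over the concentration box.
Energies are consumed as given; no pH or ionic-strength transforms are
applied.  `direction_feasibility` provides the equivalent pre-solve
interval screen.

**Objective and enumeration.**  The objective maximizes `Σ B`; the optimum
is the MCS (one data type) or GCS (combined).  Alternatives at a given
score are enumerated by fixing `Σ B = score` and adding the integer cut
`Σ_{i∈A} B_i ≤ |A| − 1` for each found active set `A` until infeasibility
(exhaustive) or a cap (default 1000).  Equality rather than `≥` is used so
sub-optimal levels (MCS − n) can be enumerated directly.  Representative
profiles re-solve with binaries pinned, minimizing the sum of all split
fluxes over both conditions.  Conditional FVA adds `Σ B ≥ score`
(configurable to equality) and minimizes/maximizes each net flux per
condition.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `eps` | 1e-5 | flux | basal-flux threshold and enforcement slack |
| `big_M` | 1000 | flux | split-flux cap / relaxation constant |
| `growth_min` | 0.1 | flux | biomass floor in both conditions |
| `eps_thermo` | 1e-6 | kJ/mol | strictness of the ΔrG′ sign requirement |
| `q` | 0.05 | — | quantile tail for regulation calling |
| `fold` | 2.0 | — | fold-change cutoff for regulation calling |
| default conc. box | 1e-8 – 0.02 | mol/L | metabolite concentrations without data |
| `max_count` | 1000 | — | enumeration cap (with explicit exhaustive flag) |

Regulation calling sorts ratios and takes the top/bottom `⌈q·N⌉` (ties at
the boundary included; ids landing in both tails dropped from both), or
applies the symmetric fold cutoff (`≥ fold` up, `≤ 1/fold` down).  Ratio
orientation is fixed as condition 2 / condition 1 throughout.  Quantile
calling operates on reaction-level ratios after GPR mapping (gene-first
mapping, then calling), and separately on metabolite ratios.  In GPR
evaluation an AND with any data-less leaf is undefined, while an OR
averages its defined children only — isoenzymes with partial data still
inform the reaction.

## Solver

Problems are built on optlang's GLPK backend.  GLPK's stock MILP paths
proved unreliable at this coefficient range (`eps`/`M′` spans eight orders
of magnitude): its MIP presolver rounds away implied binary bounds of
order `eps/M′` and returns "optimal" points violating `eps`-scale rows;
warm-started branch-and-bound misreports feasibility on re-solves; and the
plain integer optimizer can prune a feasible tree to "no solution" even
with every integer column fixed.  The package therefore solves MILPs with
its own depth-first branch-and-bound over the integer columns, in which
GLPK performs only LP solves: nodes are solved from scratch with the
simplex presolver, a node counts as infeasible only if the presolved and
the plain dual simplex agree, branching continues until every integer
column is pinned exactly, and the incumbent is re-solved with integers
fixed to populate the solution store.  GLPK's own modes remain as
fallbacks (accepted only after row-by-row verification of the returned
point) for the rare node-budget overrun.  Integrality tolerance is 1e-9;
simplex feasibility stays at GLPK's default 1e-7, because tightening it
further makes GLPK's branch-and-bound prune feasible nodes.

Flux-range endpoints produced under these constraints are meaningful only
up to the enforcement slack `eps = 1e-5` (basal and ratio rows bind at
`eps`); range-nesting comparisons and the internal monotonicity check of
`FluxRangeReport` therefore use a tolerance of 2e-5 rather than an
LP-level one.

## Synthetic data

The toy generator produces four topologies — linear chain, branched
diamond, isoenzyme chain (OR and AND GPRs), and a hub metabolite with two
producers and two consumers — each with exchange reactions, a biomass
sink, uptake capped at 10, and optional reversible reactions.  Simulated
omics plant up-regulated entities with ratios in (2, 4), down-regulated
with the reciprocal band, and log-uniform noise in (0.9, 1.1) elsewhere,
so fold-change calling at 2 recovers exactly the planted sets; baselines
are uniform in (50, 150).  Randomized consistency problems plant 2–5
reaction calls (mixed directions, so conflicts arise), up to 2 metabolite
calls, and random reaction energies in (−50, 45) kJ/mol covering ~70% of
internal reactions, redrawing deterministically when the thermodynamic
base model cannot grow.  These toys exercise conflict resolution,
branch selection, and thermodynamic blocking, but not genome-scale
degeneracy, compartmentalization, noisy low-expression genes, or GPRs
deeper than two levels — passing tests bound correctness of the
machinery, not biological accuracy on real data.

The brute-force oracle enumerates consistency-binary assignments by
fixed-binary feasibility tests (same solver, same tolerances — chosen
deliberately so oracle and solver share one feasibility notion), pruning
supersets of infeasible active sets, which is sound because enforcing more
constraints only restricts the feasible set.  It refuses more than 16
binaries.

## Design choices on open points

* Exchange/boundary reactions are split like any other reversible
  reaction.
* Relative flexibility uses range widths (`v_max − v_min`), sign-equivalent
  to the signed differences sometimes written; a reaction "carries flux in
  the reference state" if either reference endpoint exceeds 1e-6 in
  magnitude, and zero-width reference ranges are excluded from averages,
  never divided.
* BDR counting uses a 1e-6 tolerance on both signs; `n1` refers to the
  mutant model by convention.
* Score summaries use the population (divisor-`n`) standard deviation,
  which is the estimator that matches the published summary rows.
* `d_r(0, 0)` is defined as 0 (no change between two silent fluxes).
* Benchmark comparisons are restricted to reactions present in all flux
  maps; unmatched ids are reported, and net (not split) fluxes are
  compared.

## Known limitations

* GLPK is the only available MILP backend; the custom branch-and-bound
  makes small problems reliable but would not scale to genome-scale
  enumeration the way a commercial solver does.  Genome-scale runs are
  supported by the same code path but untested here at that size.
* Metabolite-branch semantics beyond the mirrored/literal switch (e.g.
  per-branch ratios) are not modeled.
* Scores and enumerations are exact set-wise; flux values carry the
  `eps`-scale ambiguity discussed above.
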