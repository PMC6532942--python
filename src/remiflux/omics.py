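"""Two-condition omics tables -> entity ratios -> up/down regulation calls.

Ratio orientation is fixed throughout as condition2 / condition1 (read:
"mutant over wildtype").  Gene ratios are lifted to reaction ratios through
the GPR tree: AND nodes (complexes) take the geometric mean of child ratios,
OR nodes (isoenzymes) the arithmetic mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .model_core import GprNode, MetabolicModel

__all__ = [
    "RatioMap",
    "RegulationSet",
    "OmicsDataError",
    "compute_gene_ratios",
    "reaction_ratio",
    "reaction_ratios",
    "metabolite_ratios",
    "call_regulation",
    "read_level_table",
]


class OmicsDataError(ValueError):
    pass


@dataclass
class RatioMap:
    """Entity -> strictly positive condition2/condition1 ratio.

    ``excluded`` lists ids dropped for missing data or a zero condition-1
    level (no pseudo-count is applied).
    """

    kind: str  # "gene", "reaction", or "metabolite"
    ratios: dict[str, float] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in ("gene", "reaction", "metabolite"):
            raise ValueError(f"unknown ratio kind {self.kind!r}")
        for k, v in self.ratios.items():
            if not (v > 0):
                raise OmicsDataError(f"{self.kind} {k!r}: ratio must be > 0, got {v}")

    def __len__(self) -> int:
        return len(self.ratios)

    def __getitem__(self, key: str) -> float:
        return self.ratios[key]


def _as_series(table) -> pd.Series:
    if isinstance(table, pd.Series):
        return table.astype(float)
    if isinstance(table, Mapping):
        return pd.Series(dict(table), dtype=float)
    raise TypeError(f"expected mapping or Series, got {type(table)}")


def read_level_table(path: str | Path) -> pd.Series:
    """Read a two-column delimited (id, level) table into a Series."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise OmicsDataError(f"{path}: expected two columns (id, level)")
    return pd.Series(df.iloc[:, 1].astype(float).values, index=df.iloc[:, 0].astype(str))


def _ratio_map(cond1, cond2, kind: str) -> RatioMap:
    s1, s2 = _as_series(cond1), _as_series(cond2)
    if (s1 < 0).any() or (s2 < 0).any():
        bad = list(s1[s1 < 0].index) + list(s2[s2 < 0].index)
        raise OmicsDataError(f"negative {kind} levels for: {sorted(set(map(str, bad)))}")
    ratios: dict[str, float] = {}
    excluded: list[str] = []
    for gid in sorted(set(s1.index) | set(s2.index), key=str):
        if gid not in s1.index or gid not in s2.index:
            excluded.append(str(gid))
            continue
        lvl1, lvl2 = float(s1[gid]), float(s2[gid])
        if lvl1 == 0 or lvl2 == 0:
            excluded.append(str(gid))
            continue
        ratios[str(gid)] = lvl2 / lvl1
    return RatioMap(kind=kind, ratios=ratios, excluded=excluded)


def compute_gene_ratios(expr_cond1, expr_cond2) -> RatioMap:
    """Gene-level level2/level1 ratios; zero or missing entries are excluded."""
    return _ratio_map(expr_cond1, expr_cond2, "gene")


def metabolite_ratios(met_cond1, met_cond2) -> RatioMap:
    """Metabolite-level abundance ratios, same rules as gene ratios."""
    return _ratio_map(met_cond1, met_cond2, "metabolite")


def reaction_ratio(gpr: GprNode | None, gene_ratios: RatioMap | Mapping[str, float]) -> float | None:
    """Evaluate a GPR tree over gene ratios into one tentative flux ratio.

    AND -> geometric mean of children; OR -> arithmetic mean of *defined*
    children (isoenzymes with partial data still inform the reaction); a leaf
    without data is undefined, and an AND with any undefined child is
    undefined.  Returns None when undefined or when the GPR is empty.
    """
    ratios = gene_ratios.ratios if isinstance(gene_ratios, RatioMap) else gene_ratios
    if gpr is None:
        return None
    if gpr.kind == "gene":
        return ratios.get(gpr.gene)
    vals = [reaction_ratio(c, ratios) for c in gpr.children]
    if gpr.kind == "and":
        if any(v is None for v in vals):
            return None
        return math.exp(sum(math.log(v) for v in vals) / len(vals))
    defined = [v for v in vals if v is not None]
    if not defined:
        return None
    return sum(defined) / len(defined)


def reaction_ratios(model: MetabolicModel, gene_ratios: RatioMap) -> RatioMap:
    """Map gene ratios onto every reaction with a defined GPR evaluation."""
    ratios: dict[str, float] = {}
    excluded: list[str] = []
    for r in model.reactions:
        val = reaction_ratio(r.gpr, gene_ratios)
        if val is None:
            excluded.append(r.id)
        else:
            ratios[r.id] = val
    return RatioMap(kind="reaction", ratios=ratios, excluded=excluded)


@dataclass
class RegulationSet:
    """Up/down calls for reactions and metabolites with their ratios p, p'."""

    up_reactions: dict[str, float] = field(default_factory=dict)
    down_reactions: dict[str, float] = field(default_factory=dict)
    up_metabolites: dict[str, float] = field(default_factory=dict)
    down_metabolites: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if set(self.up_reactions) & set(self.down_reactions):
            raise ValueError("a reaction cannot be both up- and downregulated")
        if set(self.up_metabolites) & set(self.down_metabolites):
            raise ValueError("a metabolite cannot be both up- and downregulated")

    @property
    def n(self) -> int:
        """Number of reaction constraints (u + d)."""
        return len(self.up_reactions) + len(self.down_reactions)

    @property
    def n_met(self) -> int:
        """Number of metabolite constraints (u' + d')."""
        return len(self.up_metabolites) + len(self.down_metabolites)

    @property
    def tmcs(self) -> int:
        """Theoretical maximum consistency score: all available constraints."""
        return self.n + self.n_met

    def merge(self, other: "RegulationSet") -> "RegulationSet":
        return RegulationSet(
            up_reactions={**self.up_reactions, **other.up_reactions},
            down_reactions={**self.down_reactions, **other.down_reactions},
            up_metabolites={**self.up_metabolites, **other.up_metabolites},
            down_metabolites={**self.down_metabolites, **other.down_metabolites},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d, kind, direction in (
            (self.up_reactions, "reaction", "up"),
            (self.down_reactions, "reaction", "down"),
            (self.up_metabolites, "metabolite", "up"),
            (self.down_metabolites, "metabolite", "down"),
        ):
            rows.extend({"id": k, "kind": kind, "direction": direction, "ratio": v}
                        for k, v in sorted(d.items()))
        return pd.DataFrame(rows, columns=["id", "kind", "direction", "ratio"])


def call_regulation(
    ratios: RatioMap,
    method: str = "quantile",
    q: float = 0.05,
    fold: float = 2.0,
) -> RegulationSet:
    """Call up/down regulation from a ratio map.

    quantile: the top ceil(q*N) ratios are up, the bottom ceil(q*N) down;
    ties at the boundary are included (order-independent); ids falling in both
    tails (fully tied data) are dropped from both so the sets stay disjoint.
    fold: ratio >= fold is up, ratio <= 1/fold is down.
    """
    if not ratios.ratios:
        raise OmicsDataError("ratio map is empty")
    if method == "quantile":
        if not (0 < q < 0.5):
            raise ValueError(f"tail fraction q must lie in (0, 0.5), got {q}")
        items = sorted(ratios.ratios.items(), key=lambda kv: (kv[1], kv[0]))
        k = math.ceil(q * len(items))
        low_cut = items[k - 1][1]
        high_cut = items[-k][1]
        up = {i: v for i, v in items if v >= high_cut}
        down = {i: v for i, v in items if v <= low_cut}
        overlap = set(up) & set(down)
        for i in overlap:
            up.pop(i)
            down.pop(i)
    elif method == "fold":
        if fold <= 1:
            raise ValueError(f"fold threshold must be > 1, got {fold}")
        up = {i: v for i, v in ratios.ratios.items() if v >= fold}
        down = {i: v for i, v in ratios.ratios.items() if v <= 1.0 / fold}
    else:
        raise ValueError(f"unknown regulation-calling method {method!r}")
    if ratios.kind == "metabolite":
        return RegulationSet(up_metabolites=up, down_metabolites=down)
    return RegulationSet(up_reactions=up, down_reactions=down)
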