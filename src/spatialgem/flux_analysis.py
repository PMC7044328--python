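"""Flux-dependency scans and forced-flux robustness / compensation analysis.

* :func:`dependency_scan` — which gene knockouts abolish the maximal flux
  through a target reaction (genes "essential for" that reaction).
* :func:`robustness_curve` — growth as the target reaction's flux is forced
  upward (lower bound at a rising fraction of its maximum feasible flux);
  with the lower-bound formulation the curve is non-increasing because the
  feasible sets are nested.
* :func:`compensation_scan` — with the forced flux at its maximum, how much
  a supply reaction's uptake bound must be scaled to restore growth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fba_core import disabled_by_knockout, fba, fva
from .model_io import MetabolicModel

__all__ = [
    "DependencyResult",
    "RobustnessCurve",
    "CompensationResult",
    "dependency_scan",
    "robustness_curve",
    "compensation_scan",
    "DEFAULT_MULTIPLIERS",
]

EPS_FLUX = 1e-6
DEFAULT_MULTIPLIERS = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0)
#: growth fraction (of the unconstrained optimum) counted as "restored"
RESTORE_FRACTION = 0.99


@dataclass
class DependencyResult:
    target_reaction: str
    wt_max_flux: float
    max_flux_by_gene: dict[str, float]
    essential_genes: set[str]

    def frame(self) -> pd.DataFrame:
        genes = sorted(self.max_flux_by_gene)
        return pd.DataFrame(
            {
                "max_target_flux": [self.max_flux_by_gene[g] for g in genes],
                "essential": [g in self.essential_genes for g in genes],
            },
            index=pd.Index(genes, name="gene"),
        )


@dataclass
class RobustnessCurve:
    reaction: str
    max_flux: float
    fractions: np.ndarray
    growth_pct: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fraction": self.fractions, "growth_pct": self.growth_pct}
        )


@dataclass
class CompensationResult:
    forced_reaction: str
    supply_reaction: str
    multipliers: np.ndarray
    growth_pct: np.ndarray
    restoring_multiplier: float  # inf when no grid multiplier restores

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"multiplier": self.multipliers, "growth_pct": self.growth_pct}
        )


def dependency_scan(
    model: MetabolicModel,
    target_reaction: str,
    eps_flux: float = EPS_FLUX,
) -> DependencyResult:
    """Genes essential for a target reaction's maximal flux.

    The LP objective is the target flux; each gene knockout that drops the
    attainable maximum below ``eps_flux`` is essential for the reaction.
    """
    wt = fba(model, objective_id=target_reaction)
    if not wt.ok or wt.objective_value < eps_flux:
        raise ValueError(
            f"target {target_reaction!r} carries no flux in the wild type"
        )
    by_gene: dict[str, float] = {}
    essential: set[str] = set()
    for g in sorted(model.gene_ids):
        disabled = disabled_by_knockout(model, {g})
        if not disabled:
            by_gene[g] = wt.objective_value
            continue
        lb, ub = model.lb.copy(), model.ub.copy()
        for rid in disabled:
            j = model.reaction_index(rid)
            lb[j] = ub[j] = 0.0
        sol = fba(model, objective_id=target_reaction, lb=lb, ub=ub)
        v = sol.objective_value if sol.ok else 0.0
        by_gene[g] = max(v, 0.0)
        if by_gene[g] < eps_flux:
            essential.add(g)
    return DependencyResult(target_reaction, wt.objective_value, by_gene, essential)


def robustness_curve(
    model: MetabolicModel,
    reaction: str,
    n_points: int = 21,
    equality: bool = False,
) -> RobustnessCurve:
    """Growth (% of unconstrained max) vs forced flux through a reaction.

    For each fraction f in [0, 1] the reaction's lower bound is set to
    f·v_max (or both bounds, with ``equality=True``) and biomass is
    re-maximized. Infeasible points record 0% growth.
    """
    wt = fba(model)
    if not wt.ok or wt.objective_value <= 0:
        raise ValueError("model must be viable for a robustness curve")
    j = model.reaction_index(reaction)
    vmax_sol = fba(model, objective_id=reaction)
    if not vmax_sol.ok:
        raise ValueError(f"cannot maximize flux of {reaction!r}: {vmax_sol.status}")
    vmax = vmax_sol.objective_value
    fractions = np.linspace(0.0, 1.0, n_points)
    growth = np.zeros(n_points)
    for i, f in enumerate(fractions):
        lb, ub = model.lb.copy(), model.ub.copy()
        lb[j] = max(lb[j], f * vmax)
        if equality:
            ub[j] = lb[j]
        sol = fba(model, lb=lb, ub=ub)
        growth[i] = (
            max(0.0, 100.0 * sol.objective_value / wt.objective_value) if sol.ok else 0.0
        )
    return RobustnessCurve(reaction, vmax, fractions, growth)


def compensation_scan(
    model: MetabolicModel,
    forced_reaction: str,
    supply_reaction: str,
    multipliers: Sequence[float] = DEFAULT_MULTIPLIERS,
    restore_fraction: float = RESTORE_FRACTION,
) -> CompensationResult:
    """Supply-scaling needed to restore growth under a maximal forced flux.

    The forced reaction's lower bound is pinned at its maximum feasible flux
    (the robustness-curve f = 1 endpoint); for each multiplier m the supply
    reaction's uptake bound is scaled by m and biomass re-maximized. Growth
    is reported as % of the *unconstrained* model's optimum, along with the
    smallest grid multiplier reaching ``restore_fraction`` of it (inf if
    none does).
    """
    wt = fba(model)
    if not wt.ok or wt.objective_value <= 0:
        raise ValueError("model must be viable for a compensation scan")
    jf = model.reaction_index(forced_reaction)
    js = model.reaction_index(supply_reaction)
    vmax = fba(model, objective_id=forced_reaction).objective_value
    multipliers = np.asarray(list(multipliers), dtype=float)
    growth = np.zeros(len(multipliers))
    for i, m in enumerate(multipliers):
        lb, ub = model.lb.copy(), model.ub.copy()
        lb[jf] = max(lb[jf], vmax)
        # scale the uptake capacity: positive ub for a forward uptake,
        # negative lb for an exchange-style uptake
        if ub[js] > 0:
            ub[js] = model.ub[js] * m
        if lb[js] < 0:
            lb[js] = model.lb[js] * m
        sol = fba(model, lb=lb, ub=ub)
        growth[i] = (
            max(0.0, 100.0 * sol.objective_value / wt.objective_value) if sol.ok else 0.0
        )
    restored = multipliers[growth >= 100.0 * restore_fraction]
    restoring = float(restored[0]) if restored.size else float("inf")
    return CompensationResult(
        forced_reaction, supply_reaction, multipliers, growth, restoring
    )
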