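"""Flux balance analysis primitives.

FBA maximizes an objective flux (biomass by default) over the steady-state
polytope {v : S·v = 0, lb ≤ v ≤ ub}; FVA reports per-reaction flux ranges over
the same polytope; gene knockouts disable every reaction whose GPR evaluates
false without the gene and re-solve.

The LP backend is HiGHS via :func:`scipy.optimize.linprog`. Only objective
values are contractual — flux vectors at degenerate optima are not unique.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .model_io import MetabolicModel, knockout_gpr

__all__ = [
    "FluxSolution",
    "KnockoutRecord",
    "fba",
    "fva",
    "knockout_gene",
    "screen_all_genes",
    "LETHAL_FRACTION",
]

#: knockouts reducing growth below this fraction of wild type are lethal
LETHAL_FRACTION = 0.01

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class FluxSolution:
    objective_value: float
    fluxes: dict[str, float]
    status: str

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class KnockoutRecord:
    gene_id: str
    disabled_reactions: set[str]
    growth_ratio: float
    lethal: bool


def _solve(
    model: MetabolicModel,
    c: np.ndarray,
    maximize: bool = True,
    lb: np.ndarray | None = None,
    ub: np.ndarray | None = None,
):
    lb = model.lb if lb is None else lb
    ub = model.ub if ub is None else ub
    res = linprog(
        -c if maximize else c,
        A_eq=model.S,
        b_eq=np.zeros(model.n_metabolites),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    return res


def fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    lb: np.ndarray | None = None,
    ub: np.ndarray | None = None,
) -> FluxSolution:
    """Maximize ``objective_id`` (default: the model's biomass reaction)."""
    j = model.reaction_index(objective_id or model.objective_id)
    c = np.zeros(model.n_reactions)
    c[j] = 1.0
    res = _solve(model, c, maximize=True, lb=lb, ub=ub)
    status = _STATUS.get(res.status, f"solver_status_{res.status}")
    if res.status != 0:
        return FluxSolution(float("nan"), {}, status)
    fluxes = dict(zip(model.reaction_ids, map(float, res.x)))
    return FluxSolution(float(res.x[j]), fluxes, "optimal")


def fva(
    model: MetabolicModel,
    reactions: Sequence[str] | None = None,
    fraction_of_optimum: float | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-reaction (min, max) flux over the feasible set.

    If ``fraction_of_optimum`` is given, the objective flux is first pinned to
    at least that fraction of its FBA optimum; otherwise the objective is left
    unconstrained.
    """
    rxns = list(reactions) if reactions is not None else list(model.reaction_ids)
    lb, ub = model.lb.copy(), model.ub.copy()
    if fraction_of_optimum is not None:
        wt = fba(model)
        if not wt.ok:
            raise ValueError(f"FVA reference FBA not optimal: {wt.status}")
        lb[model.objective_index] = max(
            lb[model.objective_index], fraction_of_optimum * wt.objective_value
        )
    out: dict[str, tuple[float, float]] = {}
    for rid in rxns:
        j = model.reaction_index(rid)
        c = np.zeros(model.n_reactions)
        c[j] = 1.0
        lo = _solve(model, c, maximize=False, lb=lb, ub=ub)
        hi = _solve(model, c, maximize=True, lb=lb, ub=ub)
        if lo.status != 0 or hi.status != 0:
            raise ValueError(
                f"FVA infeasible/unbounded for reaction {rid}: "
                f"{_STATUS.get(lo.status)}/{_STATUS.get(hi.status)}"
            )
        out[rid] = (float(lo.x[j]), float(hi.x[j]))
    return out


def disabled_by_knockout(model: MetabolicModel, genes: Iterable[str]) -> set[str]:
    """Reactions whose GPR turns false when ``genes`` are deleted."""
    genes = set(genes)
    return {
        rid
        for rid, t in zip(model.reaction_ids, model.gpr)
        if t is not None and not knockout_gpr(t, genes)
    }


def knockout_gene(
    model: MetabolicModel,
    gene_id: str,
    wt_growth: float,
    lethal_fraction: float = LETHAL_FRACTION,
) -> KnockoutRecord:
    """Simulate a single-gene deletion; growth ratio is v_KO / v_WT."""
    if not wt_growth > 0:
        raise ValueError("wild-type growth must be positive")
    disabled = disabled_by_knockout(model, {gene_id})
    if not disabled:
        return KnockoutRecord(gene_id, set(), 1.0, False)
    lb, ub = model.lb.copy(), model.ub.copy()
    for rid in disabled:
        j = model.reaction_index(rid)
        lb[j] = ub[j] = 0.0
    sol = fba(model, lb=lb, ub=ub)
    growth = sol.objective_value if sol.ok else 0.0
    ratio = max(growth, 0.0) / wt_growth + 0.0  # normalize -0.0
    return KnockoutRecord(gene_id, disabled, ratio, ratio < lethal_fraction)


def screen_all_genes(
    model: MetabolicModel,
    lethal_fraction: float = LETHAL_FRACTION,
) -> list[KnockoutRecord]:
    """Single-gene knockout screen over every gene, in sorted gene order."""
    wt = fba(model)
    if not wt.ok or not wt.objective_value > 0:
        raise ValueError(
            f"model is not viable before knockout (status {wt.status}, "
            f"growth {wt.objective_value})"
        )
    return [
        knockout_gene(model, g, wt.objective_value, lethal_fraction)
        for g in sorted(model.gene_ids)
    ]
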