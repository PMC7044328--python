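"""Region-specific metabolic submodel extraction (modified mCADRE).

Region expression is turned into reaction evidence: a gene's score is its
mean normalized expression across the region's spots; a reaction's score
comes from its GPR with AND → mean and OR → sum (see
:func:`spatialgem.model_io.score_gpr`). Reactions scoring strictly above the
core threshold (0.2 on the normalized-expression scale) are *core*, as are
reactions without gene control (spontaneous/exchange; they carry an infinite
sentinel score so low expression can never prune them).

Non-core reactions are ranked worst-supported first — ascending expression
score, then ascending connectivity evidence (mean score of reactions sharing
a non-currency metabolite), then reaction id — and greedily removed. A
removal is accepted only if every core reaction can still carry flux
(independent FVA) and biomass remains above a minimal growth rate; accepted
removals also sweep away any reactions they newly block (cascade). The
result is a pruned submodel plus a full audit trail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fba_core import fba, fva
from .model_io import MetabolicModel, score_gpr

__all__ = [
    "CORE_THRESHOLD",
    "RegionScore",
    "ExtractionResult",
    "score_region",
    "pseudo_bulk_score",
    "region_score_from_gene_scores",
    "connectivity_scores",
    "rank_noncore",
    "prune",
    "verify_extraction",
]

#: reactions with mean expression evidence strictly above this are core
CORE_THRESHOLD = 0.2
EPS_FLUX = 1e-6
EPS_GROWTH = 1e-6


@dataclass
class RegionScore:
    region: str
    gene_score: dict[str, float]
    reaction_score: dict[str, float]
    core: set[str]
    connectivity_score: dict[str, float] = field(default_factory=dict)


@dataclass
class ExtractionResult:
    submodel: MetabolicModel
    #: (reaction id, rank in the pruning order, "pruned" | "cascade")
    removed: list[tuple[str, int, str]]
    #: non-core reactions retained, with the reason they survived
    kept_noncore: dict[str, str]

    def audit_frame(self) -> pd.DataFrame:
        rows = [
            {"reaction": rid, "rank": rank, "action": reason}
            for rid, rank, reason in self.removed
        ] + [
            {"reaction": rid, "rank": -1, "action": f"kept: {why}"}
            for rid, why in sorted(self.kept_noncore.items())
        ]
        return pd.DataFrame(rows, columns=["reaction", "rank", "action"])


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def region_score_from_gene_scores(
    model: MetabolicModel,
    gene_scores: Mapping[str, float],
    region: str,
    core_threshold: float = CORE_THRESHOLD,
) -> RegionScore:
    """Reaction scores and core set from per-gene mean expression values."""
    rxn_score: dict[str, float] = {}
    for rid, tree in zip(model.reaction_ids, model.gpr):
        rxn_score[rid] = math.inf if tree is None else score_gpr(tree, gene_scores)
    core = {r for r, s in rxn_score.items() if s > core_threshold}
    rs = RegionScore(region, dict(gene_scores), rxn_score, core)
    rs.connectivity_score = connectivity_scores(model, rxn_score)
    return rs


def score_region(
    model: MetabolicModel,
    expr_by_spot: pd.DataFrame,
    spots_in_region: Sequence[str],
    region: str = "region",
    core_threshold: float = CORE_THRESHOLD,
) -> RegionScore:
    """Score a region from spot-level normalized expression.

    Gene-level score is the mean expression of the gene across the region's
    spots (genes absent from the matrix score 0); reaction scores follow the
    AND-mean / OR-sum rule.
    """
    spots = list(spots_in_region)
    if not spots:
        raise ValueError(f"region {region!r} has no spots")
    missing = [s for s in spots if s not in expr_by_spot.columns]
    if missing:
        raise ValueError(f"spots not in expression matrix: {missing[:5]}")
    means = expr_by_spot[spots].mean(axis=1)
    gene_scores = {g: float(means.get(g, 0.0)) for g in model.gene_ids}
    return region_score_from_gene_scores(model, gene_scores, region, core_threshold)


def pseudo_bulk_score(
    model: MetabolicModel,
    expr_by_spot: pd.DataFrame,
    core_threshold: float = CORE_THRESHOLD,
) -> RegionScore:
    """Score over *all* spots — the pseudo-bulk (section-mean) profile."""
    return score_region(
        model,
        expr_by_spot,
        list(expr_by_spot.columns),
        region="pseudo_bulk",
        core_threshold=core_threshold,
    )


def connectivity_scores(
    model: MetabolicModel, reaction_score: Mapping[str, float]
) -> dict[str, float]:
    """Mean expression score of each reaction's network neighbors.

    Two reactions are neighbors when they share at least one non-currency
    metabolite (currency cofactors like ATP/H2O would otherwise make hub
    edges out of everything). Neighbors whose score is the no-GPR infinite
    sentinel contribute no expression evidence and are skipped; reactions
    with no (informative) neighbors score 0.
    """
    currency_rows = np.array(
        [m in model.currency_ids for m in model.metabolite_ids], dtype=bool
    )
    inc = model.S != 0.0
    inc[currency_rows, :] = False
    # adjacency: reactions sharing >=1 retained metabolite
    adj = (inc.T.astype(int) @ inc.astype(int)) > 0
    np.fill_diagonal(adj, False)
    out: dict[str, float] = {}
    for j, rid in enumerate(model.reaction_ids):
        vals = [
            reaction_score[model.reaction_ids[k]]
            for k in np.nonzero(adj[j])[0]
            if math.isfinite(reaction_score[model.reaction_ids[k]])
        ]
        out[rid] = float(np.mean(vals)) if vals else 0.0
    return out


def rank_noncore(region: RegionScore) -> list[str]:
    """Non-core reactions, worst-supported first.

    Ascending expression score, then ascending connectivity evidence, then
    reaction id — fully deterministic.
    """
    noncore = [r for r in region.reaction_score if r not in region.core]
    return sorted(
        noncore,
        key=lambda r: (
            region.reaction_score[r],
            region.connectivity_score.get(r, 0.0),
            r,
        ),
    )


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------


def _inconsistent(model: MetabolicModel, reactions: Sequence[str], eps: float) -> list[str]:
    ranges = fva(model, reactions)
    return [r for r, (lo, hi) in ranges.items() if max(abs(lo), abs(hi)) < eps]


def prune(
    model: MetabolicModel,
    region: RegionScore,
    eps_flux: float = EPS_FLUX,
    eps_growth: float = EPS_GROWTH,
) -> ExtractionResult:
    """Greedy mCADRE-style pruning of non-core reactions.

    Iterates the :func:`rank_noncore` order; each candidate removal is kept
    only if (a) every core reaction remains flux-consistent (|flux| ≥
    ``eps_flux`` attainable in FVA) and (b) biomass flux stays ≥
    ``eps_growth``; accepted removals also drop reactions they newly block
    (cascade). Core reactions are never cascaded — (a) forbids it.
    """
    wt = fba(model)
    if not wt.ok or wt.objective_value < eps_growth:
        raise ValueError(
            f"input model infeasible before pruning (status {wt.status}, "
            f"growth {wt.objective_value})"
        )
    core = set(region.core)
    order = rank_noncore(region)
    current = model.copy()
    removed: list[tuple[str, int, str]] = []
    kept: dict[str, str] = {}
    for rank, rid in enumerate(order, start=1):
        if rid not in current.reaction_ids:
            continue  # swept by an earlier cascade
        if rid == current.objective_id:
            kept[rid] = "objective reaction"
            continue
        trial = current.remove_reactions([rid])
        sol = fba(trial)
        if not sol.ok or sol.objective_value < eps_growth:
            kept[rid] = "required for growth"
            continue
        core_present = [r for r in trial.reaction_ids if r in core]
        if _inconsistent(trial, core_present, eps_flux):
            kept[rid] = "required for core consistency"
            continue
        removed.append((rid, rank, "pruned"))
        blocked = _inconsistent(trial, trial.reaction_ids, eps_flux)
        blocked = [r for r in blocked if r != trial.objective_id]
        assert not set(blocked) & core, "cascade would block a core reaction"
        if blocked:
            trial = trial.remove_reactions(blocked)
            removed.extend((b, rank, "cascade") for b in blocked)
        current = trial
    for rid in order:
        if rid in current.reaction_ids and rid not in kept:
            kept.setdefault(rid, "required for consistency/growth")
    return ExtractionResult(current, removed, kept)


def verify_extraction(
    result: ExtractionResult,
    core: set[str],
    eps_flux: float = EPS_FLUX,
    eps_growth: float = EPS_GROWTH,
) -> bool:
    """Independent post-hoc check of the extraction invariants via FVA."""
    sub = result.submodel
    sol = fba(sub)
    if not sol.ok or sol.objective_value < eps_growth:
        return False
    core_present = [r for r in sub.reaction_ids if r in core]
    return not _inconsistent(sub, core_present, eps_flux)
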