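"""Differential gene lethality between context-specific models.

A differential hit is a gene whose in-silico knockout is lethal in one model
(e.g. the tumor-specific submodel) but viable in another (pseudo-bulk or
normal). Each hit is explained mechanistically by *rescue genes*: genes
whose reactions exist in the viable model but were pruned from the lethal
one, and whose re-addition (with the viable model's bounds) flips the
knockout back to viable — the alternative metabolic route the lethal context
has lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .fba_core import KnockoutRecord, LETHAL_FRACTION, disabled_by_knockout, fba
from .model_io import MetabolicModel

__all__ = ["DifferentialHit", "differential_screen", "find_rescue_genes", "hits_frame"]


@dataclass
class DifferentialHit:
    gene_id: str
    lethal_in: str
    viable_in: str
    growth_ratio_lethal: float
    growth_ratio_viable: float
    pathway: str = ""
    rescue_genes: set[str] = field(default_factory=set)


def differential_screen(
    screen_a: Sequence[KnockoutRecord],
    screen_b: Sequence[KnockoutRecord],
    label_a: str = "A",
    label_b: str = "B",
) -> list[DifferentialHit]:
    """Genes lethal in screen A but not in screen B.

    Genes missing from screen B's model are treated by B's knockout contract
    (no disabled reactions → growth ratio 1, viable).
    """
    b_by_gene = {r.gene_id: r for r in screen_b}
    hits = []
    for rec in screen_a:
        if not rec.lethal:
            continue
        other = b_by_gene.get(rec.gene_id)
        ratio_b = other.growth_ratio if other is not None else 1.0
        lethal_b = other.lethal if other is not None else False
        if not lethal_b:
            hits.append(
                DifferentialHit(
                    rec.gene_id, label_a, label_b, rec.growth_ratio, ratio_b
                )
            )
    return hits


def _restore_reactions(
    target: MetabolicModel, source: MetabolicModel, rids: Sequence[str]
) -> MetabolicModel:
    """Copy reactions (stoichiometry, bounds, GPR) from source into target."""
    import numpy as np

    out = target.copy()
    met_index = {m: i for i, m in enumerate(out.metabolite_ids)}
    new_cols = []
    for rid in rids:
        j = source.reaction_index(rid)
        col = source.S[:, j]
        stoich = {
            source.metabolite_ids[i]: col[i] for i in np.nonzero(col)[0]
        }
        for m in stoich:
            if m not in met_index:
                met_index[m] = len(out.metabolite_ids)
                out.metabolite_ids.append(m)
        new_cols.append((rid, stoich, source.lb[j], source.ub[j],
                         source.gpr[j], source.subsystem[j]))
    n_met, n_rxn = len(out.metabolite_ids), out.n_reactions + len(new_cols)
    S = np.zeros((n_met, n_rxn))
    S[: out.S.shape[0], : out.S.shape[1]] = out.S
    lb = np.concatenate([out.lb, [c[2] for c in new_cols]])
    ub = np.concatenate([out.ub, [c[3] for c in new_cols]])
    for k, (rid, stoich, *_rest) in enumerate(new_cols):
        for m, coef in stoich.items():
            S[met_index[m], out.S.shape[1] + k] = coef
        out.reaction_ids.append(rid)
        out.gpr.append(new_cols[k][4])
        out.subsystem.append(new_cols[k][5])
    genes = set(out.gene_ids)
    for c in new_cols:
        if c[4] is not None:
            for g in c[4].genes():
                if g not in genes:
                    genes.add(g)
                    out.gene_ids.append(g)
    out.S, out.lb, out.ub = S, lb, ub
    out.validate()
    return out


def find_rescue_genes(
    hit: DifferentialHit,
    model_lethal: MetabolicModel,
    model_viable: MetabolicModel,
    lethal_fraction: float = LETHAL_FRACTION,
) -> set[str]:
    """Single genes whose pruned reactions, re-added, rescue the knockout.

    Candidates are genes of reactions present in the viable model but absent
    from the lethal one. A candidate rescues when re-adding its reactions
    (with viable-model bounds) makes the hit gene's knockout non-lethal in
    the lethal model. Minimal single-gene rescues only; an empty set means
    no single absent gene explains the difference.
    """
    lethal_rxns = set(model_lethal.reaction_ids)
    absent = [r for r in model_viable.reaction_ids if r not in lethal_rxns]
    candidates: set[str] = set()
    for rid in absent:
        j = model_viable.reaction_index(rid)
        t = model_viable.gpr[j]
        if t is not None:
            candidates |= t.genes()
    candidates.discard(hit.gene_id)
    wt = fba(model_lethal)
    rescues: set[str] = set()
    for g in sorted(candidates):
        readd = [r for r in absent if g in (model_viable.gpr[model_viable.reaction_index(r)].genes()
                                            if model_viable.gpr[model_viable.reaction_index(r)] else set())]
        restored = _restore_reactions(model_lethal, model_viable, readd)
        wt_restored = fba(restored)
        if not wt_restored.ok or wt_restored.objective_value <= 0:
            continue
        disabled = disabled_by_knockout(restored, {hit.gene_id})
        lb, ub = restored.lb.copy(), restored.ub.copy()
        for rid in disabled:
            jj = restored.reaction_index(rid)
            lb[jj] = ub[jj] = 0.0
        ko = fba(restored, lb=lb, ub=ub)
        growth = ko.objective_value if ko.ok else 0.0
        if growth / wt_restored.objective_value >= lethal_fraction:
            rescues.add(g)
    # annotate the hit's pathway from the reactions its knockout disables
    if not hit.pathway:
        disabled = disabled_by_knockout(model_lethal, {hit.gene_id})
        subs = sorted(
            {
                model_lethal.subsystem[model_lethal.reaction_index(r)]
                for r in disabled
                if model_lethal.subsystem[model_lethal.reaction_index(r)]
            }
        )
        hit.pathway = "; ".join(subs)
    hit.rescue_genes = rescues
    return rescues


def hits_frame(hits: Sequence[DifferentialHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [h.gene_id for h in hits],
            "lethal_in": [h.lethal_in for h in hits],
            "viable_in": [h.viable_in for h in hits],
            "growth_ratio_lethal": [h.growth_ratio_lethal for h in hits],
            "growth_ratio_viable": [h.growth_ratio_viable for h in hits],
            "pathway": [h.pathway for h in hits],
            "rescue_genes": [",".join(sorted(h.rescue_genes)) for h in hits],
        }
    ).set_index("gene")
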