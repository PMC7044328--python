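"""Hypergeometric enrichment of SV gene sets in metabolic pathways.

Pathways are the model's reaction subsystems; the gene universe should be
the set of metabolic genes that survived the low-expression filter (the
background must match the tested set). For each pathway with K genes in a
universe of N, and n SV genes of which k overlap the pathway, the one-sided
upper-tail p-value is P(X ≥ k) with X ~ Hypergeom(N, K, n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model_io import MetabolicModel

__all__ = ["EnrichmentRow", "enrich", "enrichment_frame", "pathways_from_model"]


@dataclass
class EnrichmentRow:
    pathway: str
    n_universe: int
    n_pathway: int
    n_sv: int
    n_overlap: int
    p_value: float
    neg_log10_p: float
    q_value: float = float("nan")


def pathways_from_model(model: MetabolicModel) -> dict[str, set[str]]:
    """Subsystem → gene set map read off a model's reaction annotations."""
    out: dict[str, set[str]] = {}
    for sub, tree in zip(model.subsystem, model.gpr):
        if not sub or tree is None:
            continue
        out.setdefault(sub, set()).update(tree.genes())
    return out


def enrich(
    sv_genes: Iterable[str],
    pathways: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentRow]:
    """Hypergeometric upper-tail enrichment per pathway, sorted by p-value."""
    universe = set(universe)
    if not universe:
        raise ValueError("gene universe is empty")
    sv = set(sv_genes)
    if not sv <= universe:
        raise ValueError(
            f"SV genes outside the universe: {sorted(sv - universe)[:5]} ..."
        )
    N, n = len(universe), len(sv)
    rows = []
    for name, genes in pathways.items():
        pk = set(genes) & universe
        K = len(pk)
        k = len(pk & sv)
        # P(X >= k) = sf(k - 1)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append(EnrichmentRow(name, N, K, n, k, p, float(-np.log10(p))))
    rows.sort(key=lambda r: (r.p_value, r.pathway))
    if rows:
        _, q, _, _ = multipletests([r.p_value for r in rows], method="fdr_bh")
        for r, qi in zip(rows, q):
            r.q_value = float(qi)
    return rows


def enrichment_frame(rows: Iterable[EnrichmentRow]) -> pd.DataFrame:
    rows = list(rows)
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in rows],
            "n_universe": [r.n_universe for r in rows],
            "n_pathway": [r.n_pathway for r in rows],
            "n_sv": [r.n_sv for r in rows],
            "n_overlap": [r.n_overlap for r in rows],
            "p": [r.p_value for r in rows],
            "q": [r.q_value for r in rows],
            "neg_log10_p": [r.neg_log10_p for r in rows],
        }
    ).set_index("pathway")
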