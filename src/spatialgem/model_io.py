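"""Metabolic model I/O and gene-protein-reaction (GPR) rule handling.

A :class:`MetabolicModel` is a stoichiometric network: metabolites × reactions
matrix ``S``, per-reaction flux bounds (mmol·gDW⁻¹·h⁻¹), boolean GPR rules,
subsystem (pathway) annotations and a biomass objective. Models round-trip
through a JSON dialect (the canonical on-disk form) and import from SBML
Level 3 + fbc.

GPR rules are boolean trees over gene ids (AND = enzyme complex, OR =
isozymes). Two evaluation modes exist:

* :func:`score_gpr` — continuous expression support for a reaction. Because
  spot-level spatial data are sparse, complexes (AND) are scored by the
  *mean* of member-gene expression rather than the conventional min, and
  isozymes (OR) by the *sum*.
* :func:`knockout_gpr` — boolean activity under a set of deleted genes
  (AND = all members present, OR = any isozyme present).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GPRTree",
    "parse_gpr",
    "score_gpr",
    "knockout_gpr",
    "MetabolicModel",
    "edit_gpr",
    "read_model",
    "write_model",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_coords_tsv",
    "write_coords_tsv",
]


# ---------------------------------------------------------------------------
# GPR trees
# ---------------------------------------------------------------------------

_GENE_RE = re.compile(r"[A-Za-z0-9_.\-]+")


@dataclass(frozen=True)
class GPRTree:
    """Node of a boolean gene-reaction rule.

    ``op`` is one of ``"gene"`` (leaf; ``gene`` holds the id), ``"and"`` or
    ``"or"`` (internal; ``children`` holds ≥2 subtrees).
    """

    op: str
    gene: str | None = None
    children: tuple["GPRTree", ...] = ()

    def __post_init__(self) -> None:
        if self.op == "gene":
            if not self.gene:
                raise ValueError("gene leaf requires a gene id")
        elif self.op in ("and", "or"):
            if len(self.children) < 2:
                raise ValueError(f"{self.op} node requires >=2 children")
        else:
            raise ValueError(f"unknown GPR node op {self.op!r}")

    def genes(self) -> set[str]:
        """All gene ids referenced by the rule."""
        if self.op == "gene":
            return {self.gene}  # type: ignore[arg-type]
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def to_string(self) -> str:
        return _unparse(self, top=True)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def gene(gid: str) -> GPRTree:
    return GPRTree("gene", gene=gid)


def and_(*children: GPRTree) -> GPRTree:
    return GPRTree("and", children=tuple(children))


def or_(*children: GPRTree) -> GPRTree:
    return GPRTree("or", children=tuple(children))


def _unparse(t: GPRTree, top: bool = False) -> str:
    if t.op == "gene":
        return t.gene  # type: ignore[return-value]
    sep = f" {t.op} "
    parts = []
    for c in t.children:
        s = _unparse(c)
        # parenthesize a child operator of different precedence level
        if c.op != "gene":
            s = f"({s})"
        parts.append(s)
    body = sep.join(parts)
    return body


class GPRParseError(ValueError):
    pass


class _Tok:
    def __init__(self, text: str):
        self.toks: list[str] = []
        i, n = 0, len(text)
        while i < n:
            ch = text[i]
            if ch.isspace():
                i += 1
            elif ch in "()":
                self.toks.append(ch)
                i += 1
            else:
                m = _GENE_RE.match(text, i)
                if not m:
                    raise GPRParseError(f"bad character {ch!r} in GPR at position {i}")
                self.toks.append(m.group())
                i = m.end()
        self.pos = 0

    def peek(self) -> str | None:
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRParseError("unexpected end of GPR rule")
        self.pos += 1
        return tok


def parse_gpr(rule: str) -> GPRTree | None:
    """Parse a GPR string into a tree; empty/blank rules give ``None``.

    Grammar: case-insensitive ``and`` / ``or`` with parentheses; ``and`` binds
    tighter than ``or``; gene ids match ``[A-Za-z0-9_.-]+``.
    """
    if rule is None or not rule.strip():
        return None
    tk = _Tok(rule)
    tree = _parse_or(tk)
    if tk.peek() is not None:
        raise GPRParseError(f"trailing tokens in GPR rule: {tk.toks[tk.pos:]}")
    return tree


def _parse_or(tk: _Tok) -> GPRTree:
    terms = [_parse_and(tk)]
    while tk.peek() is not None and tk.peek().lower() == "or":
        tk.next()
        terms.append(_parse_and(tk))
    return terms[0] if len(terms) == 1 else GPRTree("or", children=tuple(terms))


def _parse_and(tk: _Tok) -> GPRTree:
    terms = [_parse_atom(tk)]
    while tk.peek() is not None and tk.peek().lower() == "and":
        tk.next()
        terms.append(_parse_atom(tk))
    return terms[0] if len(terms) == 1 else GPRTree("and", children=tuple(terms))


def _parse_atom(tk: _Tok) -> GPRTree:
    tok = tk.next()
    if tok == "(":
        t = _parse_or(tk)
        if tk.next() != ")":
            raise GPRParseError("unbalanced parentheses in GPR rule")
        return t
    if tok == ")" or tok.lower() in ("and", "or"):
        raise GPRParseError(f"unexpected token {tok!r} in GPR rule")
    return GPRTree("gene", gene=tok)


def score_gpr(tree: GPRTree, expr: Mapping[str, float]) -> float:
    """Continuous expression support of a rule.

    Leaf → the gene's score (genes absent from ``expr`` score 0, reflecting
    dropout-heavy spatial data); AND → arithmetic mean of children (complex
    limited by typical, not minimum, member abundance under sparse sampling);
    OR → sum of children (isozyme pools add).
    """
    if tree.op == "gene":
        return float(expr.get(tree.gene, 0.0))
    vals = [score_gpr(c, expr) for c in tree.children]
    if tree.op == "and":
        return float(sum(vals) / len(vals))
    return float(sum(vals))


def knockout_gpr(tree: GPRTree | None, deleted: Iterable[str]) -> bool:
    """Boolean activity of a rule after deleting ``deleted`` genes.

    Reactions without gene control (``tree is None``) stay active.
    """
    if tree is None:
        return True
    deleted = set(deleted)

    def ev(t: GPRTree) -> bool:
        if t.op == "gene":
            return t.gene not in deleted
        if t.op == "and":
            return all(ev(c) for c in t.children)
        return any(ev(c) for c in t.children)

    return ev(tree)


# ---------------------------------------------------------------------------
# MetabolicModel
# ---------------------------------------------------------------------------


@dataclass
class MetabolicModel:
    """Stoichiometric metabolic network with bounds, GPRs and an objective.

    ``S`` is metabolites × reactions; ``lb``/``ub`` are per-reaction flux
    bounds; ``gpr[j]`` is a :class:`GPRTree` or ``None`` (spontaneous /
    exchange reactions); ``objective_id`` names the biomass reaction;
    ``currency_ids`` flags ubiquitous cofactors excluded from reaction
    connectivity.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    gpr: list[GPRTree | None]
    subsystem: list[str]
    gene_ids: list[str]
    objective_id: str
    currency_ids: set[str] = field(default_factory=set)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        n_met, n_rxn = len(self.metabolite_ids), len(self.reaction_ids)
        if self.S.shape != (n_met, n_rxn):
            raise ValueError(
                f"S has shape {self.S.shape}, expected ({n_met}, {n_rxn})"
            )
        if self.lb.shape != (n_rxn,) or self.ub.shape != (n_rxn,):
            raise ValueError("lb/ub must have one entry per reaction")
        if np.any(self.lb > self.ub):
            j = int(np.argmax(self.lb > self.ub))
            raise ValueError(f"lb > ub for reaction {self.reaction_ids[j]}")
        if len(self.gpr) != n_rxn or len(self.subsystem) != n_rxn:
            raise ValueError("gpr/subsystem must have one entry per reaction")
        if self.objective_id not in self.reaction_ids:
            raise ValueError(f"objective {self.objective_id!r} not a reaction id")
        known = set(self.gene_ids)
        for rid, t in zip(self.reaction_ids, self.gpr):
            if t is None:
                continue
            missing = t.genes() - known
            if missing:
                raise ValueError(
                    f"GPR of {rid} references unknown gene(s): {sorted(missing)}"
                )

    # -- indexing ----------------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction {rid!r}") from None

    @property
    def objective_index(self) -> int:
        return self.reaction_index(self.objective_id)

    def reactions_of_gene(self, gid: str) -> list[str]:
        return [
            rid
            for rid, t in zip(self.reaction_ids, self.gpr)
            if t is not None and gid in t.genes()
        ]

    # -- functional updates ------------------------------------------------
    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            gpr=list(self.gpr),
            subsystem=list(self.subsystem),
            gene_ids=list(self.gene_ids),
            objective_id=self.objective_id,
            currency_ids=set(self.currency_ids),
            provenance=list(self.provenance),
        )

    def with_bounds(self, rid: str, lb: float, ub: float) -> "MetabolicModel":
        m = self.copy()
        j = m.reaction_index(rid)
        m.lb[j], m.ub[j] = lb, ub
        return m

    def remove_reactions(self, rids: Iterable[str]) -> "MetabolicModel":
        """Drop reactions (columns) and any metabolites left orphaned."""
        drop = set(rids)
        unknown = drop - set(self.reaction_ids)
        if unknown:
            raise KeyError(f"unknown reaction(s): {sorted(unknown)}")
        if self.objective_id in drop:
            raise ValueError("cannot remove the objective reaction")
        keep = [j for j, rid in enumerate(self.reaction_ids) if rid not in drop]
        S = self.S[:, keep]
        used = np.any(S != 0.0, axis=1)
        m = MetabolicModel(
            metabolite_ids=[mi for mi, u in zip(self.metabolite_ids, used) if u],
            reaction_ids=[self.reaction_ids[j] for j in keep],
            S=S[used, :],
            lb=self.lb[keep],
            ub=self.ub[keep],
            gpr=[self.gpr[j] for j in keep],
            subsystem=[self.subsystem[j] for j in keep],
            gene_ids=list(self.gene_ids),
            objective_id=self.objective_id,
            currency_ids=set(self.currency_ids),
            provenance=list(self.provenance),
        )
        return m


def edit_gpr(model: MetabolicModel, reaction_id: str, new_rule: str) -> MetabolicModel:
    """Return a copy of ``model`` with one reaction's GPR replaced.

    Genes newly introduced by ``new_rule`` are appended to ``gene_ids``; the
    edit is recorded in the model's provenance log.
    """
    j = model.reaction_index(reaction_id)
    tree = parse_gpr(new_rule)
    out = model.copy()
    old = out.gpr[j]
    old_str = old.to_string() if old is not None else ""
    new_str = tree.to_string() if tree is not None else ""
    if old_str == new_str:
        return out
    out.gpr[j] = tree
    if tree is not None:
        for g in sorted(tree.genes()):
            if g not in out.gene_ids:
                out.gene_ids.append(g)
    out.provenance.append(
        f"edit_gpr {reaction_id}: {old_str or '<empty>'} -> {new_str or '<empty>'}"
    )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------


def _model_to_dict(model: MetabolicModel) -> dict:
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        col = model.S[:, j]
        mets = {
            model.metabolite_ids[i]: float(col[i])
            for i in np.nonzero(col)[0]
        }
        t = model.gpr[j]
        rxns.append(
            {
                "id": rid,
                "metabolites": mets,
                "lb": float(model.lb[j]),
                "ub": float(model.ub[j]),
                "gpr": t.to_string() if t is not None else "",
                "subsystem": model.subsystem[j],
            }
        )
    return {
        "metabolites": list(model.metabolite_ids),
        "reactions": rxns,
        "genes": list(model.gene_ids),
        "objective": model.objective_id,
        "currency_metabolites": sorted(model.currency_ids),
        "provenance": list(model.provenance),
    }


def _model_from_dict(d: dict) -> MetabolicModel:
    try:
        met_ids = list(d["metabolites"])
        rxns = d["reactions"]
        genes = list(d.get("genes", []))
        objective = d["objective"]
    except KeyError as e:
        raise ValueError(f"model JSON missing required field {e.args[0]!r}") from None
    met_index = {m: i for i, m in enumerate(met_ids)}
    n_rxn = len(rxns)
    S = np.zeros((len(met_ids), n_rxn))
    lb = np.zeros(n_rxn)
    ub = np.zeros(n_rxn)
    gpr: list[GPRTree | None] = []
    subsystem: list[str] = []
    rids: list[str] = []
    declared = set(genes)
    for j, r in enumerate(rxns):
        rid = r["id"]
        rids.append(rid)
        for mid, coef in r["metabolites"].items():
            if mid not in met_index:
                raise ValueError(
                    f"reaction {rid!r} references unknown metabolite {mid!r}"
                )
            S[met_index[mid], j] = float(coef)
        lb[j], ub[j] = float(r["lb"]), float(r["ub"])
        try:
            t = parse_gpr(r.get("gpr", ""))
        except GPRParseError as e:
            raise ValueError(f"reaction {rid!r}: {e}") from None
        if t is not None:
            missing = t.genes() - declared
            if missing:
                raise ValueError(
                    f"reaction {rid!r} GPR references undeclared gene(s): "
                    f"{sorted(missing)}"
                )
        gpr.append(t)
        subsystem.append(r.get("subsystem", ""))
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rids,
        S=S,
        lb=lb,
        ub=ub,
        gpr=gpr,
        subsystem=subsystem,
        gene_ids=genes,
        objective_id=objective,
        currency_ids=set(d.get("currency_metabolites", [])),
        provenance=list(d.get("provenance", [])),
    )


def write_model(model: MetabolicModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_model_to_dict(model), indent=1, sort_keys=True))


def _read_sbml(path: str | Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ValueError(f"SBML parse error in {path}: {err.getMessage().strip()}")
    sb = doc.getModel()
    if sb is None:
        raise ValueError(f"{path} contains no SBML model")
    fbc = sb.getPlugin("fbc")

    def _strip(sid: str, prefix: str) -> str:
        # cobra-style SBML id convention (M_/R_/G_ prefixes)
        return sid[len(prefix):] if sid.startswith(prefix) else sid

    met_ids = [
        _strip(sb.getSpecies(i).getId(), "M_") for i in range(sb.getNumSpecies())
    ]
    met_index = {m: i for i, m in enumerate(met_ids)}
    n_rxn = sb.getNumReactions()
    S = np.zeros((len(met_ids), n_rxn))
    lb = np.full(n_rxn, -1000.0)
    ub = np.full(n_rxn, 1000.0)
    gpr: list[GPRTree | None] = []
    subsystem: list[str] = []
    rids: list[str] = []

    def _param(pid: str) -> float:
        p = sb.getParameter(pid)
        if p is None:
            raise ValueError(f"SBML flux bound parameter {pid!r} missing")
        return p.getValue()

    def _assoc_to_tree(assoc) -> GPRTree | None:
        import libsbml as _sbml

        if assoc is None:
            return None
        if isinstance(assoc, _sbml.GeneProductRef):
            gp = sb.getPlugin("fbc").getGeneProduct(assoc.getGeneProduct())
            label = _strip(gp.getLabel() or gp.getId(), "G_")
            return GPRTree("gene", gene=label)
        children = [
            _assoc_to_tree(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        ]
        children = [c for c in children if c is not None]
        if not children:
            return None
        if len(children) == 1:
            return children[0]
        op = "and" if isinstance(assoc, _sbml.FbcAnd) else "or"
        return GPRTree(op, children=tuple(children))

    objective_id = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj.getNumFluxObjectives() > 0:
            objective_id = _strip(obj.getFluxObjective(0).getReaction(), "R_")

    for j in range(n_rxn):
        rx = sb.getReaction(j)
        rids.append(_strip(rx.getId(), "R_"))
        for k in range(rx.getNumReactants()):
            sr = rx.getReactant(k)
            S[met_index[_strip(sr.getSpecies(), "M_")], j] -= sr.getStoichiometry()
        for k in range(rx.getNumProducts()):
            sr = rx.getProduct(k)
            S[met_index[_strip(sr.getSpecies(), "M_")], j] += sr.getStoichiometry()
        rfbc = rx.getPlugin("fbc")
        if rfbc is not None:
            if rfbc.isSetLowerFluxBound():
                lb[j] = _param(rfbc.getLowerFluxBound())
            if rfbc.isSetUpperFluxBound():
                ub[j] = _param(rfbc.getUpperFluxBound())
            gpa = rfbc.getGeneProductAssociation()
            gpr.append(_assoc_to_tree(gpa.getAssociation()) if gpa else None)
        else:
            gpr.append(None)
        # subsystem conventionally stored in notes
        sub = ""
        if rx.isSetNotes():
            notes = rx.getNotesString()
            m = re.search(r"SUBSYSTEM:\s*([^<\n]+)", notes)
            if m:
                sub = m.group(1).strip()
        subsystem.append(sub)

    genes = sorted({g for t in gpr if t is not None for g in t.genes()})
    if objective_id is None:
        raise ValueError(f"{path}: no fbc objective found")
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rids,
        S=S,
        lb=lb,
        ub=ub,
        gpr=gpr,
        subsystem=subsystem,
        gene_ids=genes,
        objective_id=objective_id,
        currency_ids=set(),
    )


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a metabolic model from JSON (canonical dialect) or SBML L3+fbc."""
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if format == "json":
        try:
            d = json.loads(path.read_text())
        except json.JSONDecodeError as e:
            raise ValueError(f"malformed model JSON {path}: {e}") from None
        return _model_from_dict(d)
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r} (expected sbml|json)")


# ---------------------------------------------------------------------------
# Expression / coordinate TSV
# ---------------------------------------------------------------------------


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a genes × spots matrix; header row = spot ids, index = gene ids."""
    df.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_coords_tsv(coords: pd.DataFrame, path: str | Path) -> None:
    """Write per-spot coordinates/labels (columns: x, y[, region]; index spot)."""
    coords.to_csv(path, sep="\t", index_label="spot_id")


def read_coords_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in ("x", "y"):
        if col not in df.columns:
            raise ValueError(f"coordinates file {path} lacks required column {col!r}")
    return df
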