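"""Region scoring, connectivity ranking and mCADRE-style pruning."""

import math

import numpy as np
import pandas as pd
import pytest

from spatialgem.gem_extraction import (
    connectivity_scores,
    prune,
    pseudo_bulk_score,
    rank_noncore,
    region_score_from_gene_scores,
    score_region,
    verify_extraction,
)
from spatialgem.model_io import MetabolicModel, parse_gpr
from spatialgem.synthetic_data import expand_to_spots, fixture_network, pseudo_bulk_vector


def chain_abc():
    """R1: x->A, R2: A->B, R3: B->y with single-gene GPRs."""
    S = np.array(
        [
            [1.0, -1.0, 0.0],
            [0.0, 1.0, -1.0],
        ]
    )
    return MetabolicModel(
        metabolite_ids=["A", "B"],
        reaction_ids=["R1", "R2", "R3"],
        S=S,
        lb=np.zeros(3),
        ub=np.full(3, 10.0),
        gpr=[parse_gpr("a"), parse_gpr("b"), parse_gpr("c")],
        subsystem=[""] * 3,
        gene_ids=["a", "b", "c"],
        objective_id="R3",
    )


class TestScoring:
    def test_gene_score_is_region_mean(self):
        model, _ = fixture_network("linear_chain")
        expr = pd.DataFrame(
            {"s1": [0.1, 0.5, 0.5], "s2": [0.5, 0.5, 0.5], "s3": [9.0, 9.0, 9.0]},
            index=["GU1", "GC1", "GC2"],
        )
        rs = score_region(model, expr, ["s1", "s2"], "tumor")
        assert rs.gene_score["GU1"] == pytest.approx(0.3)

    def test_or_sum_can_push_reaction_over_threshold(self):
        model = chain_abc()
        m = model.copy()
        m.gpr[0] = parse_gpr("g1 or g2")
        m.gene_ids = ["g1", "g2", "b", "c"]
        rs = region_score_from_gene_scores(
            m, {"g1": 0.15, "g2": 0.10, "b": 0.5, "c": 0.5}, "r"
        )
        assert rs.reaction_score["R1"] == pytest.approx(0.25)
        assert "R1" in rs.core

    def test_core_threshold_is_strict(self):
        model = chain_abc()
        rs = region_score_from_gene_scores(
            model, {"a": 0.2, "b": 0.2000001, "c": 0.5}, "r"
        )
        assert "R1" not in rs.core
        assert "R2" in rs.core

    def test_empty_gpr_reactions_get_infinite_score_and_core(self):
        model, _ = fixture_network("cysteine")
        rs = region_score_from_gene_scores(model, {"SLC3A2": 0.0, "SLC7A11": 0.0, "CBS": 0.0}, "r")
        assert math.isinf(rs.reaction_score["EX_cys"])
        assert {"EX_cys", "EX_glc", "BIOMASS"} <= rs.core

    def test_empty_region_raises(self):
        model, _ = fixture_network("linear_chain")
        expr = pd.DataFrame({"s1": [1.0, 1.0, 1.0]}, index=["GU1", "GC1", "GC2"])
        with pytest.raises(ValueError):
            score_region(model, expr, [], "empty")

    def test_pseudo_bulk_equals_all_spot_region(self):
        model, expr_vec = fixture_network("cysteine")
        region = ["tumor"] * 10 + ["non_tumor"] * 10
        spots = [f"s{i}" for i in range(20)]
        expr = expand_to_spots(expr_vec, region, spots, noise_sd=0.0)
        bulk = pseudo_bulk_score(model, expr)
        allr = score_region(model, expr, spots, "all")
        assert bulk.gene_score == allr.gene_score
        # the CBS mechanism: 0.6 in half the spots averages to 0.3 -> core
        assert bulk.gene_score["CBS"] == pytest.approx(0.3)
        assert "CBS_SYN" in bulk.core

    def test_single_spot_pseudo_bulk_is_that_spot(self):
        model, _ = fixture_network("linear_chain")
        expr = pd.DataFrame({"only": [0.4, 0.3, 0.9]}, index=["GU1", "GC1", "GC2"])
        bulk = pseudo_bulk_score(model, expr)
        assert bulk.gene_score == {"GU1": 0.4, "GC1": 0.3, "GC2": 0.9}


class TestConnectivity:
    def test_chain_neighbors_averaged(self):
        model = chain_abc()
        scores = {"R1": 0.4, "R2": 0.0, "R3": 0.6}
        conn = connectivity_scores(model, scores)
        assert conn["R2"] == pytest.approx(0.5)
        assert conn["R1"] == pytest.approx(0.0)  # only neighbor R2 scores 0

    def test_currency_only_reaction_has_no_neighbors(self):
        model, _ = fixture_network("acetoacetate")
        scores = {r: 0.5 for r in model.reaction_ids}
        conn = connectivity_scores(model, scores)
        # ATP_REGEN touches only atp/adp, both flagged currency
        assert conn["ATP_REGEN"] == 0.0

    def test_unflagging_currency_adds_neighbors(self):
        model, _ = fixture_network("acetoacetate")
        open_model = model.copy()
        open_model.currency_ids = set()
        scores = {r: 0.5 for r in model.reaction_ids}
        conn_flagged = connectivity_scores(model, scores)
        conn_open = connectivity_scores(open_model, scores)
        assert conn_open["ATP_REGEN"] > conn_flagged["ATP_REGEN"]


class TestRanking:
    def _rs(self, scores, conn):
        from spatialgem.gem_extraction import RegionScore

        return RegionScore("r", {}, scores, set(), conn)

    def test_worst_expression_first(self):
        rs = self._rs({"R1": 0.1, "R2": 0.05}, {"R1": 0.0, "R2": 0.0})
        assert rank_noncore(rs) == ["R2", "R1"]

    def test_connectivity_breaks_expression_ties(self):
        rs = self._rs({"R1": 0.1, "R2": 0.1}, {"R1": 0.5, "R2": 0.1})
        assert rank_noncore(rs) == ["R2", "R1"]

    def test_full_tie_breaks_lexicographically(self):
        rs = self._rs({"Rb": 0.1, "Ra": 0.1}, {"Rb": 0.2, "Ra": 0.2})
        assert rank_noncore(rs) == ["Ra", "Rb"]


class TestPrune:
    @pytest.mark.parametrize(
        "name,depleted_rxn",
        [
            ("cysteine", "CBS_SYN"),
            ("succinate", "FH_PATH"),
            ("acetoacetate", "ACAT2_RXN"),
        ],
    )
    def test_tumor_extraction_removes_depleted_route(self, name, depleted_rxn):
        model, expr = fixture_network(name)
        rs = region_score_from_gene_scores(model, expr["tumor"], "tumor")
        res = prune(model, rs)
        assert [r for r, _, _ in res.removed] == [depleted_rxn]
        assert depleted_rxn not in res.submodel.reaction_ids
        assert verify_extraction(res, rs.core)

    @pytest.mark.parametrize("name", ["cysteine", "succinate", "acetoacetate"])
    def test_pseudo_bulk_extraction_retains_route(self, name):
        model, expr = fixture_network(name)
        bulk = pseudo_bulk_vector(expr)
        rs = region_score_from_gene_scores(model, bulk, "pseudo_bulk")
        res = prune(model, rs)
        assert res.removed == []
        assert res.submodel.reaction_ids == model.reaction_ids

    def test_all_core_means_no_removal(self):
        model, expr = fixture_network("linear_chain")
        rs = region_score_from_gene_scores(model, expr["tumor"], "tumor")
        res = prune(model, rs)
        assert res.removed == []
        assert res.submodel.reaction_ids == model.reaction_ids

    def test_noncore_reaction_required_for_growth_is_kept(self):
        model, _ = fixture_network("linear_chain")
        # STEP1 scores below threshold but is the only path to biomass
        rs = region_score_from_gene_scores(
            model, {"GU1": 0.5, "GC1": 0.05, "GC2": 0.5}, "tumor"
        )
        assert "STEP1" not in rs.core
        res = prune(model, rs)
        assert "STEP1" in res.submodel.reaction_ids
        assert res.kept_noncore["STEP1"] == "required for growth"

    def test_urea_export_kept_for_core_arginase_consistency(self):
        model, expr = fixture_network("urea")
        rs = region_score_from_gene_scores(model, expr["tumor"], "tumor")
        assert "UREA_EXPORT" not in rs.core
        res = prune(model, rs)
        # removing the only urea sink would block core ARGINASE
        assert "UREA_EXPORT" in res.submodel.reaction_ids
        assert "consistency" in res.kept_noncore["UREA_EXPORT"]

    def test_cascade_removes_newly_blocked_reactions(self):
        # uptake -> A -> biomass, plus a dead branch A -> B -> (noncore sink)
        S = np.array(
            [
                [1.0, -1.0, -1.0, 0.0],
                [0.0, 0.0, 1.0, -1.0],
            ]
        )
        model = MetabolicModel(
            metabolite_ids=["A", "B"],
            reaction_ids=["UP", "BIOMASS", "BRANCH", "SINK"],
            S=S,
            lb=np.zeros(4),
            ub=np.full(4, 10.0),
            gpr=[None, None, parse_gpr("gbr"), parse_gpr("gsk")],
            subsystem=[""] * 4,
            gene_ids=["gbr", "gsk"],
            objective_id="BIOMASS",
        )
        rs = region_score_from_gene_scores(model, {"gbr": 0.05, "gsk": 0.1}, "r")
        res = prune(model, rs)
        actions = {r: a for r, _, a in res.removed}
        assert actions == {"BRANCH": "pruned", "SINK": "cascade"}

    def test_infeasible_input_rejected_before_pruning(self):
        model, expr = fixture_network("linear_chain")
        dead = model.with_bounds("UPTAKE", 0.0, 0.0)
        rs = region_score_from_gene_scores(dead, expr["tumor"], "tumor")
        with pytest.raises(ValueError, match="infeasible"):
            prune(dead, rs)

    def test_deterministic_and_objective_shrinks(self, fixture_pair):
        from spatialgem.fba_core import fba

        _, model, expr = fixture_pair
        rs = region_score_from_gene_scores(model, expr["tumor"], "tumor")
        res1, res2 = prune(model, rs), prune(model, rs)
        assert res1.removed == res2.removed
        assert (
            fba(res1.submodel).objective_value
            <= fba(model).objective_value + 1e-9
        )
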