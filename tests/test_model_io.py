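"""GPR grammar/semantics and model round-trip tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spatialgem.model_io import (
    GPRParseError,
    GPRTree,
    edit_gpr,
    knockout_gpr,
    parse_gpr,
    read_model,
    score_gpr,
    write_model,
)
from spatialgem.synthetic_data import fixture_network


def t(s):
    return parse_gpr(s)


class TestParse:
    @pytest.mark.parametrize(
        "rule,expected",
        [
            ("g1", ("gene", "g1")),
            ("g1 and g2", ("and", ("gene", "g1"), ("gene", "g2"))),
            ("g1 or g2", ("or", ("gene", "g1"), ("gene", "g2"))),
            # and binds tighter than or
            ("g1 and g2 or g3", ("or", ("and", ("gene", "g1"), ("gene", "g2")), ("gene", "g3"))),
            ("(g1 and g2) or g3", ("or", ("and", ("gene", "g1"), ("gene", "g2")), ("gene", "g3"))),
            ("g1 AND (g2 Or g3)", ("and", ("gene", "g1"), ("or", ("gene", "g2"), ("gene", "g3")))),
        ],
    )
    def test_grammar(self, rule, expected):
        def shape(node):
            if node.op == "gene":
                return ("gene", node.gene)
            return (node.op, *[shape(c) for c in node.children])

        assert shape(t(rule)) == expected

    def test_empty_rule_is_none(self):
        assert parse_gpr("") is None
        assert parse_gpr("   ") is None

    @pytest.mark.parametrize("bad", ["g1 and", "(g1 or g2", "and g1", "g1 ) g2", "g1 g2"])
    def test_malformed_rules_raise(self, bad):
        with pytest.raises(GPRParseError):
            parse_gpr(bad)

    def test_string_round_trip(self):
        for rule in ["g1", "g1 and g2", "(g1 and g2) or g3", "g1 or (g2 and (g3 or g4))"]:
            tree = t(rule)
            assert parse_gpr(tree.to_string()).to_string() == tree.to_string()


class TestScore:
    expr = {"g1": 2.0, "g2": 4.0, "g3": 6.0}

    def test_and_is_mean(self):
        assert score_gpr(t("g1 and g2"), self.expr) == 3.0

    def test_or_is_sum(self):
        assert score_gpr(t("g1 or g2"), self.expr) == 6.0

    def test_composition(self):
        assert score_gpr(t("(g1 and g2) or g3"), self.expr) == 9.0

    def test_missing_gene_scores_zero(self):
        assert score_gpr(t("g1 and unknown"), self.expr) == 1.0
        assert score_gpr(t("unknown"), self.expr) == 0.0

    @given(
        vals=st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=5),
        op=st.sampled_from(["and", "or"]),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, derandomize=True)
    def test_permutation_invariant_and_nonnegative(self, vals, op, seed):
        genes = [f"g{i}" for i in range(len(vals))]
        expr = dict(zip(genes, vals))
        tree = GPRTree(op, children=tuple(GPRTree("gene", gene=g) for g in genes))
        perm = list(genes)
        np.random.default_rng(seed).shuffle(perm)
        ptree = GPRTree(op, children=tuple(GPRTree("gene", gene=g) for g in perm))
        assert score_gpr(tree, expr) == pytest.approx(score_gpr(ptree, expr))
        assert score_gpr(tree, expr) >= 0.0


class TestKnockout:
    def test_complex_requires_all_members(self):
        assert knockout_gpr(t("g1 and g2"), {"g1"}) is False

    def test_isozyme_remains(self):
        assert knockout_gpr(t("g1 or g2"), {"g1"}) is True

    def test_empty_deletion_always_true(self):
        for rule in ["g1", "g1 and g2", "(g1 or g2) and g3"]:
            assert knockout_gpr(t(rule), set()) is True

    def test_no_gpr_reaction_stays_active(self):
        assert knockout_gpr(None, {"g1"}) is True


class TestModelIO:
    def test_json_round_trip_is_identity(self, tmp_path, fixture_pair):
        name, model, _ = fixture_pair
        p = tmp_path / f"{name}.json"
        write_model(model, p)
        back = read_model(p)
        assert back.metabolite_ids == model.metabolite_ids
        assert back.reaction_ids == model.reaction_ids
        assert np.array_equal(back.S, model.S)
        assert np.array_equal(back.lb, model.lb)
        assert np.array_equal(back.ub, model.ub)
        assert back.gene_ids == model.gene_ids
        assert back.objective_id == model.objective_id
        assert back.subsystem == model.subsystem
        assert back.currency_ids == model.currency_ids
        for a, b in zip(back.gpr, model.gpr):
            assert (a is None) == (b is None)
            if a is not None:
                assert a.to_string() == b.to_string()

    def test_unknown_gene_in_gpr_rejected(self, tmp_path):
        import json

        model, _ = fixture_network("linear_chain")
        p = tmp_path / "m.json"
        write_model(model, p)
        doc = json.loads(p.read_text())
        next(r for r in doc["reactions"] if r["id"] == "STEP1")["gpr"] = "NOT_DECLARED"
        p.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="NOT_DECLARED"):
            read_model(p)

    def test_malformed_json_names_file(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(ValueError, match="bad.json"):
            read_model(p)

    def test_sbml_import_via_cobra_export(self, tmp_path):
        cobra = pytest.importorskip("cobra")
        from test_fba_core import to_cobra

        model, _ = fixture_network("cysteine")
        cm = to_cobra(model)
        path = tmp_path / "cys.xml"
        cobra.io.write_sbml_model(cm, str(path))
        back = read_model(path, format="sbml")
        assert back.n_reactions == model.n_reactions
        assert back.objective_id.endswith("BIOMASS")
        # GPR of the transporter survives as the same AND complex
        j = [i for i, r in enumerate(back.reaction_ids) if r.endswith("CYSt")][0]
        assert back.gpr[j].genes() == {"SLC3A2", "SLC7A11"}


class TestEditGPR:
    def test_add_or_alternative_transporter(self):
        model, _ = fixture_network("cysteine")
        edited = edit_gpr(model, "CYSt", "(SLC3A2 and SLC7A11) or SLC27A2")
        j = edited.reaction_index("CYSt")
        assert edited.gpr[j].genes() == {"SLC3A2", "SLC7A11", "SLC27A2"}
        assert "SLC27A2" in edited.gene_ids
        assert any("edit_gpr CYSt" in line for line in edited.provenance)
        # original untouched
        assert model.gpr[model.reaction_index("CYSt")].genes() == {"SLC3A2", "SLC7A11"}

    def test_replace_gene(self):
        model, _ = fixture_network("linear_chain")
        edited = edit_gpr(model, "STEP1", "ACSL4")
        assert edited.gpr[edited.reaction_index("STEP1")].genes() == {"ACSL4"}

    def test_identical_rule_is_noop(self):
        model, _ = fixture_network("linear_chain")
        edited = edit_gpr(model, "STEP1", "GC1")
        assert edited.provenance == model.provenance

    def test_unknown_reaction_raises(self):
        model, _ = fixture_network("linear_chain")
        with pytest.raises(KeyError):
            edit_gpr(model, "NO_SUCH_RXN", "GC1")
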