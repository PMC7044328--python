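"""Normalization, GP likelihood-ratio test and t-test baseline."""

import numpy as np
import pandas as pd
import pytest

from spatialgem.sv_detection import (
    GPLikelihoodRatioTest,
    fit_sv_gene,
    infer_pitch,
    normalize,
    sv_results_frame,
    sv_screen,
    ttest_screen,
)
from spatialgem.synthetic_data import se_kernel


class TestNormalize:
    def test_equal_rates_normalize_equally(self):
        counts = pd.DataFrame([[10.0, 20.0]], index=["g"], columns=["s1", "s2"])
        out = normalize(counts, spot_totals=[100.0, 200.0], min_expressed_spots=1)
        # both spots express at rate 0.1; median total 150 -> log2(1 + 15)
        assert np.allclose(out.to_numpy(), np.log2(16.0))

    def test_low_expression_gene_filtered(self):
        counts = pd.DataFrame(
            {"s1": [0, 5], "s2": [0, 5], "s3": [1, 5]}, index=["rare", "common"]
        )
        out = normalize(counts, min_expressed_spots=2)
        assert list(out.index) == ["common"]

    def test_equal_totals_reduce_to_log2_counts(self):
        counts = pd.DataFrame(
            {"s1": [3.0], "s2": [7.0]}, index=["g"]
        )
        out = normalize(counts, spot_totals=[50.0, 50.0], min_expressed_spots=1)
        assert np.allclose(out.to_numpy(), np.log2(1 + counts.to_numpy()))

    def test_zero_total_names_spot(self):
        counts = pd.DataFrame({"s1": [1], "bad_spot": [0]}, index=["g"])
        with pytest.raises(ValueError, match="bad_spot"):
            normalize(counts, spot_totals=[10.0, 0.0], min_expressed_spots=1)


class TestGPTest:
    def test_constant_gene_gives_null(self, grid_coords):
        res = fit_sv_gene(np.full(len(grid_coords), 3.3), grid_coords)
        assert res.lr_stat == 0.0 and res.p_value == 1.0

    def test_spatial_signal_detected(self, grid_coords):
        rng = np.random.default_rng(0)
        K = se_kernel(grid_coords, 400.0)
        L = np.linalg.cholesky(K + 1e-8 * np.eye(len(grid_coords)))
        y = L @ rng.standard_normal(len(grid_coords))
        y += 0.2 * rng.standard_normal(len(grid_coords))
        res = fit_sv_gene(y, grid_coords)
        assert res.p_value < 1e-4
        assert res.best_lengthscale_um in (200.0, 400.0, 800.0)

    def test_lr_nonnegative_and_alt_dominates_null(self, grid_coords):
        rng = np.random.default_rng(1)
        runner = GPLikelihoodRatioTest(grid_coords)
        for _ in range(10):
            r = runner.fit(rng.standard_normal(len(grid_coords)))
            assert r.lr_stat >= 0.0
            assert r.ll_spatial >= r.ll_null - 1e-6

    def test_affine_invariance(self, grid_coords):
        rng = np.random.default_rng(2)
        runner = GPLikelihoodRatioTest(grid_coords)
        y = rng.standard_normal(len(grid_coords))
        base = runner.fit(y)
        for a, b in [(2.5, 0.0), (1.0, -7.0), (0.3, 4.2)]:
            res = runner.fit(a * y + b)
            assert res.lr_stat == pytest.approx(base.lr_stat, abs=1e-4)

    def test_pitch_inference(self, grid_coords):
        assert infer_pitch(grid_coords) == pytest.approx(200.0)

    def test_too_few_spots_rejected(self):
        coords = np.array([[0.0, 0.0], [200.0, 0.0]])
        with pytest.raises(ValueError):
            fit_sv_gene(np.array([1.0, 2.0]), coords)


class TestSVScreen:
    def _expr(self, grid_coords, n_null=20, n_sv=5, seed=0):
        rng = np.random.default_rng(seed)
        n = len(grid_coords)
        K = se_kernel(grid_coords, 400.0)
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        rows, names = [], []
        for i in range(n_sv):
            rows.append(L @ rng.standard_normal(n) + 0.2 * rng.standard_normal(n))
            names.append(f"sv{i}")
        for i in range(n_null):
            rows.append(rng.standard_normal(n))
            names.append(f"null{i}")
        return pd.DataFrame(rows, index=names)

    def test_bh_qvalues_dominate_pvalues_and_flag_signal(self, grid_coords):
        expr = self._expr(grid_coords)
        res = sv_screen(expr, grid_coords, alpha=0.05)
        df = sv_results_frame(res)
        assert (df["q"] >= df["p"] - 1e-12).all()
        # q monotone in p
        s = df.sort_values("p")
        assert (np.diff(s["q"]) >= -1e-12).all()
        assert all(df.loc[f"sv{i}", "is_sv"] for i in range(5))

    def test_alpha_zero_flags_nothing(self, grid_coords):
        expr = self._expr(grid_coords, n_null=5, n_sv=2)
        res = sv_screen(expr, grid_coords, alpha=0.0)
        assert not any(r.is_sv for r in res)

    def test_model_restricts_to_metabolic_genes(self, grid_coords):
        from spatialgem.synthetic_data import fixture_network

        model, _ = fixture_network("linear_chain")
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(
            rng.standard_normal((4, len(grid_coords))),
            index=["GU1", "GC1", "other1", "other2"],
        )
        res = sv_screen(expr, grid_coords, model=model)
        assert {r.gene_id for r in res} == {"GU1", "GC1"}

    def test_section_overlap_is_set_intersection(self, grid_coords):
        a = {r.gene_id for r in sv_screen(self._expr(grid_coords, seed=1), grid_coords) if r.is_sv}
        b = {r.gene_id for r in sv_screen(self._expr(grid_coords, seed=2), grid_coords) if r.is_sv}
        assert a & b == {g for g in a if g in b}
        assert a & b <= a | b


class TestTTest:
    def test_welch_closed_form(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], index=["g"])
        labels = ["tumor"] * 3 + ["normal"] * 3
        out = ttest_screen(expr, labels)
        assert out.loc["g", "t"] == pytest.approx(-3.674, abs=1e-3)

    def test_identical_groups_p_one(self):
        expr = pd.DataFrame([[2.0, 2.0, 2.0, 2.0]], index=["g"])
        out = ttest_screen(expr, ["tumor", "tumor", "normal", "normal"])
        assert out.loc["g", "t"] == 0.0
        assert out.loc["g", "p"] == 1.0

    def test_regional_shift_detected(self):
        rng = np.random.default_rng(0)
        labels = ["tumor"] * 30 + ["stroma"] * 30
        base = rng.normal(0, 0.1, (10, 60))
        base[0, :30] += 2.0  # strong tumor shift in one gene
        expr = pd.DataFrame(base, index=[f"g{i}" for i in range(10)])
        out = ttest_screen(expr, labels)
        assert out.loc["g0", "q"] < 0.05
        assert (out.drop("g0")["q"] > 0.05).all()

    def test_small_group_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"])
        with pytest.raises(ValueError):
            ttest_screen(expr, ["tumor", "normal", "normal"])
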