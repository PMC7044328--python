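"""Spatially variable (SV) gene detection.

A gene is SV when its expression covariance depends on inter-spot distance.
Per gene, two Gaussian models are compared:

* alternative: ``y ~ MVN(μ·1, σ²(K_ℓ + δI))`` with squared-exponential
  kernel ``K_ℓ[i,j] = exp(−‖xᵢ−xⱼ‖² / 2ℓ²)`` over a grid of lengthscales ℓ,
* null: ``y ~ MVN(μ·1, σ²I)``.

μ and σ² are profiled analytically after an eigendecomposition of ``K_ℓ``
(done once per lengthscale and shared across genes); the noise-to-signal
ratio δ is optimized numerically on log δ. The likelihood-ratio statistic
``2(ll_alt − ll_null)``, clipped at zero, is referred to χ²(1); since the
null sits on the boundary of the alternative (δ → ∞), this reference is
conservative. Benjamini–Hochberg q-values control the FDR across genes.

A Welch t-test screen (tumor vs non-tumor spots) is provided as the baseline
the spatial test is contrasted against.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .synthetic_data import se_kernel

__all__ = [
    "SVResult",
    "normalize",
    "GPLikelihoodRatioTest",
    "fit_sv_gene",
    "sv_screen",
    "ttest_screen",
    "sv_results_frame",
]

#: default lengthscale grid, in multiples of the spot pitch
LENGTHSCALE_FACTORS = (0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass
class SVResult:
    gene_id: str
    ll_spatial: float
    ll_null: float
    lr_stat: float
    p_value: float
    best_lengthscale_um: float
    q_value: float = float("nan")
    is_sv: bool = False


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize(
    counts: pd.DataFrame,
    spot_totals: Sequence[float] | None = None,
    min_expressed_spots: int = 10,
) -> pd.DataFrame:
    """Total-count normalize and log2-transform a genes × spots count matrix.

    ``value[g, s] = log2(1 + counts[g, s] / total_s · median(total))``; genes
    detected in fewer than ``min_expressed_spots`` spots are dropped as
    low-expression. ``spot_totals`` defaults to the column sums but should be
    whole-transcriptome totals when the counts cover only a gene subset.
    """
    counts = counts.astype(float)
    if np.any(counts.to_numpy() < 0):
        raise ValueError("counts must be non-negative")
    if spot_totals is None:
        totals = counts.sum(axis=0).to_numpy()
    else:
        totals = np.asarray(spot_totals, dtype=float)
        if totals.shape != (counts.shape[1],):
            raise ValueError("spot_totals must have one entry per spot")
    if np.any(totals <= 0):
        bad = counts.columns[int(np.argmax(totals <= 0))]
        raise ValueError(f"spot {bad!r} has zero total counts")
    scale = np.median(totals)
    values = np.log2(1.0 + counts.to_numpy() / totals[None, :] * scale)
    out = pd.DataFrame(values, index=counts.index, columns=counts.columns)
    expressed = (counts.to_numpy() > 0).sum(axis=1)
    return out.loc[expressed >= min_expressed_spots]


# ---------------------------------------------------------------------------
# GP likelihood-ratio test
# ---------------------------------------------------------------------------


def infer_pitch(coords: np.ndarray) -> float:
    """Median nearest-neighbor distance — the array's center-to-center pitch."""
    coords = np.asarray(coords, dtype=float)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    return float(np.median(np.sqrt(d2.min(axis=1))))


class GPLikelihoodRatioTest:
    """Per-section runner: eigendecomposes each kernel once, fits many genes."""

    def __init__(
        self,
        coords: np.ndarray,
        lengthscales: Sequence[float] | None = None,
        log_delta_bounds: tuple[float, float] = (-10.0, 10.0),
    ):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be spots × 2")
        self.n = coords.shape[0]
        if self.n < 10:
            raise ValueError("need at least 10 spots for the spatial test")
        if lengthscales is None:
            pitch = infer_pitch(coords)
            lengthscales = [f * pitch for f in LENGTHSCALE_FACTORS]
        self.lengthscales = [float(l) for l in lengthscales]
        self.log_delta_bounds = log_delta_bounds
        self._decomps = []
        ones = np.ones(self.n)
        for l in self.lengthscales:
            K = se_kernel(coords, l)
            w, U = np.linalg.eigh(K)
            w = np.clip(w, 0.0, None)
            self._decomps.append((l, w, U.T @ ones, U))

    # profiled negative log-likelihood pieces -------------------------------
    @staticmethod
    def _profile_ll(w: np.ndarray, yt: np.ndarray, ot: np.ndarray, log_delta: float):
        n = yt.shape[0]
        D = w + math.exp(log_delta)
        oD = ot / D
        mu = float(oD @ yt) / float(oD @ ot)
        r = yt - mu * ot
        rss = float(r @ (r / D))
        if rss <= 0:
            return -np.inf
        sigma2 = rss / n
        return -0.5 * (
            n * math.log(2.0 * math.pi) + float(np.log(D).sum()) + n * math.log(sigma2) + n
        )

    def fit(self, y: np.ndarray, gene_id: str = "") -> SVResult:
        """Fit both models to one gene's per-spot values."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError("y must have one value per spot")
        if not np.all(np.isfinite(y)):
            raise ValueError("y must be finite")
        n = self.n
        var = float(np.var(y))
        if var <= 0 or np.ptp(y) == 0:
            return SVResult(gene_id, 0.0, 0.0, 0.0, 1.0, float("nan"))
        ll_null = -0.5 * n * (math.log(2.0 * math.pi * var) + 1.0)

        best_ll, best_l = -np.inf, float("nan")
        lo, hi = self.log_delta_bounds
        for l, w, ot, U in self._decomps:
            yt = U.T @ y
            nll = lambda ld: -self._profile_ll(w, yt, ot, ld)
            res = optimize.minimize_scalar(
                nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-3}
            )
            ll = -res.fun
            # the bounded search can miss the flat δ→∞ limit; check endpoints
            for ld in (lo, hi):
                ll = max(ll, self._profile_ll(w, yt, ot, ld))
            if ll > best_ll:
                best_ll, best_l = ll, l
        # the null lies in the closure of the alternative (δ → ∞), so the
        # alternative's maximized likelihood is at least the null's
        best_ll = max(best_ll, ll_null)
        lr = max(0.0, 2.0 * (best_ll - ll_null))
        p = float(stats.chi2.sf(lr, df=1))
        return SVResult(gene_id, best_ll, ll_null, lr, p, best_l)


def fit_sv_gene(
    y: np.ndarray,
    coords: np.ndarray,
    lengthscales: Sequence[float] | None = None,
) -> SVResult:
    """One-gene convenience wrapper over :class:`GPLikelihoodRatioTest`."""
    return GPLikelihoodRatioTest(coords, lengthscales).fit(y)


def sv_screen(
    expr: pd.DataFrame,
    coords: np.ndarray,
    alpha: float = 0.05,
    lengthscales: Sequence[float] | None = None,
    model=None,
) -> list[SVResult]:
    """SV test for every gene with BH q-values; ``is_sv ⇔ q ≤ alpha``.

    If a metabolic ``model`` is supplied, only genes present in its GPRs are
    screened (the metabolic-gene subset).
    """
    if model is not None:
        keep = [g for g in expr.index if g in set(model.gene_ids)]
        expr = expr.loc[keep]
    runner = GPLikelihoodRatioTest(coords, lengthscales)
    results = [runner.fit(expr.loc[g].to_numpy(), g) for g in expr.index]
    if results:
        pvals = np.array([r.p_value for r in results])
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(results, qvals):
            r.q_value = float(q)
            r.is_sv = bool(q <= alpha) if alpha > 0 else False
    return results


def sv_results_frame(results: Sequence[SVResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene_id for r in results],
            "ll_spatial": [r.ll_spatial for r in results],
            "ll_null": [r.ll_null for r in results],
            "lr_stat": [r.lr_stat for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
            "lengthscale_um": [r.best_lengthscale_um for r in results],
            "is_sv": [r.is_sv for r in results],
        }
    ).set_index("gene")


# ---------------------------------------------------------------------------
# t-test baseline
# ---------------------------------------------------------------------------


def ttest_screen(
    expr: pd.DataFrame,
    region_labels: Sequence[str],
    tumor_label: str = "tumor",
) -> pd.DataFrame:
    """Welch two-sample t-test per gene, tumor vs all non-tumor spots."""
    labels = np.asarray(list(region_labels))
    if labels.shape != (expr.shape[1],):
        raise ValueError("region_labels must have one entry per spot")
    in_tumor = labels == tumor_label
    if in_tumor.sum() < 2 or (~in_tumor).sum() < 2:
        raise ValueError("both tumor and non-tumor groups need >= 2 spots")
    a = expr.to_numpy()[:, in_tumor]
    b = expr.to_numpy()[:, ~in_tumor]
    with warnings.catch_warnings():
        # constant genes trigger scipy's precision-loss warning; the
        # degenerate outputs are replaced explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # zero variance in both groups with equal means: no evidence, not NaN
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({"t": t, "p": p, "q": q}, index=expr.index)
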