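"""Synthetic spatial transcriptomics data and fixture metabolic networks.

The spatial simulator emulates an ST-style array section: a square spot grid
at 200 μm pitch, a circular tumor region with an annular normal rim inside a
stromal background, spatially covarying genes (squared-exponential Gaussian
process on log intensity) against white-noise genes, region-restricted genes
(present outside the tumor, absent inside — the CBS/FH/ACAT2 pattern), and
per-spot library-size variation with Poisson counts.

The fixture networks are hand-built ≤20-reaction models, each encoding one
of the differential-lethality mechanisms studied downstream: a target gene
whose knockout is lethal only in the tumor-specific model because the
alternative route (CBS / FH / ACAT2 analog) is expressed only outside the
tumor, plus a urea-cycle fixture for forced-flux robustness and arginine
compensation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model_io import (
    MetabolicModel,
    parse_gpr,
    write_coords_tsv,
    write_expression_tsv,
    write_model,
)

__all__ = [
    "SimConfig",
    "SpatialDataset",
    "simulate_spatial",
    "fixture_network",
    "FIXTURE_NAMES",
    "expand_to_spots",
    "random_feasible_network",
]


# ---------------------------------------------------------------------------
# Spatial simulator
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Parameters of the synthetic section.

    Defaults emulate the study conditions: 200 μm center-to-center spot
    pitch, a few hundred spots per section, GP lengthscale twice the pitch,
    signal-to-noise 5 on the log scale, and per-spot library sizes around a
    few thousand reads with the tested (metabolic) genes a minority share of
    the transcriptome.
    """

    n_spots_side: int = 15
    pitch_um: float = 200.0
    n_genes: int = 200
    frac_sv: float = 0.2
    #: fraction of SV genes that are region-restricted rather than GP-smooth
    frac_regional: float = 0.25
    gp_lengthscale_um: float = 400.0
    gp_variance: float = 1.0
    noise_variance: float = 0.2
    library_size_mean: int = 5000
    #: share of each spot's reads carried by the simulated (tested) genes;
    #: the remainder is a flat whole-transcriptome background
    tested_fraction: float = 0.2
    tumor_radius_um: float = 800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_sv <= 1.0):
            raise ValueError("frac_sv must lie in [0, 1]")
        for name in (
            "n_spots_side",
            "pitch_um",
            "n_genes",
            "gp_lengthscale_um",
            "gp_variance",
            "noise_variance",
            "library_size_mean",
            "tumor_radius_um",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SpatialDataset:
    """Genes × spots counts with coordinates, region labels and ground truth.

    ``total_counts`` holds per-spot whole-transcriptome read totals (tested
    genes plus flat background); normalization should divide by these, as the
    real pipeline normalizes to the totals of *all* genes, not just the
    tested subset.
    """

    counts: np.ndarray  # genes × spots, non-negative ints
    gene_ids: list[str]
    spot_ids: list[str]
    coords: np.ndarray  # spots × 2, μm
    region: list[str]
    truth: list[str]  # per gene: sv_spatial | sv_regional | flat
    total_counts: np.ndarray | None = None
    latent_intensity: np.ndarray | None = None  # genes × spots, pre-Poisson

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.spot_ids)):
            raise ValueError("counts must be genes × spots")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.coords.shape != (len(self.spot_ids), 2):
            raise ValueError("coords must be spots × 2")
        if len({tuple(xy) for xy in self.coords}) != len(self.spot_ids):
            raise ValueError("spot coordinates must be pairwise distinct")
        if len(self.region) != len(self.spot_ids):
            raise ValueError("region must label every spot")

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.spot_ids)

    def coords_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coords, index=self.spot_ids, columns=["x", "y"])
        df["region"] = self.region
        if self.total_counts is not None:
            df["total_counts"] = self.total_counts
        return df

    def spot_totals(self) -> np.ndarray:
        """Per-spot totals to normalize against (whole-transcriptome if known)."""
        if self.total_counts is not None:
            return np.asarray(self.total_counts, dtype=float)
        return self.counts.sum(axis=0).astype(float)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_expression_tsv(self.counts_frame(), outdir / "counts.tsv")
        write_coords_tsv(self.coords_frame(), outdir / "coords.tsv")
        pd.Series(self.truth, index=self.gene_ids, name="truth").to_csv(
            outdir / "truth.tsv", sep="\t", index_label="gene"
        )


def se_kernel(coords: np.ndarray, lengthscale: float, variance: float = 1.0) -> np.ndarray:
    """Squared-exponential covariance over spot coordinates."""
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    return variance * np.exp(-d2 / (2.0 * lengthscale**2))


def _gp_draws(
    coords: np.ndarray, lengthscale: float, variance: float, n_draws: int, rng
) -> np.ndarray:
    """Zero-mean GP draws (n_draws × spots) via jittered Cholesky."""
    K = se_kernel(coords, lengthscale, variance)
    n = K.shape[0]
    jitter = 1e-8 * np.trace(K) / n
    L = np.linalg.cholesky(K + jitter * np.eye(n))
    z = rng.standard_normal((n_draws, n))
    return z @ L.T


def assign_regions(
    coords: np.ndarray, tumor_radius_um: float, normal_outer_factor: float = 1.5
) -> list[str]:
    """Concentric geometry: central tumor disc, annular normal rim, stroma."""
    center = coords.mean(axis=0)
    r = np.hypot(*(coords - center).T)
    out = np.where(
        r <= tumor_radius_um,
        "tumor",
        np.where(r <= normal_outer_factor * tumor_radius_um, "normal", "stroma"),
    )
    return list(out)


def simulate_spatial(cfg: SimConfig) -> SpatialDataset:
    """Simulate one synthetic section; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    side, n_genes = cfg.n_spots_side, cfg.n_genes
    n_spots = side * side
    xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    coords = np.column_stack([xs.ravel(), ys.ravel()]) * cfg.pitch_um
    spot_ids = [f"s{i:04d}" for i in range(n_spots)]
    region = assign_regions(coords, cfg.tumor_radius_um)
    not_tumor = np.array([r != "tumor" for r in region], dtype=float)

    n_sv = int(round(cfg.frac_sv * n_genes))
    n_regional = int(round(cfg.frac_regional * n_sv))
    n_spatial = n_sv - n_regional
    truth = (
        ["sv_spatial"] * n_spatial + ["sv_regional"] * n_regional + ["flat"] * (n_genes - n_sv)
    )
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]

    # log-intensity: GP + iid noise for sv_spatial, iid noise otherwise
    eta = rng.standard_normal((n_genes, n_spots)) * np.sqrt(cfg.noise_variance)
    if n_spatial:
        eta[:n_spatial] += _gp_draws(
            coords, cfg.gp_lengthscale_um, cfg.gp_variance, n_spatial, rng
        )
    intensity = np.exp(eta)
    # region-restricted genes: latent intensity exactly zero inside the tumor
    if n_regional:
        intensity[n_spatial : n_spatial + n_regional] *= not_tumor[None, :]

    # per-spot library size with ~35% lognormal variation, mean preserved
    sigma_lib = 0.3
    lib = cfg.library_size_mean * rng.lognormal(-0.5 * sigma_lib**2, sigma_lib, n_spots)
    tested_target = cfg.tested_fraction * lib
    mean_tested_intensity = intensity.sum(axis=0).mean()
    lam = intensity * (tested_target / mean_tested_intensity)[None, :]
    counts = rng.poisson(lam)
    background = rng.poisson((1.0 - cfg.tested_fraction) * lib)
    total_counts = counts.sum(axis=0) + background

    return SpatialDataset(
        counts=counts,
        gene_ids=gene_ids,
        spot_ids=spot_ids,
        coords=coords,
        region=region,
        truth=truth,
        total_counts=total_counts,
        latent_intensity=lam,
    )


def expand_to_spots(
    vectors: Mapping[str, Mapping[str, float]],
    region: list[str],
    spot_ids: list[str],
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Expand per-region gene score vectors to a genes × spots matrix.

    Each spot gets its region's score plus iid Gaussian noise, clipped at 0 —
    a spot-level stand-in for end-to-end tests of region scoring, which
    consumes mean-per-region values.
    """
    rng = np.random.default_rng(seed)
    genes = sorted({g for v in vectors.values() for g in v})
    mat = np.zeros((len(genes), len(spot_ids)))
    for j, reg in enumerate(region):
        if reg not in vectors:
            raise KeyError(f"no expression vector for region {reg!r}")
        v = vectors[reg]
        mat[:, j] = [v.get(g, 0.0) for g in genes]
    mat = np.clip(mat + rng.normal(0.0, noise_sd, mat.shape) * (mat > 0), 0.0, None)
    return pd.DataFrame(mat, index=genes, columns=spot_ids)


# ---------------------------------------------------------------------------
# Fixture metabolic networks
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("cysteine", "succinate", "acetoacetate", "urea", "linear_chain")


def _build(mets, rxns, genes, objective, currency=()):
    """rxns: list of (id, {met: coef}, lb, ub, gpr string, subsystem)."""
    met_index = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(rxns)))
    lb, ub, gpr, subsystem, rids = [], [], [], [], []
    for j, (rid, stoich, lo, hi, rule, sub) in enumerate(rxns):
        rids.append(rid)
        for m, c in stoich.items():
            S[met_index[m], j] = c
        lb.append(lo)
        ub.append(hi)
        gpr.append(parse_gpr(rule))
        subsystem.append(sub)
    return MetabolicModel(
        metabolite_ids=list(mets),
        reaction_ids=rids,
        S=S,
        lb=np.array(lb),
        ub=np.array(ub),
        gpr=gpr,
        subsystem=subsystem,
        gene_ids=list(genes),
        objective_id=objective,
        currency_ids=set(currency),
    )


def fixture_network(name: str) -> tuple[MetabolicModel, dict[str, dict[str, float]]]:
    """Hand-built fixture model plus tumor / non-tumor gene score vectors.

    In every tumor-vs-bulk fixture the tumor vector zeroes the alternative-
    route gene (CBS, FH or ACAT2 analog) while the non-tumor vector keeps it
    above the core threshold, so region-specific extraction deletes exactly
    that route in the tumor model and the route's partner gene becomes
    selectively lethal there.
    """
    if name == "cysteine":
        # cysteine for biomass: import via the SLC3A2/SLC7A11 complex, or
        # synthesize de novo via CBS from central carbon
        model = _build(
            mets=["cys_e", "cys_c", "glc_c"],
            rxns=[
                ("EX_cys", {"cys_e": 1}, 0, 10, "", "Exchange"),
                ("EX_glc", {"glc_c": 1}, 0, 10, "", "Exchange"),
                ("CYSt", {"cys_e": -1, "cys_c": 1}, 0, 10,
                 "SLC3A2 and SLC7A11", "Transport, extracellular"),
                ("CBS_SYN", {"glc_c": -1, "cys_c": 1}, 0, 10,
                 "CBS", "Cysteine metabolism"),
                ("BIOMASS", {"cys_c": -1, "glc_c": -1}, 0, 1000, "", "Biomass"),
            ],
            genes=["SLC3A2", "SLC7A11", "CBS"],
            objective="BIOMASS",
        )
        expr = {
            "tumor": {"SLC3A2": 0.5, "SLC7A11": 0.5, "CBS": 0.0},
            "non_tumor": {"SLC3A2": 0.5, "SLC7A11": 0.5, "CBS": 0.6},
        }
    elif name == "succinate":
        # succinate feeds a biomass precursor either through the heme
        # synthesis/degradation route (HMBS analog) or through FH
        model = _build(
            mets=["succ_c", "gly_c", "prec_c"],
            rxns=[
                ("EX_succ", {"succ_c": 1}, 0, 10, "", "Exchange"),
                ("EX_gly", {"gly_c": 1}, 0, 10, "", "Exchange"),
                ("HEME_PATH", {"succ_c": -1, "gly_c": -1, "prec_c": 1}, 0, 10,
                 "HMBS", "Heme synthesis"),
                ("FH_PATH", {"succ_c": -1, "prec_c": 1}, 0, 10,
                 "FH", "Citric acid cycle"),
                ("BIOMASS", {"prec_c": -1}, 0, 1000, "", "Biomass"),
            ],
            genes=["HMBS", "FH"],
            objective="BIOMASS",
        )
        expr = {
            "tumor": {"HMBS": 0.5, "FH": 0.0},
            "non_tumor": {"HMBS": 0.5, "FH": 0.6},
        }
    elif name == "acetoacetate":
        # acetoacetyl-CoA (cholesterol precursor) made either by the
        # ATP-dependent AACS route or by ACAT2 condensation of acetyl-CoA
        model = _build(
            mets=["acac_c", "accoa_c", "aacoa_c", "atp_c", "adp_c"],
            rxns=[
                ("EX_acac", {"acac_c": 1}, 0, 10, "", "Exchange"),
                ("EX_accoa", {"accoa_c": 1}, 0, 10, "", "Exchange"),
                ("AACS_RXN", {"acac_c": -1, "atp_c": -1, "aacoa_c": 1, "adp_c": 1},
                 0, 10, "AACS", "Ketone body metabolism"),
                ("ACAT2_RXN", {"accoa_c": -2, "aacoa_c": 1}, 0, 10,
                 "ACAT2", "Cholesterol metabolism"),
                ("ATP_REGEN", {"adp_c": -1, "atp_c": 1}, 0, 1000, "",
                 "Oxidative phosphorylation"),
                ("BIOMASS", {"aacoa_c": -1, "accoa_c": -1}, 0, 1000, "", "Biomass"),
            ],
            genes=["AACS", "ACAT2"],
            objective="BIOMASS",
            currency=["atp_c", "adp_c"],
        )
        expr = {
            "tumor": {"AACS": 0.5, "ACAT2": 0.0},
            "non_tumor": {"AACS": 0.5, "ACAT2": 0.6},
        }
    elif name == "urea":
        # arginine is used for growth or catabolized by arginase to
        # ornithine (polyamine precursor) + urea, exported by SLC14A1;
        # de novo arginine synthesis and OAT-derived ornithine set the
        # compensation arithmetic: max urea flux 1.4, uptake bound 0.4,
        # so restoring full growth at forced urea flux needs 4.5× uptake
        model = _build(
            mets=["arg_c", "orn_c", "urea_c", "glu_c"],
            rxns=[
                ("ARG_UPTAKE", {"arg_c": 1}, 0, 0.4,
                 "SLC7A1", "Transport, extracellular"),
                ("EX_glu", {"glu_c": 1}, 0, 10, "", "Exchange"),
                ("ARG_SYNTH", {"glu_c": -1, "arg_c": 1}, 0, 1.0,
                 "ASS1", "Urea cycle"),
                ("OAT_RXN", {"glu_c": -1, "orn_c": 1}, 0, 10,
                 "OAT", "Arginine and proline metabolism"),
                ("ARGINASE", {"arg_c": -1, "orn_c": 1, "urea_c": 1}, 0, 10,
                 "ARG2", "Urea cycle"),
                ("UREA_EXPORT", {"urea_c": -1}, 0, 10,
                 "SLC14A1", "Transport, extracellular"),
                ("POLYAMINE", {"orn_c": -1}, 0, 10,
                 "ODC1", "Polyamine synthesis"),
                ("BIOMASS", {"arg_c": -1, "orn_c": -0.5}, 0, 1000, "", "Biomass"),
            ],
            genes=["SLC7A1", "ASS1", "OAT", "ARG2", "SLC14A1", "ODC1"],
            objective="BIOMASS",
        )
        expr = {
            "tumor": {"SLC7A1": 0.5, "ASS1": 0.5, "OAT": 0.5, "ARG2": 0.5,
                      "ODC1": 0.5, "SLC14A1": 0.0},
            "non_tumor": {"SLC7A1": 0.5, "ASS1": 0.5, "OAT": 0.5, "ARG2": 0.5,
                          "ODC1": 0.5, "SLC14A1": 0.6},
        }
    elif name == "linear_chain":
        model = _build(
            mets=["A", "B", "C"],
            rxns=[
                ("UPTAKE", {"A": 1}, 0, 10, "GU1", "Exchange"),
                ("STEP1", {"A": -1, "B": 1}, 0, 10, "GC1", "Chain"),
                ("STEP2", {"B": -1, "C": 1}, 0, 10, "GC2", "Chain"),
                ("BIOMASS", {"C": -1}, 0, 1000, "", "Biomass"),
            ],
            genes=["GU1", "GC1", "GC2"],
            objective="BIOMASS",
        )
        expr = {
            "tumor": {"GU1": 0.5, "GC1": 0.5, "GC2": 0.5},
            "non_tumor": {"GU1": 0.5, "GC1": 0.5, "GC2": 0.5},
        }
    else:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    return model, expr


def pseudo_bulk_vector(
    expr: Mapping[str, Mapping[str, float]],
    weights: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Spot-weighted mean of per-region score vectors (equal weights default).

    With the alternative-route gene at 0 in the tumor half and 0.6 outside,
    the 50/50 pseudo-bulk score is 0.3 — still above the 0.2 core threshold,
    which is exactly why bulk averaging hides region-specific gene loss.
    """
    regions = list(expr)
    if weights is None:
        weights = {r: 1.0 / len(regions) for r in regions}
    total = sum(weights[r] for r in regions)
    genes = sorted({g for v in expr.values() for g in v})
    return {
        g: sum(weights[r] * expr[r].get(g, 0.0) for r in regions) / total
        for g in genes
    }


def random_feasible_network(seed: int, n_layers: int | None = None) -> MetabolicModel:
    """Random layered network, feasible by construction (growth > 0).

    Metabolite layers M0 → … → Mk are connected by 1–2 parallel reactions
    with random bounds; an uptake feeds M0 and biomass drains Mk. Used for
    property tests (e.g. robustness-curve monotonicity) on varied topologies.
    """
    rng = np.random.default_rng(seed)
    k = n_layers if n_layers is not None else int(rng.integers(2, 5))
    mets = [f"M{i}" for i in range(k + 1)]
    rxns = [("UPTAKE", {"M0": 1}, 0.0, float(rng.uniform(2, 10)), "", "Exchange")]
    genes: list[str] = []
    for i in range(k):
        n_par = int(rng.integers(1, 3))
        for p in range(n_par):
            g = f"gl{i}p{p}"
            genes.append(g)
            rxns.append(
                (
                    f"R{i}_{p}",
                    {mets[i]: -1.0, mets[i + 1]: 1.0},
                    0.0,
                    float(rng.uniform(1, 10)),
                    g,
                    "Chain",
                )
            )
        if rng.random() < 0.3:
            rxns.append(
                (f"SINK{i}", {mets[i]: -1.0}, 0.0, float(rng.uniform(0.5, 3)), "", "Sink")
            )
    rxns.append(("BIOMASS", {mets[k]: -1.0}, 0.0, 1000.0, "", "Biomass"))
    return _build(mets, rxns, genes, "BIOMASS")


def write_fixture(name: str, outdir: str | Path) -> None:
    """Write a fixture model (JSON) and its region vectors (TSV) to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, expr = fixture_network(name)
    write_model(model, outdir / f"{name}_model.json")
    pd.DataFrame(expr).fillna(0.0).to_csv(
        outdir / f"{name}_expression.tsv", sep="\t", index_label="gene"
    )
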