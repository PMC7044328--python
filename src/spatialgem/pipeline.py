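"""End-to-end pipeline: expression → SV screen → enrichment → region-specific
model extraction → knockout screens → differential lethality.

Configured from a YAML mapping (all keys overridable from the CLI); every
stage writes a self-describing TSV/JSON artifact and the run ends with a
manifest recording versions, seed, thresholds and output hashes, so a rerun
with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential_lethality import differential_screen, find_rescue_genes, hits_frame
from .fba_core import screen_all_genes
from .gem_extraction import (
    CORE_THRESHOLD,
    prune,
    pseudo_bulk_score,
    score_region,
)
from .model_io import (
    read_coords_tsv,
    read_expression_tsv,
    read_model,
    write_model,
)
from .pathway_enrichment import enrich, enrichment_frame, pathways_from_model
from .sv_detection import normalize, sv_results_frame, sv_screen, ttest_screen
from .synthetic_data import SimConfig, simulate_spatial

log = logging.getLogger("spatialgem")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    outdir: str = "spatialgem_out"
    model: str | None = None
    expression: str | None = None
    coords: str | None = None
    simulate: dict | None = None
    regions: list[str] = field(default_factory=lambda: ["tumor"])
    alpha: float = 0.05
    core_threshold: float = CORE_THRESHOLD
    lethal_fraction: float = 0.01
    min_expressed_spots: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if not (0.0 <= self.lethal_fraction < 1.0):
            raise ValueError("lethal_fraction must lie in [0, 1)")
        if self.expression is None and self.simulate is None:
            raise ValueError("config needs either an expression path or a simulate block")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; return (and write) the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setLevel(logging.INFO)
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    artifacts: dict[str, str] = {}

    def emit(name: str, path: Path) -> None:
        artifacts[name] = str(path)
        log.info("wrote %s", path)

    try:
        stage = "load"
        if cfg.expression is not None:
            counts = read_expression_tsv(cfg.expression)
            coords_df = read_coords_tsv(cfg.coords)
            if "region" not in coords_df.columns:
                raise ValueError("coords file must carry a 'region' column")
            totals = (
                coords_df["total_counts"].to_numpy(dtype=float)
                if "total_counts" in coords_df.columns
                else None
            )
        else:
            sim_kwargs = dict(cfg.simulate or {})
            sim_kwargs.setdefault("seed", cfg.seed)
            ds = simulate_spatial(SimConfig(**sim_kwargs))
            ds.write(outdir / "simulated")
            emit("simulated_counts", outdir / "simulated" / "counts.tsv")
            emit("simulated_coords", outdir / "simulated" / "coords.tsv")
            counts = ds.counts_frame()
            coords_df = ds.coords_frame()
            totals = ds.spot_totals()
        coords = coords_df[["x", "y"]].to_numpy(dtype=float)
        region_labels = coords_df["region"].astype(str).tolist()
        model = read_model(cfg.model) if cfg.model else None

        stage = "normalize"
        expr = normalize(counts, totals, min_expressed_spots=cfg.min_expressed_spots)
        log.info("normalized: %d genes retained of %d", expr.shape[0], counts.shape[0])

        stage = "sv_screen"
        results = sv_screen(expr, coords, alpha=cfg.alpha, model=model)
        sv_df = sv_results_frame(results)
        sv_path = outdir / "sv_results.tsv"
        sv_df.to_csv(sv_path, sep="\t")
        emit("sv_results", sv_path)

        stage = "ttest_screen"
        tt = ttest_screen(expr, region_labels)
        tt_path = outdir / "ttest_results.tsv"
        tt.to_csv(tt_path, sep="\t")
        emit("ttest_results", tt_path)

        screens = {}
        models = {}
        if model is not None:
            stage = "enrichment"
            universe = [g for g in expr.index if g in set(model.gene_ids)]
            sv_genes = {r.gene_id for r in results if r.is_sv}
            rows = enrich(sv_genes & set(universe), pathways_from_model(model), universe)
            enr_path = outdir / "enrichment.tsv"
            enrichment_frame(rows).to_csv(enr_path, sep="\t")
            emit("enrichment", enr_path)

            stage = "extraction"
            scores = {}
            for reg in cfg.regions:
                spots = [
                    s for s, r in zip(coords_df.index, region_labels) if r == reg
                ]
                if not spots:
                    raise ValueError(f"unknown or empty region {reg!r}")
                scores[reg] = score_region(
                    model, expr, spots, reg, core_threshold=cfg.core_threshold
                )
            scores["pseudo_bulk"] = pseudo_bulk_score(
                model, expr, core_threshold=cfg.core_threshold
            )
            for name, rs in scores.items():
                res = prune(model, rs)
                models[name] = res.submodel
                mp = outdir / f"model_{name}.json"
                write_model(res.submodel, mp)
                emit(f"model_{name}", mp)
                ap = outdir / f"extraction_audit_{name}.tsv"
                res.audit_frame().to_csv(ap, sep="\t", index=False)
                emit(f"extraction_audit_{name}", ap)

            stage = "knockout_screens"
            for name, sub in models.items():
                recs = screen_all_genes(sub, lethal_fraction=cfg.lethal_fraction)
                screens[name] = recs
                df = pd.DataFrame(
                    {
                        "gene": [r.gene_id for r in recs],
                        "n_disabled": [len(r.disabled_reactions) for r in recs],
                        "growth_ratio": [r.growth_ratio for r in recs],
                        "lethal": [r.lethal for r in recs],
                    }
                ).set_index("gene")
                sp = outdir / f"screen_{name}.tsv"
                df.to_csv(sp, sep="\t")
                emit(f"screen_{name}", sp)

            stage = "differential_lethality"
            for reg in cfg.regions:
                hits = differential_screen(
                    screens[reg], screens["pseudo_bulk"], reg, "pseudo_bulk"
                )
                for h in hits:
                    find_rescue_genes(
                        h, models[reg], models["pseudo_bulk"],
                        lethal_fraction=cfg.lethal_fraction,
                    )
                dp = outdir / f"differential_{reg}_vs_pseudo_bulk.tsv"
                hits_frame(hits).to_csv(dp, sep="\t")
                emit(f"differential_{reg}", dp)

        stage = "manifest"
        manifest = {
            "spatialgem_version": __version__,
            "seed": cfg.seed,
            "config": asdict(cfg),
            "artifacts": artifacts,
            "hashes": {k: _sha256(Path(v)) for k, v in artifacts.items()},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001 - annotate failing stage, keep partial outputs
        raise StageError(stage, e) from e
    finally:
        log.removeHandler(fh)
        fh.close()
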