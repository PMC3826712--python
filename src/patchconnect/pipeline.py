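"""End-to-end pipeline: reclassify -> overlay -> patches -> network.

``run_pipeline`` ties the stages together the way the original workflow ran:
build the habitat-suitability surface and the movement-cost surface from the
raw layers, identify potential habitat patches, compute the gated pairwise
connectivity network, optionally classify traversability against a reference
pair, and summarize.  All intermediates are written under the output
directory and a machine-readable JSON report records the configuration,
per-stage timings and the summary block.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .ahp import WeightSet
from .classification import (
    COST_VARIABLES,
    SUITABILITY_VARIABLES,
    load_rule_tables,
    reclassify_layer,
    default_cost_weights,
    default_suitability_weights,
)
from .grid import RasterGrid, read_ascii_grid, write_ascii_grid
from .network import build_network, classify_traversable, summarize
from .patches import identify_patches
from .surfaces import resample_to, weighted_overlay

logger = logging.getLogger("patchconnect")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "build_surfaces"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    """Configuration of one full run.

    Thresholds default to the study's criteria: patch suitability > 9.50
    over > 60 km^2, 25 km Euclidean gate, 1-km corridor width.
    """

    layers: dict[str, str] | None = None  # variable name -> .asc path (None with in-memory grids)
    rule_tables: str | None = None  # None = shipped defaults
    suitability_weights: dict[str, float] | None = None  # None = shipped defaults
    cost_weights: dict[str, float] | None = None
    suitability_resolution_m: float | None = None  # None = native layer resolution
    cost_resolution_m: float | None = None
    score_threshold: float = 9.50
    min_area_km2: float = 60.0
    max_euclid_km: float = 25.0
    corridor_width_km: float = 1.0
    reference_pair: tuple[str, str] | None = None
    out_dir: str = "pipeline_out"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        try:
            obj = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            obj = yaml.safe_load(text)
        if "reference_pair" in obj and obj["reference_pair"] is not None:
            obj["reference_pair"] = tuple(obj["reference_pair"])
        return cls(**obj)

    def defaults_dict(self) -> dict:
        d = dict(self.__dict__)
        d["reference_pair"] = list(self.reference_pair) if self.reference_pair else None
        return d


def _load_layers(config: PipelineConfig, grids: dict[str, RasterGrid] | None) -> dict[str, RasterGrid]:
    if grids is not None:
        return grids
    if not config.layers:
        raise PipelineError("load", "no input layers configured")
    return {name: read_ascii_grid(path) for name, path in config.layers.items()}


def build_surfaces(
    config: PipelineConfig,
    grids: dict[str, RasterGrid],
):
    """Reclassify raw layers and overlay the two surfaces at their configured
    resolutions.  Returns ``(suitability_surface, cost_surface)``."""
    tables = load_rule_tables(config.rule_tables)
    sw = (
        WeightSet.from_weights(config.suitability_weights)
        if config.suitability_weights
        else default_suitability_weights()
    )
    cw = WeightSet.from_weights(config.cost_weights) if config.cost_weights else default_cost_weights()

    def surface_for(kind: str, variables, weights):
        res = config.suitability_resolution_m if kind == "suitability" else config.cost_resolution_m
        score_grids = {}
        for v in variables:
            if v not in grids:
                raise PipelineError("reclassify", f"missing input layer {v!r}")
            layer = grids[v]
            if res is not None and abs(layer.cell_size_m - res) > 1e-9:
                layer = resample_to(layer, res)
            score_grids[v] = reclassify_layer(layer, tables[v][kind])
        surf = weighted_overlay(score_grids, weights, kind)
        logger.info(
            "%s surface: %dx%d @ %gm, %d barrier cells",
            kind,
            *surf.grid.shape,
            surf.cell_size_m,
            int(surf.barrier_mask.sum()),
        )
        return surf

    return surface_for("suitability", SUITABILITY_VARIABLES, sw), surface_for("cost", COST_VARIABLES, cw)


def run_pipeline(config: PipelineConfig, grids: dict[str, RasterGrid] | None = None) -> dict:
    """Execute the full workflow; returns the report dict (also written to
    ``out_dir/report.json``).  Any stage error aborts with the stage name;
    partial outputs are kept alongside a FAILED marker file."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": config.defaults_dict(), "timings_s": {}}
    t_all = time.perf_counter()
    stage = "load"
    try:
        t0 = time.perf_counter()
        raw = _load_layers(config, grids)
        report["timings_s"]["load"] = time.perf_counter() - t0

        stage = "surfaces"
        t0 = time.perf_counter()
        suit, cost = build_surfaces(config, raw)
        write_ascii_grid(suit.grid, out / "suitability.asc")
        write_ascii_grid(cost.grid, out / "cost.asc")
        for name, surf in (("suitability", suit), ("cost", cost)):
            sidecar = {"barrier_cells": int(surf.barrier_mask.sum()), "kind": surf.kind}
            (out / f"{name}.sidecar.json").write_text(json.dumps(sidecar))
        report["timings_s"]["surfaces"] = time.perf_counter() - t0

        stage = "patches"
        t0 = time.perf_counter()
        patches = identify_patches(suit, config.score_threshold, config.min_area_km2)
        logger.info("identified %d patches", len(patches))
        report["patches"] = [
            {"id": p.id, "area_km2": p.area_km2, "mean_suitability": p.mean_suitability, "label": p.label}
            for p in patches
        ]
        report["timings_s"]["patches"] = time.perf_counter() - t0

        stage = "network"
        t0 = time.perf_counter()
        if len(patches) >= 2:
            # Patches live on the suitability grid; transfer to the cost grid
            # resolution if the two differ.
            net_patches = patches
            if abs(suit.cell_size_m - cost.cell_size_m) > 1e-9:
                from .patches import patch_from_cells

                scale = suit.cell_size_m / cost.cell_size_m
                net_patches = []
                for p in patches:
                    cells = _rescale_cells(p.cells, scale, cost.grid.shape)
                    net_patches.append(
                        patch_from_cells(p.id, cells, None, cost.cell_size_m, cost.grid.shape, p.label)
                    )
            table = build_network(net_patches, cost, config.max_euclid_km, config.corridor_width_km)
            if config.reference_pair is not None and len(table):
                table = classify_traversable(table, config.reference_pair)
            table.to_csv(out / "connectivity.csv")
            report["n_pairs"] = len(table)
            if len(table):
                report["summary"] = json.loads(summarize(table).to_json())
                costs = [(r.movement_cost, r.pair) for r in table.records if np.isfinite(r.movement_cost)]
                if costs:
                    mc, pair = min(costs)
                    report["min_cost_pair"] = {"pair": list(pair), "movement_cost": mc}
        else:
            report["n_pairs"] = 0
        report["timings_s"]["network"] = time.perf_counter() - t0
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
    report["timings_s"]["total"] = time.perf_counter() - t_all
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def _rescale_cells(cells: np.ndarray, scale: float, target_shape: tuple[int, int]) -> np.ndarray:
    """Map patch cells between grid resolutions sharing an origin."""
    if scale >= 1:  # finer target: each cell becomes a block
        k = int(round(scale))
        out = []
        for r, c in cells:
            for dr in range(k):
                for dc in range(k):
                    rr, cc = r * k + dr, c * k + dc
                    if rr < target_shape[0] and cc < target_shape[1]:
                        out.append((rr, cc))
        return np.array(sorted(set(out)), dtype=int)
    k = int(round(1 / scale))
    out = {(r // k, c // k) for r, c in cells}
    return np.array(sorted(out), dtype=int)
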