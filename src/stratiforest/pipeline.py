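"""Two-phase inventory workflow orchestration.

Stages (summarize -> reduce -> fit -> stratify -> allocate -> cruise ->
estimate) each read cached artifacts from, and write their outputs into, a
single artifact directory, so any stage can be rerun in isolation.  A
manifest records content hashes and seeds for reproducibility audits.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as design_mod
from . import estimate as est_mod
from . import features as feat_mod
from . import models as mod_mod
from . import reduction as red_mod
from . import stratify as strat_mod
from .raster import GridSpec, read_ascii_grid
from .synthetic import (
    Landscape,
    LandscapeConfig,
    simulate_landscape,
    simulate_prism_plot,
    write_landscape,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

BAND_SETS = {
    "CIR": ["cir_ir", "cir_red", "cir_green"],
    "RGB": ["rgb_red", "rgb_green", "rgb_blue"],
}


@dataclass
class PipelineConfig:
    out_dir: str = "artifacts"
    landscape: dict = field(default_factory=dict)  # LandscapeConfig overrides
    pca_k: int = 8
    lasso_folds: int = 10
    seed: int = 0
    baf: float = 4.6
    min_dbh_cm: float = 14.0
    phase1_n: int = 60
    total_n: int = 120
    strata_k: int = 8
    min_area_ha: float = 4.05
    closure_threshold_pct: float = 10.0
    height_threshold_m: float = 2.0
    alpha: float = 0.10
    allocation_floor: int = 2
    bias_correction: bool = True

    def __post_init__(self) -> None:
        if self.pca_k < 1 or self.strata_k < 1:
            raise ValueError("pca_k and strata_k must be >= 1")
        if self.total_n < 1 or self.phase1_n < 1:
            raise ValueError("sample sizes must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def landscape_config(self) -> LandscapeConfig:
        kwargs = dict(self.landscape)
        kwargs.setdefault("seed", self.seed)
        if "extent_m" in kwargs:
            kwargs["extent_m"] = tuple(kwargs["extent_m"])
        return LandscapeConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(out: Path, stage: str, t0: float, seed: int | None = None) -> None:
    entry = {"stage": stage, "elapsed_s": round(time.time() - t0, 3), "seed": seed}
    with open(out / "pipeline.log", "a") as fh:
        fh.write(json.dumps(entry) + "\n")


def stage_simulate(cfg: PipelineConfig, out: Path) -> Landscape:
    t0 = time.time()
    landscape = simulate_landscape(cfg.landscape_config())
    write_landscape(landscape, out)
    _log(out, "simulate", t0, cfg.landscape_config().seed)
    return landscape


def _load_landscape_pieces(cfg: PipelineConfig, out: Path):
    lcfg = cfg.landscape_config()
    grid = lcfg.grid()
    layers = {}
    for p in sorted(out.glob("*.asc")):
        layers[p.stem] = read_ascii_grid(p)
    if not layers:
        raise FileNotFoundError(f"no rasters found in {out}; run the simulate stage first")
    return lcfg, grid, layers


def stage_summarize(cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    t0 = time.time()
    lcfg, grid, layers = _load_landscape_pieces(cfg, out)
    chm = layers.get("chm")
    if chm is None:
        raise FileNotFoundError("missing CHM raster (chm.asc)")
    crowns = feat_mod.segment_crowns(chm, min_height_m=cfg.height_threshold_m)
    cells = feat_mod.summarize_cells(grid, layers, crowns)
    cells.to_csv(out / "cells.csv", index=False)
    _log(out, "summarize", t0)
    return cells


def stage_reduce(cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    t0 = time.time()
    cells = pd.read_csv(out / "cells.csv")
    ok = ~cells["flag_nodata"]
    for set_name, bands in BAND_SETS.items():
        cols = [c for c in cells.columns if any(c.startswith(b) for b in bands) and not c.startswith("crown_")]
        if not cols:
            continue
        comp = red_mod.pca_reduce(cells.loc[ok, cols], k=min(cfg.pca_k, len(cols)), name=set_name)
        for j in range(comp.k):
            col = f"{set_name}{j + 1}"
            cells[col] = np.nan
            cells.loc[ok, col] = comp.scores[:, j]
    li_cols = [c for c in ("chm_mean", "chm_var") if c in cells.columns]
    li_cols += [c for c in cells.columns if c.startswith("chm_") and c not in ("chm_mean", "chm_var")]
    if li_cols:
        comp = red_mod.pca_reduce(cells.loc[ok, li_cols], k=min(cfg.pca_k, len(li_cols)), name="LI")
        for j in range(comp.k):
            col = f"LI{j + 1}"
            cells[col] = np.nan
            cells.loc[ok, col] = comp.scores[:, j]
    cells.to_csv(out / "cells.csv", index=False)
    _log(out, "reduce", t0)
    return cells


def _phase1_plots(cfg: PipelineConfig, landscape: Landscape, out: Path) -> pd.DataFrame:
    """Initial random sample of grid cells, cruised with the prism."""
    rng = np.random.default_rng(cfg.seed + 1)
    grid = landscape.grid
    chosen = rng.choice(grid.n_cells, size=min(cfg.phase1_n, grid.n_cells), replace=False)
    r, c = grid.rowcol_of(chosen)
    xs, ys = grid.cell_center(r, c)
    rows = []
    for cid, x, y in zip(chosen, np.atleast_1d(xs), np.atleast_1d(ys)):
        plot = simulate_prism_plot(
            landscape.stem_map,
            (float(x), float(y)),
            baf=cfg.baf,
            min_dbh_cm=cfg.min_dbh_cm,
            gps_error_95_m=landscape.config.gps_error_95_m,
            rng=rng,
        )
        s = est_mod.plot_statistics(plot)
        rows.append(
            {
                "cell_id": int(cid),
                "x": float(x),
                "y": float(y),
                "ba": s.ba,
                "tph": s.tph,
                "pct_conifer_ba": s.pct_conifer_ba,
                "tally_count": s.tally_count,
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "phase1_plots.csv", index=False)
    return frame


PREDICTOR_PREFIXES = (
    "elev_", "slope_", "aspect_", "plane_", "pcount", "crown_", "ndvi", "ir_red_ratio",
    "CIR", "RGB", "LI",
)


def _predictor_columns(cells: pd.DataFrame) -> list[str]:
    return [
        c
        for c in cells.columns
        if any(c.startswith(p) for p in PREDICTOR_PREFIXES)
        and np.issubdtype(cells[c].dtype, np.number)
    ]


def stage_fit(cfg: PipelineConfig, out: Path, landscape: Landscape | None = None) -> dict:
    t0 = time.time()
    cells = pd.read_csv(out / "cells.csv")
    p1 = out / "phase1_plots.csv"
    if not p1.exists():
        if landscape is None:
            raise FileNotFoundError("phase-1 plots missing; provide the landscape or run simulate")
        _phase1_plots(cfg, landscape, out)
    plots = pd.read_csv(p1)
    merged = plots.merge(cells, on="cell_id", suffixes=("", "_cell"))
    pred_cols = _predictor_columns(cells)
    merged = merged.dropna(subset=pred_cols)
    X = merged[pred_cols]

    specs = {}
    for response, transform in (("ba", "ln"), ("tph", "ln"), ("pct_conifer_ba", "logit")):
        y = merged[response].to_numpy(dtype=float)
        if transform == "ln":
            y_t, _ = mod_mod._prepare_ln(y, None)
        else:
            prop = np.clip(y / 100.0, 1e-6, 1 - 1e-6)
            y_t = np.log(prop / (1 - prop))
        selected, lam = mod_mod.lasso_screen(X, y_t, folds=min(cfg.lasso_folds, len(y_t)), seed=cfg.seed)
        weights = merged["tally_count"].to_numpy(dtype=float) if transform == "logit" else None
        weights = np.maximum(weights, 1.0) if weights is not None else None
        spec = mod_mod.fit_model(
            merged[selected] if selected else merged[[]],
            y,
            transform=transform,
            response=response,
            lam=lam,
            weights=weights,
            bias_correction=cfg.bias_correction and transform == "ln",
        )
        specs[response] = spec

    with open(out / "models.json", "w") as fh:
        json.dump({k: v.to_dict() for k, v in specs.items()}, fh, indent=2)
    ok = ~cells[pred_cols].isna().any(axis=1)
    for response, spec in specs.items():
        col = f"pred_{response}"
        cells[col] = np.nan
        cells.loc[ok, col] = mod_mod.predict_cells(spec, cells.loc[ok])
    cells.to_csv(out / "cells.csv", index=False)
    _log(out, "fit", t0, cfg.seed)
    return specs


def stage_stratify(cfg: PipelineConfig, out: Path) -> strat_mod.StratumAssignment:
    t0 = time.time()
    cells = pd.read_csv(out / "cells.csv")
    lcfg = cfg.landscape_config()
    usable = cells["pred_ba"].notna() & cells["chm_mean"].notna()
    proxy = np.zeros(len(cells))
    proxy[usable] = strat_mod.volume_proxy(
        cells.loc[usable, "pred_ba"].to_numpy(), cells.loc[usable, "chm_mean"].to_numpy()
    )
    nonforest = strat_mod.nonforest_mask(
        cells.fillna({"crown_closure_pct": 0.0, "chm_mean": 0.0}),
        cfg.closure_threshold_pct,
        cfg.height_threshold_m,
    ) | ~usable.to_numpy()
    attrs = pd.DataFrame(
        {
            "ba": cells["pred_ba"].fillna(0.0),
            "height": cells["chm_mean"].fillna(0.0),
            "tph": cells.get("pred_tph", pd.Series(np.zeros(len(cells)))).fillna(0.0),
            "pct_conifer": cells.get(
                "pred_pct_conifer_ba", pd.Series(np.zeros(len(cells)))
            ).fillna(0.0),
        }
    )
    assignment = strat_mod.build_strata(
        proxy,
        cfg.strata_k,
        attrs,
        lcfg.grid().cell_area_ha,
        nonforest=nonforest,
        min_area_ha=cfg.min_area_ha,
    )
    cells["stratum"] = assignment.labels
    cells["volume_proxy"] = proxy
    cells.to_csv(out / "cells.csv", index=False)
    assignment.table.to_csv(out / "strata.csv", index=False)
    _log(out, "stratify", t0)
    return assignment


def stage_allocate(cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    t0 = time.time()
    cells = pd.read_csv(out / "cells.csv")
    strata_table = pd.read_csv(out / "strata.csv")
    lcfg = cfg.landscape_config()
    grid = lcfg.grid()
    forested = strata_table[strata_table["stratum"] > 0]
    labels = cells["stratum"].to_numpy()
    sds = []
    for s in forested["stratum"]:
        preds = cells.loc[cells["stratum"] == s, "pred_ba"].dropna().to_numpy()
        sds.append(design_mod.model_variance(preds) if len(preds) > 1 else 0.0)
    plan = design_mod.neyman_allocate(
        forested["n_cells"].to_numpy(),
        np.array(sds),
        cfg.total_n,
        floor=cfg.allocation_floor,
        strata=forested["stratum"].to_numpy(),
    )
    assignment = strat_mod.StratumAssignment(
        labels=labels,
        proxy=cells["volume_proxy"].to_numpy(),
        cell_area_ha=grid.cell_area_ha,
        table=strata_table,
    )
    n_h = {int(s): int(n) for s, n in zip(plan.strata, plan.n_plots)}
    plots = design_mod.place_plots(assignment, n_h, grid, seed=cfg.seed + 2)
    plan.frame().to_csv(out / "allocation.csv", index=False)
    plots.to_csv(out / "phase2_locations.csv", index=False)
    _log(out, "allocate", t0, cfg.seed + 2)
    return plots


def stage_estimate(cfg: PipelineConfig, out: Path, landscape: Landscape | None = None) -> pd.DataFrame:
    t0 = time.time()
    locations = pd.read_csv(out / "phase2_locations.csv")
    strata_table = pd.read_csv(out / "strata.csv")
    if landscape is None:
        raise ValueError("estimation in synthetic mode needs the landscape for cruising")
    rng = np.random.default_rng(cfg.seed + 3)
    rows = []
    for _, rec in locations.iterrows():
        plot = simulate_prism_plot(
            landscape.stem_map,
            (rec["x"], rec["y"]),
            baf=cfg.baf,
            min_dbh_cm=cfg.min_dbh_cm,
            gps_error_95_m=landscape.config.gps_error_95_m,
            rng=rng,
        )
        s = est_mod.plot_statistics(plot)
        rows.append(
            {
                "stratum": int(rec["stratum"]),
                "ba": s.ba,
                "tph": s.tph,
                "pct_conifer_ba": s.pct_conifer_ba,
                "volume_proxy": s.volume_proxy,
                "carbon_mg_ha": s.carbon_mg_ha,
                "board_feet_ha": s.board_feet_ha,
            }
        )
    summaries = pd.DataFrame(rows)
    summaries.to_csv(out / "phase2_plots.csv", index=False)
    report = est_mod.poststratified_estimate(summaries, strata_table, alpha=cfg.alpha)
    report.to_csv(out / "estimates.csv", index=False)
    _log(out, "estimate", t0, cfg.seed + 3)
    return report


def _write_manifest(out: Path) -> dict:
    artifacts = {}
    for p in sorted(out.iterdir()):
        if p.name in ("manifest.json", "pipeline.log") or p.is_dir():
            continue
        artifacts[p.name] = _sha256(p)
    manifest = {"artifacts": artifacts}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages end to end; returns the artifact manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = out / "pipeline.log"
    if log.exists():
        log.unlink()
    stage = "simulate"
    try:
        landscape = stage_simulate(cfg, out)
        stage = "summarize"
        stage_summarize(cfg, out)
        stage = "reduce"
        stage_reduce(cfg, out)
        stage = "fit"
        stage_fit(cfg, out, landscape)
        stage = "stratify"
        stage_stratify(cfg, out)
        stage = "allocate"
        stage_allocate(cfg, out)
        stage = "estimate"
        stage_estimate(cfg, out, landscape)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return _write_manifest(out)
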