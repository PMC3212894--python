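"""Optimal grid-cell size by concentric circular extraction + BIC search.

Remote-sensing summaries are extracted in circles of increasing area around
each plot; per candidate area, an exhaustive best-subset regression is run
and the lowest-BIC model recorded.  The candidate with the overall lowest
BIC (ties to the smaller area) is the recommended cell size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .raster import RasterLayer

__all__ = ["GridSizeResult", "circular_extract", "best_subset_bic", "scan_sizes", "radius_for_area_ha"]

_ENUMERATION_GUARD = 1_000_000


def radius_for_area_ha(area_ha: float) -> float:
    """Radius (m) of a circle with the given area in hectares."""
    return float(np.sqrt(area_ha * 10_000.0 / np.pi))


@dataclass
class GridSizeResult:
    table: pd.DataFrame  # per area: radius_m, predictors, bic, r_squared, n
    optimum_area_ha: float

    @property
    def optimum_radius_m(self) -> float:
        return radius_for_area_ha(self.optimum_area_ha)


def circular_extract(
    layers: dict[str, RasterLayer],
    plot_points: np.ndarray,
    radius_m: float,
) -> pd.DataFrame:
    """Mean and sd of each layer over pixels whose centers fall in a circle.

    One row per plot; plots whose circle extends beyond a raster are
    flagged (``partial``) and summarized over the covered part.
    """
    coarsest = max(l.pixel_size for l in layers.values())
    if radius_m < coarsest:
        raise ValueError(f"radius {radius_m} m is below the coarsest pixel ({coarsest} m)")
    pts = np.asarray(plot_points, dtype=float)
    rows = []
    for px, py in pts:
        rec: dict[str, float] = {"x": px, "y": py, "partial": False}
        for name, layer in layers.items():
            xs, ys = layer.pixel_centers()
            ci = np.where((xs >= px - radius_m) & (xs <= px + radius_m))[0]
            ri = np.where((ys >= py - radius_m) & (ys <= py + radius_m))[0]
            if len(ci) == 0 or len(ri) == 0:
                rec[f"{name}_mean"] = np.nan
                rec[f"{name}_sd"] = np.nan
                rec["partial"] = True
                continue
            xx, yy = np.meshgrid(xs[ci], ys[ri])
            inside = (xx - px) ** 2 + (yy - py) ** 2 <= radius_m**2
            block = layer.data[np.ix_(ri, ci)]
            vals = block[inside]
            vals = vals[np.isfinite(vals)]
            # detect truncation at the raster edge
            full_count = inside.sum()
            expected = np.pi * radius_m**2 / layer.pixel_size**2
            if full_count < 0.8 * expected:
                rec["partial"] = True
            if len(vals) == 0:
                rec[f"{name}_mean"] = np.nan
                rec[f"{name}_sd"] = np.nan
                rec["partial"] = True
            else:
                rec[f"{name}_mean"] = float(vals.mean())
                rec[f"{name}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(rec)
    return pd.DataFrame(rows)


def bic_gaussian(n: int, rss: float, k: int) -> float:
    """BIC = n ln(RSS/n) + (k+1) ln(n) for a Gaussian linear model."""
    rss = max(rss, 1e-300)
    return float(n * np.log(rss / n) + (k + 1) * np.log(n))


def best_subset_bic(
    X: pd.DataFrame,
    y: np.ndarray,
    max_predictors: int = 5,
) -> tuple[list[str], float, float]:
    """Exhaustive subset search minimizing BIC; returns (subset, BIC, R^2)."""
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    n_models = sum(
        int(np.prod([(p - i) / (i + 1) for i in range(k)])) for k in range(0, max_predictors + 1)
    )
    if n_models > _ENUMERATION_GUARD:
        raise ValueError(
            f"{n_models} candidate models exceeds the guard; reduce max_predictors"
        )
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    best_subset: list[str] = []
    best_rss = ss_tot
    best_bic = bic_gaussian(n, ss_tot, 0)
    ones = np.ones((n, 1))
    for k in range(1, max_predictors + 1):
        for combo in combinations(range(p), k):
            design = np.hstack([ones, Xm[:, combo]])
            coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
            rss = float(np.sum((y - design @ coef) ** 2))
            b = bic_gaussian(n, rss, k)
            if b < best_bic - 1e-12:
                best_bic = b
                best_rss = rss
                best_subset = [names[i] for i in combo]
    r2 = 1.0 - best_rss / ss_tot if ss_tot > 0 else 1.0
    return best_subset, best_bic, float(r2)


def scan_sizes(
    layers: dict[str, RasterLayer],
    plot_points: np.ndarray,
    response: np.ndarray,
    areas_ha: list[float] | None = None,
    max_predictors: int = 5,
) -> GridSizeResult:
    """Best-subset BIC search at each candidate circular area.

    The optimum is the area with the lowest BIC (ties go to the smaller
    area).  Sizes where too few complete plots remain are skipped with a
    warning.
    """
    if areas_ha is None:
        areas_ha = [0.02, 0.04, 0.06, 0.08, 0.10, 0.14, 0.20]
    if len(areas_ha) < 1:
        raise ValueError("need at least one candidate area")
    y_all = np.asarray(response, dtype=float)
    rows = []
    for area in sorted(areas_ha):
        radius = radius_for_area_ha(area)
        try:
            feats = circular_extract(layers, plot_points, radius)
        except ValueError as exc:
            warnings.warn(f"area {area} ha skipped: {exc}")
            continue
        cols = [c for c in feats.columns if c.endswith(("_mean", "_sd"))]
        ok = ~feats[cols].isna().any(axis=1)
        X = feats.loc[ok, cols]
        y = y_all[ok.to_numpy()]
        if len(y) < len(cols) + 2 or len(y) < max_predictors + 2:
            warnings.warn(f"area {area} ha skipped: only {len(y)} usable plots")
            continue
        subset, bic, r2 = best_subset_bic(X, y, max_predictors=max_predictors)
        rows.append(
            {
                "area_ha": area,
                "radius_m": radius,
                "predictors": ",".join(subset),
                "n_predictors": len(subset),
                "bic": bic,
                "r_squared": r2,
                "n_plots": len(y),
            }
        )
    if not rows:
        raise ValueError("no candidate area produced a usable model")
    table = pd.DataFrame(rows)
    best = table.sort_values(["bic", "area_ha"]).iloc[0]
    return GridSizeResult(table=table, optimum_area_ha=float(best["area_ha"]))
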