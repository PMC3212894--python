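"""Summarize rasters and crown segments to the analysis grid.

Implements watershed crown segmentation of the canopy height model,
topographic descriptors (elevation / slope / aspect statistics and a
plane-departure metric), crown-segment metrics (polygon counts, heights,
closure, band fusion, NDVI) and optional greyscale image summaries, all
keyed to the row-major analysis grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import kurtosis, skew
from shapely.geometry import Polygon, box
from shapely.strtree import STRtree
from skimage.feature import peak_local_max
from skimage.measure import find_contours
from skimage.segmentation import watershed

from .raster import GridSpec, RasterLayer

__all__ = ["CrownPolygon", "segment_crowns", "summarize_cells", "image_summaries"]


@dataclass
class CrownPolygon:
    geometry: Polygon
    max_height_m: float
    area_m2: float


def segment_crowns(
    chm: RasterLayer,
    min_height_m: float = 2.0,
    smoothing_sigma_m: float = 0.5,
    min_area_m2: float = 1.0,
) -> list[CrownPolygon]:
    """Watershed segmentation of the CHM into non-overlapping crown polygons.

    The CHM is Gaussian-smoothed, local maxima above ``min_height_m`` seed a
    watershed flood of the inverted surface restricted to the above-threshold
    canopy mask; each region becomes one polygon.
    """
    if min_height_m <= 0 or smoothing_sigma_m <= 0 or min_area_m2 <= 0:
        raise ValueError("segmentation parameters must be positive")
    data = np.where(chm.valid_mask(), chm.data, 0.0)
    if not chm.valid_mask().any():
        warnings.warn("CHM is all nodata; no crowns segmented")
        return []
    sigma_px = smoothing_sigma_m / chm.pixel_size
    smooth = ndimage.gaussian_filter(data, sigma=sigma_px)
    mask = smooth >= min_height_m
    if not mask.any():
        return []
    peaks = peak_local_max(smooth, min_distance=1, threshold_abs=min_height_m, exclude_border=False)
    if len(peaks) == 0:
        return []
    markers = np.zeros(data.shape, dtype=int)
    # deterministic marker ids: row-major order of the peak pixels
    order = np.lexsort((peaks[:, 1], peaks[:, 0]))
    for i, idx in enumerate(order, start=1):
        markers[tuple(peaks[idx])] = i
    labels = watershed(-smooth, markers=markers, mask=mask)

    crowns: list[CrownPolygon] = []
    px = chm.pixel_size
    min_pixels = max(1, int(round(min_area_m2 / px**2)))
    for lab in range(1, labels.max() + 1):
        region_mask = labels == lab
        n_px = int(region_mask.sum())
        if n_px < min_pixels:
            continue
        poly = _mask_to_polygon(region_mask, chm)
        if poly is None or poly.is_empty:
            continue
        crowns.append(
            CrownPolygon(
                geometry=poly,
                max_height_m=float(data[region_mask].max()),
                area_m2=float(poly.area),
            )
        )
    return crowns


def _mask_to_polygon(mask: np.ndarray, layer: RasterLayer) -> Polygon | None:
    """Outer boundary of a pixel region as a polygon in map coordinates."""
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    rows = contour[:, 0] - 1.0
    cols = contour[:, 1] - 1.0
    xs = layer.origin_x + (cols + 0.5) * layer.pixel_size
    ys = layer.origin_y - (rows + 0.5) * layer.pixel_size
    if len(xs) < 4:
        return None
    poly = Polygon(zip(xs, ys))
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def _zonal(layer: RasterLayer, grid: GridSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell count, mean and population variance of valid pixels."""
    idx = layer.cell_index_of_pixels(grid).ravel()
    vals = layer.data.ravel()
    ok = (idx >= 0) & np.isfinite(vals) & (vals != layer.nodata)
    idx, vals = idx[ok], vals[ok]
    n = grid.n_cells
    count = np.bincount(idx, minlength=n).astype(float)
    s1 = np.bincount(idx, weights=vals, minlength=n)
    s2 = np.bincount(idx, weights=vals**2, minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, s1 / count, np.nan)
        var = np.where(count > 0, s2 / count - mean**2, np.nan)
    return count, mean, np.clip(var, 0.0, None)


def _slope_aspect(dem: RasterLayer) -> tuple[np.ndarray, np.ndarray]:
    """Slope (degrees) and aspect (radians, east=0 CCW) from DEM gradients."""
    gy, gx = np.gradient(dem.data, dem.pixel_size)
    gy = -gy  # row index increases southwards
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    aspect = np.arctan2(-gy, -gx)  # downslope direction
    return slope, aspect


def summarize_cells(
    grid: GridSpec,
    layers: dict[str, RasterLayer],
    crowns: list[CrownPolygon] | None = None,
    include_image_summaries: bool = False,
) -> pd.DataFrame:
    """Build the per-cell feature table.

    ``layers`` keys recognized: ``dem``, ``chm``, optical bands (any other
    key, e.g. ``cir_ir``/``cir_red``/``rgb_blue``).  Crown metrics use
    centroid membership for counts/heights and exact polygon-cell
    intersection for closure.  Raises on CRS mismatch.
    """
    for name, layer in layers.items():
        if layer.crs != grid.crs:
            raise ValueError(f"CRS mismatch for layer {name!r}: {layer.crs} != {grid.crs}")
    n = grid.n_cells
    rows, cols = np.divmod(np.arange(n), grid.n_cols)
    out = pd.DataFrame({"cell_id": np.arange(n), "row": rows, "col": cols})
    cx, cy = grid.cell_center(rows, cols)
    out["x_center"] = cx
    out["y_center"] = cy

    coverage = np.ones(n, dtype=bool)
    if "dem" in layers:
        dem = layers["dem"]
        count, mean, var = _zonal(dem, grid)
        out["elev_mean"] = mean
        out["elev_var"] = var
        expected = (grid.cell_size_m / dem.pixel_size) ** 2
        coverage &= count >= 0.999 * expected
        slope, aspect = _slope_aspect(dem)
        s_layer = RasterLayer(slope, dem.origin_x, dem.origin_y, dem.pixel_size, crs=dem.crs)
        _, out["slope_mean"], out["slope_var"] = _zonal(s_layer, grid)
        out["aspect_mean"], out["aspect_circvar"] = _circular_zonal(aspect, dem, grid)
        out["plane_departure"] = _plane_departure(dem, grid)

    if "chm" in layers:
        chm = layers["chm"]
        count, mean, var = _zonal(chm, grid)
        out["chm_mean"] = mean
        out["chm_var"] = var
        expected = (grid.cell_size_m / chm.pixel_size) ** 2
        coverage &= count >= 0.999 * expected

    band_names = [k for k in layers if k not in ("dem", "chm")]
    for name in band_names:
        _, mean, var = _zonal(layers[name], grid)
        out[f"{name}_mean"] = mean
        out[f"{name}_var"] = var

    if "cir_ir_mean" in out.columns and "cir_red_mean" in out.columns:
        ir, red = out["cir_ir_mean"], out["cir_red_mean"]
        with np.errstate(invalid="ignore", divide="ignore"):
            out["ir_red_ratio"] = ir / red
            out["ndvi"] = (ir - red) / (ir + red)

    if crowns is not None:
        crown_cols = _crown_metrics(grid, crowns, layers)
        for k, v in crown_cols.items():
            out[k] = v

    if include_image_summaries:
        for name in band_names + (["chm"] if "chm" in layers else []):
            stats = _per_cell_image_summaries(layers[name], grid)
            for k, v in stats.items():
                out[f"{name}_{k}"] = v

    out["flag_partial"] = ~coverage
    value_cols = [
        c for c in out.columns if c not in ("cell_id", "row", "col", "x_center", "y_center", "flag_partial")
    ]
    out["flag_nodata"] = out[value_cols].isna().any(axis=1)
    return out


def _circular_zonal(
    aspect: np.ndarray, dem: RasterLayer, grid: GridSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Circular mean (radians) and circular variance of aspect per cell."""
    cosl = RasterLayer(np.cos(aspect), dem.origin_x, dem.origin_y, dem.pixel_size, crs=dem.crs)
    sinl = RasterLayer(np.sin(aspect), dem.origin_x, dem.origin_y, dem.pixel_size, crs=dem.crs)
    _, mc, _ = _zonal(cosl, grid)
    _, ms, _ = _zonal(sinl, grid)
    mean = np.arctan2(ms, mc)
    r = np.hypot(mc, ms)
    return mean, np.clip(1.0 - r, 0.0, 1.0)


def _plane_departure(dem: RasterLayer, grid: GridSpec) -> np.ndarray:
    """RMS residual of cell DEM pixels from the bilinear corner surface."""
    out = np.full(grid.n_cells, np.nan)
    xpix, ypix = dem.pixel_centers()
    s = grid.cell_size_m
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            x0 = grid.origin_x + c * s
            y0 = grid.origin_y - r * s  # north edge
            ci = np.where((xpix >= x0) & (xpix < x0 + s))[0]
            ri = np.where((ypix <= y0) & (ypix > y0 - s))[0]
            if len(ci) < 2 or len(ri) < 2:
                continue
            block = dem.data[np.ix_(ri, ci)]
            if not np.isfinite(block).all():
                continue
            # corner values approximated by the corner-most pixels
            znw, zne = block[0, 0], block[0, -1]
            zsw, zse = block[-1, 0], block[-1, -1]
            u = (xpix[ci] - xpix[ci[0]]) / max(xpix[ci[-1]] - xpix[ci[0]], 1e-12)
            v = (ypix[ri[0]] - ypix[ri]) / max(ypix[ri[0]] - ypix[ri[-1]], 1e-12)
            plane = (
                znw * (1 - u)[None, :] * (1 - v)[:, None]
                + zne * u[None, :] * (1 - v)[:, None]
                + zsw * (1 - u)[None, :] * v[:, None]
                + zse * u[None, :] * v[:, None]
            )
            out[grid.cell_id(r, c)] = np.sqrt(np.mean((block - plane) ** 2))
    return out


def _crown_metrics(
    grid: GridSpec, crowns: list[CrownPolygon], layers: dict[str, RasterLayer]
) -> dict[str, np.ndarray]:
    n = grid.n_cells
    pcount = np.zeros(n)
    heights: list[list[float]] = [[] for _ in range(n)]
    closure_area = np.zeros(n)
    band_names = [k for k in layers if k not in ("dem",)]
    band_sums = {b: np.zeros(n) for b in band_names}
    band_sqsums = {b: np.zeros(n) for b in band_names}
    band_counts = np.zeros(n)

    cell_boxes = []
    s = grid.cell_size_m
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            x0 = grid.origin_x + c * s
            y1 = grid.origin_y - r * s
            cell_boxes.append(box(x0, y1 - s, x0 + s, y1))
    tree = STRtree(cell_boxes)

    for crown in crowns:
        geom = crown.geometry
        cx, cy = geom.centroid.x, geom.centroid.y
        rr, cc = grid.cell_of_point(cx, cy)
        if rr >= 0:
            cid = int(rr * grid.n_cols + cc)
            pcount[cid] += 1
            heights[cid].append(crown.max_height_m)
        for ci in tree.query(geom):
            inter = cell_boxes[ci].intersection(geom)
            if not inter.is_empty:
                closure_area[ci] += inter.area
        # fuse bands: mean over crown pixels, accredited to the centroid cell
        if rr >= 0 and band_names:
            cid = int(rr * grid.n_cols + cc)
            for b in band_names:
                val = _polygon_pixel_mean(layers[b], geom)
                if np.isfinite(val):
                    band_sums[b][cid] += val
                    band_sqsums[b][cid] += val**2
            band_counts[cid] += 1

    cell_area = grid.cell_size_m**2
    metrics: dict[str, np.ndarray] = {
        "pcount": pcount,
        "crown_closure_pct": np.clip(100.0 * closure_area / cell_area, 0.0, 100.0),
    }
    cell_h = np.zeros(n)
    cell_hvar = np.zeros(n)
    for i, hs in enumerate(heights):
        if hs:
            cell_h[i] = float(np.mean(hs))
            cell_hvar[i] = float(np.var(hs))
    metrics["crown_cell_height"] = cell_h
    metrics["crown_height_var"] = cell_hvar
    with np.errstate(invalid="ignore", divide="ignore"):
        for b in band_names:
            m = np.where(band_counts > 0, band_sums[b] / np.maximum(band_counts, 1), 0.0)
            v = np.where(
                band_counts > 0, band_sqsums[b] / np.maximum(band_counts, 1) - m**2, 0.0
            )
            metrics[f"crown_{b}_mean"] = m
            metrics[f"crown_{b}_var"] = np.clip(v, 0.0, None)
    if "crown_cir_ir_mean" in metrics and "crown_cir_red_mean" in metrics:
        ir, red = metrics["crown_cir_ir_mean"], metrics["crown_cir_red_mean"]
        with np.errstate(invalid="ignore", divide="ignore"):
            metrics["crown_ir_red_ratio"] = np.where(red > 0, ir / red, 0.0)
            denom = ir + red
            metrics["crown_ndvi"] = np.where(denom > 0, (ir - red) / denom, 0.0)
    return metrics


def _polygon_pixel_mean(layer: RasterLayer, geom: Polygon) -> float:
    """Mean of pixels whose centers fall inside the polygon."""
    xs, ys = layer.pixel_centers()
    minx, miny, maxx, maxy = geom.bounds
    ci = np.where((xs >= minx - layer.pixel_size) & (xs <= maxx + layer.pixel_size))[0]
    ri = np.where((ys >= miny - layer.pixel_size) & (ys <= maxy + layer.pixel_size))[0]
    if len(ci) == 0 or len(ri) == 0:
        return np.nan
    from shapely import contains_xy

    xx, yy = np.meshgrid(xs[ci], ys[ri])
    inside = contains_xy(geom, xx.ravel(), yy.ravel()).reshape(xx.shape)
    if not inside.any():
        # tiny polygon: fall back to the nearest pixel
        cx, cy = geom.centroid.x, geom.centroid.y
        ri0 = int(np.argmin(np.abs(ys - cy)))
        ci0 = int(np.argmin(np.abs(xs - cx)))
        return float(layer.data[ri0, ci0])
    block = layer.data[np.ix_(ri, ci)]
    vals = block[inside]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if len(vals) else np.nan


# ---------------------------------------------------------------------------
# greyscale image summaries


def _entropy_bits(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _profile_coords(shape: tuple[int, int]) -> list[tuple[np.ndarray, np.ndarray]]:
    """Eight radial profiles: center to corners and edge midpoints."""
    nr, nc = shape
    r0, c0 = (nr - 1) / 2.0, (nc - 1) / 2.0
    targets = [
        (0, 0), (0, nc - 1), (nr - 1, 0), (nr - 1, nc - 1),
        (0, c0), (nr - 1, c0), (r0, 0), (r0, nc - 1),
    ]
    profiles = []
    for tr, tc in targets:
        length = int(np.ceil(np.hypot(tr - r0, tc - c0))) + 1
        rr = np.clip(np.round(np.linspace(r0, tr, length)).astype(int), 0, nr - 1)
        cc = np.clip(np.round(np.linspace(c0, tc, length)).astype(int), 0, nc - 1)
        profiles.append((rr, cc))
    return profiles


def _vector_stats(v: np.ndarray) -> dict[str, float]:
    v = np.asarray(v, dtype=float)
    med = float(np.median(v))
    if v.max() == v.min():  # degenerate distribution: all moments vanish
        return {
            "mean": float(v[0]),
            "var": 0.0,
            "median": med,
            "skew": 0.0,
            "kurtosis": 0.0,
            "entropy": 0.0,
            "mad_mean": 0.0,
            "mad_median": 0.0,
        }
    return {
        "mean": float(v.mean()),
        "var": float(v.var()),
        "median": med,
        "skew": float(skew(v)),
        "kurtosis": float(kurtosis(v)),
        "entropy": _entropy_bits(v),
        "mad_mean": float(np.mean(np.abs(v - v.mean()))),
        "mad_median": float(np.median(np.abs(v - med))),
    }


def image_summaries(window: np.ndarray) -> dict[str, float]:
    """Profile, pixel and histogram statistics of one greyscale window.

    Profile statistics are the eight order statistics (mean, variance,
    median, skewness, kurtosis, entropy, mean/median absolute deviation)
    computed on each of eight radial profiles and averaged across profiles;
    pixel statistics apply the same set to all pixels; histogram statistics
    summarize a 16-bin intensity histogram.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] < 4 or window.shape[1] < 4:
        raise ValueError(f"window must be at least 4x4 pixels, got {window.shape}")
    out: dict[str, float] = {}
    prof_stats: dict[str, list[float]] = {}
    for rr, cc in _profile_coords(window.shape):
        for k, v in _vector_stats(window[rr, cc]).items():
            prof_stats.setdefault(k, []).append(v)
    for k, vs in prof_stats.items():
        out[f"profile_{k}"] = float(np.mean(vs))
    for k, v in _vector_stats(window.ravel()).items():
        out[f"pixel_{k}"] = v

    flat = window.ravel()
    lo, hi = flat.min(), flat.max()
    if hi > lo:
        hist, _ = np.histogram(flat, bins=16, range=(lo, hi))
    else:
        hist = np.array([flat.size] + [0] * 15)
    p = hist / hist.sum()
    nz = p[p > 0]
    out["hist_entropy"] = float(-(nz * np.log2(nz)).sum())
    out["hist_peak_frac"] = float(p.max())
    out["hist_q25"] = float(np.percentile(flat, 25))
    out["hist_q75"] = float(np.percentile(flat, 75))
    return out


def _per_cell_image_summaries(layer: RasterLayer, grid: GridSpec) -> dict[str, np.ndarray]:
    idx = layer.cell_index_of_pixels(grid)
    n = grid.n_cells
    keys: list[str] | None = None
    store: dict[str, np.ndarray] = {}
    for cid in range(n):
        rr, cc = np.where(idx == cid)
        if len(rr) < 16:
            continue
        r0, r1 = rr.min(), rr.max() + 1
        c0, c1 = cc.min(), cc.max() + 1
        win = layer.data[r0:r1, c0:c1]
        if win.shape[0] < 4 or win.shape[1] < 4 or not np.isfinite(win).all():
            continue
        stats = image_summaries(win)
        if keys is None:
            keys = list(stats)
            store = {k: np.full(n, np.nan) for k in keys}
        for k in keys:
            store[k][cid] = stats[k]
    return store
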