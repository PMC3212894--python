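"""Synthetic forest landscape generator and prism-cruise simulator.

Generates spatially correlated per-cell truth fields (basal area, stem
density, conifer share, canopy height), realizes an individual-tree stem map
consistent with those fields, renders raster products (DEM, CHM, optical
bands) and crown polygons, and simulates variable-radius (prism) plot
tallies with GPS location error.

The latent fields are Gaussian random fields with exponential covariance,
sampled by circulant embedding; basal area and stem density get log-normal
marginals by exponentiation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, mapping

from .raster import GridSpec, RasterLayer, write_ascii_grid

__all__ = [
    "LandscapeConfig",
    "StemMap",
    "TruthFields",
    "PrismPlot",
    "Landscape",
    "simulate_landscape",
    "limiting_distance",
    "simulate_prism_plot",
    "write_landscape",
]

# 95% quantile of the radius of a standard circular bivariate normal:
# sqrt(-2 ln 0.05)
_RAYLEIGH_Q95 = 2.447746830680816


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of a synthetic landscape.

    ``extent_m`` is (width, height); all random draws are fixed by ``seed``.
    """

    extent_m: tuple[float, float] = (1000.0, 1000.0)
    cell_size_m: float = 20.0
    spatial_corr_range_m: float = 150.0
    ba_mean: float = 40.0
    ba_sd: float = 20.0
    tph_mean: float = 300.0
    tph_sd: float = 100.0
    conifer_logit_mean: float = 0.5
    conifer_logit_sd: float = 1.0
    image_noise_sd: float = 0.02
    gps_error_95_m: float = 10.0
    seed: int = 0
    chm_pixel_m: float = 2.0
    dem_pixel_m: float = 4.0
    image_pixel_m: float = 2.0
    tph_ba_corr: float = 0.5
    dead_fraction: float = 0.05
    crown_min_height_m: float = 2.0

    def __post_init__(self) -> None:
        w, h = self.extent_m
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        if w < self.cell_size_m or h < self.cell_size_m:
            raise ValueError("extent smaller than one cell")
        for name in ("ba_sd", "tph_sd", "conifer_logit_sd", "image_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.gps_error_95_m < 0:
            raise ValueError("gps_error_95_m must be non-negative")

    @property
    def n_rows(self) -> int:
        return int(self.extent_m[1] // self.cell_size_m)

    @property
    def n_cols(self) -> int:
        return int(self.extent_m[0] // self.cell_size_m)

    def grid(self) -> GridSpec:
        return GridSpec(0.0, self.extent_m[1], self.cell_size_m, self.n_rows, self.n_cols)


@dataclass
class StemMap:
    """Individual-tree records for the whole landscape."""

    trees: pd.DataFrame  # x, y, species, conifer, dbh_cm, height_m, live

    def __post_init__(self) -> None:
        required = {"x", "y", "species", "conifer", "dbh_cm", "height_m", "live"}
        missing = required - set(self.trees.columns)
        if missing:
            raise ValueError(f"stem map missing columns: {sorted(missing)}")
        if len(self.trees) and (self.trees["dbh_cm"] <= 0).any():
            raise ValueError("all DBH values must be positive")
        if len(self.trees) and (self.trees["height_m"] <= 0).any():
            raise ValueError("all heights must be positive")

    def __len__(self) -> int:
        return len(self.trees)

    def checksum(self) -> str:
        import hashlib

        payload = self.trees.round(9).to_csv(index=False).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class TruthFields:
    """Per-cell ground truth, aggregation-consistent with the stem map."""

    grid: GridSpec
    ba: np.ndarray  # m2/ha, (n_rows, n_cols)
    tph: np.ndarray  # stems/ha
    pct_conifer: np.ndarray  # 0..100, BA share
    height: np.ndarray  # mean tree height, m

    def frame(self) -> pd.DataFrame:
        rows, cols = np.divmod(np.arange(self.grid.n_cells), self.grid.n_cols)
        return pd.DataFrame(
            {
                "cell_id": np.arange(self.grid.n_cells),
                "row": rows,
                "col": cols,
                "true_ba": self.ba.ravel(),
                "true_tph": self.tph.ravel(),
                "true_pct_conifer": self.pct_conifer.ravel(),
                "true_height": self.height.ravel(),
            }
        )


@dataclass
class PrismPlot:
    """One variable-radius tally with its realized (jittered) center."""

    nominal_x: float
    nominal_y: float
    realized_x: float
    realized_y: float
    baf: float
    min_dbh_cm: float
    trees: pd.DataFrame  # dbh_cm, height_m, species, conifer, live, distance_m

    @property
    def tally_count(self) -> int:
        return len(self.trees)


@dataclass
class Landscape:
    config: LandscapeConfig
    grid: GridSpec
    stem_map: StemMap
    truth: TruthFields
    rasters: dict[str, RasterLayer]
    crowns: list[dict]  # geometry (shapely), max_height_m, area_m2


def limiting_distance(dbh_cm: float, baf: float) -> float:
    """Maximum tally distance (m) for a tree of ``dbh_cm`` under ``baf``.

    A prism with basal area factor F (m2/ha) tallies a tree iff
    F >= 2500 (D/R)^2 with D, R in meters, i.e. R = 50 D / sqrt(F).
    """
    dbh_cm = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh_cm <= 0):
        raise ValueError("dbh_cm must be positive")
    if baf <= 0:
        raise ValueError("baf must be positive")
    out = 50.0 * (dbh_cm / 100.0) / np.sqrt(baf)
    return float(out) if out.ndim == 0 else out


def _gaussian_field(n_rows: int, n_cols: int, range_cells: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance GRF with exponential correlation, via circulant embedding.

    ``range_cells`` is the practical range (corr ~ 0.05) in cell units.
    Negative embedding eigenvalues are clipped; the resulting field is
    rescaled to unit variance in expectation.
    """
    if range_cells <= 1e-9:
        return rng.standard_normal((n_rows, n_cols))
    ell = range_cells / 3.0  # exp(-3) ~ 0.05 at the practical range
    m, n = 2 * n_rows, 2 * n_cols
    iy = np.minimum(np.arange(m), m - np.arange(m))
    ix = np.minimum(np.arange(n), n - np.arange(n))
    d = np.hypot(iy[:, None], ix[None, :])
    cov = np.exp(-d / ell)
    lam = np.fft.fft2(cov).real
    lam = np.clip(lam, 0.0, None)
    scale = np.sqrt(lam / (m * n))
    noise = rng.standard_normal((m, n)) + 1j * rng.standard_normal((m, n))
    f = np.fft.fft2(scale * noise).real[:n_rows, :n_cols]
    # after clipping, the marginal variance is sum(lam)/(m n); renormalize
    var = lam.sum() / (m * n)
    if var > 0:
        f /= np.sqrt(var)
    return f


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    if mean <= 0:
        raise ValueError("log-normal mean must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _canopy_height_from_ba(ba: np.ndarray) -> np.ndarray:
    # allometric-style monotone link; capped at tall-forest heights
    return np.minimum(4.0 + 3.2 * np.sqrt(ba), 45.0)


def _crown_radius(dbh_cm: np.ndarray) -> np.ndarray:
    return 0.5 + 0.05 * dbh_cm


def simulate_landscape(config: LandscapeConfig) -> Landscape:
    """Generate stems, truth fields, rasters and crown polygons.

    The per-cell truth BA/TPH equal the stem-map aggregation exactly: tree
    diameters are drawn with random relative sizes, then rescaled so the
    summed stem basal area matches the cell's target.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    nr, nc = grid.n_rows, grid.n_cols
    range_cells = config.spatial_corr_range_m / config.cell_size_m

    z_ba = _gaussian_field(nr, nc, range_cells, rng)
    z_ind = _gaussian_field(nr, nc, range_cells, rng)
    rho = config.tph_ba_corr
    z_tph = rho * z_ba + np.sqrt(max(0.0, 1 - rho**2)) * z_ind
    z_con = _gaussian_field(nr, nc, range_cells, rng)

    if config.ba_sd > 0:
        mu, sig = _lognormal_params(config.ba_mean, config.ba_sd)
        ba_target = np.exp(mu + sig * z_ba)
    else:
        ba_target = np.full((nr, nc), config.ba_mean)
    if config.tph_sd > 0:
        mu, sig = _lognormal_params(config.tph_mean, config.tph_sd)
        tph_target = np.exp(mu + sig * z_tph)
    else:
        tph_target = np.full((nr, nc), config.tph_mean)
    pcon_target = 100.0 * _sigmoid(config.conifer_logit_mean + config.conifer_logit_sd * z_con)
    h_cell = _canopy_height_from_ba(ba_target)

    area_ha = grid.cell_area_ha
    records: list[pd.DataFrame] = []
    ba_true = np.zeros((nr, nc))
    tph_true = np.zeros((nr, nc))
    pcon_true = np.zeros((nr, nc))
    h_true = np.zeros((nr, nc))

    for r in range(nr):
        for c in range(nc):
            n_trees = int(round(tph_target[r, c] * area_ha))
            if n_trees == 0:
                continue
            target_ba_m2 = ba_target[r, c] * area_ha  # total stem BA in the cell
            mean_tree_ba = target_ba_m2 / n_trees
            qmd_cm = 200.0 * np.sqrt(mean_tree_ba / np.pi)
            rel = rng.lognormal(mean=0.0, sigma=0.3, size=n_trees)
            dbh = qmd_cm * rel
            # exact rescale: sum pi (d/200)^2 == target
            dbh *= np.sqrt(target_ba_m2 / (np.pi * np.sum((dbh / 200.0) ** 2)))
            top_h = h_cell[r, c]
            ht = 1.3 + (top_h * 1.15 - 1.3) * np.clip(dbh / qmd_cm, 0.05, None) ** 0.5
            ht *= np.exp(rng.normal(0.0, 0.05, size=n_trees))
            ht = np.maximum(ht, 1.5)
            conifer = rng.random(n_trees) < pcon_target[r, c] / 100.0
            live = rng.random(n_trees) >= config.dead_fraction
            x = grid.origin_x + (c + rng.random(n_trees)) * grid.cell_size_m
            y = grid.origin_y - (r + rng.random(n_trees)) * grid.cell_size_m

            tree_ba = np.pi * (dbh / 200.0) ** 2
            ba_true[r, c] = tree_ba.sum() / area_ha
            tph_true[r, c] = n_trees / area_ha
            pcon_true[r, c] = min(100.0 * tree_ba[conifer].sum() / tree_ba.sum(), 100.0)
            h_true[r, c] = ht.mean()
            records.append(
                pd.DataFrame(
                    {
                        "x": x,
                        "y": y,
                        "species": np.where(conifer, "CON", "HWD"),
                        "conifer": conifer,
                        "dbh_cm": dbh,
                        "height_m": ht,
                        "live": live,
                        "cell_id": grid.cell_id(r, c),
                    }
                )
            )

    if records:
        trees = pd.concat(records, ignore_index=True)
    else:
        trees = pd.DataFrame(
            columns=["x", "y", "species", "conifer", "dbh_cm", "height_m", "live", "cell_id"]
        )
    stem_map = StemMap(trees)
    truth = TruthFields(grid, ba_true, tph_true, pcon_true, h_true)

    rasters = _render_rasters(config, grid, stem_map, ba_target, pcon_target, rng)
    crowns = _crown_polygons(config, stem_map)
    return Landscape(config, grid, stem_map, truth, rasters, crowns)


def _render_rasters(
    config: LandscapeConfig,
    grid: GridSpec,
    stem_map: StemMap,
    ba_target: np.ndarray,
    pcon_target: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, RasterLayer]:
    w, h = config.extent_m

    # DEM: smooth analytic surface so slope/aspect gradients are realistic
    dp = config.dem_pixel_m
    nxr, nyr = int(w / dp), int(h / dp)
    xs = (np.arange(nxr) + 0.5) * dp
    ys = h - (np.arange(nyr) + 0.5) * dp
    xx, yy = np.meshgrid(xs, ys)
    dem = (
        120.0
        + 40.0 * np.sin(2 * np.pi * xx / w) * np.cos(2 * np.pi * yy / h)
        + 0.03 * xx
        + 0.015 * yy
    )
    layers = {"dem": RasterLayer(dem, 0.0, h, dp, name="dem")}

    # CHM: stamp parabolic crowns onto a zero surface
    cp = config.chm_pixel_m
    chm = np.zeros((int(h / cp), int(w / cp)))
    t = stem_map.trees
    if len(t):
        rc = _crown_radius(t["dbh_cm"].to_numpy())
        txs, tys = t["x"].to_numpy(), t["y"].to_numpy()
        ths = t["height_m"].to_numpy()
        nrow, ncol = chm.shape
        for xi, yi, hi, ri in zip(txs, tys, ths, rc):
            c0 = int((xi - ri) / cp)
            c1 = int((xi + ri) / cp) + 1
            r0 = int((h - yi - ri) / cp)
            r1 = int((h - yi + ri) / cp) + 1
            c0, c1 = max(c0, 0), min(c1, ncol)
            r0, r1 = max(r0, 0), min(r1, nrow)
            if c0 >= c1 or r0 >= r1:
                continue
            px = (np.arange(c0, c1) + 0.5) * cp
            py = h - (np.arange(r0, r1) + 0.5) * cp
            dist2 = (px[None, :] - xi) ** 2 + (py[:, None] - yi) ** 2
            prof = hi * np.clip(1.0 - dist2 / ri**2, 0.0, None) ** 0.6
            np.maximum(chm[r0:r1, c0:c1], prof, out=chm[r0:r1, c0:c1])
    layers["chm"] = RasterLayer(chm, 0.0, h, cp, name="chm")

    # optical bands: monotone-in-expectation functions of BA and %conifer
    ip = config.image_pixel_m
    nri, nci = int(h / ip), int(w / ip)
    ry = np.minimum((np.arange(nri) * ip / config.cell_size_m).astype(int), grid.n_rows - 1)
    cx = np.minimum((np.arange(nci) * ip / config.cell_size_m).astype(int), grid.n_cols - 1)
    # row index measured from the top matches raster row order
    ba_px = ba_target[np.ix_(ry, cx)]
    pc_px = pcon_target[np.ix_(ry, cx)]
    dens = np.tanh(ba_px / 40.0)
    bands = {
        "cir_ir": 0.55 + 0.25 * dens - 0.0015 * pc_px,
        "cir_red": 0.30 - 0.10 * dens + 0.0008 * pc_px,
        "cir_green": 0.35 - 0.05 * dens + 0.0004 * pc_px,
        "rgb_red": 0.32 - 0.08 * dens + 0.0006 * pc_px,
        "rgb_green": 0.38 - 0.06 * dens - 0.0005 * pc_px,
        "rgb_blue": 0.28 - 0.04 * dens - 0.0002 * pc_px,
    }
    for name, vals in bands.items():
        if config.image_noise_sd > 0:
            vals = vals + rng.normal(0.0, config.image_noise_sd, vals.shape)
        layers[name] = RasterLayer(np.clip(vals, 0.0, 1.2), 0.0, h, ip, name=name)
    return layers


def _crown_polygons(config: LandscapeConfig, stem_map: StemMap) -> list[dict]:
    crowns = []
    t = stem_map.trees
    if not len(t):
        return crowns
    sel = t["height_m"].to_numpy() >= config.crown_min_height_m
    sub = t.loc[sel]
    radii = _crown_radius(sub["dbh_cm"].to_numpy())
    for (xi, yi, hi), ri in zip(sub[["x", "y", "height_m"]].to_numpy(), radii):
        geom = Point(xi, yi).buffer(ri, quad_segs=8)
        crowns.append({"geometry": geom, "max_height_m": float(hi), "area_m2": geom.area})
    return crowns


def simulate_prism_plot(
    stem_map: StemMap,
    location: tuple[float, float],
    baf: float,
    min_dbh_cm: float = 14.0,
    gps_error_95_m: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PrismPlot:
    """Tally all trees visible from ``location`` through a ``baf`` prism.

    The realized plot center is the nominal location plus circular bivariate
    normal GPS error scaled so 95% of draws fall within ``gps_error_95_m``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    x0, y0 = location
    if gps_error_95_m > 0:
        sigma = gps_error_95_m / _RAYLEIGH_Q95
        x0 = x0 + rng.normal(0.0, sigma)
        y0 = y0 + rng.normal(0.0, sigma)

    t = stem_map.trees
    if len(t) == 0:
        tallied = t.copy()
        tallied["distance_m"] = pd.Series(dtype=float)
    else:
        dbh = t["dbh_cm"].to_numpy()
        dist = np.hypot(t["x"].to_numpy() - x0, t["y"].to_numpy() - y0)
        eligible = dbh >= min_dbh_cm
        lim = np.zeros_like(dbh)
        lim[eligible] = limiting_distance(dbh[eligible], baf)
        keep = eligible & (dist <= lim)
        tallied = t.loc[keep].copy()
        tallied["distance_m"] = dist[keep]
    cols = ["dbh_cm", "height_m", "species", "conifer", "live", "distance_m"]
    return PrismPlot(
        nominal_x=location[0],
        nominal_y=location[1],
        realized_x=x0,
        realized_y=y0,
        baf=baf,
        min_dbh_cm=min_dbh_cm,
        trees=tallied[cols].reset_index(drop=True),
    )


def write_landscape(landscape: Landscape, out_dir: str | Path) -> dict[str, str]:
    """Write rasters (.asc), crowns (GeoJSON), stems and truth (CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, layer in landscape.rasters.items():
        p = out / f"{name}.asc"
        write_ascii_grid(layer, p)
        written[name] = str(p)
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(c["geometry"]),
            "properties": {"max_height_m": c["max_height_m"], "area_m2": c["area_m2"]},
        }
        for c in landscape.crowns
    ]
    crowns_path = out / "crowns.geojson"
    crowns_path.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
    written["crowns"] = str(crowns_path)
    stems_path = out / "stems.csv"
    landscape.stem_map.trees.to_csv(stems_path, index=False)
    written["stems"] = str(stems_path)
    truth_path = out / "truth.csv"
    landscape.truth.frame().to_csv(truth_path, index=False)
    written["truth"] = str(truth_path)
    cfg_path = out / "landscape_config.json"
    cfg_path.write_text(json.dumps(asdict(landscape.config), indent=2))
    written["config"] = str(cfg_path)
    return written
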