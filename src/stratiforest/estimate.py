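"""Prism-plot expansion and post-stratified inventory estimation.

Each tallied tree in a variable-radius plot represents exactly BAF m2/ha of
basal area and BAF / (pi (DBH/200)^2) stems/ha.  Stratum and property
estimates use the classic stratified (post-stratification) estimators with
Student-t 90% accuracy half-widths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import PrismPlot

__all__ = [
    "PlotSummary",
    "ALLOMETRY_REGISTRY",
    "register_allometry",
    "plot_statistics",
    "poststratified_estimate",
    "strata_tree_list",
    "compare_designs",
]


# ---------------------------------------------------------------------------
# pluggable per-tree allometry (volume / carbon stubs, replaceable)

AllometryFn = Callable[[str, float, float], dict[str, float]]


def _default_allometry(species_class: str, dbh_cm: float, height_m: float) -> dict[str, float]:
    """Simplified biomass / merchantable-volume stubs.

    Carbon: 0.25 x exponential biomass curve in ln(DBH); board feet only for
    conifers from a quadratic DBH-height volume stub.  Placeholder for
    regional equations, which are intentionally out of scope.
    """
    biomass_kg = np.exp(-2.0 + 2.4 * np.log(max(dbh_cm, 1e-6)))
    carbon_kg = 0.25 * biomass_kg
    if species_class == "CON":
        bf = 0.005 * dbh_cm**2 * height_m
    else:
        bf = 0.0
    return {"carbon_kg": float(carbon_kg), "board_feet": float(bf)}


ALLOMETRY_REGISTRY: dict[str, AllometryFn] = {"default": _default_allometry}


def register_allometry(name: str, fn: AllometryFn) -> None:
    ALLOMETRY_REGISTRY[name] = fn


@dataclass
class PlotSummary:
    ba: float  # m2/ha
    tph: float  # stems/ha
    pct_conifer_ba: float  # 0..100
    volume_proxy: float  # BA x mean tallied height
    carbon_mg_ha: float
    board_feet_ha: float
    tally_count: int


def plot_statistics(
    plot: PrismPlot,
    baf: float | None = None,
    allometry: str | AllometryFn = "default",
    include_dead_carbon: bool = False,
) -> PlotSummary:
    """Expand one prism tally to per-hectare values.

    BA is exactly BAF x tally count; each tree's TPH expansion is
    BAF / (pi (DBH/200)^2).  Conifer share is on a BA (tally-count) basis.
    Dead trees are excluded from the carbon slot unless requested.
    """
    baf = plot.baf if baf is None else baf
    t = plot.trees
    n = len(t)
    if n == 0:
        return PlotSummary(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0)
    dbh = t["dbh_cm"].to_numpy(dtype=float)
    if np.any(dbh <= 0):
        bad = int(np.where(dbh <= 0)[0][0])
        raise ValueError(f"non-positive DBH in tallied tree index {bad}")
    ht = t["height_m"].to_numpy(dtype=float)
    conifer = t["conifer"].to_numpy(dtype=bool)
    live = t["live"].to_numpy(dtype=bool) if "live" in t.columns else np.ones(n, dtype=bool)

    ba = baf * n
    tree_tph = baf / (np.pi * (dbh / 200.0) ** 2)
    tph = float(tree_tph.sum())
    pct_con = 100.0 * conifer.sum() / n
    vol = ba * float(ht.mean())

    fn = ALLOMETRY_REGISTRY[allometry] if isinstance(allometry, str) else allometry
    carbon = 0.0
    bf = 0.0
    for i in range(n):
        species = "CON" if conifer[i] else "HWD"
        a = fn(species, float(dbh[i]), float(ht[i]))
        if live[i] or include_dead_carbon:
            carbon += a["carbon_kg"] * tree_tph[i] / 1000.0  # Mg/ha
        if live[i]:
            bf += a["board_feet"] * tree_tph[i]
    return PlotSummary(float(ba), tph, float(pct_con), float(vol), carbon, bf, n)


def summaries_frame(plots: list[PrismPlot], strata: list[int], **kwargs) -> pd.DataFrame:
    rows = []
    for plot, stratum in zip(plots, strata):
        s = plot_statistics(plot, **kwargs)
        rows.append(
            {
                "stratum": stratum,
                "ba": s.ba,
                "tph": s.tph,
                "pct_conifer_ba": s.pct_conifer_ba,
                "volume_proxy": s.volume_proxy,
                "carbon_mg_ha": s.carbon_mg_ha,
                "board_feet_ha": s.board_feet_ha,
                "tally_count": s.tally_count,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# post-stratified estimation


def _fold_small_strata(plots: pd.DataFrame, strata: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold strata with < 2 plots into the nearest proxy-rank stratum."""
    plots = plots.copy()
    strata = strata[strata["stratum"] > 0].copy().sort_values("proxy_mean").reset_index(drop=True)
    while True:
        counts = plots.groupby("stratum").size()
        small = [
            s for s in strata["stratum"] if counts.get(s, 0) < 2
        ]
        if not small or len(strata) == 1:
            break
        victim = small[0]
        others = strata[strata["stratum"] != victim]
        vmean = float(strata.loc[strata["stratum"] == victim, "proxy_mean"].iloc[0])
        target = int(
            others.iloc[(others["proxy_mean"] - vmean).abs().argmin()]["stratum"]
        )
        warnings.warn(f"folding stratum {victim} (<2 plots) into stratum {target}")
        plots.loc[plots["stratum"] == victim, "stratum"] = target
        for col in ("n_cells", "area_ha"):
            if col in strata.columns:
                strata.loc[strata["stratum"] == target, col] += float(
                    strata.loc[strata["stratum"] == victim, col].iloc[0]
                )
        strata = strata[strata["stratum"] != victim].reset_index(drop=True)
    return plots, strata


def poststratified_estimate(
    plots: pd.DataFrame,
    strata: pd.DataFrame,
    variables: list[str] | None = None,
    alpha: float = 0.10,
    use_t: bool = True,
    fold_small: bool = True,
) -> pd.DataFrame:
    """Stratified (post-stratification) estimates with accuracy half-widths.

    ``plots`` needs a ``stratum`` column plus the value columns; ``strata``
    needs ``stratum`` and ``area_ha`` (weights) and, if folding is enabled,
    ``proxy_mean``.  Returns one row per variable with the property mean,
    variance of the mean, SE, half-width and accuracy% (100 x half-width /
    mean), plus per-stratum means.
    """
    if variables is None:
        variables = [
            c for c in plots.columns if c != "stratum" and np.issubdtype(plots[c].dtype, np.number)
        ]
    missing = set(plots["stratum"].unique()) - set(strata["stratum"])
    if missing:
        raise ValueError(f"plots reference strata absent from the table: {sorted(missing)}")
    if fold_small:
        if "proxy_mean" not in strata.columns:
            strata = strata.assign(proxy_mean=strata["stratum"].astype(float))
        plots, strata = _fold_small_strata(plots, strata)
    strata = strata[strata["stratum"].isin(plots["stratum"].unique())]
    W = strata.set_index("stratum")["area_ha"]
    W = W / W.sum()

    rows = []
    for var in variables:
        grp = plots.groupby("stratum")[var]
        n_h = grp.size()
        ybar = grp.mean()
        s2 = grp.var(ddof=1).fillna(0.0)
        idx = ybar.index
        w = W.loc[idx].to_numpy()
        mean = float(np.sum(w * ybar.to_numpy()))
        a_h = w**2 * s2.to_numpy() / n_h.to_numpy()
        var_mean = float(np.sum(a_h))
        se = float(np.sqrt(var_mean))
        if use_t and var_mean > 0:
            denom = np.sum(a_h**2 / np.maximum(n_h.to_numpy() - 1, 1))
            df = var_mean**2 / denom if denom > 0 else float(n_h.sum() - len(idx))
            mult = float(stats.t.ppf(1 - alpha / 2, df))
        else:
            mult = float(stats.norm.ppf(1 - alpha / 2))
        hw = mult * se
        rows.append(
            {
                "variable": var,
                "mean": mean,
                "var_of_mean": var_mean,
                "se": se,
                "half_width": hw,
                "accuracy_pct": 100.0 * hw / abs(mean) if mean != 0 else 0.0,
                "n_plots": int(n_h.sum()),
                "n_strata": len(idx),
            }
        )
    return pd.DataFrame(rows)


def stratum_estimates(plots: pd.DataFrame, variables: list[str] | None = None) -> pd.DataFrame:
    if variables is None:
        variables = [
            c for c in plots.columns if c != "stratum" and np.issubdtype(plots[c].dtype, np.number)
        ]
    grp = plots.groupby("stratum")
    out = grp[variables].mean()
    out["n_plots"] = grp.size()
    return out.reset_index()


def strata_tree_list(plots: list[PrismPlot], dbh_class_cm: float = 5.0) -> pd.DataFrame:
    """Per-ha species x diameter-class stem table for one stratum.

    Averages per-tree TPH and BA expansions over plots; summed BA equals the
    mean plot BA exactly.
    """
    if not plots:
        raise ValueError("need at least one plot")
    n_plots = len(plots)
    rows = []
    for plot in plots:
        t = plot.trees
        if len(t) == 0:
            continue
        dbh = t["dbh_cm"].to_numpy(dtype=float)
        tph = plot.baf / (np.pi * (dbh / 200.0) ** 2) / n_plots
        ba = np.full(len(t), plot.baf / n_plots)
        rows.append(
            pd.DataFrame(
                {
                    "species": t["species"].to_numpy(),
                    "dbh_class": (np.floor(dbh / dbh_class_cm) * dbh_class_cm).astype(float),
                    "tph": tph,
                    "ba": ba,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["species", "dbh_class", "tph", "ba"])
    allt = pd.concat(rows, ignore_index=True)
    return (
        allt.groupby(["species", "dbh_class"], as_index=False)[["tph", "ba"]]
        .sum()
        .sort_values(["species", "dbh_class"])
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# design comparison on a synthetic population


def compare_designs(
    values: np.ndarray,
    labels: np.ndarray,
    n_total: int,
    replicates: int = 200,
    seed: int = 0,
    alpha: float = 0.10,
    floor: int = 2,
) -> pd.DataFrame:
    """Monte-Carlo accuracy of stratified vs simple random sampling.

    ``values`` are per-cell population values, ``labels`` the stratum of each
    cell (0 = excluded).  Each replicate draws a Neyman-allocated stratified
    sample and an SRS of the same size and records the 90% accuracy
    statistic of each.
    """
    if replicates < 30:
        warnings.warn("fewer than 30 replicates; comparison will be noisy")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = labels > 0
    values, labels = values[keep], labels[keep]
    strata = np.unique(labels)
    N_h = np.array([(labels == s).sum() for s in strata], dtype=float)
    S_h = np.array(
        [values[labels == s].std(ddof=1) if (labels == s).sum() > 1 else 0.0 for s in strata]
    )
    from .design import neyman_allocate

    plan = neyman_allocate(N_h, S_h, n_total, floor=floor, strata=strata)
    n_h = plan.n_plots
    W = N_h / N_h.sum()
    idx_by_stratum = [np.where(labels == s)[0] for s in strata]

    rng = np.random.default_rng(seed)
    recs = []
    for rep in range(replicates):
        # stratified draw
        means, variances = [], []
        a_list = []
        for i, s in enumerate(strata):
            take = rng.choice(idx_by_stratum[i], size=int(n_h[i]), replace=False)
            v = values[take]
            means.append(v.mean())
            variances.append(v.var(ddof=1) if len(v) > 1 else 0.0)
        means = np.array(means)
        variances = np.array(variances)
        est = float(np.sum(W * means))
        a_h = W**2 * variances / n_h
        var_mean = float(a_h.sum())
        denom = np.sum(a_h**2 / np.maximum(n_h - 1, 1))
        df = var_mean**2 / denom if denom > 0 else float(n_h.sum() - len(strata))
        hw = stats.t.ppf(1 - alpha / 2, df) * np.sqrt(var_mean)
        acc_strat = 100.0 * hw / abs(est) if est != 0 else 0.0

        # SRS at matched size
        n_srs = int(n_h.sum())
        take = rng.choice(len(values), size=n_srs, replace=False)
        v = values[take]
        est_srs = float(v.mean())
        se_srs = v.std(ddof=1) / np.sqrt(n_srs)
        hw_srs = stats.t.ppf(1 - alpha / 2, n_srs - 1) * se_srs
        acc_srs = 100.0 * hw_srs / abs(est_srs) if est_srs != 0 else 0.0
        recs.append(
            {
                "replicate": rep,
                "stratified_mean": est,
                "stratified_accuracy_pct": float(acc_strat),
                "srs_mean": est_srs,
                "srs_accuracy_pct": float(acc_srs),
            }
        )
    return pd.DataFrame(recs)
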