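"""Volume-proxy stratification: optimal 1-D binning and minimum-area merging.

Cells are binned on the product of predicted basal area and mean canopy
height by an exact dynamic program minimizing total within-bin sum of
squared deviations; undersized strata are dissolved into proxy-rank
neighbors by attribute nearness.  Stratum 0 is reserved for non-forest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BinningResult",
    "StratumAssignment",
    "volume_proxy",
    "optimal_bin",
    "nonforest_mask",
    "enforce_min_area",
    "stratum_table",
    "build_strata",
]

ATTRIBUTE_COLUMNS = ["ba", "height", "tph", "pct_conifer"]


def volume_proxy(pred_ba: np.ndarray, mean_height: np.ndarray) -> np.ndarray:
    """Per-cell volume proxy v = BA x canopy height."""
    ba = np.asarray(pred_ba, dtype=float)
    h = np.asarray(mean_height, dtype=float)
    if ba.shape != h.shape:
        raise ValueError("BA and height arrays must align")
    if np.any(ba < 0) or np.any(h < 0):
        raise ValueError("BA and height must be non-negative")
    return ba * h


@dataclass
class BinningResult:
    boundaries: np.ndarray  # (k-1,) upper inclusive edges of bins 0..k-2
    assignment: np.ndarray  # bin index per input value, 0-based
    sse: float

    @property
    def k(self) -> int:
        return len(self.boundaries) + 1

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin new values with the fitted boundaries."""
        return np.searchsorted(self.boundaries, np.asarray(values, dtype=float), side="left")


def optimal_bin(values: np.ndarray, k: int) -> BinningResult:
    """Globally optimal k-bin partition of sorted values by dynamic program.

    Runs Fisher-style O(k u^2) DP on the u distinct values with
    multiplicities; minimizes total within-bin SSE over contiguous bins.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError("need at least k values")
    uniq, counts = np.unique(values, return_counts=True)
    u = len(uniq)
    if k > u:
        raise ValueError(f"k={k} exceeds the {u} distinct values")

    w = counts.astype(float)
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cs1 = np.concatenate([[0.0], np.cumsum(w * uniq)])
    cs2 = np.concatenate([[0.0], np.cumsum(w * uniq**2)])

    def cost(i: int, j: int) -> float:
        # SSE of distinct values i..j inclusive (0-based)
        cnt = cw[j + 1] - cw[i]
        s1 = cs1[j + 1] - cs1[i]
        s2 = cs2[j + 1] - cs2[i]
        return max(s2 - s1 * s1 / cnt, 0.0)

    dp = np.full((k, u), np.inf)
    back = np.zeros((k, u), dtype=int)
    for j in range(u):
        dp[0, j] = cost(0, j)
    for m in range(1, k):
        for j in range(m, u):
            best, arg = np.inf, m
            for i in range(m, j + 1):
                c = dp[m - 1, i - 1] + cost(i, j)
                if c < best:
                    best, arg = c, i
            dp[m, j] = best
            back[m, j] = arg

    # recover distinct-value boundaries
    cuts = []
    j = u - 1
    for m in range(k - 1, 0, -1):
        i = back[m, j]
        cuts.append(uniq[i - 1])  # upper edge of the lower bin
        j = i - 1
    boundaries = np.array(sorted(cuts))
    assignment = np.searchsorted(boundaries, values, side="left")
    return BinningResult(boundaries=boundaries, assignment=assignment, sse=float(dp[k - 1, u - 1]))


def nonforest_mask(
    cells: pd.DataFrame,
    closure_threshold_pct: float = 10.0,
    height_threshold_m: float = 2.0,
) -> np.ndarray:
    """True where a cell is non-forest (strictly below both thresholds)."""
    closure = cells["crown_closure_pct"].to_numpy(dtype=float)
    height = cells["chm_mean"].to_numpy(dtype=float)
    return (closure < closure_threshold_pct) & (height < height_threshold_m)


@dataclass
class StratumAssignment:
    labels: np.ndarray  # per-cell stratum label, 0 = non-forest
    proxy: np.ndarray  # per-cell proxy value
    cell_area_ha: float
    table: pd.DataFrame  # per-stratum summary

    @property
    def n_strata(self) -> int:
        return int((self.table["stratum"] > 0).sum())


def stratum_table(
    labels: np.ndarray,
    proxy: np.ndarray,
    attributes: pd.DataFrame,
    cell_area_ha: float,
) -> pd.DataFrame:
    rows = []
    for lab in sorted(np.unique(labels)):
        sel = labels == lab
        row = {
            "stratum": int(lab),
            "n_cells": int(sel.sum()),
            "area_ha": float(sel.sum() * cell_area_ha),
            "proxy_mean": float(proxy[sel].mean()),
            "proxy_var": float(proxy[sel].var(ddof=1)) if sel.sum() > 1 else 0.0,
        }
        for col in ATTRIBUTE_COLUMNS:
            if col in attributes.columns:
                row[f"mean_{col}"] = float(attributes.loc[sel, col].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def build_strata(
    proxy: np.ndarray,
    k: int,
    attributes: pd.DataFrame,
    cell_area_ha: float,
    nonforest: np.ndarray | None = None,
    min_area_ha: float = 4.05,
) -> StratumAssignment:
    """Bin forested cells into k strata, then enforce the minimum area."""
    proxy = np.asarray(proxy, dtype=float)
    n = len(proxy)
    labels = np.zeros(n, dtype=int)
    forest = np.ones(n, dtype=bool) if nonforest is None else ~np.asarray(nonforest)
    k_eff = min(k, len(np.unique(proxy[forest]))) if forest.any() else 0
    if k_eff > 0:
        result = optimal_bin(proxy[forest], k_eff)
        labels[forest] = result.assignment + 1
    assignment = StratumAssignment(
        labels=labels,
        proxy=proxy,
        cell_area_ha=cell_area_ha,
        table=stratum_table(labels, proxy, attributes, cell_area_ha),
    )
    return enforce_min_area(assignment, attributes, min_area_ha=min_area_ha)


def enforce_min_area(
    assignment: StratumAssignment,
    attributes: pd.DataFrame,
    min_area_ha: float = 4.05,
) -> StratumAssignment:
    """Dissolve forested strata below ``min_area_ha`` into proxy-rank neighbors.

    Undersized strata are processed smallest first; each of their cells moves
    to the adjacent-rank stratum (one rank up or down among survivors)
    minimizing the standardized Euclidean distance between the cell's
    (BA, height, TPH, %conifer) attributes and the stratum means.
    """
    labels = assignment.labels.copy()
    proxy = assignment.proxy
    cell_area = assignment.cell_area_ha
    attr_cols = [c for c in ATTRIBUTE_COLUMNS if c in attributes.columns]
    if not attr_cols:
        raise ValueError("attribute table lacks BA/height/TPH/%conifer columns")
    A = attributes[attr_cols].to_numpy(dtype=float)
    mu, sd = A.mean(axis=0), A.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (A - mu) / sd

    forest_total = float((labels > 0).sum() * cell_area)
    if 0 < forest_total < min_area_ha:
        warnings.warn("total forested area below the minimum stratum size; single stratum")
        labels[labels > 0] = 1
        table = stratum_table(labels, proxy, attributes, cell_area)
        return StratumAssignment(labels, proxy, cell_area, table)

    def rank_order(labs: np.ndarray) -> list[int]:
        out = []
        for lab in np.unique(labs):
            if lab > 0:
                out.append((proxy[labs == lab].mean(), int(lab)))
        return [lab for _, lab in sorted(out)]

    while True:
        order = rank_order(labels)
        areas = {lab: (labels == lab).sum() * cell_area for lab in order}
        under = [lab for lab in order if areas[lab] < min_area_ha]
        if not under or len(order) == 1:
            break
        victim = min(under, key=lambda lab: areas[lab])
        pos = order.index(victim)
        neighbors = [order[i] for i in (pos - 1, pos + 1) if 0 <= i < len(order)]
        centroids = {lab: Z[labels == lab].mean(axis=0) for lab in neighbors}
        for i in np.where(labels == victim)[0]:
            d = {lab: float(np.sum((Z[i] - centroids[lab]) ** 2)) for lab in neighbors}
            labels[i] = min(neighbors, key=lambda lab: d[lab])

    # relabel 1..m by ascending proxy mean
    order = rank_order(labels)
    remap = {old: new for new, old in enumerate(order, start=1)}
    new_labels = np.array([remap.get(lab, 0) for lab in labels])
    table = stratum_table(new_labels, proxy, attributes, cell_area)
    return StratumAssignment(new_labels, proxy, cell_area, table)
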