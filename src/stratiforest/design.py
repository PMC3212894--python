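"""Second-phase sample design: Neyman/optimal allocation and plot placement.

Plots are allocated across strata proportional to N_h * S_h (optionally
divided by sqrt(cost)), integerized by largest remainder, floored so every
sampled stratum stays estimable, and placed by simple random sampling of
cells (at most one plot per cell, plot at the cell center).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import GridSpec
from .stratify import StratumAssignment

__all__ = ["AllocationPlan", "neyman_allocate", "model_variance", "place_plots"]


@dataclass
class AllocationPlan:
    strata: np.ndarray  # stratum labels
    n_cells: np.ndarray  # N_h
    sds: np.ndarray  # S_h
    n_plots: np.ndarray  # n_h
    floor_applied: np.ndarray  # bool per stratum
    total_exceeds_request: bool = False
    plots: pd.DataFrame | None = None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.strata,
                "N_h": self.n_cells,
                "S_h": self.sds,
                "n_h": self.n_plots,
                "floor_applied": self.floor_applied,
            }
        )


def _largest_remainder(target: np.ndarray, total: int) -> np.ndarray:
    """Integerize non-negative real targets to the given total."""
    base = np.floor(target).astype(int)
    short = total - base.sum()
    if short > 0:
        remainders = target - base
        # ties broken by stratum order (stable argsort on negated remainder)
        order = np.argsort(-remainders, kind="stable")
        base[order[:short]] += 1
    return base


def neyman_allocate(
    N: np.ndarray,
    S: np.ndarray,
    total_n: int,
    floor: int = 2,
    costs: np.ndarray | None = None,
    strata: np.ndarray | None = None,
) -> AllocationPlan:
    """Allocate ``total_n`` plots with n_h proportional to N_h S_h (/ sqrt c_h).

    Floors apply to strata with positive allocation weight; n_h is capped at
    N_h with the excess redistributed.  If floors push the total above the
    request the plan is flagged.
    """
    N = np.asarray(N, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(N <= 0):
        raise ValueError("all stratum cell counts must be positive")
    if np.any(S < 0):
        raise ValueError("stratum standard deviations must be non-negative")
    H = len(N)
    if strata is None:
        strata = np.arange(1, H + 1)
    w = N * S
    if costs is not None:
        costs = np.asarray(costs, dtype=float)
        if np.any(costs <= 0):
            raise ValueError("costs must be positive")
        w = w / np.sqrt(costs)

    sampled = w > 0
    n_floors = int(sampled.sum()) * floor
    if total_n < n_floors:
        raise ValueError(
            f"total_n={total_n} below the floor requirement of {n_floors} "
            f"({int(sampled.sum())} sampled strata x floor {floor})"
        )
    if w.sum() == 0:
        target = np.zeros(H)
    else:
        target = total_n * w / w.sum()
    n_h = _largest_remainder(target, total_n)

    floor_applied = np.zeros(H, dtype=bool)
    if floor > 0:
        low = sampled & (n_h < floor)
        floor_applied[low] = True
        n_h[low] = floor
    # cap at N_h, redistribute the excess among uncapped sampled strata
    for _ in range(H):
        over = n_h > N
        if not over.any():
            break
        excess = int((n_h - N)[over].sum())
        n_h = np.minimum(n_h, N.astype(int))
        room = sampled & (n_h < N) & ~over
        if not room.any() or excess == 0:
            break
        share = w[room] / w[room].sum()
        n_h[room] += _largest_remainder(excess * share, excess)

    if costs is None:
        # polish to the exact integer variance optimum (cost-aware targets
        # optimize a different objective and are left at the rounded split)
        n_h = _exchange_refine(n_h, N, S, w, floor, sampled)
    total_exceeds = int(n_h.sum()) > total_n
    return AllocationPlan(
        strata=np.asarray(strata),
        n_cells=N.astype(int),
        sds=S,
        n_plots=n_h.astype(int),
        floor_applied=floor_applied,
        total_exceeds_request=total_exceeds,
    )


def _alloc_variance(n_h: np.ndarray, W2S2: np.ndarray) -> float:
    """Stratified-mean variance sum W_h^2 S_h^2 / n_h (inf if unsampled)."""
    with np.errstate(divide="ignore"):
        terms = np.where(W2S2 > 0, W2S2 / np.where(n_h > 0, n_h, np.nan), 0.0)
    return float(np.inf) if np.isnan(terms).any() else float(terms.sum())


def _exchange_refine(
    n_h: np.ndarray,
    N: np.ndarray,
    S: np.ndarray,
    w: np.ndarray,
    floor: int,
    sampled: np.ndarray,
) -> np.ndarray:
    """Pairwise exchanges until the integer allocation is variance-optimal.

    The objective sum W_h^2 S_h^2 / n_h is separable and convex in n_h, so
    single-plot exchange moves reach the exact integer optimum from any
    feasible start (largest-remainder rounding can be off by a plot).
    """
    n_h = n_h.astype(int).copy()
    W = N / N.sum()
    W2S2 = (W * S) ** 2
    lower = np.where(sampled, floor, 0)
    H = len(n_h)
    for _ in range(10 * max(int(n_h.sum()), 1)):
        improved = False
        current = _alloc_variance(n_h, W2S2)
        best_move, best_var = None, current
        for i in range(H):
            if n_h[i] <= lower[i] or n_h[i] <= 0:
                continue
            for j in range(H):
                if i == j or n_h[j] >= N[j] or not sampled[j]:
                    continue
                trial = n_h.copy()
                trial[i] -= 1
                trial[j] += 1
                v = _alloc_variance(trial, W2S2)
                if v < best_var - 1e-15:
                    best_var, best_move = v, (i, j)
        if best_move is not None:
            i, j = best_move
            n_h[i] -= 1
            n_h[j] += 1
            improved = True
        if not improved:
            break
    return n_h


def model_variance(predictions: np.ndarray) -> float:
    """Model-based S_h: sample sd of per-cell predictions within a stratum."""
    p = np.asarray(predictions, dtype=float)
    if len(p) < 2:
        raise ValueError("need at least 2 cells to estimate a stratum sd")
    return float(np.std(p, ddof=1))


def place_plots(
    assignment: StratumAssignment,
    n_h: dict[int, int] | np.ndarray,
    grid: GridSpec,
    seed: int = 0,
) -> pd.DataFrame:
    """Simple random sample of cells within each stratum, one plot per cell.

    Returns a frame of (stratum, cell_id, x, y); plot coordinates are cell
    centers.  Reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    labels = assignment.labels
    if not isinstance(n_h, dict):
        strata = sorted(int(s) for s in np.unique(labels) if s > 0)
        n_h = {s: int(v) for s, v in zip(strata, np.asarray(n_h))}
    rows = []
    for stratum in sorted(n_h):
        want = int(n_h[stratum])
        if want == 0:
            continue
        cells = np.where(labels == stratum)[0]
        if want > len(cells):
            raise ValueError(
                f"stratum {stratum}: requested {want} plots but only {len(cells)} cells"
            )
        chosen = rng.choice(cells, size=want, replace=False)
        r, c = grid.rowcol_of(chosen)
        x, y = grid.cell_center(r, c)
        for cid, xi, yi in zip(chosen, np.atleast_1d(x), np.atleast_1d(y)):
            rows.append({"stratum": stratum, "cell_id": int(cid), "x": float(xi), "y": float(yi)})
    return pd.DataFrame(rows, columns=["stratum", "cell_id", "x", "y"])
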