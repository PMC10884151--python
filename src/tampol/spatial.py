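"""Nearest-neighbour spatial statistics and marker-vs-distance smoothing.

Each macrophage's nearest-neighbour distance (NND) is the Euclidean distance
to the closest tumour cell *within the same TMA core* — cores are separate
tissue islands, so cross-core distances are meaningless.  NNDs are pooled
across cores for cohort-level summaries (class-conditional medians and the
"percent closer" contrast between M1-like and M2-like macrophages).

Marker intensity as a function of distance to tumour cells is summarised
with a penalized cubic B-spline smoother (second-difference coefficient
penalty, the classical P-spline).  The roughness penalty's null space
contains all linear functions, so constants and straight lines are
reproduced exactly at any penalty weight; the penalty weight is chosen by
generalized cross-validation unless fixed by the caller.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import solve
from scipy.spatial import cKDTree

from .cell_model import CoreTable, cells_frame
from .errors import TampolError
from .polarisation import POLARISATION_MARKERS


def nearest_neighbour_distances(sources, targets) -> np.ndarray:
    """Euclidean distance from each source point to its nearest target point.

    ``sources`` and ``targets`` are (n, 2) arrays in the same core-local
    coordinate frame (µm).  Empty targets give all-NaN.  Uses a k-d tree;
    results agree exactly with an O(n*m) brute-force scan.
    """
    sources = np.asarray(sources, dtype=float).reshape(-1, 2)
    targets = np.asarray(targets, dtype=float).reshape(-1, 2)
    if sources.size == 0:
        return np.empty(0)
    if targets.size == 0:
        return np.full(len(sources), np.nan)
    d, _ = cKDTree(targets).query(sources, k=1)
    return np.asarray(d, dtype=float)


def nnd_table(cores: list[CoreTable], polar: pd.DataFrame,
              target_phenotype: str = "tumour") -> pd.DataFrame:
    """Per-macrophage NND records pooled over cores.

    Returns columns cell_id, core_id, klass, nnd_um plus the four scaled
    polarisation-marker intensities (z-scored per marker across the pooled
    macrophages) used for distance-profile smoothing.  NND is missing for
    macrophages in cores without any target-phenotype cell.
    """
    cells = cells_frame(cores)
    if cells.empty:
        return pd.DataFrame(columns=["cell_id", "core_id", "klass", "nnd_um"])
    macs = cells[cells["phenotype"] == "macrophage"].copy()
    if len(polar):
        macs = macs.merge(polar[["cell_id", "klass"]], on="cell_id", how="left")
    else:
        macs["klass"] = np.nan

    nnd = np.full(len(macs), np.nan)
    for core_id, idx in macs.groupby("core_id").indices.items():
        targets = cells[(cells["core_id"] == core_id)
                        & (cells["phenotype"] == target_phenotype)]
        nnd[idx] = nearest_neighbour_distances(
            macs.iloc[idx][["x_um", "y_um"]].to_numpy(),
            targets[["x_um", "y_um"]].to_numpy())
    out = macs[["cell_id", "core_id", "klass"]].copy()
    out["nnd_um"] = nnd
    for m in POLARISATION_MARKERS:
        v = macs[m].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        out[f"z_{m}"] = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    return out.reset_index(drop=True)


def median_nnd_by_class(nnd: pd.DataFrame, klass: str) -> float:
    """Cohort median NND (µm) of one macrophage class; NaN with no records."""
    d = nnd.loc[nnd["klass"] == klass, "nnd_um"].dropna().to_numpy()
    if d.size == 0:
        return float("nan")
    return float(np.median(d))


def percent_closer(median_a: float, median_b: float) -> float:
    """How much closer class a sits to tumour cells than class b, in percent.

    (1 - median_a / median_b) * 100; missing when median_b is 0 or either
    median is missing.  Rounding is left to display code.
    """
    if not np.isfinite(median_a) or not np.isfinite(median_b) or median_b == 0:
        return float("nan")
    return (1.0 - median_a / median_b) * 100.0


# ---------------------------------------------------------------------------
# Penalized-spline smoother


@dataclass
class SmoothCurve:
    """Smoothed curve on a fixed grid, with the penalty weight that produced it."""

    grid_x: np.ndarray
    fitted_y: np.ndarray
    lam: float


def _pspline_design(x: np.ndarray, n_basis: int):
    """Cubic B-spline design matrix on uniformly extended knots covering x.

    Uniform knot spacing (including the extension beyond the data range)
    makes the basis reproduce polynomials up to degree 3 on [min x, max x]
    and puts all linear functions in the second-difference penalty's null
    space.
    """
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        hi = lo + 1.0
    n_seg = n_basis - 3
    h = (hi - lo) / n_seg
    knots = lo + h * np.arange(-3, n_seg + 4)
    # extrapolate=True tolerates the last knot landing one ulp below max(x)
    basis = BSpline.design_matrix(np.clip(x, lo, hi), knots, 3,
                                  extrapolate=True).toarray()
    return basis, knots


def smooth_marker_vs_nnd(x, y, lam: float | None = None, n_basis: int = 40,
                         n_grid: int = 100) -> SmoothCurve:
    """Penalized cubic-spline fit of y against x (GAM-style smoothing).

    Minimises ||y - B a||^2 + lam * ||D2 a||^2 where B is a cubic B-spline
    basis and D2 the second-difference operator on its coefficients.  With
    ``lam=None`` the weight is selected by generalized cross-validation over
    a log-spaced grid.  Returns fitted values on an ``n_grid``-point uniform
    grid spanning [min x, max x].  Requires at least 20 points; below that a
    raw scatter is the honest display.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise TampolError("smooth_marker_vs_nnd: x and y lengths differ")
    if x.size < 20:
        raise TampolError("smooth_marker_vs_nnd: need >= 20 points; "
                          "plot the raw scatter instead")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise TampolError("smooth_marker_vs_nnd: x and y must be finite")

    n_basis = min(n_basis, max(6, x.size - 1))
    basis, knots = _pspline_design(x, n_basis)
    m = basis.shape[1]
    d2 = np.diff(np.eye(m), n=2, axis=0)
    btb = basis.T @ basis
    bty = basis.T @ y
    penalty = d2.T @ d2

    def fit(l):
        return solve(btb + l * penalty, bty, assume_a="pos")

    if lam is None:
        best = (np.inf, 1.0, None)
        n = x.size
        for l in np.logspace(-4, 8, 49):
            try:
                coef = fit(l)
            except np.linalg.LinAlgError:
                continue
            resid = y - basis @ coef
            # effective dof = tr(B (B'B + l P)^-1 B') = tr((B'B + l P)^-1 B'B)
            edof = np.trace(solve(btb + l * penalty, btb, assume_a="pos"))
            denom = max(n - edof, 1e-8)
            gcv = n * float(resid @ resid) / denom**2
            if gcv < best[0]:
                best = (gcv, l, coef)
        lam, coef = best[1], best[2]
        if coef is None:
            raise TampolError("smooth_marker_vs_nnd: GCV failed to fit any penalty")
    else:
        coef = fit(float(lam))

    grid = np.linspace(x.min(), x.max(), n_grid)
    spline = BSpline(knots, coef, 3, extrapolate=True)
    return SmoothCurve(grid_x=grid, fitted_y=spline(grid), lam=float(lam))


def marker_distance_curves(nnd: pd.DataFrame, lam: float | None = None,
                           min_points: int = 20) -> pd.DataFrame:
    """Smoothed scaled-intensity-vs-NND curve per polarisation marker.

    Returns a long DataFrame (marker, grid_x, fitted_y, lam); markers with
    fewer than ``min_points`` finite records are omitted.
    """
    frames = []
    ok = nnd.dropna(subset=["nnd_um"])
    for m in POLARISATION_MARKERS:
        col = f"z_{m}"
        if col not in ok.columns or len(ok) < min_points:
            continue
        curve = smooth_marker_vs_nnd(ok["nnd_um"].to_numpy(), ok[col].to_numpy(), lam=lam)
        frames.append(pd.DataFrame({"marker": m, "grid_x": curve.grid_x,
                                    "fitted_y": curve.fitted_y, "lam": curve.lam}))
    if not frames:
        return pd.DataFrame(columns=["marker", "grid_x", "fitted_y", "lam"])
    return pd.concat(frames, ignore_index=True)
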