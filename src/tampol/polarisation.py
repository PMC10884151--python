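"""Macrophage polarisation scoring and quartile M1/M2 classification.

Each macrophage gets a polarisation index built from rank-based percentile
scores of its four polarisation markers,

    index = (s_CD86 + s_HLADR) - (s_CD163 + s_MRC1),

where s_m is the percentile score of marker m's staining intensity across the
pooled macrophage population.  The index lies in [-200, 200]; under the
default orientation a high index (M1 markers dominant) is M1-like.  The
pooled index distribution is cut at its quartiles: cells in one extreme
quartile are M1-like, the opposite extreme quartile M2-like, and the middle
two quartiles "mixed" (excluded from downstream density work).

Because scores are rank-based, the index is invariant to any strictly
monotone transform of a single marker's raw intensities.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cell_model import CoreTable, cells_frame
from .errors import TampolError

log = logging.getLogger(__name__)

M1_MARKERS = ("CD86", "HLADR")
M2_MARKERS = ("CD163", "MRC1")
POLARISATION_MARKERS = M1_MARKERS + M2_MARKERS

ORIENTATIONS = ("index_high_is_M1", "paper_literal")


@dataclass
class QuartileCutoffs:
    """25th/50th/75th percentiles of the pooled polarisation-index distribution."""

    q1: float
    q2: float
    q3: float

    def __post_init__(self):
        if not (self.q1 <= self.q2 <= self.q3):
            raise TampolError("quartile cutoffs must be non-decreasing")


def percentile_scores(values) -> np.ndarray:
    """Convert raw values to percentile scores in [0, 100].

    Uses the symmetric convention score_i = (rank_i - 0.5) / n * 100 with
    average ranks for ties, so scores are bounded away from 0 and 100 and
    the mean score is always exactly 50.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise TampolError("percentile_scores: empty input")
    if not np.all(np.isfinite(values)):
        raise TampolError("percentile_scores: values must be finite")
    ranks = rankdata(values, method="average")
    return (ranks - 0.5) / values.size * 100.0


def polarisation_index(s_cd86, s_hladr, s_cd163, s_mrc1):
    """(s_CD86 + s_HLADR) - (s_CD163 + s_MRC1), scores in [0, 100] each."""
    arrs = [np.asarray(a, dtype=float) for a in (s_cd86, s_hladr, s_cd163, s_mrc1)]
    for a in arrs:
        if np.any((a < 0) | (a > 100) | ~np.isfinite(a)):
            raise TampolError("polarisation_index: percentile scores must lie in [0, 100]")
    return (arrs[0] + arrs[1]) - (arrs[2] + arrs[3])


def quartile_cutoffs(indices) -> QuartileCutoffs:
    """Empirical 25/50/75 percentiles (linear interpolation) of pooled indices."""
    indices = np.asarray(indices, dtype=float)
    if indices.size < 4:
        raise TampolError("quartile_cutoffs: need at least 4 indices")
    q1, q2, q3 = np.percentile(indices, [25, 50, 75], method="linear")
    return QuartileCutoffs(float(q1), float(q2), float(q3))


def assign_quartiles(indices, cutoffs: QuartileCutoffs) -> np.ndarray:
    """Quartile label per index with half-open bins (-inf,q1], (q1,q2], (q2,q3], (q3,inf)."""
    indices = np.asarray(indices, dtype=float)
    out = np.full(indices.shape, "Q4", dtype=object)
    out[indices <= cutoffs.q3] = "Q3"
    out[indices <= cutoffs.q2] = "Q2"
    out[indices <= cutoffs.q1] = "Q1"
    return out


def classify_macrophages(indices, cutoffs: QuartileCutoffs,
                         orientation: str = "index_high_is_M1") -> np.ndarray:
    """Classify macrophages as M1 / mixed / M2 from quartiles of the pooled index.

    Default orientation follows the index's semantics: the top quartile
    (M1-marker-dominant, index > q3) is M1-like and the bottom quartile
    (index <= q1) is M2-like.  ``paper_literal`` reverses the assignment
    (lowest quartile M1-like).  Mixed-type cells (middle quartiles) are
    excluded from downstream density analyses.

    Degenerate input with q1 == q3 (no extreme quartile exists) labels every
    cell mixed and logs a warning.
    """
    if orientation not in ORIENTATIONS:
        raise TampolError(f"unknown orientation {orientation!r}; choose from {ORIENTATIONS}")
    indices = np.asarray(indices, dtype=float)
    klass = np.full(indices.shape, "mixed", dtype=object)
    if cutoffs.q1 == cutoffs.q3:
        log.warning("classify_macrophages: degenerate index distribution "
                    "(q1 == q3); labelling all %d cells mixed", indices.size)
        return klass
    high, low = ("M1", "M2") if orientation == "index_high_is_M1" else ("M2", "M1")
    klass[indices > cutoffs.q3] = high
    klass[indices <= cutoffs.q1] = low
    return klass


def score_macrophages(cores: list[CoreTable] | pd.DataFrame,
                      orientation: str = "index_high_is_M1",
                      population: str = "macrophage") -> pd.DataFrame:
    """Full scoring pipeline: percentile scores, index, quartile, class.

    ``population`` selects the cells over which percentiles and quartiles are
    pooled: "macrophage" (default; CD68+ macrophages only, matching the
    marker panel's intent) or "all" (every detected cell, with only
    macrophages classified).

    Returns a DataFrame with columns cell_id, s_CD86, s_HLADR, s_CD163,
    s_MRC1, index, quartile, klass — one row per macrophage.
    """
    df = cells_frame(cores) if not isinstance(cores, pd.DataFrame) else cores
    if population == "macrophage":
        pool = df[df["phenotype"] == "macrophage"]
    elif population == "all":
        pool = df
    else:
        raise TampolError(f"unknown population {population!r}")
    if pool.empty:
        raise TampolError("score_macrophages: no cells in scoring population")

    scores = {m: percentile_scores(pool[m].to_numpy()) for m in POLARISATION_MARKERS}
    index = polarisation_index(scores["CD86"], scores["HLADR"],
                               scores["CD163"], scores["MRC1"])
    out = pd.DataFrame({
        "cell_id": pool["cell_id"].to_numpy(),
        "s_CD86": scores["CD86"], "s_HLADR": scores["HLADR"],
        "s_CD163": scores["CD163"], "s_MRC1": scores["MRC1"],
        "index": index,
    })
    cutoffs = quartile_cutoffs(index)
    out["quartile"] = assign_quartiles(index, cutoffs)
    out["klass"] = classify_macrophages(index, cutoffs, orientation)
    if population == "all":
        is_mac = (pool["phenotype"] == "macrophage").to_numpy()
        out = out.loc[is_mac].reset_index(drop=True)
    return out
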