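"""Per-case macrophage densities, M1:M2 ratios, and intratumoural heterogeneity.

Densities are counts per compartment area (cells/mm^2), computed per core and
summarised per sample for each region (tumour centre / invasive margin) and
compartment (epithelium / stroma).  Two summaries are supported: the
unweighted mean of per-core densities (default, "average density per case")
and area-weighted pooling (sum of counts / sum of areas).

The M1:M2 density ratio uses an explicit +inf sentinel when the M2 density
is zero but M1 is not — zero denominators do occur in sparse compartments and
the sentinel keeps low/high ordering well defined — and is missing (NaN) when
both densities are zero.  The integrative polarisation score is the ratio of
the pooled M1 density to the pooled M2 density over all regions and
compartments of a sample.  Intratumoural heterogeneity is the sample
standard deviation (n-1) of per-core densities over all usable cores of a
sample (tumour centre and invasive margin pooled), per compartment and class;
it is missing for samples with fewer than two usable cores.

Mixed-type macrophages count towards "all_macrophages" densities but never
towards M1/M2 densities or ratios.
"""
from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .cell_model import COMPARTMENTS, CoreTable, REGIONS, cells_frame
from .errors import TampolError

log = logging.getLogger(__name__)

DENSITY_METHODS = ("mean_of_cores", "pooled")
KLASSES = ("M1", "M2", "all_macrophages")

_REGION_SHORT = {"tumour_centre": "TC", "invasive_margin": "IM"}
_COMP_SHORT = {"epithelium": "epi", "stroma": "stroma"}


def compartment_density(n_cells: int, area_mm2: float) -> float:
    """Density of one compartment of one core: count / area (cells/mm^2)."""
    if area_mm2 <= 0:
        raise TampolError(f"compartment_density: area must be positive, got {area_mm2}")
    if n_cells < 0:
        raise TampolError("compartment_density: negative count")
    return n_cells / area_mm2


def case_region_density(counts, areas, method: str = "mean_of_cores") -> float:
    """Per-case density over the usable cores of one sample x region.

    ``mean_of_cores`` is the unweighted mean of per-core densities;
    ``pooled`` is sum(counts)/sum(areas).  Cores with non-positive area are
    unusable; with no usable core the value is missing (NaN) and logged.
    """
    if method not in DENSITY_METHODS:
        raise TampolError(f"unknown density method {method!r}")
    counts = np.asarray(counts, dtype=float)
    areas = np.asarray(areas, dtype=float)
    usable = areas > 0
    if not usable.any():
        log.info("case_region_density: no usable core, value missing")
        return float("nan")
    counts, areas = counts[usable], areas[usable]
    if method == "mean_of_cores":
        return float(np.mean(counts / areas))
    return float(counts.sum() / areas.sum())


def m1_m2_ratio(d_m1: float, d_m2: float) -> float:
    """M1:M2 density ratio with +inf sentinel (d_M2=0 < d_M1) and NaN (both 0)."""
    if d_m1 < 0 or d_m2 < 0:
        raise TampolError("m1_m2_ratio: densities must be non-negative")
    if d_m2 > 0:
        return d_m1 / d_m2
    if d_m1 > 0:
        return math.inf
    return float("nan")


def integrative_polarisation_score(counts_m1, counts_m2, areas) -> float:
    """Whole-tumour M1:M2 ratio pooling counts and areas over all compartments.

    ``counts_m1``, ``counts_m2`` and ``areas`` are aligned sequences over the
    usable core x compartment units of one sample (epithelium and stroma of
    tumour centre and invasive margin).  Equals pooled M1 density / pooled M2
    density; since the same total area appears in both pooled densities this
    reduces to sum(counts_m1)/sum(counts_m2), with the same sentinel
    conventions as :func:`m1_m2_ratio`.
    """
    areas = np.asarray(areas, dtype=float)
    usable = areas > 0
    if not usable.any():
        return float("nan")
    total_area = areas[usable].sum()
    d1 = np.asarray(counts_m1, dtype=float)[usable].sum() / total_area
    d2 = np.asarray(counts_m2, dtype=float)[usable].sum() / total_area
    return m1_m2_ratio(d1, d2)


def heterogeneity_sd(densities) -> float:
    """Sample SD (n-1 divisor) of per-core densities; NaN with < 2 cores."""
    densities = np.asarray(densities, dtype=float)
    densities = densities[np.isfinite(densities)]
    if densities.size < 2:
        return float("nan")
    return float(np.std(densities, ddof=1))


# ---------------------------------------------------------------------------
# Profile construction


def _core_unit_table(cores: list[CoreTable], polar: pd.DataFrame) -> pd.DataFrame:
    """One row per core x compartment with areas and M1/M2/all macrophage counts."""
    cells = cells_frame(cores)
    if len(polar):
        cells = cells.merge(polar[["cell_id", "klass"]], on="cell_id", how="left")
    else:
        cells = cells.assign(klass=np.nan)
    macs = cells[cells["phenotype"] == "macrophage"]

    rows = []
    for core in cores:
        sub = macs[macs["core_id"] == core.core_id]
        for comp in COMPARTMENTS:
            area = core.area_epithelium_mm2 if comp == "epithelium" else core.area_stroma_mm2
            in_comp = sub[sub["compartment"] == comp]
            rows.append({
                "core_id": core.core_id, "sample_id": core.sample_id,
                "patient_id": core.patient_id, "region": core.region,
                "compartment": comp, "area_mm2": area,
                "n_M1": int((in_comp["klass"] == "M1").sum()),
                "n_M2": int((in_comp["klass"] == "M2").sum()),
                "n_all_macrophages": int(len(in_comp)),
            })
    return pd.DataFrame(rows)


def build_density_profiles(cores: list[CoreTable], polar: pd.DataFrame,
                           method: str = "mean_of_cores") -> pd.DataFrame:
    """Per-sample density profile (wide format), one row per sample.

    Columns: d_{TC|IM}_{epi|stroma}_{M1|M2|all_macrophages} densities,
    ratio_{TC|IM}_{epi|stroma}, integrative_score, and
    sd_{epi|stroma}_{M1|M2} heterogeneity SDs.  ``polar`` is the output of
    :func:`tampol.polarisation.score_macrophages`; only QC-passed cores
    should be supplied.
    """
    if method not in DENSITY_METHODS:
        raise TampolError(f"unknown density method {method!r}")
    units = _core_unit_table(cores, polar)
    if units.empty:
        return pd.DataFrame()

    profiles = []
    for sample_id, su in units.groupby("sample_id", sort=True):
        row: dict[str, object] = {"sample_id": sample_id,
                                  "patient_id": su["patient_id"].iloc[0]}
        dens: dict[tuple[str, str, str], float] = {}
        for region in REGIONS:
            for comp in COMPARTMENTS:
                u = su[(su["region"] == region) & (su["compartment"] == comp)]
                for klass in KLASSES:
                    d = case_region_density(u[f"n_{klass}"].to_numpy(),
                                            u["area_mm2"].to_numpy(), method)
                    dens[(region, comp, klass)] = d
                    row[f"d_{_REGION_SHORT[region]}_{_COMP_SHORT[comp]}_{klass}"] = d
                d1 = dens[(region, comp, "M1")]
                d2 = dens[(region, comp, "M2")]
                key = f"ratio_{_REGION_SHORT[region]}_{_COMP_SHORT[comp]}"
                row[key] = (float("nan") if (math.isnan(d1) or math.isnan(d2))
                            else m1_m2_ratio(d1, d2))
        row["integrative_score"] = integrative_polarisation_score(
            su["n_M1"].to_numpy(), su["n_M2"].to_numpy(), su["area_mm2"].to_numpy())
        for comp in COMPARTMENTS:
            u = su[(su["compartment"] == comp) & (su["area_mm2"] > 0)]
            for klass in ("M1", "M2"):
                d = u[f"n_{klass}"].to_numpy() / u["area_mm2"].to_numpy() if len(u) else []
                row[f"sd_{_COMP_SHORT[comp]}_{klass}"] = heterogeneity_sd(d)
        profiles.append(row)
    return pd.DataFrame(profiles)


def long_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Long-format alternative: sample_id, measure, value."""
    value_cols = [c for c in profiles.columns if c not in ("sample_id", "patient_id")]
    return profiles.melt(id_vars=["sample_id"], value_vars=value_cols,
                         var_name="measure", value_name="value")
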