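"""Synthetic multiplex-IHC cohort generator.

Emulates the data structure the analysis assumes so every downstream stage
is testable without patient data: ~1-mm TMA cores with an epithelial /
stromal segmentation, phenotype-specific cell densities of realistic
magnitude (hundreds of cells per mm^2, macrophages predominantly stromal),
class-conditional lognormal marker intensities producing an M1 / mixed / M2
structure, class-dependent macrophage-tumour-cell attraction, and
exponential proportional-hazards survival linked to a planted patient-level
feature.  Every planted quantity (per-cell polarisation class, per-patient
linear predictor, true log hazard ratios) is recorded as ground truth.

The generative model, in order:

1. *Geometry* — each core is a disc (default 1 mm diameter); the epithelial
   compartment is a union of random discs clipped to the core, grown until
   its polygonal area matches the configured epithelium fraction to within
   0.5%; the stroma is the remainder.
2. *Cells* — a homogeneous Poisson point process per phenotype x
   compartment with configurable intensity (cells/mm^2).
3. *Polarisation classes* — macrophages draw a planted class from the
   sample-kind-specific mixture (metastases are configured more M2-rich than
   primaries); macrophages are then displaced towards their nearest tumour
   cell by a class-specific exponential step (M1 strongest), after which
   compartment labels are re-derived from the final coordinates.
4. *Markers* — lognormal intensities conditional on phenotype and planted
   class: planted M1 cells high CD86/HLADR, planted M2 cells high
   CD163/MRC1, mixed intermediate; CD68 high in macrophages, KRT high in
   tumour cells, background elsewhere.
5. *Survival* — exponential proportional hazards on a planted binary
   patient feature ("m2_rich", which also shifts that patient's metastasis
   class mixture towards M2), with uniform administrative censoring.

Randomness comes from one integer seed; sub-streams are derived with fixed
key order (seed, stream, patient, sample, region, core) so that adding
patients never perturbs earlier ones.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import Point
from shapely.ops import unary_union

from .cell_model import (
    COMPARTMENTS, CellRecord, CoreTable, MARKERS, PHENOTYPES, QC_FLAGS, REGIONS,
    SAMPLE_KINDS, SampleInfo, SurvivalRecord, SYNCHRONOUS_DFI_DAYS,
    write_cell_table, write_clinical_table,
)
from .errors import GenerationError

PLANTED_CLASSES = ("M1", "mixed", "M2")

_REGION_SHORT = {"tumour_centre": "TC", "invasive_margin": "IM"}


def default_intensity_map() -> dict:
    """Poisson intensities (cells/mm^2) per (phenotype, compartment, region, sample_kind).

    Magnitudes chosen to put overall macrophage core densities in the
    observed regime (several hundred cells/mm^2, higher in the invasive
    margin than the tumour centre, slightly lower in primaries than in
    metastases), tumour cells concentrated in the epithelium, and stroma
    dominated by non-tumour cells.
    """
    base = {
        ("macrophage", "epithelium", "tumour_centre"): 250.0,
        ("macrophage", "stroma", "tumour_centre"): 700.0,
        ("macrophage", "epithelium", "invasive_margin"): 350.0,
        ("macrophage", "stroma", "invasive_margin"): 900.0,
        ("tumour", "epithelium", "tumour_centre"): 1400.0,
        ("tumour", "stroma", "tumour_centre"): 80.0,
        ("tumour", "epithelium", "invasive_margin"): 1400.0,
        ("tumour", "stroma", "invasive_margin"): 80.0,
        ("other", "epithelium", "tumour_centre"): 400.0,
        ("other", "stroma", "tumour_centre"): 600.0,
        ("other", "epithelium", "invasive_margin"): 400.0,
        ("other", "stroma", "invasive_margin"): 600.0,
    }
    out = {}
    for (phen, comp, region), rate in base.items():
        for kind in SAMPLE_KINDS:
            # primaries carry modestly fewer macrophages than metastases
            mult = 0.85 if (kind == "primary_tumour" and phen == "macrophage") else 1.0
            out[(phen, comp, region, kind)] = rate * mult
    return out


def default_marker_model() -> dict:
    """Lognormal (log-mean, log-sd) parameters per planted class and marker."""
    return {
        "M1": {"CD86": (4.0, 0.5), "HLADR": (4.0, 0.5),
               "CD163": (2.0, 0.5), "MRC1": (2.0, 0.5)},
        "mixed": {"CD86": (3.0, 0.5), "HLADR": (3.0, 0.5),
                  "CD163": (3.0, 0.5), "MRC1": (3.0, 0.5)},
        "M2": {"CD86": (2.0, 0.5), "HLADR": (2.0, 0.5),
               "CD163": (4.0, 0.5), "MRC1": (4.0, 0.5)},
        "CD68_macrophage": (4.5, 0.4),
        "KRT_tumour": (5.0, 0.4),
        "background": (1.0, 0.6),
    }


@dataclass
class SurvivalModel:
    """Exponential proportional-hazards survival with uniform censoring."""

    baseline_rate_per_day: float = 4.5e-4
    log_hr_m2_rich: float = math.log(2.0)
    censor_low_days: float = 365.0
    censor_high_days: float = 2920.0


@dataclass
class SimConfig:
    """Full configuration of the synthetic cohort generator."""

    n_patients: int = 74
    cores_per_region: int = 2
    core_diameter_mm: float = 1.0
    epithelium_fraction: dict = field(default_factory=lambda: {
        "tumour_centre": 0.45, "invasive_margin": 0.30})
    cell_intensity_per_mm2: dict = field(default_factory=default_intensity_map)
    class_mix: dict = field(default_factory=lambda: {
        "primary_tumour": (0.30, 0.45, 0.25),
        "first_metastasis": (0.20, 0.45, 0.35),
        "re_metastasectomy": (0.20, 0.45, 0.35)})
    marker_model: dict = field(default_factory=default_marker_model)
    attraction_um: dict = field(default_factory=lambda: {
        "M1": 25.0, "mixed": 12.0, "M2": 5.0})
    m2_rich_shift: float = 0.10
    qc_fail_prob: float = 0.05
    survival_model: SurvivalModel = field(default_factory=SurvivalModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise GenerationError("n_patients must be >= 1")
        for region, frac in self.epithelium_fraction.items():
            if not 0 < frac < 1:
                raise GenerationError(
                    f"epithelium_fraction[{region}] must lie in (0, 1), got {frac}")
        for kind, mix in self.class_mix.items():
            if abs(sum(mix) - 1.0) > 1e-9 or any(p < 0 for p in mix):
                raise GenerationError(f"class_mix[{kind}] must be a distribution")
        if any(v < 0 for v in self.cell_intensity_per_mm2.values()):
            raise GenerationError("cell intensities must be >= 0")
        if self.survival_model.baseline_rate_per_day <= 0:
            raise GenerationError("baseline hazard must be positive")


@dataclass
class CoreGeometry:
    """Generated core geometry with exact polygonal compartment areas."""

    region: str
    core: object  # shapely Polygon, µm coordinates, origin at bbox top-left
    epithelium: object  # shapely geometry (may be multi-part)
    area_epithelium_mm2: float
    area_stroma_mm2: float


@dataclass
class SyntheticCohort:
    """A generated cohort with its ground truth."""

    cores: list[CoreTable]
    samples: list[SampleInfo]
    clinical: list[SurvivalRecord]
    truth_cells: pd.DataFrame  # cell_id, planted_class
    truth_patients: pd.DataFrame  # patient_id, m2_rich, linear_predictor
    true_log_hrs: dict

    def to_csv(self, outdir) -> None:
        """Write the cohort in the published CSV schemas plus truth tables."""
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cell_table(self.cores, outdir / "cells.csv", outdir / "areas.csv")
        write_clinical_table(self.clinical, outdir / "clinical.csv")
        pd.DataFrame([{"sample_id": s.sample_id, "patient_id": s.patient_id,
                       "sample_kind": s.sample_kind} for s in self.samples]) \
            .to_csv(outdir / "samples.csv", index=False)
        self.truth_cells.to_csv(outdir / "truth_cells.csv", index=False)
        self.truth_patients.to_csv(outdir / "truth_patients.csv", index=False,
                                   float_format="%.6f")


# ---------------------------------------------------------------------------
# Geometry


def _uniform_points_in(geom, n: int, rng) -> np.ndarray:
    """n points uniform in a shapely geometry, by rejection from its bbox."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = geom.bounds
    pts = np.empty((0, 2))
    while len(pts) < n:
        m = max(4 * (n - len(pts)), 64)
        x = rng.uniform(minx, maxx, m)
        y = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(geom, x, y)
        pts = np.vstack([pts, np.column_stack([x[keep], y[keep]])])
    return pts[:n]


def generate_core_geometry(config: SimConfig, rng, region: str) -> CoreGeometry:
    """Disc core with an epithelial blob region hitting the configured fraction.

    The epithelium is grown as a union of random discs clipped to the core;
    the final disc's radius is bisected so the polygonal epithelial area
    matches fraction x core area to within 0.5%.  Reported areas are the
    exact measures of the generated polygons and sum to the core disc area.
    """
    frac = config.epithelium_fraction[region]
    if not 0 < frac < 1:
        raise GenerationError(f"epithelium_fraction must lie in (0,1), got {frac}")
    r_um = config.core_diameter_mm * 500.0
    core = Point(r_um, r_um).buffer(r_um, quad_segs=64)
    target = frac * core.area

    epi = None
    for _ in range(1000):
        centre = _uniform_points_in(core, 1, rng)[0]
        radius = rng.uniform(0.15, 0.35) * r_um
        disc = Point(centre).buffer(radius, quad_segs=32)
        cand = disc if epi is None else unary_union([epi, disc])
        cand = cand.intersection(core)
        if cand.area < target:
            epi = cand
            continue
        # bisect the last disc's radius to land on the target area
        lo, hi = 0.0, radius
        for _ in range(50):
            mid = (lo + hi) / 2
            disc = Point(centre).buffer(mid, quad_segs=32)
            trial = disc if epi is None else unary_union([epi, disc])
            trial = trial.intersection(core)
            if trial.area > target:
                hi = mid
            else:
                lo = mid
            if abs(trial.area - target) / target <= 0.002:
                break
        epi = trial
        break
    else:
        raise GenerationError(
            f"could not reach epithelium_fraction={frac} in 1000 proposal rounds")
    if epi is None or abs(epi.area - target) / target > 0.005:
        raise GenerationError("epithelium area missed its target fraction")
    return CoreGeometry(
        region=region, core=core, epithelium=epi,
        area_epithelium_mm2=epi.area / 1e6,
        area_stroma_mm2=(core.area - epi.area) / 1e6,
    )


# ---------------------------------------------------------------------------
# Cells and markers


def sample_cells(geometry: CoreGeometry, config: SimConfig, rng,
                 sample_kind: str) -> pd.DataFrame:
    """Homogeneous Poisson cells per phenotype x compartment for one core.

    Expected count in a compartment is intensity x compartment area; each
    cell's compartment label matches the sub-region containing its
    coordinates.  Returns columns x_um, y_um, phenotype, compartment.
    """
    stroma = geometry.core.difference(geometry.epithelium)
    geoms = {"epithelium": geometry.epithelium, "stroma": stroma}
    areas = {"epithelium": geometry.area_epithelium_mm2,
             "stroma": geometry.area_stroma_mm2}
    rows = []
    for phen in PHENOTYPES:
        for comp in COMPARTMENTS:
            rate = config.cell_intensity_per_mm2.get(
                (phen, comp, geometry.region, sample_kind), 0.0)
            if not math.isfinite(rate):
                raise GenerationError(f"non-finite intensity for {phen}/{comp}")
            n = int(rng.poisson(rate * areas[comp]))
            pts = _uniform_points_in(geoms[comp], n, rng)
            for x, y in pts:
                rows.append((x, y, phen, comp))
    df = pd.DataFrame(rows, columns=["x_um", "y_um", "phenotype", "compartment"])
    return df


def _apply_attraction(cells: pd.DataFrame, planted: np.ndarray,
                      geometry: CoreGeometry, config: SimConfig, rng) -> pd.DataFrame:
    """Displace macrophages towards their nearest tumour cell, by class.

    Step length is exponential with the class-specific scale (µm), truncated
    at 95% of the current distance so macrophages approach but do not overlap
    their target.  Compartment labels are re-derived afterwards.
    """
    from scipy.spatial import cKDTree

    mac = cells["phenotype"] == "macrophage"
    tum = cells["phenotype"] == "tumour"
    if not mac.any() or not tum.any():
        return cells
    scales = np.array([config.attraction_um.get(k, 0.0) for k in planted])
    if not (scales > 0).any():
        return cells
    mac_xy = cells.loc[mac, ["x_um", "y_um"]].to_numpy()
    tum_xy = cells.loc[tum, ["x_um", "y_um"]].to_numpy()
    d, j = cKDTree(tum_xy).query(mac_xy, k=1)
    step = rng.exponential(np.maximum(scales, 1e-12))
    step = np.minimum(step, 0.95 * d)
    step[scales <= 0] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(d[:, None] > 0, (tum_xy[j] - mac_xy) / d[:, None], 0.0)
    new_xy = mac_xy + unit * step[:, None]
    cells = cells.copy()
    cells.loc[mac, "x_um"] = new_xy[:, 0]
    cells.loc[mac, "y_um"] = new_xy[:, 1]
    in_epi = shapely.contains_xy(geometry.epithelium,
                                 cells["x_um"].to_numpy(), cells["y_um"].to_numpy())
    cells["compartment"] = np.where(in_epi, "epithelium", "stroma")
    return cells


def assign_planted_classes(n: int, mix, rng) -> np.ndarray:
    """Draw planted polarisation classes from the (M1, mixed, M2) mixture."""
    return rng.choice(np.array(PLANTED_CLASSES, dtype=object), size=n, p=list(mix))


def assign_marker_intensities(cells: pd.DataFrame, planted: np.ndarray,
                              config: SimConfig, rng) -> pd.DataFrame:
    """Lognormal class-conditional marker intensities for every cell.

    Macrophages draw the four polarisation markers from their planted class's
    parameters and CD68 from the macrophage signal distribution; tumour cells
    draw high KRT; all other marker/phenotype combinations use the shared
    background distribution.  With zero log-sd every cell of a class gets
    exactly exp(log-mean).
    """
    mm = config.marker_model
    n = len(cells)
    out = cells.copy()
    phen = cells["phenotype"].to_numpy()
    mac = phen == "macrophage"
    tum = phen == "tumour"

    for marker in MARKERS:
        mu = np.full(n, mm["background"][0], dtype=float)
        sd = np.full(n, mm["background"][1], dtype=float)
        if marker == "CD68":
            mu[mac], sd[mac] = mm["CD68_macrophage"]
        elif marker == "KRT":
            mu[tum], sd[tum] = mm["KRT_tumour"]
        else:
            for klass in PLANTED_CLASSES:
                sel = mac & (planted == klass)
                mu[sel], sd[sel] = mm[klass][marker]
        out[marker] = np.exp(mu + sd * rng.standard_normal(n))
    return out


# ---------------------------------------------------------------------------
# Clinical covariates and survival


def simulate_clinical_covariates(n: int, rng) -> pd.DataFrame:
    """Patient covariates with realistic marginals for a metastasectomy cohort."""
    dfi = np.round(rng.exponential(500.0, n)).astype(int)
    return pd.DataFrame({
        "sex_male": rng.integers(0, 2, n),
        "age_years": np.round(rng.normal(67.0, 10.0, n), 1),
        "rcscs": rng.choice([1, 2, 3], size=n, p=[0.55, 0.25, 0.20]),
        "neoadjuvant": (rng.random(n) < 0.40).astype(int),
        "n_pulm_mets_dx": rng.choice([1, 2, 3], size=n, p=[0.60, 0.30, 0.10]),
        "former_liver_mets": (rng.random(n) < 0.43).astype(int),
        "dfi_days": dfi,
        "synchronous": (dfi <= SYNCHRONOUS_DFI_DAYS).astype(int),
        "r1_resection": (rng.random(n) < 0.057).astype(int),
    })


def simulate_survival(linear_predictor, model: SurvivalModel, rng):
    """Exponential proportional-hazards times with uniform censoring.

    Event time T_i ~ Exp(rate * exp(lp_i)); censoring C_i ~ Uniform(low,
    high).  Returns (time_days int >= 0, event bool).  A non-finite
    censoring window observes every event.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if model.baseline_rate_per_day <= 0:
        raise GenerationError("baseline hazard must be positive")
    rate = model.baseline_rate_per_day * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if math.isfinite(model.censor_high_days):
        c = rng.uniform(model.censor_low_days, model.censor_high_days, lp.size)
    else:
        c = np.full(lp.size, np.inf)
    event = t_event <= c
    time_days = np.where(event, t_event, c)
    return np.maximum(np.round(time_days), 0).astype(int), event


def simulate_cox_cohort(n: int, true_log_hr: float, rng,
                        model: SurvivalModel | None = None) -> pd.DataFrame:
    """Patient-level cohort for hazard-recovery experiments.

    A Bernoulli(0.5) binary exposure carries the (only) true log hazard
    ratio; the seven standard adjustment covariates are simulated
    independently of outcome, so they act as pure noise in the fit.
    """
    model = model or SurvivalModel()
    cov = simulate_clinical_covariates(n, rng)
    cov["exposure"] = rng.integers(0, 2, n)
    t, e = simulate_survival(cov["exposure"].to_numpy() * true_log_hr, model, rng)
    cov["time_days"] = t
    cov["event"] = e.astype(int)
    cov["rcscs_ge2"] = (cov["rcscs"] >= 2).astype(int)
    cov["n_mets_ge2"] = (cov["n_pulm_mets_dx"] >= 2).astype(int)
    return cov


# ---------------------------------------------------------------------------
# Cohort assembly


def _sample_class_mix(config: SimConfig, kind: str, m2_rich: bool):
    mix = list(config.class_mix[kind])
    if m2_rich and kind != "primary_tumour":
        shift = min(config.m2_rich_shift, mix[0])
        mix = [mix[0] - shift, mix[1], mix[2] + shift]
    return mix


def _core_rng(seed: int, p: int, s: int, r: int, k: int):
    return np.random.default_rng([seed, 2, p, s, r, k])


def generate_cohort(config: SimConfig | None = None) -> SyntheticCohort:
    """Generate a full cohort: cores, cells, markers, clinical outcomes, truth.

    Deterministic given the config (including its seed).  Each patient
    contributes a primary tumour and a first metastasis sample, each sampled
    with ``cores_per_region`` cores in both the tumour centre and the
    invasive margin.
    """
    config = config or SimConfig()
    config.validate()
    seed = int(config.seed)

    cores: list[CoreTable] = []
    samples: list[SampleInfo] = []
    clinical: list[SurvivalRecord] = []
    truth_cells: list[tuple[str, str]] = []
    truth_patients = []

    kinds = ("primary_tumour", "first_metastasis")
    sm = config.survival_model

    for p in range(config.n_patients):
        patient_id = f"P{p:03d}"
        crng = np.random.default_rng([seed, 1, p])
        cov = simulate_clinical_covariates(1, crng).iloc[0]
        m2_rich = bool(crng.integers(0, 2))
        lp = sm.log_hr_m2_rich * m2_rich
        time_days, event = simulate_survival([lp], sm, crng)
        clinical.append(SurvivalRecord(
            patient_id=patient_id,
            sex="male" if cov["sex_male"] else "female",
            age_years=float(cov["age_years"]), rcscs=int(cov["rcscs"]),
            neoadjuvant=bool(cov["neoadjuvant"]),
            n_pulm_mets_dx=int(cov["n_pulm_mets_dx"]),
            former_liver_mets=bool(cov["former_liver_mets"]),
            synchronous=bool(cov["synchronous"]), dfi_days=int(cov["dfi_days"]),
            r1_resection=bool(cov["r1_resection"]),
            time_days=int(time_days[0]), event=bool(event[0]),
        ))
        truth_patients.append({"patient_id": patient_id, "m2_rich": int(m2_rich),
                               "linear_predictor": lp})

        for s, kind in enumerate(kinds):
            suffix = "PT" if kind == "primary_tumour" else "MET"
            sample_id = f"{patient_id}_{suffix}"
            samples.append(SampleInfo(sample_id=sample_id, patient_id=patient_id,
                                      sample_kind=kind))
            mix = _sample_class_mix(config, kind, m2_rich)
            for r, region in enumerate(REGIONS):
                for k in range(config.cores_per_region):
                    rng = _core_rng(seed, p, s, r, k)
                    core_id = f"{sample_id}_{_REGION_SHORT[region]}{k}"
                    qc = "ok"
                    if rng.random() < config.qc_fail_prob:
                        qc = str(rng.choice(QC_FLAGS[1:]))
                    geom = generate_core_geometry(config, rng, region)
                    cells = sample_cells(geom, config, rng, kind)
                    mac_mask = (cells["phenotype"] == "macrophage").to_numpy()
                    planted = assign_planted_classes(int(mac_mask.sum()), mix, rng)
                    cells = _apply_attraction(cells, planted, geom, config, rng)
                    cells = assign_marker_intensities(
                        cells, _expand(planted, mac_mask), config, rng)

                    records = []
                    mac_i = 0
                    for i, row in enumerate(cells.itertuples(index=False)):
                        cell_id = f"{core_id}_c{i:05d}"
                        records.append(CellRecord(
                            cell_id=cell_id, core_id=core_id,
                            x_um=float(row.x_um), y_um=float(row.y_um),
                            phenotype=row.phenotype, compartment=row.compartment,
                            intensity={m: float(getattr(row, m)) for m in MARKERS},
                        ))
                        if mac_mask[i]:
                            truth_cells.append((cell_id, planted[mac_i]))
                            mac_i += 1
                    cores.append(CoreTable(
                        core_id=core_id, sample_id=sample_id, patient_id=patient_id,
                        region=region, qc=qc,
                        area_epithelium_mm2=geom.area_epithelium_mm2,
                        area_stroma_mm2=geom.area_stroma_mm2, cells=records))

    return SyntheticCohort(
        cores=cores, samples=samples, clinical=clinical,
        truth_cells=pd.DataFrame(truth_cells, columns=["cell_id", "planted_class"]),
        truth_patients=pd.DataFrame(truth_patients),
        true_log_hrs={"m2_rich": sm.log_hr_m2_rich},
    )


def _expand(planted: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Scatter per-macrophage classes onto the full cell table (None elsewhere)."""
    out = np.full(mask.size, None, dtype=object)
    out[mask] = planted
    return out


# ---------------------------------------------------------------------------
# YAML config round-trip


def _key_str(key: tuple) -> str:
    return "|".join(key)


def config_to_dict(config: SimConfig) -> dict:
    d = {
        "n_patients": config.n_patients,
        "cores_per_region": config.cores_per_region,
        "core_diameter_mm": config.core_diameter_mm,
        "epithelium_fraction": dict(config.epithelium_fraction),
        "cell_intensity_per_mm2": {_key_str(k): float(v)
                                   for k, v in config.cell_intensity_per_mm2.items()},
        "class_mix": {k: list(v) for k, v in config.class_mix.items()},
        "marker_model": {k: ({m: list(p) for m, p in v.items()}
                             if isinstance(v, dict) else list(v))
                         for k, v in config.marker_model.items()},
        "attraction_um": dict(config.attraction_um),
        "m2_rich_shift": config.m2_rich_shift,
        "qc_fail_prob": config.qc_fail_prob,
        "survival_model": {
            "baseline_rate_per_day": config.survival_model.baseline_rate_per_day,
            "log_hr_m2_rich": config.survival_model.log_hr_m2_rich,
            "censor_low_days": config.survival_model.censor_low_days,
            "censor_high_days": config.survival_model.censor_high_days,
        },
        "seed": config.seed,
    }
    return d


def config_from_dict(d: dict) -> SimConfig:
    kwargs = dict(d)
    if "cell_intensity_per_mm2" in kwargs:
        kwargs["cell_intensity_per_mm2"] = {
            tuple(k.split("|")): float(v)
            for k, v in kwargs["cell_intensity_per_mm2"].items()}
    if "class_mix" in kwargs:
        kwargs["class_mix"] = {k: tuple(v) for k, v in kwargs["class_mix"].items()}
    if "marker_model" in kwargs:
        kwargs["marker_model"] = {
            k: ({m: tuple(p) for m, p in v.items()} if isinstance(v, dict)
                else tuple(v))
            for k, v in kwargs["marker_model"].items()}
    if "survival_model" in kwargs and isinstance(kwargs["survival_model"], dict):
        kwargs["survival_model"] = SurvivalModel(**kwargs["survival_model"])
    return SimConfig(**kwargs)


def config_to_yaml(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def config_from_yaml(path) -> SimConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
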