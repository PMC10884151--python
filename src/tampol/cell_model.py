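"""Domain types and CSV I/O for single-cell multiplex-IHC tissue-microarray data.

The unit of analysis is a 1-mm TMA core: a disc of tissue segmented into a
tumour-epithelium and a stroma compartment, with every detected cell carrying
core-local coordinates (micrometres, origin at the top-left of the core
bounding box, y increasing downward), a phenotype (macrophage / tumour /
other) and one staining intensity per marker.  Six markers are carried:
CD68 (pan-macrophage), CD86 and HLADR (M1-type), CD163 and MRC1 (M2-type),
and KRT (tumour epithelium).

All tables are plain UTF-8 CSV with "." decimals; numeric fields are written
with 6 decimal places and "NA" encodes a missing value.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

log = logging.getLogger(__name__)

MARKERS = ("CD68", "CD86", "HLADR", "CD163", "MRC1", "KRT")
PHENOTYPES = ("macrophage", "tumour", "other")
COMPARTMENTS = ("epithelium", "stroma")
REGIONS = ("tumour_centre", "invasive_margin")
QC_FLAGS = ("ok", "folded_or_detached", "minimal_tumour", "necrotic")
SAMPLE_KINDS = ("primary_tumour", "first_metastasis", "re_metastasectomy")

#: DFI threshold (days) operationalising "synchronous within 6 months".
SYNCHRONOUS_DFI_DAYS = 183

#: Nominal area of a 1-mm-diameter core, mm^2.
CORE_AREA_MM2 = math.pi * 0.5**2

#: Tolerance (mm^2) allowed on area_epithelium + area_stroma <= disc area.
AREA_TOLERANCE_MM2 = 0.02

#: Column order of the published cell CSV schema.
CELL_CSV_COLUMNS = (
    "core_id", "sample_id", "patient_id", "region", "qc", "cell_id",
    "x_um", "y_um", "phenotype", "compartment",
    "CD68", "CD86", "HLADR", "CD163", "MRC1", "KRT",
)

AREA_CSV_COLUMNS = ("core_id", "area_epithelium_mm2", "area_stroma_mm2")

CLINICAL_CSV_COLUMNS = (
    "patient_id", "sex", "age_years", "rcscs", "neoadjuvant",
    "n_pulm_mets_dx", "former_liver_mets", "synchronous", "dfi_days",
    "r1_resection", "time_days", "event",
)


@dataclass
class CellRecord:
    """One detected cell with coordinates, phenotype, compartment and markers."""

    cell_id: str
    core_id: str
    x_um: float
    y_um: float
    phenotype: str
    compartment: str
    intensity: dict[str, float]

    def validate(self, row: int | None = None) -> None:
        where = f" (row {row})" if row is not None else ""
        if not (math.isfinite(self.x_um) and math.isfinite(self.y_um)):
            raise SchemaError(f"non-finite coordinates for cell {self.cell_id}{where}")
        if self.phenotype not in PHENOTYPES:
            raise SchemaError(f"unknown phenotype {self.phenotype!r} for cell {self.cell_id}{where}")
        if self.compartment not in COMPARTMENTS:
            raise SchemaError(f"unknown compartment {self.compartment!r} for cell {self.cell_id}{where}")
        if set(self.intensity) != set(MARKERS):
            raise SchemaError(f"cell {self.cell_id}{where}: markers must be exactly {MARKERS}")
        for m, v in self.intensity.items():
            if not math.isfinite(v) or v < 0:
                raise SchemaError(f"cell {self.cell_id}{where}: intensity {m}={v} must be finite and >= 0")


@dataclass
class CoreTable:
    """All cells of one TMA core plus geometry, areas and QC status."""

    core_id: str
    sample_id: str
    patient_id: str
    region: str
    qc: str
    area_epithelium_mm2: float
    area_stroma_mm2: float
    cells: list[CellRecord] = field(default_factory=list)

    def validate(self) -> None:
        if self.region not in REGIONS:
            raise SchemaError(f"core {self.core_id}: unknown region {self.region!r}")
        if self.qc not in QC_FLAGS:
            raise SchemaError(f"core {self.core_id}: unknown qc flag {self.qc!r}")
        if self.area_epithelium_mm2 < 0 or self.area_stroma_mm2 < 0:
            raise SchemaError(f"core {self.core_id}: negative compartment area")
        total = self.area_epithelium_mm2 + self.area_stroma_mm2
        if total > CORE_AREA_MM2 + AREA_TOLERANCE_MM2:
            raise SchemaError(
                f"core {self.core_id}: compartment areas sum to {total:.4f} mm^2, "
                f"exceeding a 1-mm core ({CORE_AREA_MM2:.4f} mm^2)"
            )
        for i, cell in enumerate(self.cells):
            if cell.core_id != self.core_id:
                raise SchemaError(f"core {self.core_id}: cell {cell.cell_id} has core_id {cell.core_id}")
            cell.validate(row=i)

    @property
    def area_total_mm2(self) -> float:
        return self.area_epithelium_mm2 + self.area_stroma_mm2


@dataclass
class SampleInfo:
    """One tissue sample (primary tumour, first metastasis, or re-metastasectomy)."""

    sample_id: str
    patient_id: str
    sample_kind: str

    def validate(self) -> None:
        if self.sample_kind not in SAMPLE_KINDS:
            raise SchemaError(f"sample {self.sample_id}: unknown sample_kind {self.sample_kind!r}")


@dataclass
class SurvivalRecord:
    """Per-patient covariates and right-censored all-cause survival.

    ``time_days`` counts from first pulmonary metastasectomy; ``event`` is
    death from any cause.  ``synchronous`` must agree with the disease-free
    interval: DFI <= 183 days defines a synchronous metastasis.
    """

    patient_id: str
    sex: str  # "female" / "male"
    age_years: float
    rcscs: int
    neoadjuvant: bool
    n_pulm_mets_dx: int
    former_liver_mets: bool
    synchronous: bool
    dfi_days: int
    r1_resection: bool
    time_days: int
    event: bool

    def validate(self) -> None:
        if self.sex not in ("female", "male"):
            raise SchemaError(f"patient {self.patient_id}: sex must be female/male")
        if self.rcscs < 1:
            raise SchemaError(f"patient {self.patient_id}: rcscs must be >= 1")
        if self.n_pulm_mets_dx < 1:
            raise SchemaError(f"patient {self.patient_id}: n_pulm_mets_dx must be >= 1")
        if self.dfi_days < 0 or self.time_days < 0:
            raise SchemaError(f"patient {self.patient_id}: negative duration")
        if self.synchronous != (self.dfi_days <= SYNCHRONOUS_DFI_DAYS):
            raise SchemaError(
                f"patient {self.patient_id}: synchronous flag inconsistent with "
                f"dfi_days={self.dfi_days} (threshold {SYNCHRONOUS_DFI_DAYS} days)"
            )


# ---------------------------------------------------------------------------
# CSV I/O


def _require_columns(df: pd.DataFrame, expected: tuple[str, ...], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_cell_table(path, areas_path=None) -> list[CoreTable]:
    """Read a cell CSV (and optional per-core area CSV) into validated CoreTables.

    Row order is preserved within each core; cores appear in order of first
    occurrence.  When ``areas_path`` is omitted both compartment areas are
    set to 0 (densities cannot be computed until areas are supplied).
    """
    df = pd.read_csv(path, dtype={"core_id": str, "sample_id": str, "patient_id": str,
                                  "cell_id": str}, na_values=["NA"], keep_default_na=False)
    _require_columns(df, CELL_CSV_COLUMNS, path)

    areas: dict[str, tuple[float, float]] = {}
    if areas_path is not None:
        adf = pd.read_csv(areas_path, dtype={"core_id": str}, na_values=["NA"],
                          keep_default_na=False)
        _require_columns(adf, AREA_CSV_COLUMNS, areas_path)
        for _, r in adf.iterrows():
            areas[r["core_id"]] = (float(r["area_epithelium_mm2"]), float(r["area_stroma_mm2"]))

    cores: dict[str, CoreTable] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        cid = row.core_id
        if cid not in cores:
            a_epi, a_str = areas.get(cid, (0.0, 0.0))
            cores[cid] = CoreTable(
                core_id=cid, sample_id=row.sample_id, patient_id=row.patient_id,
                region=row.region, qc=row.qc,
                area_epithelium_mm2=a_epi, area_stroma_mm2=a_str,
            )
        try:
            intensity = {m: float(getattr(row, m)) for m in MARKERS}
            cell = CellRecord(
                cell_id=row.cell_id, core_id=cid,
                x_um=float(row.x_um), y_um=float(row.y_um),
                phenotype=row.phenotype, compartment=row.compartment,
                intensity=intensity,
            )
            cell.validate(row=i)
        except (ValueError, SchemaError) as exc:
            raise SchemaError(f"{path} row {i}: {exc}") from exc
        cores[cid].cells.append(cell)

    out = list(cores.values())
    for core in out:
        core.validate()
    return out


def write_cell_table(cores: list[CoreTable], path, areas_path=None) -> None:
    """Write CoreTables in the published cell CSV schema (6-decimal numerics).

    ``read_cell_table(write_cell_table(...))`` is the identity on values at
    the declared precision.  Cores without cells contribute no rows to the
    cell CSV (they still appear in the area CSV when one is written).
    """
    rows = []
    for core in cores:
        core.validate()
        for cell in core.cells:
            rows.append({
                "core_id": core.core_id, "sample_id": core.sample_id,
                "patient_id": core.patient_id, "region": core.region, "qc": core.qc,
                "cell_id": cell.cell_id, "x_um": cell.x_um, "y_um": cell.y_um,
                "phenotype": cell.phenotype, "compartment": cell.compartment,
                **{m: cell.intensity[m] for m in MARKERS},
            })
    df = pd.DataFrame(rows, columns=list(CELL_CSV_COLUMNS))
    df.to_csv(path, index=False, float_format="%.6f", na_rep="NA")

    if areas_path is not None:
        adf = pd.DataFrame(
            [{"core_id": c.core_id,
              "area_epithelium_mm2": c.area_epithelium_mm2,
              "area_stroma_mm2": c.area_stroma_mm2} for c in cores],
            columns=list(AREA_CSV_COLUMNS))
        adf.to_csv(areas_path, index=False, float_format="%.6f", na_rep="NA")


def filter_cores(cores: list[CoreTable]) -> list[CoreTable]:
    """Keep only cores that passed visual QC (qc == "ok").

    Cores folded or detached during processing, containing minimal tumour, or
    necrotic are dropped; the count excluded per reason is logged.  Surviving
    CoreTables are returned unmodified (pure selection).
    """
    excluded = Counter(c.qc for c in cores if c.qc != "ok")
    for reason, n in sorted(excluded.items()):
        log.info("filter_cores: excluded %d core(s) with qc=%s", n, reason)
    return [c for c in cores if c.qc == "ok"]


# ---------------------------------------------------------------------------
# Clinical table I/O


def read_clinical_table(path) -> list[SurvivalRecord]:
    """Read the per-patient clinical/outcome CSV into validated SurvivalRecords."""
    df = pd.read_csv(path, dtype={"patient_id": str}, na_values=["NA"],
                     keep_default_na=False)
    _require_columns(df, CLINICAL_CSV_COLUMNS, path)
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            rec = SurvivalRecord(
                patient_id=row.patient_id, sex=row.sex,
                age_years=float(row.age_years), rcscs=int(row.rcscs),
                neoadjuvant=bool(int(row.neoadjuvant)),
                n_pulm_mets_dx=int(row.n_pulm_mets_dx),
                former_liver_mets=bool(int(row.former_liver_mets)),
                synchronous=bool(int(row.synchronous)), dfi_days=int(row.dfi_days),
                r1_resection=bool(int(row.r1_resection)),
                time_days=int(row.time_days), event=bool(int(row.event)),
            )
            rec.validate()
        except (ValueError, SchemaError) as exc:
            raise SchemaError(f"{path} row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_clinical_table(records: list[SurvivalRecord], path) -> None:
    rows = []
    for r in records:
        r.validate()
        rows.append({
            "patient_id": r.patient_id, "sex": r.sex, "age_years": r.age_years,
            "rcscs": r.rcscs, "neoadjuvant": int(r.neoadjuvant),
            "n_pulm_mets_dx": r.n_pulm_mets_dx,
            "former_liver_mets": int(r.former_liver_mets),
            "synchronous": int(r.synchronous), "dfi_days": r.dfi_days,
            "r1_resection": int(r.r1_resection), "time_days": r.time_days,
            "event": int(r.event),
        })
    df = pd.DataFrame(rows, columns=list(CLINICAL_CSV_COLUMNS))
    df.to_csv(path, index=False, float_format="%.6f", na_rep="NA")


def clinical_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    """Per-patient DataFrame with numeric covariate codings used downstream."""
    return pd.DataFrame({
        "patient_id": [r.patient_id for r in records],
        "sex_male": [int(r.sex == "male") for r in records],
        "age_years": [r.age_years for r in records],
        "rcscs_ge2": [int(r.rcscs >= 2) for r in records],
        "neoadjuvant": [int(r.neoadjuvant) for r in records],
        "n_mets_ge2": [int(r.n_pulm_mets_dx >= 2) for r in records],
        "former_liver_mets": [int(r.former_liver_mets) for r in records],
        "synchronous": [int(r.synchronous) for r in records],
        "r1_resection": [int(r.r1_resection) for r in records],
        "time_days": [r.time_days for r in records],
        "event": [int(r.event) for r in records],
    })


def cells_frame(cores: list[CoreTable]) -> pd.DataFrame:
    """Flatten CoreTables into one row-per-cell DataFrame (cell CSV layout)."""
    rows = []
    for core in cores:
        for cell in core.cells:
            rows.append((core.core_id, core.sample_id, core.patient_id, core.region,
                         core.qc, cell.cell_id, cell.x_um, cell.y_um, cell.phenotype,
                         cell.compartment, *(cell.intensity[m] for m in MARKERS)))
    return pd.DataFrame(rows, columns=list(CELL_CSV_COLUMNS))


def areas_frame(cores: list[CoreTable]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.core_id, c.sample_id, c.patient_id, c.region, c.qc,
          c.area_epithelium_mm2, c.area_stroma_mm2) for c in cores],
        columns=["core_id", "sample_id", "patient_id", "region", "qc",
                 "area_epithelium_mm2", "area_stroma_mm2"])
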