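"""End-to-end orchestration: simulate -> polarise -> densities -> spatial ->
survive -> report.

Each stage reads and writes flat CSV/JSON artifacts in the output directory,
so any stage can be re-run in isolation from its persisted inputs and the
whole bundle is inspectable with a text editor.  Given the same
configuration (including the seed) two runs produce byte-identical bundles.
"""
from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cell_model, density, polarisation, spatial, survival
from .errors import ConfigError, StageError
from .synthetic import SimConfig, config_from_dict, config_to_dict, generate_cohort

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6f"

#: Exposure measures analysed for survival, mirroring a densities-by-
#: region/compartment hazard table plus the whole-tumour score and
#: heterogeneity SDs.
DEFAULT_EXPOSURES = tuple(
    f"d_{r}_{c}_{k}" for r in ("TC", "IM") for c in ("epi", "stroma")
    for k in ("M1", "M2")
) + tuple(
    f"ratio_{r}_{c}" for r in ("TC", "IM") for c in ("epi", "stroma")
) + ("integrative_score",) + tuple(
    f"sd_{c}_{k}" for c in ("epi", "stroma") for k in ("M1", "M2")
)

PAIRED_MEASURES = tuple(
    f"d_{r}_{c}_{k}" for r in ("TC", "IM") for c in ("epi", "stroma")
    for k in ("M1", "M2")
) + tuple(f"ratio_{r}_{c}" for r in ("TC", "IM") for c in ("epi", "stroma"))


@dataclass
class PipelineConfig:
    """One configuration object for the whole pipeline.

    Exactly one of ``sim`` (synthetic mode) or ``paths`` (real-data mode;
    keys cells, areas, clinical and optionally samples) must be set.
    """

    outdir: str = "tampol_out"
    seed: int = 0
    sim: SimConfig | None = None
    paths: dict | None = None
    orientation: str = "index_high_is_M1"
    density_method: str = "mean_of_cores"
    horizon_days: int = survival.FIVE_YEARS_DAYS
    exposures: tuple = DEFAULT_EXPOSURES
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.sim is None) == (self.paths is None):
            raise ConfigError("exactly one of sim (synthetic) or paths (real data) "
                              "must be configured")
        if self.orientation not in polarisation.ORIENTATIONS:
            raise ConfigError(f"unknown orientation {self.orientation!r}")
        if self.density_method not in density.DENSITY_METHODS:
            raise ConfigError(f"unknown density method {self.density_method!r}")
        if self.paths is not None:
            for key in ("cells", "areas", "clinical"):
                if key not in self.paths:
                    raise ConfigError(f"real-data mode needs a {key!r} path")
                if not Path(self.paths[key]).exists():
                    raise ConfigError(f"{key} file not found: {self.paths[key]}")

    def config_hash(self) -> str:
        payload = {
            "outdir": "", "seed": self.seed,
            "sim": config_to_dict(self.sim) if self.sim else None,
            "paths": {k: str(v) for k, v in (self.paths or {}).items()} or None,
            "orientation": self.orientation, "density_method": self.density_method,
            "horizon_days": self.horizon_days, "exposures": list(self.exposures),
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def pipeline_config_from_yaml(path) -> PipelineConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if "sim" in d and d["sim"] is not None:
        d["sim"] = config_from_dict(d["sim"])
    if "exposures" in d:
        d["exposures"] = tuple(d["exposures"])
    try:
        return PipelineConfig(**d)
    except TypeError as exc:
        raise ConfigError(f"bad pipeline config: {exc}") from exc


# ---------------------------------------------------------------------------
# Stages (each runs from files, writes files)


def stage_simulate(sim: SimConfig, data_dir) -> None:
    cohort = generate_cohort(sim)
    cohort.to_csv(data_dir)


def stage_polarise(cells_csv, areas_csv, out_csv,
                   orientation: str = "index_high_is_M1") -> pd.DataFrame:
    cores = cell_model.filter_cores(cell_model.read_cell_table(cells_csv, areas_csv))
    polar = polarisation.score_macrophages(cores, orientation=orientation)
    polar.to_csv(out_csv, index=False, float_format=FLOAT_FORMAT)
    return polar


def stage_densities(cells_csv, areas_csv, polar_csv, out_csv,
                    method: str = "mean_of_cores",
                    samples_csv=None) -> pd.DataFrame:
    cores = cell_model.filter_cores(cell_model.read_cell_table(cells_csv, areas_csv))
    polar = pd.read_csv(polar_csv, dtype={"cell_id": str})
    profiles = density.build_density_profiles(cores, polar, method=method)
    if samples_csv is not None and Path(samples_csv).exists():
        samples = pd.read_csv(samples_csv, dtype=str)
        profiles = profiles.merge(samples[["sample_id", "sample_kind"]],
                                  on="sample_id", how="left")
    else:
        profiles["sample_kind"] = "first_metastasis"
    profiles.to_csv(out_csv, index=False, float_format=FLOAT_FORMAT)
    return profiles


def stage_spatial(cells_csv, areas_csv, polar_csv, nnd_csv, curves_csv,
                  target_phenotype: str = "tumour") -> pd.DataFrame:
    cores = cell_model.filter_cores(cell_model.read_cell_table(cells_csv, areas_csv))
    polar = pd.read_csv(polar_csv, dtype={"cell_id": str})
    nnd = spatial.nnd_table(cores, polar, target_phenotype=target_phenotype)
    nnd.to_csv(nnd_csv, index=False, float_format=FLOAT_FORMAT)
    curves = spatial.marker_distance_curves(nnd)
    curves.to_csv(curves_csv, index=False, float_format=FLOAT_FORMAT)
    return nnd


def _exposure_survival(values, clin: pd.DataFrame, horizon_days: int) -> dict:
    """ROC cutoff, KM, log-rank and Cox results for one continuous exposure."""
    d = clin.copy()
    d["exposure_value"] = np.asarray(values, dtype=float)
    d = d[~d["exposure_value"].isna()]
    label = survival.five_year_death_label(d["time_days"], d["event"])
    cut = survival.roc_youden_cutoff(d["exposure_value"], label)
    group = survival.dichotomise(d["exposure_value"], cut.cutoff)
    d["high"] = (group == "high").astype(int)

    out = {
        "cutoff": _j(cut.cutoff), "direction": cut.direction,
        "youden_j": round(cut.youden_j, 6),
        "n_low": int((d["high"] == 0).sum()), "n_high": int((d["high"] == 1).sum()),
    }
    groups = {}
    for name, sub in d.groupby("high"):
        _, surv_at = survival.km_estimate(sub["time_days"], sub["event"],
                                          horizon_days)
        groups["high" if name else "low"] = {
            "n": len(sub),
            "five_year_os_pct": round(100 * surv_at(horizon_days), 1),
        }
    out["km"] = groups
    chi2, p = survival.logrank_test(d["high"], d["time_days"], d["event"],
                                    horizon_days)
    out["logrank"] = {"chi2": round(chi2, 4), "p": round(p, 6)}
    for label_, covs in (("crude", ()), ("adjusted", survival.ADJUSTMENT_COVARIATES)):
        try:
            fit = survival.cox_ph(d, "high", covs, horizon_days=horizon_days)
            row = fit[fit["term"] == "high"].iloc[0]
            out[f"{label_}_hr"] = {
                "hr": round(float(row["hr"]), 4),
                "ci_low": round(float(row["ci_low"]), 4),
                "ci_high": round(float(row["ci_high"]), 4),
                "p": round(float(row["p"]), 6),
            }
        except Exception as exc:
            out[f"{label_}_hr"] = {"error": str(exc)}
    return out


def _j(x: float):
    """JSON-safe number (inf becomes the string 'inf')."""
    if isinstance(x, float) and not math.isfinite(x):
        return "inf" if x > 0 else "-inf"
    return round(float(x), 6)


def stage_survive(profiles_csv, clinical_csv, out_json, exposures=DEFAULT_EXPOSURES,
                  horizon_days: int = survival.FIVE_YEARS_DAYS) -> dict:
    profiles = pd.read_csv(profiles_csv, dtype={"sample_id": str, "patient_id": str})
    clinical = cell_model.clinical_frame(cell_model.read_clinical_table(clinical_csv))
    included, excl = survival.survival_exclusions(clinical)

    mets = profiles[profiles["sample_kind"] == "first_metastasis"]
    merged = included.merge(mets, on="patient_id", how="inner")

    report = {"n_patients": int(len(clinical)), "n_included": int(len(merged)),
              "exclusions": excl, "horizon_days": horizon_days, "exposures": {}}
    for measure in exposures:
        if measure not in merged.columns:
            report["exposures"][measure] = {"error": "measure missing from profiles"}
            continue
        try:
            report["exposures"][measure] = _exposure_survival(
                merged[measure], merged, horizon_days)
        except Exception as exc:
            report["exposures"][measure] = {"error": str(exc)}
    with open(out_json, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


# ---------------------------------------------------------------------------
# Report


def _fmt(x, nd=2):
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return "inf" if (isinstance(x, float) and x > 0) else "NA"
    return f"{x:.{nd}f}"


def _paired_rows(profiles: pd.DataFrame, measures) -> list[dict]:
    """Wilcoxon signed-rank comparisons of paired primary vs metastasis values."""
    prim = profiles[profiles["sample_kind"] == "primary_tumour"] \
        .set_index("patient_id")
    mets = profiles[profiles["sample_kind"] == "first_metastasis"] \
        .set_index("patient_id")
    common = prim.index.intersection(mets.index)
    rows = []
    for m in measures:
        if m not in profiles.columns:
            continue
        a = prim.loc[common, m].to_numpy(dtype=float)
        b = mets.loc[common, m].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        row = {"measure": m, "n_pairs": int(ok.sum()),
               "median_primary": float(np.nanmedian(a[ok])) if ok.any() else float("nan"),
               "median_metastasis": float(np.nanmedian(b[ok])) if ok.any() else float("nan")}
        try:
            _, p = survival.compare_groups(a[ok], b[ok], test="wilcoxon_signed_rank")
            row["p"] = p
        except Exception:
            row["p"] = float("nan")
        rows.append(row)
    return rows


def generate_report(outdir) -> str:
    """Regenerate report.md from the persisted bundle (idempotent).

    Missing stage artifacts produce an explicit "stage skipped" section
    instead of an error.
    """
    outdir = Path(outdir)
    lines = ["# Macrophage polarisation analysis report", ""]
    missing = []

    manifest_p = outdir / "manifest.json"
    if manifest_p.exists():
        manifest = json.loads(manifest_p.read_text())
        lines += [f"Seed: {manifest['seed']}  ",
                  f"Config hash: {manifest['config_hash']}  ",
                  f"Package version: {manifest['version']}", ""]

    polar_p = outdir / "polarisation.csv"
    if polar_p.exists():
        polar = pd.read_csv(polar_p)
        counts = polar["klass"].value_counts()
        n = len(polar)
        lines += ["## Macrophage polarisation", "",
                  f"{n} macrophages scored; class fractions: "
                  + ", ".join(f"{k} {counts.get(k, 0) / n:.3f}"
                              for k in ("M1", "mixed", "M2")), ""]
    else:
        missing.append("polarisation")

    prof_p = outdir / "profiles.csv"
    if prof_p.exists():
        profiles = pd.read_csv(prof_p, dtype={"sample_id": str, "patient_id": str})
        mets = profiles[profiles["sample_kind"] == "first_metastasis"]
        lines += ["## Densities (first metastases)", ""]
        for r, rn in (("TC", "tumour centre"), ("IM", "invasive margin")):
            cols = [f"d_{r}_epi_all_macrophages", f"d_{r}_stroma_all_macrophages"]
            if all(c in mets.columns for c in cols) and len(mets):
                epi = mets[cols[0]].median()
                st = mets[cols[1]].median()
                lines.append(f"- median macrophage density, {rn}: "
                             f"epithelium {_fmt(epi, 1)}, stroma {_fmt(st, 1)} cells/mm^2")
        for r in ("TC", "IM"):
            for c in ("epi", "stroma"):
                col = f"ratio_{r}_{c}"
                if col in mets.columns and len(mets):
                    vals = mets[col].replace([np.inf, -np.inf], np.nan).dropna()
                    lines.append(f"- median M1:M2 ratio {r}/{c}: "
                                 f"{_fmt(vals.median(), 2)}")
        lines.append("")
        rows = _paired_rows(profiles, PAIRED_MEASURES)
        if rows:
            lines += ["## Paired primary vs first metastasis "
                      "(Wilcoxon signed-rank)", "",
                      "| measure | n pairs | median primary | median metastasis | p |",
                      "|---|---|---|---|---|"]
            for row in rows:
                lines.append(
                    f"| {row['measure']} | {row['n_pairs']} "
                    f"| {_fmt(row['median_primary'])} "
                    f"| {_fmt(row['median_metastasis'])} "
                    f"| {_fmt(row['p'], 4)} |")
            lines.append("")
        sd_cols = [c for c in profiles.columns if c.startswith("sd_")]
        if sd_cols:
            rows = _paired_rows(profiles, sd_cols)
            lines += ["## Intratumoural heterogeneity (per-core density SDs)", "",
                      "| measure | n pairs | median primary | median metastasis | p |",
                      "|---|---|---|---|---|"]
            for row in rows:
                lines.append(
                    f"| {row['measure']} | {row['n_pairs']} "
                    f"| {_fmt(row['median_primary'])} "
                    f"| {_fmt(row['median_metastasis'])} "
                    f"| {_fmt(row['p'], 4)} |")
            lines.append("")
    else:
        missing.append("densities")

    nnd_p = outdir / "nnd.csv"
    if nnd_p.exists():
        nnd = pd.read_csv(nnd_p)
        m1 = spatial.median_nnd_by_class(nnd, "M1")
        m2 = spatial.median_nnd_by_class(nnd, "M2")
        pc = spatial.percent_closer(m1, m2)
        lines += ["## Spatial analysis (macrophage to nearest tumour cell)", "",
                  f"- median NND: M1-like {_fmt(m1, 1)} um, M2-like {_fmt(m2, 1)} um",
                  f"- M1-like macrophages are {_fmt(pc, 1)}% closer to tumour cells "
                  "than M2-like", ""]
    else:
        missing.append("spatial")

    surv_p = outdir / "survival.json"
    if surv_p.exists():
        surv = json.loads(surv_p.read_text())
        lines += ["## Survival analysis (5-year overall survival)", "",
                  f"Included {surv['n_included']} patients "
                  f"(exclusions: {surv['exclusions']})", "",
                  "| exposure | cutoff | 5y OS low | 5y OS high | log-rank p "
                  "| crude HR (95% CI) | adjusted HR (95% CI) |",
                  "|---|---|---|---|---|---|---|"]
        for name, e in sorted(surv["exposures"].items()):
            if "error" in e:
                lines.append(f"| {name} | — | — | — | — | {e['error']} | |")
                continue
            km = e.get("km", {})
            crude = e.get("crude_hr", {})
            adj = e.get("adjusted_hr", {})

            def hr_str(h):
                if "error" in h or "hr" not in h:
                    return "NA"
                return (f"{h['hr']:.2f} ({h['ci_low']:.2f}-{h['ci_high']:.2f}; "
                        f"p={h['p']:.3f})")

            lines.append(
                f"| {name} | {e['cutoff']} "
                f"| {km.get('low', {}).get('five_year_os_pct', 'NA')}% "
                f"| {km.get('high', {}).get('five_year_os_pct', 'NA')}% "
                f"| {_fmt(e['logrank']['p'], 4)} "
                f"| {hr_str(crude)} | {hr_str(adj)} |")
        lines.append("")
    else:
        missing.append("survival")

    if missing:
        lines += ["## Stages skipped", ""]
        lines += [f"- {m}: artifact not found" for m in missing]
        lines.append("")

    text = "\n".join(lines)
    (outdir / "report.md").write_text(text)
    return text


# ---------------------------------------------------------------------------
# Orchestration


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage, persisting artifacts under ``config.outdir``.

    Returns the output directory.  A failing stage aborts with a StageError
    naming the stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data_dir = outdir / "data"

    def _run(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    if config.sim is not None:
        sim = config.sim
        sim.seed = int(config.seed)
        _run("simulate", stage_simulate, sim, data_dir)
        paths = {"cells": data_dir / "cells.csv", "areas": data_dir / "areas.csv",
                 "clinical": data_dir / "clinical.csv",
                 "samples": data_dir / "samples.csv"}
    else:
        paths = {k: Path(v) for k, v in config.paths.items()}

    _run("polarise", stage_polarise, paths["cells"], paths["areas"],
         outdir / "polarisation.csv", orientation=config.orientation)
    _run("densities", stage_densities, paths["cells"], paths["areas"],
         outdir / "polarisation.csv", outdir / "profiles.csv",
         method=config.density_method, samples_csv=paths.get("samples"))
    _run("spatial", stage_spatial, paths["cells"], paths["areas"],
         outdir / "polarisation.csv", outdir / "nnd.csv", outdir / "curves.csv")
    _run("survive", stage_survive, outdir / "profiles.csv", paths["clinical"],
         outdir / "survival.json", exposures=config.exposures,
         horizon_days=config.horizon_days)

    manifest = {
        "seed": int(config.seed),
        "config_hash": config.config_hash(),
        "version": _pkg_version("tampol"),
        "artifacts": sorted(str(p.relative_to(outdir))
                            for p in outdir.rglob("*") if p.is_file()
                            and p.name not in ("manifest.json", "report.md")),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    _run("report", generate_report, outdir)
    return outdir
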