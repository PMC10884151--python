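"""Outcome statistics: ROC dichotomisation, Kaplan-Meier, log-rank, Cox models.

Survival is 5-year overall survival from first pulmonary metastasectomy
(all-cause death, administratively censored at 1826 days).  Patients with an
incomplete (R1) resection and patients who died within 30 post-operative
days are excluded before any survival analysis.

Continuous exposures (densities, M1:M2 ratios, heterogeneity SDs) are
dichotomised at the cutpoint maximising Youden's J on the ROC curve against
5-year all-cause mortality; values at or above the cutoff are "high".
Kaplan-Meier estimation, the two-group log-rank test and multivariable Cox
proportional-hazards regression (Efron tie handling, Wald 95% CIs) are
delegated to lifelines; group-comparison and correlation tests to scipy.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .errors import TampolError

log = logging.getLogger(__name__)

#: 5-year horizon in days used for KM curves and the ROC mortality label.
FIVE_YEARS_DAYS = 1826

#: Covariates of the adjusted Cox model (numeric codings of clinical_frame).
ADJUSTMENT_COVARIATES = ("sex_male", "age_years", "rcscs_ge2", "neoadjuvant",
                         "n_mets_ge2", "former_liver_mets", "synchronous")


def survival_exclusions(clinical: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the survival-analysis exclusions; returns (included, exclusion log).

    Removes R1-resected patients and patients deceased within 30
    post-operative days (event with time <= 30; early censoring is kept).
    """
    r1 = clinical["r1_resection"].astype(bool)
    death30 = clinical["event"].astype(bool) & (clinical["time_days"] <= 30)
    excl = {"r1_resection": int(r1.sum()),
            "death_within_30_days": int((death30 & ~r1).sum())}
    included = clinical[~(r1 | death30)].reset_index(drop=True)
    log.info("survival_exclusions: %s excluded, %d retained", excl, len(included))
    return included, excl


def five_year_death_label(time_days, event) -> np.ndarray:
    """Binary 5-year all-cause-mortality label for ROC cutoff selection.

    1 = died within the 5-year horizon; 0 otherwise (patients censored before
    the horizon count as survivors — a documented simplification).
    """
    time_days = np.asarray(time_days, dtype=float)
    event = np.asarray(event, dtype=bool)
    return (event & (time_days <= FIVE_YEARS_DAYS)).astype(int)


@dataclass
class CutoffResult:
    """ROC-derived dichotomisation cutpoint with its operating characteristics."""

    variable: str
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    direction: str  # "high" (value >= cutoff predicts death) or "low"


def roc_youden_cutoff(values, labels, variable: str = "") -> CutoffResult:
    """Cutpoint maximising Youden's J = sensitivity + specificity - 1.

    Candidate cutoffs are midpoints between adjacent sorted unique values;
    the rule "value >= cutoff predicts death" is scored against the binary
    mortality labels, ties broken towards the smallest cutoff.  +inf sentinel
    values (from zero-denominator ratios) rank above all finite values.  If
    the association runs the other way (J maximal for the reversed rule) the
    reported ``direction`` is "low"; sensitivity/specificity refer to the
    reported direction.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise TampolError("roc_youden_cutoff: need both outcome classes present")

    order = np.argsort(values, kind="stable")
    v, lab = values[order], labels[order]
    uniq = np.unique(v)
    if uniq.size < 2:
        raise TampolError("roc_youden_cutoff: all values identical")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    # midpoint with +inf stays +inf: the rule ">= inf" isolates sentinel values

    best = None  # (youden, cutoff, sens, spec, direction)
    for c in candidates:
        pred_high = values >= c
        tp = int((pred_high & (labels == 1)).sum())
        fp = int((pred_high & (labels == 0)).sum())
        sens_hi = tp / n_pos
        spec_hi = 1 - fp / n_neg
        for direction, sens, spec in (("high", sens_hi, spec_hi),
                                      ("low", 1 - sens_hi, 1 - spec_hi)):
            j = sens + spec - 1
            key = (round(j, 12), -c, direction == "high")
            if best is None or key > (round(best[0], 12), -best[1], best[4] == "high"):
                best = (j, float(c), sens, spec, direction)
    j, cutoff, sens, spec, direction = best
    return CutoffResult(variable=variable, cutoff=cutoff, sensitivity=sens,
                        specificity=spec, youden_j=j, direction=direction)


def dichotomise(values, cutoff: float) -> np.ndarray:
    """Two-tier low/high labels: value >= cutoff is "high"; NaN stays missing."""
    if not np.isfinite(cutoff) and not np.isposinf(cutoff):
        raise TampolError("dichotomise: cutoff must be finite or +inf")
    values = np.asarray(values, dtype=float)
    out = np.where(values >= cutoff, "high", "low").astype(object)
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        log.info("dichotomise: %d missing value(s) left unlabelled", n_missing)
        out[np.isnan(values)] = None
    return out


def apply_horizon(time_days, event, horizon_days: int = FIVE_YEARS_DAYS):
    """Administrative censoring at the analysis horizon."""
    t = np.asarray(time_days, dtype=float).copy()
    e = np.asarray(event, dtype=bool).copy()
    over = t > horizon_days
    e[over] = False
    t[over] = horizon_days
    return t, e


def km_estimate(time_days, event, horizon_days: int = FIVE_YEARS_DAYS):
    """Product-limit survival estimate up to the horizon.

    Returns (curve DataFrame with columns time, at_risk, events, survival;
    survival_at callable).  S(0) = 1 and the curve is non-increasing.
    """
    t, e = apply_horizon(time_days, event, horizon_days)
    if t.size == 0:
        raise TampolError("km_estimate: empty input")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    ev = kmf.event_table
    curve = pd.DataFrame({
        "time": ev.index.to_numpy(dtype=float),
        "at_risk": ev["at_risk"].to_numpy(dtype=int),
        "events": ev["observed"].to_numpy(dtype=int),
        "survival": kmf.survival_function_["KM_estimate"].to_numpy(dtype=float),
    })

    def survival_at(q: float) -> float:
        return float(kmf.predict(min(float(q), float(horizon_days))))

    return curve, survival_at


def logrank_test(groups, time_days, event,
                 horizon_days: int = FIVE_YEARS_DAYS) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    groups = np.asarray(groups)
    t, e = apply_horizon(time_days, event, horizon_days)
    labels = pd.unique(groups[pd.notna(groups)])
    if len(labels) != 2:
        raise TampolError(f"logrank_test: need exactly 2 groups, got {len(labels)}")
    if not e.any():
        raise TampolError("logrank_test: no events")
    a = groups == labels[0]
    b = groups == labels[1]
    res = _ll_logrank(t[a], t[b], event_observed_A=e[a], event_observed_B=e[b])
    return float(res.test_statistic), float(res.p_value)


def cox_ph(data: pd.DataFrame, exposure: str, covariates=(),
           duration_col: str = "time_days", event_col: str = "event",
           horizon_days: int | None = None) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties, Wald 95% CIs).

    ``exposure`` and ``covariates`` name numeric columns of ``data``; a
    binary low/high exposure should be coded 0/1 beforehand.  Returns one row
    per model term with columns hr, ci_low, ci_high, p, coef, se.  Constant
    columns raise; fewer than 10 events logs a warning.  Non-convergence or
    separation surfaces as a flagged error with lifelines' diagnostics.
    """
    cols = [exposure, *covariates]
    df = data[[duration_col, event_col, *cols]].dropna().copy()
    for c in cols:
        if df[c].nunique() < 2:
            raise TampolError(f"cox_ph: covariate {c!r} is constant")
    n_events = int(df[event_col].sum())
    if n_events < 10:
        log.warning("cox_ph: only %d events; estimates may be unstable", n_events)
    if horizon_days is not None:
        t, e = apply_horizon(df[duration_col], df[event_col], horizon_days)
        df[duration_col], df[event_col] = t, e.astype(int)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(df, duration_col=duration_col, event_col=event_col,
                    fit_options={"precision": 1e-9, "max_steps": 500})
        for w in caught:
            log.info("cox_ph: %s", str(w.message).strip().splitlines()[0])
    except Exception as exc:  # lifelines raises several convergence errors
        raise TampolError(f"cox_ph: fit failed ({exc})") from exc
    s = cph.summary
    out = pd.DataFrame({
        "term": s.index,
        "hr": s["exp(coef)"].to_numpy(),
        "ci_low": s["exp(coef) lower 95%"].to_numpy(),
        "ci_high": s["exp(coef) upper 95%"].to_numpy(),
        "p": s["p"].to_numpy(),
        "coef": s["coef"].to_numpy(),
        "se": s["se(coef)"].to_numpy(),
    }).reset_index(drop=True)
    out.attrs["n_included"] = len(df)
    out.attrs["n_events"] = n_events
    return out


def compare_groups(x, y=None, test: str = "mann_whitney",
                   paired: bool = False) -> tuple[float, float]:
    """Two-sided group-comparison / correlation tests used in the reports.

    ``test`` is one of chi_square, fisher (x is a 2x2 contingency table),
    t_test, mann_whitney (x, y independent samples),
    wilcoxon_signed_rank (x, y paired samples), spearman (x, y paired
    measurements).  Returns (statistic, p).  Degenerate inputs (all-tied
    signed ranks, low expected counts for chi-square) raise with a pointer
    to the appropriate alternative.
    """
    if test == "chi_square":
        table = np.asarray(x)
        chi2, p, _, expected = stats.chi2_contingency(table)
        if (expected < 1).any():
            raise TampolError("chi_square: expected count < 1; use fisher")
        return float(chi2), float(p)
    if test == "fisher":
        odds, p = stats.fisher_exact(np.asarray(x), alternative="two-sided")
        return float(odds), float(p)
    if y is None:
        raise TampolError(f"compare_groups: test {test!r} needs two samples")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if test == "t_test":
        r = stats.ttest_ind(x, y)
    elif test == "mann_whitney":
        r = stats.mannwhitneyu(x, y, alternative="two-sided")
    elif test == "wilcoxon_signed_rank":
        if len(x) != len(y):
            raise TampolError("wilcoxon_signed_rank: paired samples must align")
        if np.all(x == y):
            raise TampolError("wilcoxon_signed_rank: all paired differences are "
                              "zero; the test is undefined")
        r = stats.wilcoxon(x, y)
    elif test == "spearman":
        r = stats.spearmanr(x, y)
        return float(r.statistic), float(r.pvalue)
    else:
        raise TampolError(f"compare_groups: unknown test {test!r}")
    return float(r.statistic), float(r.pvalue)
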