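"""ROC cutoffs, Kaplan-Meier, log-rank, Cox regression, group tests."""
import math

import numpy as np
import pandas as pd
import pytest

from tampol.errors import TampolError
from tampol.survival import (
    compare_groups, cox_ph, dichotomise, five_year_death_label, km_estimate,
    logrank_test, roc_youden_cutoff, survival_exclusions,
)
from tampol.synthetic import SurvivalModel, simulate_survival


def brute_force_youden(values, labels):
    """Independent exhaustive enumeration over midpoint thresholds, both directions."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, int)
    uniq = np.unique(values)
    best = (-np.inf, None, None)
    for c in (uniq[:-1] + uniq[1:]) / 2:
        for direction in ("high", "low"):
            pred = values >= c if direction == "high" else values < c
            sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
            spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
            j = sens + spec - 1
            if j > best[0] + 1e-12:
                best = (j, c, direction)
    return best


def _clin(rows):
    return pd.DataFrame(rows, columns=["patient_id", "r1_resection", "time_days", "event"])


def test_exclusion_rules_and_boundaries():
    df = _clin([("a", 1, 400, 1),   # R1 -> out
                ("b", 0, 30, 1),    # death at day 30 -> out
                ("c", 0, 31, 1),    # death at day 31 -> stays
                ("d", 0, 10, 0),    # censored early -> stays
                ("e", 0, 900, 0)])
    kept, excl = survival_exclusions(df)
    assert list(kept["patient_id"]) == ["c", "d", "e"]
    assert excl == {"r1_resection": 1, "death_within_30_days": 1}
    # predicate oracle on a random cohort
    rng = np.random.default_rng(0)
    rand = _clin([(str(i), rng.integers(0, 2), rng.integers(0, 200),
                   rng.integers(0, 2)) for i in range(200)])
    kept, _ = survival_exclusions(rand)
    oracle = [not (r or (e and t <= 30)) for r, t, e in
              zip(rand["r1_resection"], rand["time_days"], rand["event"])]
    assert list(kept["patient_id"]) == list(rand.loc[oracle, "patient_id"])


def test_youden_cutoff_separable_case():
    cut = roc_youden_cutoff([1, 2, 3, 4], [0, 0, 1, 1])
    assert cut.cutoff == 2.5 and cut.youden_j == 1.0 and cut.direction == "high"
    assert cut.sensitivity == 1.0 and cut.specificity == 1.0


def test_youden_reports_reversed_direction():
    cut = roc_youden_cutoff([4, 3, 2, 1], [1, 1, 0, 0])
    assert cut.youden_j == 1.0 and cut.direction == "high"
    cut = roc_youden_cutoff([1, 2, 3, 4], [1, 1, 0, 0])
    assert cut.youden_j == 1.0 and cut.direction == "low"


def test_youden_handles_inf_sentinel():
    cut = roc_youden_cutoff([1.0, 2.0, math.inf, math.inf], [0, 0, 1, 1])
    assert cut.youden_j == 1.0


def test_youden_matches_enumeration_oracle(rng):
    for _ in range(25):
        n = int(rng.integers(6, 40))
        values = rng.choice([1.0, 2.5, 3.0, 7.0, 9.5], size=n)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max() or np.unique(values).size < 2:
            continue
        j, _, _ = brute_force_youden(values, labels)
        cut = roc_youden_cutoff(values, labels)
        assert cut.youden_j == pytest.approx(j, abs=1e-12)


def test_dichotomise_boundary_and_missing():
    out = dichotomise([1.0, 2.0, 2.0, 3.0, np.nan], 2.0)
    assert list(out[:4]) == ["low", "high", "high", "high"]
    assert out[4] is None


def test_km_uncensored_equals_empirical_survivor():
    curve, s_at = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
    assert s_at(2) == pytest.approx(0.5)
    assert s_at(4) == pytest.approx(0.0)
    assert curve["survival"].iloc[0] == 1.0


def test_km_all_censored_is_one():
    _, s_at = km_estimate([100, 200, 300], [0, 0, 0])
    assert s_at(300) == 1.0


def test_km_matches_hand_product_limit():
    # times 1,2,3,4,5,6; events 1,1,0,1,0,1
    _, s_at = km_estimate([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1])
    assert s_at(1) == pytest.approx(5 / 6)
    assert s_at(2) == pytest.approx(5 / 6 * 4 / 5)
    assert s_at(4) == pytest.approx(2 / 3 * 2 / 3)
    assert s_at(6) == pytest.approx(0.0)


def test_logrank_duplicated_groups_is_zero():
    t = [5, 10, 15, 20, 30]
    e = [1, 0, 1, 1, 0]
    chi2, p = logrank_test(np.repeat([0, 1], 5), t + t, e + e)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_matches_hand_computation():
    """Hand O-E oracle: groups A=(1+,3+),B=(2+,4) (+ = event)."""
    times = [1, 3, 2, 4]
    events = [1, 1, 1, 1]
    groups = ["A", "A", "B", "B"]
    # event at t=1: risk 4 (2A), A observed 1, E_A=0.5, V=0.25
    # event at t=2: risk 3 (1A), B observed,   E_A=1/3, V=2/9
    # event at t=3: risk 2 (1A), A observed 1, E_A=0.5, V=0.25
    # event at t=4: risk 1 (0A), B observed,   E_A=0,   V=0
    o_minus_e = (1 - 0.5) + (0 - 1 / 3) + (1 - 0.5) + 0
    var = 0.25 + 2 / 9 + 0.25
    chi2, _ = logrank_test(groups, times, events)
    assert chi2 == pytest.approx(o_minus_e**2 / var, rel=1e-9)


def test_logrank_single_group_errors():
    with pytest.raises(TampolError):
        logrank_test([0, 0, 0], [1, 2, 3], [1, 1, 0])


def test_cox_matches_hand_partial_likelihood():
    """No ties, 2 events, binary covariate: score equation solves e^b = 1/sqrt(2)."""
    df = pd.DataFrame({"time_days": [1, 2, 3], "event": [1, 1, 0],
                       "x": [1, 0, 1]})
    fit = cox_ph(df, "x")
    assert fit.loc[0, "coef"] == pytest.approx(-0.5 * math.log(2), abs=1e-6)
    assert fit.loc[0, "hr"] == pytest.approx(1 / math.sqrt(2), abs=1e-6)


def test_cox_recovers_two_group_hazard_ratio():
    rng = np.random.default_rng(1)
    x = rng.integers(0, 2, 500)
    model = SurvivalModel(baseline_rate_per_day=1 / 1000, censor_low_days=300,
                          censor_high_days=3000)
    t, e = simulate_survival(x * math.log(3.0), model, rng)
    df = pd.DataFrame({"time_days": t, "event": e.astype(int), "x": x})
    fit = cox_ph(df, "x")
    hr = fit.loc[0, "hr"]
    assert 2.2 <= hr <= 4.0
    assert fit.loc[0, "ci_low"] <= 3.0 <= fit.loc[0, "ci_high"]


def test_cox_constant_covariate_errors():
    df = pd.DataFrame({"time_days": [1, 2, 3], "event": [1, 1, 0], "x": [1, 1, 1]})
    with pytest.raises(TampolError, match="constant"):
        cox_ph(df, "x")


def test_five_year_label_horizon():
    lab = five_year_death_label([100, 1826, 1827, 3000], [1, 1, 1, 0])
    assert list(lab) == [1, 1, 0, 0]


def test_fisher_hypergeometric_oracle():
    _, p = compare_groups([[5, 0], [0, 5]], test="fisher")
    assert p == pytest.approx(2 / 252, rel=1e-9)


def test_spearman_and_degenerate_signed_rank():
    rho, _ = compare_groups([1, 2, 3, 4], [10, 20, 30, 40], test="spearman")
    assert rho == pytest.approx(1.0)
    with pytest.raises(TampolError, match="zero"):
        compare_groups([1.0, 2.0], [1.0, 2.0], test="wilcoxon_signed_rank")
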