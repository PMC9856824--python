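import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, rankdata

from methamplicon.diagnostic_stats import (
    CASE_HIGH,
    CASE_LOW,
    bonferroni,
    compare_all,
    compare_variable,
    comparisons_to_frame,
    cutoff_and_ratio,
    exact_mann_whitney,
    format_adjusted_p,
    is_completely_separated,
    loo_cv_logistic,
    roc_auc_delong,
    sens_spec_extremes,
)
from methamplicon.variable_builder import VariableMatrix, parse_variable_name


def mw_enumerate(x, y):
    """Oracle: two-sided exact Mann-Whitney p by enumerating every labeling."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n, n1 = len(pooled), len(x)
    w_obs = ranks[:n1].sum()
    lo = hi = total = 0
    for subset in itertools.combinations(range(n), n1):
        w = ranks[list(subset)].sum()
        total += 1
        if w <= w_obs + 1e-9:
            lo += 1
        if w >= w_obs - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def auc_bruteforce(x, y):
    """Oracle: concordant-pair counting."""
    total = 0.0
    for xi in x:
        for yj in y:
            total += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
    return total / (len(x) * len(y))


# ---------------------------------------------------------------------------
# exact Mann-Whitney
# ---------------------------------------------------------------------------


def test_mw_toy_no_ties():
    assert exact_mann_whitney([1, 2], [3, 4]) == pytest.approx(1 / 3)


def test_mw_identical_singletons():
    assert exact_mann_whitney([5.0], [5.0]) == 1.0


def test_mw_complete_separation_19_vs_18():
    p = exact_mann_whitney(np.arange(19) + 100.0, np.arange(18, dtype=float))
    assert p == pytest.approx(2 / math.comb(37, 18))


def test_mw_equals_enumeration_with_and_without_ties():
    rng = np.random.default_rng(21)
    for _ in range(40):
        n1 = int(rng.integers(1, 6))
        n2 = int(rng.integers(1, 6))
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        assert exact_mann_whitney(x, y) == pytest.approx(mw_enumerate(x, y))
        xt = rng.integers(0, 3, size=n1).astype(float)  # heavy ties
        yt = rng.integers(0, 3, size=n2).astype(float)
        assert exact_mann_whitney(xt, yt) == pytest.approx(mw_enumerate(xt, yt))


def test_mw_matches_scipy_exact_without_ties():
    rng = np.random.default_rng(22)
    for _ in range(20):
        x = rng.normal(size=int(rng.integers(3, 10)))
        y = rng.normal(size=int(rng.integers(3, 10)))
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert exact_mann_whitney(x, y) == pytest.approx(ref)


def test_mw_empty_group_is_error():
    with pytest.raises(ValueError):
        exact_mann_whitney([], [1.0])


# ---------------------------------------------------------------------------
# Bonferroni
# ---------------------------------------------------------------------------


def test_bonferroni_display_and_significance():
    p_adj, display, sig = bonferroni(0.01, 1167)
    assert p_adj == pytest.approx(11.67)
    assert display == ">1" and not sig
    p_adj, display, sig = bonferroni(2 / math.comb(37, 18), 1167)
    assert display == "0.00000013" and sig
    assert bonferroni(0.0, 10) == (0.0, "0", True)


def test_format_adjusted_p_two_significant_figures():
    assert format_adjusted_p(0.6321) == "0.63"
    assert format_adjusted_p(0.0017421) == "0.0017"
    assert format_adjusted_p(1.0) == "1.0"


# ---------------------------------------------------------------------------
# sensitivity / specificity extremes, cutoff and ratio
# ---------------------------------------------------------------------------


def test_sens_spec_extremes_direct_count():
    sens, spec = sens_spec_extremes([10, 12, 1], [2, 3], CASE_HIGH)
    assert sens == pytest.approx(100 * 2 / 3)  # 2 of 3 cases above max control
    assert spec == pytest.approx(0.0)          # no control below min case (=1)
    sens, spec = sens_spec_extremes([10, 12, 4], [2, 3], CASE_HIGH)
    assert (sens, spec) == (100.0, 100.0)


def test_sens_spec_fully_separated_and_constant():
    assert sens_spec_extremes([5, 6], [1, 2], CASE_HIGH) == (100.0, 100.0)
    assert sens_spec_extremes([3, 3], [3, 3], CASE_HIGH) == (0.0, 0.0)


def test_cutoff_geometric_mean_and_ratio():
    cutoff, ratio = cutoff_and_ratio([4.0, 9.0], [1.0, 0.5], CASE_HIGH)
    assert cutoff == pytest.approx(2.0)
    assert ratio == pytest.approx(4.0)


def test_cutoff_arithmetic_mean_when_zero():
    cutoff, ratio = cutoff_and_ratio([0.4, 2.0], [0.0, 0.0], CASE_HIGH)
    assert cutoff == pytest.approx(0.2)
    assert ratio is None


def test_cutoff_without_separation_maximizes_youden():
    x = [1.0, 3.0, 5.0, 7.0]
    y = [0.0, 2.0, 4.0, 9.0]
    cutoff, ratio = cutoff_and_ratio(x, y, CASE_HIGH)
    assert ratio is None
    # classification at the reported cutoff reproduces the best sens+spec
    best = max(
        np.mean(np.array(x) >= t) + np.mean(np.array(y) < t)
        for t in sorted(set(x) | set(y))
    )
    achieved = np.mean(np.array(x) >= cutoff) + np.mean(np.array(y) < cutoff)
    assert achieved == pytest.approx(best)


def test_cutoff_rules_on_random_separated_instances():
    rng = np.random.default_rng(23)
    for _ in range(50):
        a = float(rng.uniform(0.1, 1.0))
        b = a * float(rng.uniform(1.01, 20.0))
        y = np.sort(rng.uniform(0, a, size=8))
        y[-1] = a
        x = np.sort(rng.uniform(b, 3 * b, size=9))
        x[0] = b
        cutoff, ratio = cutoff_and_ratio(x, y, CASE_HIGH)
        assert cutoff == pytest.approx(math.sqrt(a * b))
        assert ratio == pytest.approx(b / a)
        assert a < cutoff < b  # cutoff separates the groups on these data


# ---------------------------------------------------------------------------
# LOO-CV logistic classification
# ---------------------------------------------------------------------------


def test_loo_cv_shortcircuits_on_complete_separation():
    x = np.arange(19) + 50.0
    y = np.arange(18) * 1.0
    assert loo_cv_logistic(x, y) == (100.0, 100.0, 100.0)
    # separation in the case-low direction short-circuits too
    assert loo_cv_logistic(y, x) == (100.0, 100.0, 100.0)


def test_loo_cv_constant_variable_closed_form():
    """Constant predictor: balanced weights give p = 0.5 everywhere, the
    0.5-threshold tie rule classifies control: sens 0, spec 100."""
    acc, sens, spec = loo_cv_logistic(np.full(19, 2.0), np.full(18, 2.0))
    assert acc == pytest.approx(100 * 18 / 37)
    assert sens == 0.0
    assert spec == 100.0


def test_loo_cv_informative_variable_beats_chance():
    rng = np.random.default_rng(24)
    x = rng.normal(3.0, 1.0, 19)
    y = rng.normal(0.0, 1.0, 18)
    if is_completely_separated(x, y):
        x[0] = y.max()  # force overlap so CV actually runs
    acc, sens, spec = loo_cv_logistic(x, y)
    assert acc > 80.0


def test_loo_cv_null_accuracy_near_chance():
    """Pure-noise variables: mean LOO accuracy within [40, 60] over replicates."""
    rng = np.random.default_rng(25)
    accs = []
    for _ in range(200):
        v = rng.normal(size=37)
        accs.append(loo_cv_logistic(v[:19], v[19:])[0])
    assert 40.0 <= np.mean(accs) <= 60.0


# ---------------------------------------------------------------------------
# ROC AUC with DeLong CI
# ---------------------------------------------------------------------------


def test_auc_toy():
    auc, ci = roc_auc_delong([2, 4], [1, 3], CASE_HIGH)
    assert auc == pytest.approx(75.0)
    assert ci is not None


def test_auc_matches_bruteforce_pair_counting():
    rng = np.random.default_rng(26)
    for _ in range(20):
        x = rng.normal(0.5, 1, int(rng.integers(3, 12)))
        y = rng.normal(0, 1, int(rng.integers(3, 12)))
        auc, _ = roc_auc_delong(x, y, CASE_HIGH)
        assert auc == pytest.approx(100 * auc_bruteforce(x, y))


def test_auc_complete_separation_suppresses_ci():
    auc, ci = roc_auc_delong([5, 6, 7], [1, 2], CASE_HIGH)
    assert auc == 100.0 and ci is None


def test_auc_invariant_under_monotone_transform_and_label_swap():
    rng = np.random.default_rng(27)
    x = rng.normal(1, 1, 10)
    y = rng.normal(0, 1, 9)
    auc, _ = roc_auc_delong(x, y, CASE_HIGH)
    auc_t, _ = roc_auc_delong(np.exp(x), np.exp(y), CASE_HIGH)
    assert auc_t == pytest.approx(auc)
    auc_swapped, _ = roc_auc_delong(y, x, CASE_HIGH)
    assert auc_swapped == pytest.approx(100 - auc)


def test_auc_null_is_half_within_3se():
    rng = np.random.default_rng(28)
    aucs = [
        roc_auc_delong(rng.normal(size=19), rng.normal(size=18), CASE_HIGH)[0]
        for _ in range(300)
    ]
    se = np.std(aucs) / math.sqrt(len(aucs))
    assert abs(np.mean(aucs) - 50.0) <= 3 * se


def test_delong_variance_close_to_bootstrap():
    rng = np.random.default_rng(29)
    x = rng.normal(1.0, 1.0, 19)
    y = rng.normal(0.0, 1.0, 18)
    auc, ci = roc_auc_delong(x, y, CASE_HIGH)
    half = (ci[1] - ci[0]) / 2 / 100
    delong_var = (half / 1.959964) ** 2
    boot = []
    for _ in range(10_000):
        bx = rng.choice(x, size=x.size, replace=True)
        by = rng.choice(y, size=y.size, replace=True)
        boot.append(auc_bruteforce(bx, by))
    boot_var = np.var(boot, ddof=1)
    assert delong_var == pytest.approx(boot_var, rel=0.2)


# ---------------------------------------------------------------------------
# the assembled battery
# ---------------------------------------------------------------------------


def _matrix(columns, n_case=3, n_control=3):
    samples = [f"P{i}" for i in range(n_case)] + [f"H{i}" for i in range(n_control)]
    df = pd.DataFrame(columns, index=samples)
    groups = pd.Series(["case"] * n_case + ["control"] * n_control, index=samples)
    return VariableMatrix(values=df, groups=groups,
                          defs=[parse_variable_name(c) for c in df.columns])


def test_compare_all_single_variable_row_count():
    m = _matrix({"L.C1": [5.0, 6.0, 7.0, 1.0, 2.0, 3.0]})
    rows = compare_all(m, "case", "control")
    assert len(rows) == 1
    r = rows[0]
    assert r.complete_separation
    assert r.cv_accuracy == r.auc == 100.0 and r.auc_ci is None
    assert r.cutoff == pytest.approx(math.sqrt(3 * 5))
    assert r.ratio == pytest.approx(5 / 3)


def test_t_status_variables_tested_case_low():
    # unmethylated proportions run lower in cases
    m = _matrix({"L.T1.T2": [80.0, 85.0, 90.0, 99.0, 99.5, 99.9]})
    r = compare_all(m, "case", "control")[0]
    assert r.orientation == CASE_LOW
    assert r.complete_separation
    assert r.sens_at_100spec == 100.0


def test_separation_flag_consistency_on_random_data():
    """complete_separation <=> sens@100spec = 100 <=> spec@100sens = 100."""
    rng = np.random.default_rng(30)
    for _ in range(50):
        x = rng.normal(rng.uniform(0, 4), 1, 8)
        y = rng.normal(0, 1, 7)
        r = compare_variable("L.C1", ("C",), x, y, m=10)
        assert r.complete_separation == (r.sens_at_100spec == 100.0)
        assert r.complete_separation == (r.spec_at_100sens == 100.0)
        if r.complete_separation:
            assert r.cv_accuracy == 100.0 and r.auc_ci is None


def test_missing_values_are_excluded_per_variable():
    m = _matrix({"L.C1": [5.0, 6.0, np.nan, 1.0, 2.0, 3.0]})
    r = compare_all(m, "case", "control")[0]
    assert (r.n_case, r.n_control) == (2, 3)


def test_comparisons_frame_sorted_by_adjusted_p():
    m = _matrix({
        "L.C1": [5.0, 6.0, 7.0, 1.0, 2.0, 3.0],      # separated
        "L.C2": [3.0, 1.0, 2.5, 2.0, 3.5, 1.5],      # overlapping
    })
    df = comparisons_to_frame(compare_all(m, "case", "control"))
    assert list(df["variable"]) == ["L.C1", "L.C2"]
    assert list(df["option"]) == [1, 2]
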