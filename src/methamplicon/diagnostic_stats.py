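"""Group-comparison statistics for methylation variables.

Per variable: the exact two-sided Mann-Whitney test (full permutation
distribution of the rank-sum statistic, ties handled exactly by dynamic
programming over midranks), Bonferroni adjustment (p x m, default
m = 1167, displayed ">1" past 1), sensitivity at 100% specificity and
specificity at 100% sensitivity, the cutoff/ratio rules (geometric mean
of the two closest cross-group values, arithmetic mean when one is zero,
sens+spec-maximising threshold when the groups overlap),
leave-one-out cross-validated logistic classification with
group-balancing weights at threshold 0.5, and ROC AUC with DeLong's 95%
confidence interval (suppressed at AUC = 1).  Variables attaining
complete separation report 100% for all accuracy measures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .variable_builder import VariableMatrix

__all__ = [
    "GroupComparison",
    "exact_mann_whitney",
    "bonferroni",
    "format_adjusted_p",
    "sens_spec_extremes",
    "is_completely_separated",
    "cutoff_and_ratio",
    "loo_cv_logistic",
    "roc_auc_delong",
    "compare_all",
    "comparisons_to_frame",
    "write_comparisons",
    "DEFAULT_M",
]

logger = logging.getLogger(__name__)

DEFAULT_M = 1167
CASE_HIGH = "case_high"
CASE_LOW = "case_low"


# ---------------------------------------------------------------------------
# Exact Mann-Whitney
# ---------------------------------------------------------------------------

_dist_cache: dict[tuple, tuple[np.ndarray, int]] = {}


def _ranksum_distribution(doubled_ranks: tuple[int, ...], n1: int) -> tuple[np.ndarray, int]:
    """Exact distribution of the group-1 rank sum over all labelings.

    ``doubled_ranks`` are the pooled midranks multiplied by two (integers
    even under ties).  Returns ``(counts, total)`` where ``counts[s]`` is
    the number of size-``n1`` subsets with doubled rank sum ``s`` and
    ``total = C(n, n1)``.  Dynamic programming; exact for any tie pattern.
    """
    key = (tuple(sorted(doubled_ranks)), n1)
    cached = _dist_cache.get(key)
    if cached is not None:
        return cached
    n = len(doubled_ranks)
    total = math.comb(n, n1)
    S = sum(doubled_ranks)
    dtype = object if total > 2**62 else np.int64
    dp = np.zeros((n1 + 1, S + 1), dtype=dtype)
    dp[0, 0] = 1
    for r in doubled_ranks:
        new = dp.copy()
        new[1:, r:] += dp[:-1, : S + 1 - r]
        dp = new
    counts = dp[n1]
    assert int(counts.sum()) == total
    _dist_cache[key] = (counts, total)
    return counts, total


def exact_mann_whitney(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided Mann-Whitney p over all C(n1+n2, n1) group labelings.

    p = min(1, 2 * min(P(W <= w), P(W >= w))) where W is the rank-sum of
    group ``x`` (midranks under ties) under random relabeling.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled, method="average")
    doubled = np.rint(2.0 * ranks).astype(int)
    w = int(doubled[: x.size].sum())
    counts, total = _ranksum_distribution(tuple(doubled), x.size)
    lo = int(counts[: w + 1].sum())
    hi = int(counts[w:].sum())
    return min(1.0, 2.0 * min(lo, hi) / total)


# ---------------------------------------------------------------------------
# Bonferroni
# ---------------------------------------------------------------------------


def bonferroni(p_raw: float, m: int = DEFAULT_M) -> tuple[float, str, bool]:
    """(p_adj, display form, significant); p_adj = p_raw * m, shown '>1' past 1."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError("p_raw must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    p_adj = p_raw * m
    return p_adj, format_adjusted_p(p_adj), p_adj < 0.05


def format_adjusted_p(p_adj: float) -> str:
    """Adjusted p at two significant figures in plain decimal; '>1' past 1."""
    if p_adj > 1.0:
        return ">1"
    if p_adj == 0.0:
        return "0"
    decimals = max(0, 1 - int(math.floor(math.log10(p_adj))))
    return f"{p_adj:.{decimals}f}"


# ---------------------------------------------------------------------------
# Sensitivity / specificity at the extremes, cutoff and ratio
# ---------------------------------------------------------------------------


def _oriented(x: np.ndarray, y: np.ndarray, orientation: str) -> tuple[np.ndarray, np.ndarray]:
    """Map to (high group, low group) value arrays."""
    if orientation == CASE_HIGH:
        return x, y
    if orientation == CASE_LOW:
        return y, x
    raise ValueError(f"unknown orientation {orientation!r}")


def is_completely_separated(x, y, orientation: str = CASE_HIGH) -> bool:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    high, low = _oriented(x, y, orientation)
    return float(high.min()) > float(low.max())


def sens_spec_extremes(x, y, orientation: str = CASE_HIGH) -> tuple[float, float]:
    """(sensitivity at 100% specificity, specificity at 100% sensitivity), in %.

    Case-high: sens@100spec counts case values strictly above the control
    maximum; spec@100sens counts control values strictly below the case
    minimum.  Mirrored for case-low variables.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if orientation == CASE_HIGH:
        sens = 100.0 * np.mean(x > y.max())
        spec = 100.0 * np.mean(y < x.min())
    else:
        sens = 100.0 * np.mean(x < y.min())
        spec = 100.0 * np.mean(y > x.max())
    return float(sens), float(spec)


def cutoff_and_ratio(x, y, orientation: str = CASE_HIGH) -> tuple[float, float | None]:
    """Diagnostic cutoff and (optional) ratio of the two closest values.

    Complete separation: with a = max of the low group and b = min of the
    high group, the cutoff is sqrt(a*b) and the ratio b/a when both are
    nonzero, or the arithmetic mean (a+b)/2 with no ratio when a = 0.
    Without separation, the cutoff is the observed value maximising
    sensitivity + specificity (ties -> smallest value); no ratio.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    high, low = _oriented(x, y, orientation)
    a = float(low.max())
    b = float(high.min())
    if b > a:  # complete separation
        if a > 0.0:
            return math.sqrt(a * b), b / a
        return (a + b) / 2.0, None
    best_t, best_j = None, -np.inf
    for t in sorted(np.unique(np.concatenate([x, y]))):
        sens = np.mean(high >= t)
        spec = np.mean(low < t)
        j = sens + spec
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    return best_t, None


# ---------------------------------------------------------------------------
# Leave-one-out cross-validated logistic classification
# ---------------------------------------------------------------------------

_RIDGE = 1e-8


def _fit_logistic(v: np.ndarray, labels: np.ndarray, weights: np.ndarray) -> tuple[float, float, float, float]:
    """Weighted one-predictor logistic fit via IRLS with a tiny ridge.

    Returns (intercept, slope, center, scale); the predictor is
    standardised internally for numerical stability.
    """
    center = float(v.mean())
    scale = float(v.std())
    if scale == 0.0:
        scale = 1.0
    z = (v - center) / scale
    X = np.column_stack([np.ones_like(z), z])
    beta = np.zeros(2)
    for _ in range(100):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        g = X.T @ (weights * (labels - p)) - _RIDGE * beta
        W = weights * p * (1.0 - p)
        H = X.T @ (W[:, None] * X) + _RIDGE * np.eye(2)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.abs(g).max() < 1e-10 or np.abs(step).max() < 1e-10:
            break
    return float(beta[0]), float(beta[1]), center, scale


def loo_cv_logistic(x, y) -> tuple[float, float, float]:
    """LOO-CV accuracy, sensitivity, specificity (%) of a one-variable
    weighted logistic classifier at probability threshold 0.5.

    Training weights balance the groups (each group contributes equal
    total weight).  A held-out probability strictly above 0.5 classifies
    as case; exactly 0.5 classifies as control.  When the full data show
    complete separation in either direction all three measures are
    reported as 100 without cross-validating.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size + y.size < 3:
        raise ValueError("need at least 3 samples")
    if is_completely_separated(x, y, CASE_HIGH) or is_completely_separated(x, y, CASE_LOW):
        return 100.0, 100.0, 100.0
    v = np.concatenate([x, y])
    labels = np.concatenate([np.ones(x.size), np.zeros(y.size)])
    correct = np.zeros(v.size, dtype=bool)
    for held in range(v.size):
        mask = np.ones(v.size, dtype=bool)
        mask[held] = False
        tv, tl = v[mask], labels[mask]
        n1 = int(tl.sum())
        n0 = tl.size - n1
        if n1 == 0 or n0 == 0:
            prior = float(tl.mean())  # weighted prior degenerates to the lone group
            logger.warning("training fold %d has an empty group; using prior", held)
            p_held = prior
        elif np.ptp(tv) == 0.0:
            p_held = 0.5  # constant predictor: balanced weights give even odds
        else:
            w = np.where(tl == 1, 0.5 / n1, 0.5 / n0)
            b0, b1, center, scale = _fit_logistic(tv, tl, w)
            eta = b0 + b1 * (v[held] - center) / scale
            p_held = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        predicted_case = p_held > 0.5
        correct[held] = predicted_case == bool(labels[held])
    acc = 100.0 * correct.mean()
    sens = 100.0 * correct[labels == 1].mean()
    spec = 100.0 * correct[labels == 0].mean()
    return float(acc), float(sens), float(spec)


# ---------------------------------------------------------------------------
# ROC AUC with DeLong confidence interval
# ---------------------------------------------------------------------------


def roc_auc_delong(
    x, y, orientation: str = CASE_HIGH, level: float = 0.95
) -> tuple[float, tuple[float, float] | None]:
    """ROC AUC (%) and DeLong confidence interval, oriented so separation = 100.

    The CI uses DeLong's structural-components variance with a normal
    approximation, truncated to [0, 100]; it is suppressed (None) when
    AUC = 100 since it is degenerate there.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx = x if orientation == CASE_HIGH else -x
    sy = y if orientation == CASE_HIGH else -y
    diff = sx[:, None] - sy[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    auc = float(psi.mean())
    if auc == 1.0:
        return 100.0, None
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    var = 0.0
    if x.size > 1:
        var += v10.var(ddof=1) / x.size
    if y.size > 1:
        var += v01.var(ddof=1) / y.size
    from scipy.stats import norm
    z = norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(var)
    lo = max(0.0, auc - half)
    hi = min(1.0, auc + half)
    return 100.0 * auc, (100.0 * lo, 100.0 * hi)


# ---------------------------------------------------------------------------
# The full battery
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """One variable's full statistics row."""

    variable: str
    orientation: str
    n_case: int
    n_control: int
    p_raw: float
    p_adj: float
    p_adj_display: str
    significant: bool
    mean_case: float
    mean_control: float
    sens_at_100spec: float
    spec_at_100sens: float
    cutoff: float
    ratio: float | None
    cv_accuracy: float
    cv_sensitivity: float
    cv_specificity: float
    auc: float
    auc_ci: tuple[float, float] | None
    complete_separation: bool


def _variable_orientation(statuses: Sequence[str], x: np.ndarray, y: np.ndarray) -> str:
    """C-status variables test case-high, T-status case-low; mixed pairs
    (CT/TC) follow the observed group means."""
    unique = set(statuses)
    if unique == {"C"}:
        return CASE_HIGH
    if unique == {"T"}:
        return CASE_LOW
    return CASE_HIGH if x.mean() >= y.mean() else CASE_LOW


def compare_variable(
    variable: str,
    statuses: Sequence[str],
    x: np.ndarray,
    y: np.ndarray,
    m: int = DEFAULT_M,
) -> GroupComparison:
    orientation = _variable_orientation(statuses, x, y)
    p_raw = exact_mann_whitney(x, y)
    p_adj, display, significant = bonferroni(p_raw, m)
    sens, spec = sens_spec_extremes(x, y, orientation)
    cutoff, ratio = cutoff_and_ratio(x, y, orientation)
    separated = is_completely_separated(x, y, orientation)
    if separated:
        cv = (100.0, 100.0, 100.0)
        auc, ci = 100.0, None
    else:
        cv = loo_cv_logistic(x, y)
        auc, ci = roc_auc_delong(x, y, orientation)
    return GroupComparison(
        variable=variable, orientation=orientation,
        n_case=int(x.size), n_control=int(y.size),
        p_raw=p_raw, p_adj=p_adj, p_adj_display=display, significant=significant,
        mean_case=float(x.mean()), mean_control=float(y.mean()),
        sens_at_100spec=sens, spec_at_100sens=spec,
        cutoff=cutoff, ratio=ratio,
        cv_accuracy=cv[0], cv_sensitivity=cv[1], cv_specificity=cv[2],
        auc=auc, auc_ci=ci, complete_separation=separated,
    )


def compare_all(
    matrix: VariableMatrix,
    case_group: str,
    control_group: str,
    m: int | None = None,
) -> list[GroupComparison]:
    """Run the battery on every variable of the matrix.

    ``m`` defaults to the number of variables (the Bonferroni family
    size).  Samples with missing values for a variable are excluded from
    that variable's test; the per-group n's are recorded in the row.
    """
    if m is None:
        m = len(matrix.defs)
    rows = []
    for d in matrix.defs:
        x = matrix.group_values(d.name, case_group)
        y = matrix.group_values(d.name, control_group)
        if x.size == 0 or y.size == 0:
            logger.warning("variable %s has an empty group after missing-value "
                           "exclusion; skipped", d.name)
            continue
        rows.append(compare_variable(d.name, d.statuses, x, y, m=m))
    return rows


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def _sig3(v: float) -> str:
    return f"{v:.3g}"


def comparisons_to_frame(rows: Sequence[GroupComparison]) -> pd.DataFrame:
    """Table-shaped frame: one row per variable, sorted by adjusted p then name."""
    ordered = sorted(rows, key=lambda r: (r.p_adj, r.variable))
    records = []
    for i, r in enumerate(ordered, start=1):
        cutoff_ratio = _sig3(r.cutoff)
        if r.ratio is not None:
            cutoff_ratio += f" ({_sig3(r.ratio)})"
        auc_str = f"{r.auc:.1f}"
        if r.auc_ci is not None:
            auc_str += f" ({r.auc_ci[0]:.1f}, {r.auc_ci[1]:.1f})"
        records.append({
            "option": i,
            "variable": r.variable,
            "p_adj": r.p_adj_display,
            "means_case_control": f"{_sig3(r.mean_case)}/{_sig3(r.mean_control)}",
            "sens_at_100spec": round(r.sens_at_100spec, 1),
            "spec_at_100sens": round(r.spec_at_100sens, 1),
            "cutoff_ratio": cutoff_ratio,
            "cv_accuracy": round(r.cv_accuracy, 1),
            "cv_sensitivity": round(r.cv_sensitivity, 1),
            "cv_specificity": round(r.cv_specificity, 1),
            "auc_ci": auc_str,
            "orientation": r.orientation,
            "complete_separation": r.complete_separation,
            "p_raw": r.p_raw,
        })
    return pd.DataFrame.from_records(records)


def write_comparisons(rows: Sequence[GroupComparison], path: str | Path) -> None:
    comparisons_to_frame(rows).to_csv(path, sep="\t", index=False)
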