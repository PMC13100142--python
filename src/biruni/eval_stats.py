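"""Classification metrics, Wald intervals, exact Wilcoxon signed-rank,
one-way ANOVA, cosine similarity and complexity accounting.

Metric conventions: the positive class defaults to Osteoarthritis (label 1)
but is configurable; specificity is TN/(TN+FP) (the standard true-negative
rate); balanced accuracy is the mean of sensitivity and specificity, which
is robust to class imbalance.  Confidence intervals use the normal
(Wald) approximation p +/- 1.96*sqrt(p(1-p)/n), clipped to [0, 1].

The Wilcoxon signed-rank test drops zero differences, uses midranks for
ties, and computes the exact two-tailed p-value for n <= 20 from the full
null distribution of the positive-rank sum (a dynamic program over doubled
midranks, equivalent to enumerating all 2^n sign assignments); beyond that
it falls back to the normal approximation with continuity and tie
corrections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

Z_95 = 1.96


# ---------------------------------------------------------------------------
# Confusion counts and derived metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray,
                         positive_label: int = 1) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have the same length")
        pos = y_true == positive_label
        pred_pos = y_pred == positive_label
        return cls(
            tp=int(np.sum(pos & pred_pos)),
            tn=int(np.sum(~pos & ~pred_pos)),
            fp=int(np.sum(~pos & pred_pos)),
            fn=int(np.sum(pos & ~pred_pos)),
        )


def wald_interval(p_hat: float, n: int, z: float = Z_95) -> tuple[float, float]:
    """Normal-approximation CI for a proportion, clipped to [0, 1]."""
    half = z * math.sqrt(p_hat * (1.0 - p_hat) / n)
    return (max(0.0, p_hat - half), min(1.0, p_hat + half))


@dataclass(frozen=True)
class MetricReport:
    """Binary-classification metrics; undefined ratios are None."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f1: float | None
    balanced_accuracy: float | None
    ci: dict | None = None

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv, "npv": self.npv,
            "f1": self.f1, "balanced_accuracy": self.balanced_accuracy,
        }
        if self.ci is not None:
            out["ci_95"] = self.ci
        return out


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def balanced_accuracy(tpr: float, tnr: float) -> float:
    """Mean of sensitivity and specificity."""
    if not (0.0 <= tpr <= 1.0 and 0.0 <= tnr <= 1.0):
        raise ValueError("tpr and tnr must lie in [0, 1]")
    return (tpr + tnr) / 2.0


def compute_metrics(counts: ConfusionCounts,
                    n_for_ci: int | None = None) -> MetricReport:
    """All confusion-derived metrics; optional 95% Wald CIs at sample size n.

    Metrics with a zero denominator are reported as None, the rest are still
    computed.
    """
    acc = _ratio(counts.tp + counts.tn, counts.total)
    tpr = _ratio(counts.tp, counts.tp + counts.fn)
    tnr = _ratio(counts.tn, counts.tn + counts.fp)
    ppv = _ratio(counts.tp, counts.tp + counts.fp)
    npv = _ratio(counts.tn, counts.tn + counts.fn)
    f1 = _ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn)
    bal = None if (tpr is None or tnr is None) else balanced_accuracy(tpr, tnr)

    ci = None
    if n_for_ci is not None:
        if n_for_ci <= 0:
            raise ValueError("n_for_ci must be positive")
        ci = {
            name: (None if val is None else wald_interval(val, n_for_ci))
            for name, val in [
                ("accuracy", acc), ("sensitivity", tpr), ("specificity", tnr),
                ("ppv", ppv), ("npv", npv), ("f1", f1),
                ("balanced_accuracy", bal),
            ]
        }
    return MetricReport(accuracy=acc, sensitivity=tpr, specificity=tnr,
                        ppv=ppv, npv=npv, f1=f1, balanced_accuracy=bal, ci=ci)


def f1_from_ppv_tpr(ppv: float, tpr: float) -> float:
    """F1 as the harmonic mean of precision and sensitivity."""
    if ppv <= 0 or tpr <= 0:
        raise ValueError("ppv and tpr must be positive")
    return 2.0 * ppv * tpr / (ppv + tpr)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    w: float            # sum of signed ranks (W+ - W-)
    w_plus: float
    w_minus: float
    p_two_tailed: float
    method: str         # "exact" or "normal"
    n_nonzero: int


def _midranks(abs_diffs: np.ndarray) -> np.ndarray:
    order = np.argsort(abs_diffs, kind="stable")
    ranks = np.empty(abs_diffs.size, dtype=float)
    sorted_vals = abs_diffs[order]
    i = 0
    while i < sorted_vals.size:
        j = i
        while j + 1 < sorted_vals.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _exact_null_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of each doubled positive-rank sum over all 2^n sign patterns.

    Polynomial product prod_i (1 + x^(2 r_i)); index = doubled W+ value.
    """
    counts = np.zeros(int(doubled_ranks.sum()) + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(differences: Sequence[float],
                         exact_max_n: int = 20) -> WilcoxonResult:
    """Paired signed-rank test on a vector of differences.

    Zeros are dropped; ties get midranks.  For n <= ``exact_max_n`` the
    two-tailed p is exact: 2 * min(P(W+ <= w), P(W+ >= w)) under the
    enumeration null, capped at 1.  Larger n uses the normal approximation
    with continuity correction and the standard tie correction.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; the test is undefined")

    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())

    if n <= exact_max_n:
        doubled = np.rint(2.0 * ranks).astype(int)
        counts = _exact_null_counts(doubled)
        total = counts.sum()                     # 2^n
        wd = int(round(2.0 * w_plus))
        p_low = counts[: wd + 1].sum() / total
        p_high = counts[wd:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        tie_term = 0.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        sd = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w_plus - mean - 0.5 * math.copysign(1.0, w_plus - mean)) / sd
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
        method = "normal"

    return WilcoxonResult(
        w=w_plus - w_minus, w_plus=w_plus, w_minus=w_minus,
        p_two_tailed=float(p), method=method, n_nonzero=n,
    )


# ---------------------------------------------------------------------------
# One-way ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaTable:
    ss_between: float
    df_between: int
    ms_between: float
    ss_within: float
    df_within: int
    ms_within: float
    f_stat: float
    p_value: float
    ss_total: float
    df_total: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "ss_between", "df_between", "ms_between", "ss_within", "df_within",
            "ms_within", "f_stat", "p_value", "ss_total", "df_total",
            "degenerate",
        )}


def anova_from_ss(ss_between: float, df_between: int,
                  ss_within: float, df_within: int) -> AnovaTable:
    """Assemble the ANOVA table from already-computed sums of squares."""
    if df_between < 1 or df_within < 1:
        raise ValueError("degrees of freedom must be >= 1")
    ms_b = ss_between / df_between
    ms_w = ss_within / df_within
    if ms_w == 0.0:
        return AnovaTable(
            ss_between=ss_between, df_between=df_between, ms_between=ms_b,
            ss_within=ss_within, df_within=df_within, ms_within=ms_w,
            f_stat=math.nan, p_value=math.nan,
            ss_total=ss_between + ss_within, df_total=df_between + df_within,
            degenerate=True,
        )
    f = ms_b / ms_w
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaTable(
        ss_between=ss_between, df_between=df_between, ms_between=ms_b,
        ss_within=ss_within, df_within=df_within, ms_within=ms_w,
        f_stat=f, p_value=p,
        ss_total=ss_between + ss_within, df_total=df_between + df_within,
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaTable:
    """Between/within decomposition and F test over >= 2 groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df_between = len(arrays) - 1
    df_within = all_vals.size - len(arrays)
    return anova_from_ss(ss_between, df_between, ss_within, df_within)


# ---------------------------------------------------------------------------
# Miscellaneous statistics
# ---------------------------------------------------------------------------

def cosine_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """dot(a, b) / (|a| |b|); errors on zero vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have the same length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def complexity_product(n: int, d: int, iters: int) -> int:
    """Abstract work units of a population search: n * d * iterations."""
    if min(n, d, iters) < 0:
        raise ValueError("inputs must be nonnegative")
    return n * d * iters
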