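"""Diagnostic evaluation: ROC over criteria scores, paired AUC comparison
(DeLong), and accuracy tables with Wilson confidence intervals.

AUC is computed two ways — trapezoidal area of the stepwise ROC and the
tie-corrected Mann-Whitney placement statistic — and the two are asserted
equal to 1e-12 on every call.  The paired comparison uses DeLong's
placement-value covariance; the AUC interval is Wald from the DeLong
variance.  Binomial metric intervals are Wilson score intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import DegenerateInputError


def _positive_mask(labels, positive) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    return arr == positive


@dataclass(frozen=True)
class ROCResult:
    """Stepwise ROC over an ordinal score: one operating point per distinct
    threshold (positive = score >= t) plus the trivial endpoints."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    auc_ci: tuple[float, float]


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values (ties get half credit)."""
    n1, n0 = pos.size, neg.size
    mid = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (mid[:n1] - stats.rankdata(pos)) / n0
    v01 = 1.0 - (mid[n1:] - stats.rankdata(neg)) / n1
    return v10, v01


def _split(scores, labels, positive) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = _positive_mask(labels, positive)
    if y.all() or not y.any():
        raise DegenerateInputError("both classes must be present")
    return s[y], s[~y]


def _auc_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    if v10.size < 2 or v01.size < 2:
        return float("nan")
    return float(np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size)


def roc_from_scores(
    scores: Sequence[float],
    labels: Sequence,
    positive: str = "malignant",
    level: float = 0.95,
) -> ROCResult:
    pos, neg = _split(scores, labels, positive)
    thr = np.unique(np.concatenate([pos, neg]))[::-1]
    sens = (pos[:, None] >= thr[None, :]).mean(axis=0)
    spec = (neg[:, None] < thr[None, :]).mean(axis=0)
    # endpoints: threshold above max (sens 0, spec 1) and below min (1, 0)
    thresholds = np.concatenate(([np.inf], thr, [-np.inf]))
    sens = np.concatenate(([0.0], sens, [1.0]))
    spec = np.concatenate(([1.0], spec, [0.0]))
    fpr = 1.0 - spec
    auc_trap = float(np.trapezoid(sens, fpr))
    v10, v01 = _placements(pos, neg)
    auc_mw = float(v10.mean())
    if abs(auc_trap - auc_mw) > 1e-12:
        raise AssertionError(
            f"trapezoidal AUC {auc_trap!r} != Mann-Whitney AUC {auc_mw!r}"
        )
    var = _auc_variance(v10, v01)
    se = math.sqrt(var) if var == var else float("nan")
    z = stats.norm.ppf(0.5 + level / 2)
    ci = (max(0.0, auc_mw - z * se), min(1.0, auc_mw + z * se))
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc_mw,
        auc_se=se,
        auc_ci=ci,
    )


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    delta: float
    variance: float
    z: float
    p: float
    degenerate: bool = False


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence,
    positive: str = "malignant",
) -> DeLongResult:
    """DeLong's paired nonparametric comparison of two correlated AUCs.

    Both score vectors must cover the same lesions in the same order.
    Identical scores (zero variance of the difference) are flagged
    degenerate with p = 1.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape:
        raise DegenerateInputError("paired score vectors must align")
    pos_a, neg_a = _split(sa, labels, positive)
    pos_b, neg_b = _split(sb, labels, positive)
    v10a, v01a = _placements(pos_a, neg_a)
    v10b, v01b = _placements(pos_b, neg_b)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    n1, n0 = pos_a.size, neg_a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = float(
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    )
    delta = auc_a - auc_b
    if var < 1e-12:
        return DeLongResult(auc_a, auc_b, delta, var, 0.0, 1.0, degenerate=True)
    z = delta / math.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, delta, var, z, p)


def delong_auc_variance(
    scores: Sequence[float], labels: Sequence, positive: str = "malignant"
) -> tuple[float, float]:
    """(AUC, DeLong variance) for a single marker."""
    pos, neg = _split(scores, labels, positive)
    v10, v01 = _placements(pos, neg)
    return float(v10.mean()), _auc_variance(v10, v01)


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Confusion counts and derived metrics with Wilson intervals.

    Metrics whose denominator is empty are ``None`` and listed in
    ``undefined``.  The identity ppv = sens*pi / (sens*pi + (1-spec)(1-pi))
    with pi the sample prevalence holds by construction.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    ppv: float | None
    npv: float | None
    ci: dict[str, tuple[float, float] | None]
    undefined: tuple[str, ...]


def confusion_metrics(
    tp: int, fp: int, tn: int, fn: int, level: float = 0.95
) -> DiagnosticPerformance:
    """Metrics + Wilson score intervals from raw confusion counts."""
    if min(tp, fp, tn, fn) < 0:
        raise DegenerateInputError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise DegenerateInputError("empty confusion table")

    def frac(num: int, den: int):
        if den == 0:
            return None, None
        ci = proportion_confint(num, den, alpha=1 - level, method="wilson")
        return num / den, (float(ci[0]), float(ci[1]))

    metrics = {
        "sensitivity": frac(tp, tp + fn),
        "specificity": frac(tn, tn + fp),
        "accuracy": frac(tp + tn, total),
        "ppv": frac(tp, tp + fp),
        "npv": frac(tn, tn + fn),
    }
    undefined = tuple(k for k, (v, _) in metrics.items() if v is None)
    return DiagnosticPerformance(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=metrics["sensitivity"][0],
        specificity=metrics["specificity"][0],
        accuracy=metrics["accuracy"][0],
        ppv=metrics["ppv"][0],
        npv=metrics["npv"][0],
        ci={k: v[1] for k, v in metrics.items()},
        undefined=undefined,
    )


def diagnostic_metrics(
    scores: Sequence[float],
    labels: Sequence,
    threshold: float,
    positive: str = "malignant",
    level: float = 0.95,
) -> DiagnosticPerformance:
    """Performance of the rule 'positive when score >= threshold'."""
    s = np.asarray(scores, dtype=float)
    y = _positive_mask(labels, positive)
    pred = s >= threshold
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())
    fn = int((~pred & y).sum())
    return confusion_metrics(tp, fp, tn, fn, level=level)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def ppv_npv_from_sens_spec(
    sens: float, spec: float, n_pos: int, n_neg: int
) -> tuple[float | None, float | None, tuple[int, int, int, int]]:
    """Reconstruct confusion counts (round half-up) from sensitivity,
    specificity and the class sizes; return (ppv, npv, (tp, fp, tn, fn)).

    This is the audit identity linking a published accuracy table's
    predictive values to its sensitivity/specificity columns.
    """
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise DegenerateInputError("sens/spec must be proportions in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise DegenerateInputError("class sizes must be positive")
    tp = _round_half_up(sens * n_pos)
    tn = _round_half_up(spec * n_neg)
    fp = n_neg - tn
    fn = n_pos - tp
    ppv = tp / (tp + fp) if tp + fp > 0 else None
    npv = tn / (tn + fn) if tn + fn > 0 else None
    return ppv, npv, (tp, fp, tn, fn)


def plot_roc(results: dict[str, ROCResult], path) -> None:
    """Basic overlaid ROC plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, roc in results.items():
        ax.plot(
            1.0 - roc.specificity,
            roc.sensitivity,
            marker="o",
            label=f"{name} (AUC {roc.auc:.2f})",
        )
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
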