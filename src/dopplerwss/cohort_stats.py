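"""Group comparison and diagnostic-threshold statistics.

Two statistical layers sit on top of the imaging pipeline:

* Welch's unequal-variance two-sided t-test for group comparisons — the
  group standard deviations in this setting differ by up to a factor of
  six, so pooling is inappropriate (a pooled variant is available behind a
  flag).

* Empirical ROC analysis for the disease-threshold question: wall shear
  stress falls with atherosclerosis, so by default a case is called
  positive when its score is at or below the threshold
  (direction="low_positive").  The AUC is accumulated from integer pair
  counts, so it equals the Mann-Whitney statistic
  (#{positive beats negative} + 1/2 #{ties}) / (n_pos * n_neg) exactly,
  which is also the trapezoidal area under the empirical curve.

No multiple-testing correction is applied anywhere: per-week comparisons
are reported as unadjusted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import STAGES

__all__ = [
    "TTestResult",
    "ROCResult",
    "welch_t_test",
    "roc_curve",
    "threshold_performance",
    "youden_optimal_threshold",
    "compare_groups",
    "stage_labels_to_binary",
]


@dataclass(frozen=True)
class TTestResult:
    """Two-sample t-test outcome with the group summaries echoed back."""

    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    pooled: bool = False

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "sd_a": self.sd_a,
            "sd_b": self.sd_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
        }


def welch_t_test(sample_a, sample_b, pooled: bool = False) -> TTestResult:
    """Two-sided two-sample t-test; Welch-Satterthwaite df by default.

    Each sample needs at least two values and positive variance in at least
    one sample.  If both variances are zero and the means are equal, the
    samples are indistinguishable and p = 1 by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each sample needs >= 2 values, got {a.size} and {b.size}")
    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if ma == mb:
            return TTestResult(
                t=0.0, df=float(na + nb - 2), p=1.0,
                mean_a=ma, mean_b=mb, sd_a=0.0, sd_b=0.0, n_a=na, n_b=nb,
                pooled=pooled,
            )
        raise ValueError("both samples have zero variance but different means")
    if pooled:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = float(na + nb - 2)
    else:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = (ma - mb) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    p = max(p, np.nextafter(0.0, 1.0))  # p in (0, 1]
    return TTestResult(
        t=float(t), df=float(df), p=float(p),
        mean_a=float(ma), mean_b=float(mb),
        sd_a=float(np.sqrt(va)), sd_b=float(np.sqrt(vb)),
        n_a=na, n_b=nb, pooled=pooled,
    )


@dataclass(eq=False)
class ROCResult:
    """Empirical ROC curve over the unique score thresholds.

    thresholds are the sorted unique scores; sens[i]/spec[i] are the
    sensitivity and specificity obtained when calls are made at
    thresholds[i] (score <= t positive for direction="low_positive",
    score >= t for "high_positive").
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    direction: str
    n_pos: int
    n_neg: int

    @property
    def youden(self) -> np.ndarray:
        return self.sens + self.spec - 1.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sens,
                "specificity": self.spec,
                "fpr": 1.0 - self.spec,
            }
        )


def _validate_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present in labels")
    return labels


def roc_curve(scores, labels, direction: str = "low_positive") -> ROCResult:
    """Empirical ROC with tied scores grouped at a single threshold.

    AUC is computed from integer counts of positive/negative score pairs,
    making it exactly the Mann-Whitney probability that a random positive
    scores more disease-like than a random negative (ties counted half),
    and identical to the trapezoidal area under (1 - specificity,
    sensitivity).
    """
    if direction not in ("low_positive", "high_positive"):
        raise ValueError("direction must be 'low_positive' or 'high_positive'")
    scores = np.asarray(scores, dtype=float)
    labels = _validate_binary(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    uniq, inv = np.unique(scores, return_inverse=True)
    pos_at = np.bincount(inv, weights=labels.astype(float)).astype(np.int64)
    neg_at = np.bincount(inv, weights=(~labels).astype(float)).astype(np.int64)
    n_pos = int(pos_at.sum())
    n_neg = int(neg_at.sum())
    if direction == "low_positive":
        tp = np.cumsum(pos_at)  # called positive: score <= threshold
        fp = np.cumsum(neg_at)
    else:
        tp = np.cumsum(pos_at[::-1])[::-1]  # called positive: score >= threshold
        fp = np.cumsum(neg_at[::-1])[::-1]
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg  # = TN/N, bit-identical to threshold_performance

    # exact trapezoid over the grouped curve, in integers:
    # 2*area*n_pos*n_neg = sum over threshold groups of dFP * (TP_prev + TP_now)
    if direction == "low_positive":
        tp_prev = np.r_[0, tp[:-1]]
        num = int(np.sum(neg_at * (tp_prev + tp)))
    else:
        order = np.arange(uniq.size - 1, -1, -1)  # walk thresholds downward
        tp_d, fp_d = tp[order], neg_at[order]
        tp_prev = np.r_[0, tp_d[:-1]]
        num = int(np.sum(fp_d * (tp_prev + tp_d)))
    auc = num / (2.0 * n_pos * n_neg)
    return ROCResult(
        thresholds=uniq,
        sens=sens,
        spec=spec,
        auc=float(auc),
        direction=direction,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def threshold_performance(
    scores, labels, threshold: float, direction: str = "low_positive"
) -> tuple[float, float]:
    """(sensitivity, specificity) at a fixed decision threshold.

    A case is called positive when score <= threshold (low_positive) or
    score >= threshold (high_positive); calls at exactly the threshold
    count as positive.
    """
    if direction not in ("low_positive", "high_positive"):
        raise ValueError("direction must be 'low_positive' or 'high_positive'")
    scores = np.asarray(scores, dtype=float)
    labels = _validate_binary(labels)
    called = scores <= threshold if direction == "low_positive" else scores >= threshold
    sens = float((called & labels).sum() / labels.sum())
    spec = float((~called & ~labels).sum() / (~labels).sum())
    return sens, spec


def youden_optimal_threshold(roc: ROCResult) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties in J are broken toward higher sensitivity; remaining ties toward
    the first such threshold in sorted order.
    """
    j = roc.youden
    best_j = j.max()
    candidates = np.flatnonzero(j == best_j)
    best = candidates[np.argmax(roc.sens[candidates])]
    return float(roc.thresholds[best])


# ---------------------------------------------------------------------------
# Cohort-table conveniences
# ---------------------------------------------------------------------------

_VAR_COLUMNS = {
    "wss": "wss_dyne_cm2",
    "imt": "imt_mm",
    "tc": "tc_mmol_l",
    "ldl": "ldl_mmol_l",
}


def compare_groups(cohort: pd.DataFrame, variable: str, week: int, pooled: bool = False) -> TTestResult:
    """Welch t-test of experimental vs control for one variable and week."""
    col = _VAR_COLUMNS.get(variable, variable)
    sub = cohort[cohort["week"] == week]
    a = sub.loc[sub["group"] == "experimental", col].to_numpy()
    b = sub.loc[sub["group"] == "control", col].to_numpy()
    return welch_t_test(a, b, pooled=pooled)


def stage_labels_to_binary(stages, min_positive_stage: str = "fatty_streak") -> np.ndarray:
    """Binary disease labels from histology stages: positive when the stage
    is at least ``min_positive_stage`` in lesion severity."""
    severity = {s: i for i, s in enumerate(STAGES)}
    if min_positive_stage not in severity:
        raise ValueError(f"unknown stage {min_positive_stage!r}; expected one of {STAGES}")
    cut = severity[min_positive_stage]
    return np.asarray([severity[s] >= cut for s in stages], dtype=bool)
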