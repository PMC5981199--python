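"""Subject-level aggregation, ROC/AUC and AUC comparison statistics.

Window scores are aggregated to one value per subject by the median of that
subject's window predictions; subject medians and their faller labels yield
the ROC curve and its area.  Identity heads are scored one-versus-all per
subject.  Two comparison tests are provided: a two-sample z-test on fold-wise
AUC summary statistics and a t-test (paired or unpaired) on fold AUC vectors.
A Hanley–McNeil standard error gives a confidence interval for a single AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass
class SubjectScore:
    subject_id: str
    window_scores: list[float]
    aggregate: float
    label: int


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    degenerate: bool = False


@dataclass
class EvalReport:
    """ROC points, AUC and optional fold-wise summaries for one task/arm."""

    roc_points: np.ndarray | None = None  # (k, 2) columns FPR, TPR
    auc: float | None = None
    undefined: bool = False
    per_fold_aucs: list[float] = field(default_factory=list)
    mean_auc: float | None = None
    sd_auc: float | None = None
    auc_ci95: tuple[float, float] | None = None
    comparison_tests: list[tuple[str, float, float]] = field(default_factory=list)


def aggregate_subject(window_scores) -> float:
    """Median of a subject's window scores (even counts average the middle two)."""
    scores = np.asarray(list(window_scores), float)
    if scores.size == 0:
        raise ValueError("cannot aggregate an empty score list")
    return float(np.median(scores))


def subject_scores(
    window_scores: np.ndarray, window_subjects: list[str], label_of: dict[str, int]
) -> list[SubjectScore]:
    """Group per-window scores by subject and aggregate by the median."""
    by_subject: dict[str, list[float]] = {}
    for s, sc in zip(window_subjects, window_scores):
        by_subject.setdefault(s, []).append(float(sc))
    return [
        SubjectScore(subject_id=s, window_scores=v, aggregate=aggregate_subject(v), label=label_of[s])
        for s, v in sorted(by_subject.items())
    ]


def roc_auc(scores, labels) -> EvalReport:
    """ROC curve and trapezoidal AUC; a single-class label vector flags the
    AUC undefined instead of returning a number."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if len(np.unique(labels)) < 2:
        return EvalReport(undefined=True)
    fpr, tpr, _ = roc_curve(labels, scores)
    pts = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    n_pos = int(labels.sum())
    return EvalReport(roc_points=pts, auc=auc, auc_ci95=hanley_mcneil_ci(auc, n_pos, len(labels) - n_pos))


def hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int, level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for one AUC from the Hanley–McNeil standard error."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def identity_ova_auc(score_matrix: np.ndarray, true_ids, vocabulary: list[str]) -> dict:
    """One-versus-all ROC AUC per subject for the identity head.

    ``score_matrix`` is (windows × vocabulary) of identity probabilities;
    each subject's column is scored against the binary indicator of that
    subject's windows.  Subjects with no test windows (or degenerate all-tied
    columns) are excluded and listed.  Returns per-subject AUCs, their mean,
    and the exclusion list.
    """
    score_matrix = np.asarray(score_matrix, float)
    true_ids = list(true_ids)
    if score_matrix.shape[0] != len(true_ids):
        raise ValueError("score rows must align with true ids")
    present = set(true_ids)
    if len(present) < 2:
        raise ValueError("one-vs-all needs at least two subjects in the test windows")
    per_subject: dict[str, float] = {}
    excluded: list[str] = []
    for j, sid in enumerate(vocabulary):
        if sid not in present:
            excluded.append(sid)
            continue
        y = np.array([1 if t == sid else 0 for t in true_ids])
        col = score_matrix[:, j]
        if np.ptp(col) == 0.0:
            per_subject[sid] = 0.5  # all-tied scores: chance by the half-credit tie convention
            continue
        per_subject[sid] = float(roc_auc_score(y, col))
    return {
        "per_subject": per_subject,
        "mean_auc": float(np.mean(list(per_subject.values()))),
        "excluded": excluded,
    }


def compare_auc_ztest(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> ComparisonResult:
    """Two-sample z-test on fold-wise AUC summaries (two-sided)."""
    if n_a < 1 or n_b < 1:
        raise ValueError("n must be >= 1 in both arms")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    se = np.sqrt(sd_a**2 / n_a + sd_b**2 / n_b)
    if se == 0.0:
        if mean_a == mean_b:
            return ComparisonResult(statistic=0.0, p_value=1.0, degenerate=True)
        raise ValueError("zero pooled variance with unequal means: z undefined")
    z = (mean_a - mean_b) / se
    return ComparisonResult(statistic=float(z), p_value=float(2.0 * stats.norm.sf(abs(z))))


def compare_auc_ttest(fold_aucs_a, fold_aucs_b, paired: bool = False) -> ComparisonResult:
    """Two-sided t-test on fold AUC vectors (unpaired by default)."""
    a = np.asarray(fold_aucs_a, float)
    b = np.asarray(fold_aucs_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two folds per arm")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal-length fold vectors")
        d = a - b
        if np.allclose(d, d[0], rtol=0.0, atol=1e-12):
            # zero-variance differences: identical vectors are indistinguishable,
            # a constant nonzero shift has no estimable error
            if d[0] == 0.0:
                return ComparisonResult(statistic=0.0, p_value=1.0, degenerate=True)
            return ComparisonResult(statistic=float(np.sign(d[0]) * np.inf), p_value=0.0, degenerate=True)
        t, p = stats.ttest_rel(a, b)
    else:
        if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
            equal = a[0] == b[0]
            return ComparisonResult(statistic=0.0 if equal else np.inf, p_value=1.0 if equal else 0.0, degenerate=True)
        t, p = stats.ttest_ind(a, b)
    return ComparisonResult(statistic=float(t), p_value=float(p))
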