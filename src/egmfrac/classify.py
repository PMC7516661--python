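"""AF-type classification from median CGCD values.

A single ordered feature (the per-record median CGCD) separates the three
organization classes, so the classifier is a pair of thresholds

    value < T1        -> Type I
    T1 <= value < T2  -> Type II
    value >= T2       -> Type III

fitted by exhaustive search over candidate cut pairs (equivalent to a
depth-limited decision tree with two splits on one feature, but exactly
reproducible).  The shipped reference thresholds, learned on the authors'
full clinical dataset, are T1 = 1.3880, T2 = 2.0326.

Type IV (alternating) records are detected segment-by-segment: classify
each 1-s epoch; if at least one epoch is Type III and at least one is
Type I or II, the record is Type IV; otherwise it gets the class of its
median CGCD.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import ParameterError

__all__ = [
    "ThresholdModel",
    "ROCResult",
    "TypeDecision",
    "REFERENCE_MODEL",
    "fit_thresholds",
    "cross_validate",
    "classify_value",
    "detect_type_iv",
    "roc_one_vs_all",
    "compare_groups",
]

_ORDERED_CLASSES = ("I", "II", "III")


@dataclass(frozen=True)
class ThresholdModel:
    """Two ordinal cuts on median CGCD; boundary values go up (>= rule)."""

    T1: float
    T2: float
    training_accuracy: Optional[float] = None
    cv_accuracy: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.T1 < self.T2:
            raise ParameterError(f"need T1 < T2, got {self.T1} >= {self.T2}")


#: Thresholds learned on the authors' full 119-EGM clinical dataset;
#: shipped as a pretrained default, not reproduced by this package.
REFERENCE_MODEL = ThresholdModel(T1=1.3880, T2=2.0326)


@dataclass(frozen=True)
class ROCResult:
    auc: float
    youden_index: float
    optimal_threshold: float
    sensitivity: float
    specificity: float
    positive_class: str


@dataclass
class TypeDecision:
    per_segment_types: List[Optional[str]]
    final_type: Optional[str]
    thresholds_used: ThresholdModel
    analysis_failed: bool = False


def classify_value(median_cgcd: float, model: ThresholdModel) -> str:
    """Apply the ordinal rule; values exactly at a cut go to the upper class."""
    if median_cgcd < model.T1:
        return "I"
    if median_cgcd < model.T2:
        return "II"
    return "III"


def _accuracy(values: np.ndarray, labels: Sequence[str], t1: float, t2: float) -> int:
    model = ThresholdModel(t1, t2)
    return sum(classify_value(v, model) == lab for v, lab in zip(values, labels))


def fit_thresholds(
    values: Sequence[float], labels: Sequence[str]
) -> ThresholdModel:
    """Exhaustive two-cut ordinal fit minimizing misclassifications.

    Candidate cuts are midpoints between consecutive sorted unique values,
    plus one sentinel below the smallest and one above the largest value
    (so a cut can also predict an empty class); among cut pairs with equal
    training error, the pair with the largest summed gap (maximal margin)
    wins, with the smaller (T1, T2) pair as the final deterministic
    tie-break.
    """
    values = np.asarray(values, dtype=float)
    labels = list(labels)
    if len(values) != len(labels):
        raise ParameterError("values and labels length mismatch")
    present = set(labels)
    if not present.issuperset(_ORDERED_CLASSES):
        raise ParameterError(
            f"all of classes {_ORDERED_CLASSES} must be present, got {sorted(present)}"
        )
    for cls in _ORDERED_CLASSES:
        if labels.count(cls) < 2:
            raise ParameterError(f"need >= 2 examples of class {cls}")

    uniq = np.unique(values)
    if len(uniq) < 3:
        raise ParameterError("need at least 3 distinct values to place two cuts")
    span = uniq[-1] - uniq[0]
    mids = np.r_[uniq[0] - span, (uniq[:-1] + uniq[1:]) / 2.0, uniq[-1] + span]
    # sentinel cuts carry zero margin so interior cuts win ties
    gaps = np.r_[0.0, uniq[1:] - uniq[:-1], 0.0]

    best = None  # (errors, -summed_gap, t1, t2)
    for (i, c1), (j, c2) in itertools.combinations(enumerate(mids), 2):
        errors = len(values) - _accuracy(values, labels, c1, c2)
        key = (errors, -(gaps[i] + gaps[j]), c1, c2)
        if best is None or key < best:
            best = key
    errors, _, t1, t2 = best
    return ThresholdModel(
        T1=float(t1),
        T2=float(t2),
        training_accuracy=1.0 - errors / len(values),
    )


def cross_validate(
    values: Sequence[float],
    labels: Sequence[str],
    k: int = 10,
    seed: Optional[int] = 0,
) -> float:
    """Stratified k-fold cross-validated accuracy of the two-cut fit.

    Folds are drawn with a seeded shuffle; when k exceeds the smallest
    class count (e.g. 10 folds over 8 records per class) strict
    stratification is impossible and a plain shuffled k-fold is used
    instead.  Either way, a draw whose training part lacks a class is
    retried with a perturbed seed (up to 100 attempts).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n = len(values)
    if n < k:
        raise ParameterError(f"need n >= k, got n={n}, k={k}")

    min_class = min(np.count_nonzero(labels == c) for c in _ORDERED_CLASSES)
    for attempt in range(100):
        rs = (seed or 0) + attempt
        if k <= min_class:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        else:
            splitter = KFold(n_splits=k, shuffle=True, random_state=rs)
        folds = list(splitter.split(values, labels))
        if all(
            set(np.unique(labels[tr])) >= set(_ORDERED_CLASSES) for tr, _ in folds
        ):
            break
    else:
        raise ParameterError(
            "could not draw folds whose training parts contain every class"
        )

    correct = 0
    for train_idx, test_idx in folds:
        model = fit_thresholds(values[train_idx], labels[train_idx])
        correct += sum(
            classify_value(v, model) == lab
            for v, lab in zip(values[test_idx], labels[test_idx])
        )
    return correct / n


def detect_type_iv(
    per_segment_cgcds: Sequence[Optional[float]], model: ThresholdModel
) -> TypeDecision:
    """Segment-wise alternation detection.

    Undefined epochs (None) are skipped.  If the defined epochs contain a
    Type III epoch and also a Type I-or-II epoch, the record is Type IV;
    otherwise the median of the defined epochs is classified directly.
    """
    seg_types: List[Optional[str]] = [
        None if v is None else classify_value(v, model) for v in per_segment_cgcds
    ]
    defined = [v for v in per_segment_cgcds if v is not None]
    if not defined:
        return TypeDecision(
            per_segment_types=seg_types,
            final_type=None,
            thresholds_used=model,
            analysis_failed=True,
        )
    types_present = {t for t in seg_types if t is not None}
    if "III" in types_present and types_present & {"I", "II"}:
        final = "IV"
    else:
        final = classify_value(float(np.median(defined)), model)
    return TypeDecision(
        per_segment_types=seg_types, final_type=final, thresholds_used=model
    )


def roc_one_vs_all(
    values: Sequence[float], labels: Sequence[str], positive_class: str
) -> ROCResult:
    """One-vs-all ROC of median CGCD for the given positive class.

    Higher CGCD means more fractionation, so the score direction is the
    raw value for Type III (and II) and the negated value for Type I, where
    lower CGCD indicates the positive class.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    y = (labels == positive_class).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ParameterError("both classes must be non-empty after binarization")
    scores = -values if positive_class == "I" else values
    fpr, tpr, thresholds = roc_curve(y, scores)
    auc_value = float(_trapezoid_auc(fpr, tpr))
    youden = tpr - fpr
    best = int(np.argmax(youden))
    thr = float(thresholds[best])
    return ROCResult(
        auc=auc_value,
        youden_index=float(youden[best]),
        optimal_threshold=-thr if positive_class == "I" else thr,
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        positive_class=positive_class,
    )


def compare_groups(
    values: Sequence[float], labels: Sequence[str]
) -> Dict[str, object]:
    """Distributional group comparison of median CGCDs.

    Shapiro–Wilk normality per group, Levene homoscedasticity across
    groups, Kruskal–Wallis omnibus, then pairwise Mann–Whitney U tests with
    Bonferroni correction (factor = number of pairwise tests run).  Groups
    of size < 3 skip the per-group tests with a notice.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = {lab: values[labels == lab] for lab in np.unique(labels)}
    if len(groups) < 2:
        raise ParameterError("need at least two groups")

    notices: List[str] = []
    shapiro: Dict[str, Optional[dict]] = {}
    for lab, g in groups.items():
        if len(g) < 3:
            shapiro[str(lab)] = None
            notices.append(f"Shapiro–Wilk skipped for group {lab} (n={len(g)} < 3)")
        else:
            s = stats.shapiro(g)
            shapiro[str(lab)] = {"statistic": float(s.statistic), "p": float(s.pvalue)}

    arrays = list(groups.values())
    lev = stats.levene(*arrays)
    if len(groups) > 2:
        omni = stats.kruskal(*arrays)
    else:
        omni = stats.mannwhitneyu(*arrays, alternative="two-sided")

    pairs = list(itertools.combinations(sorted(groups), 2))
    bonferroni = len(pairs)
    pairwise = {}
    for a, b in pairs:
        mw = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        pairwise[f"{a} vs {b}"] = {
            "statistic": float(mw.statistic),
            "p_raw": float(mw.pvalue),
            "p_corrected": float(min(1.0, mw.pvalue * bonferroni)),
        }
    return {
        "shapiro_wilk": shapiro,
        "levene": {"statistic": float(lev.statistic), "p": float(lev.pvalue)},
        "omnibus": {
            "test": "kruskal-wallis" if len(groups) > 2 else "mann-whitney",
            "statistic": float(omni.statistic),
            "p": float(omni.pvalue),
        },
        "pairwise_mann_whitney": pairwise,
        "bonferroni_factor": bonferroni,
        "notices": notices,
    }
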