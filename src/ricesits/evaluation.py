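"""Confusion-matrix metrics, Cohen's kappa, and the McNemar paired test.

The positive class is rice (label 1). Kappa uses the standard Cohen form
Pe = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / N^2, kappa = (Po - Pe)/(1 - Pe).
The McNemar test compares two classifiers on the same samples through their
discordant predictions b (A correct, B wrong) and c (A wrong, B correct);
the continuity-corrected statistic (|b-c|-1)^2/(b+c) is the default, the
uncorrected (b-c)^2/(b+c) is available, and p comes from the chi-square(1)
upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as _chi2

POSITIVE_LABEL = 1  # rice


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class McNemarResult:
    b: int                      # A correct, B wrong
    c: int                      # A wrong, B correct
    chi2: float
    p_value: float
    continuity_corrected: bool


def _check_binary(y, name):
    y = np.asarray(y)
    bad = ~np.isin(y, (0, 1))
    if bad.any():
        raise ValueError(f"{name} contains labels outside {{0, 1}}")
    return y


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must share length")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def classification_metrics(cm: ConfusionCounts) -> dict:
    """Accuracy, precision, recall, F1 and Cohen's kappa from counts.

    Undefined ratios (zero denominators) are reported as None together with
    an ``undefined`` list naming them.
    """
    n = cm.n
    if n <= 0:
        raise ValueError("empty confusion matrix")
    undefined = []
    accuracy = (cm.tp + cm.tn) / n
    precision = recall = f1 = kappa = None
    if cm.tp + cm.fp > 0:
        precision = cm.tp / (cm.tp + cm.fp)
    else:
        undefined.append("precision")
    if cm.tp + cm.fn > 0:
        recall = cm.tp / (cm.tp + cm.fn)
    else:
        undefined.append("recall")
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        undefined.append("f1")
    pe = ((cm.tp + cm.fp) * (cm.tp + cm.fn)
          + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / n ** 2
    if pe < 1.0:
        kappa = (accuracy - pe) / (1.0 - pe)
    else:
        undefined.append("kappa")
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "f1": f1, "kappa": kappa, "po": accuracy, "pe": pe,
            "undefined": undefined}


def mcnemar_chi2(b: int, c: int, continuity: bool = True) -> float:
    """Chi-square statistic from the discordant pair counts alone."""
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    if b + c == 0:
        return 0.0
    num = (abs(b - c) - 1.0) ** 2 if continuity else float(b - c) ** 2
    return num / (b + c)


def mcnemar_test(y_true, pred_a, pred_b,
                 continuity: bool = True) -> McNemarResult:
    y_true = _check_binary(y_true, "y_true")
    pred_a = _check_binary(pred_a, "pred_a")
    pred_b = _check_binary(pred_b, "pred_b")
    if not (y_true.shape == pred_a.shape == pred_b.shape):
        raise ValueError("prediction vectors must align with y_true")
    a_ok = pred_a == y_true
    b_ok = pred_b == y_true
    b_count = int((a_ok & ~b_ok).sum())
    c_count = int((~a_ok & b_ok).sum())
    if b_count + c_count == 0:
        return McNemarResult(0, 0, 0.0, 1.0, continuity)
    stat = mcnemar_chi2(b_count, c_count, continuity)
    p = float(_chi2.sf(stat, df=1))
    return McNemarResult(b=b_count, c=c_count, chi2=stat, p_value=p,
                         continuity_corrected=continuity)


def bonferroni(p_values, n_tests: int | None = None) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    m = n_tests if n_tests is not None else p.size
    return np.minimum(p * m, 1.0)


def area_agreement_ratio(reference_area: float,
                         estimated_area: float) -> float:
    """Agreement between a mapped area and a reference area, in percent:
    the smaller divided by the larger, times 100."""
    if reference_area <= 0 or estimated_area <= 0:
        raise ValueError("areas must be positive")
    lo, hi = sorted((reference_area, estimated_area))
    return lo / hi * 100.0


def probability_summary(rice_probability, labels, bins: int = 20) -> dict:
    """Class-conditional histogram densities of the predicted rice
    probability, plus their overlap coefficient (integral of the bin-wise
    minimum; 0 = perfectly separated, 1 = identical)."""
    p = np.asarray(rice_probability, dtype=float)
    labels = _check_binary(labels, "labels")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, bins + 1)
    width = 1.0 / bins
    out = {"bin_edges": edges}
    dens = {}
    for cls in (0, 1):
        sel = p[labels == cls]
        if sel.size:
            d, _ = np.histogram(sel, bins=edges, density=True)
        else:
            d = np.zeros(bins)
        dens[cls] = d
        out[f"density_class{cls}"] = d
    out["overlap"] = float(np.minimum(dens[0], dens[1]).sum() * width)
    return out
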