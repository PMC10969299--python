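"""Support-weighted classification metrics and result matrices.

Test cohorts are unbalanced, so class-specific metrics (sensitivity/recall,
specificity, precision, F1) are computed one-vs-rest per class and combined
by the support-weighted mean; accuracy is the plain fraction correct and
AUROC uses the rank-sum (Mann-Whitney) formulation with tie correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .learning.models import POSITIVE_CLASS

__all__ = ["EvaluationReport", "evaluate", "auroc", "results_matrix", "METRIC_ORDER"]

#: row ordering of the result matrices
METRIC_ORDER = ("accuracy", "sensitivity", "specificity", "precision",
                "f_score", "auroc", "errors")


@dataclass
class EvaluationReport:
    """Weighted confusion-matrix metrics of one model on one cohort."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_score: float
    auroc: float
    errors: int
    n: int
    model_id: str = ""
    category: str = ""
    cohort_id: str = ""
    per_class: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_ORDER}


def auroc(scores, labels, positive=POSITIVE_CLASS) -> float:
    """AUROC by the Mann-Whitney rank-sum statistic with tie correction."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = rankdata(scores)  # average ranks handle ties
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate(probabilities, labels, decisions=None, threshold: float = 0.5,
             model_id: str = "", category: str = "", cohort_id: str = "") -> EvaluationReport:
    """Weighted metrics from IDH-mutant probabilities and true labels.

    ``decisions`` (predicted labels) defaults to thresholding the
    probabilities at 0.5.  A class absent from the cohort is excluded from
    the weighting with a warning.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    if probabilities.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    if probabilities.shape[0] != labels.shape[0]:
        raise ValueError("predictions and labels must have equal length")
    if decisions is None:
        decisions = np.where(probabilities >= threshold, POSITIVE_CLASS,
                             "IDHwt" if POSITIVE_CLASS == "IDHmut" else "IDHmut")
    decisions = np.asarray(decisions)

    classes = ("IDHwt", "IDHmut")
    n = labels.size
    correct = int((decisions == labels).sum())
    per_class = {}
    weights, rows = [], []
    for c in classes:
        support = int((labels == c).sum())
        if support == 0:
            warnings.warn(f"class {c} absent from the cohort; excluded from weighting")
            continue
        tp = int(((decisions == c) & (labels == c)).sum())
        fp = int(((decisions == c) & (labels != c)).sum())
        fn = int(((decisions != c) & (labels == c)).sum())
        tn = n - tp - fp - fn
        recall = tp / (tp + fn)
        spec = tn / (tn + fp) if (tn + fp) > 0 else 0.0
        prec = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        f1 = 2 * prec * recall / (prec + recall) if (prec + recall) > 0 else 0.0
        per_class[c] = {"support": support, "tp": tp, "fp": fp, "fn": fn, "tn": tn,
                        "recall": recall, "specificity": spec, "precision": prec, "f1": f1}
        weights.append(support)
        rows.append((recall, spec, prec, f1))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    rec, spec, prec, f1 = (float(np.dot(w, [r[k] for r in rows])) for k in range(4))

    return EvaluationReport(
        accuracy=correct / n, sensitivity=rec, specificity=spec, precision=prec,
        f_score=f1, auroc=auroc(probabilities, labels), errors=n - correct, n=n,
        model_id=model_id, category=category, cohort_id=cohort_id, per_class=per_class)


def results_matrix(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Metrics x (model, category) table mirroring the heat-map layout.

    Rows follow :data:`METRIC_ORDER`; missing (model, category) cells are NA;
    duplicate cells are rejected.
    """
    if not reports:
        raise ValueError("at least one report required")
    seen = set()
    for r in reports:
        key = (r.model_id, r.category)
        if key in seen:
            raise ValueError(f"duplicate report for model={r.model_id!r} "
                             f"category={r.category!r}")
        seen.add(key)
    models = list(dict.fromkeys(r.model_id for r in reports))
    cats = list(dict.fromkeys(r.category for r in reports))
    cols = pd.MultiIndex.from_product([models, cats], names=["model", "category"])
    df = pd.DataFrame(np.nan, index=list(METRIC_ORDER), columns=cols)
    for r in reports:
        for m, v in r.as_row().items():
            df.loc[m, (r.model_id, r.category)] = v
    return df
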