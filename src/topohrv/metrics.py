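"""Performance measures and feature screening for sleep-stage models.

From an m x m confusion matrix M (rows = true class k, columns = predicted
class l) the per-class sensitivity SE_k = M_kk / sum_l M_kl, positive
predictivity +P_k = M_kk / sum_l M_lk, their harmonic-mean F1, the overall
accuracy Acc = trace / total, the chance-expected accuracy
EA = sum_p (row_p * col_p) / total^2 and Cohen's kappa = (Acc - EA)/(1 - EA)
are derived.  Per-subject aggregation reports the across-subject mean and
sample standard deviation of each measure.  Rates with an empty denominator
are reported as 0 with a warning flag, so a degenerate all-majority
classifier shows sensitivity 0 for the missed class.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import ranksums
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "confusion",
    "metrics_from_confusion",
    "per_subject_report",
    "auc",
    "feature_screening",
]


def confusion(true_labels, predicted_labels, class_order) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    y_true = np.asarray(true_labels, dtype=object)
    y_pred = np.asarray(predicted_labels, dtype=object)
    if y_true.size != y_pred.size:
        raise ValueError("label vectors differ in length")
    order = list(class_order)
    index = {c: i for i, c in enumerate(order)}
    unknown = sorted({*y_true, *y_pred} - set(order))
    if unknown:
        raise ValueError(f"labels {unknown} not in class order {order}")
    m = len(order)
    cm = np.zeros((m, m), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


def _safe_div(num: float, den: float, flags: list, what: str) -> float:
    if den == 0:
        flags.append(f"{what}: 0/0 reported as 0")
        return 0.0
    return num / den


def metrics_from_confusion(cm, class_order=None) -> dict:
    """Per-class SE/+P/F1 and overall Acc, expected accuracy, kappa."""
    M = np.asarray(cm, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = M.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    m = M.shape[0]
    names = list(class_order) if class_order is not None else list(range(m))
    flags: list[str] = []
    per_class = {}
    for k in range(m):
        row = M[k].sum()
        col = M[:, k].sum()
        se = _safe_div(M[k, k], row, flags, f"SE[{names[k]}]")
        pp = _safe_div(M[k, k], col, flags, f"+P[{names[k]}]")
        f1 = _safe_div(2 * pp * se, pp + se, flags, f"F1[{names[k]}]")
        tp = M[k, k]
        per_class[names[k]] = {
            "SE": se, "PPV": pp, "F1": f1,
            "TP": tp, "FP": col - tp, "FN": row - tp,
            "TN": total - row - col + tp,
        }
    acc = M.trace() / total
    ea = float((M.sum(axis=1) * M.sum(axis=0)).sum()) / total ** 2
    kappa = _safe_div(acc - ea, 1.0 - ea, flags, "Kappa")
    return {
        "per_class": per_class,
        "Acc": float(acc),
        "EA": float(ea),
        "Kappa": float(kappa),
        "n": int(total),
        "warnings": flags,
    }


def auc(true_binary, scores, positive_label=None) -> float | None:
    """Rank-based ROC area; ``None`` when only one class is present."""
    y = np.asarray(true_binary, dtype=object)
    classes = np.unique(y.astype(str))
    if classes.size != 2:
        logger.warning("AUC undefined: %d class(es) present", classes.size)
        return None
    if positive_label is None:
        positive_label = classes[-1]  # sklearn's decision_function convention
    return float(roc_auc_score((y == positive_label).astype(int), scores))


def per_subject_report(subjects, true_labels, predicted_labels, class_order,
                       scores=None, positive_label=None) -> dict:
    """Metrics per subject, summarized as mean +/- sample sd across subjects.

    Pooled metrics over all rows are reported alongside (the two differ when
    subjects contribute unequal epoch counts).  A subject missing a class
    contributes nothing to that class's per-class averages (logged).
    """
    subjects = np.asarray(subjects, dtype=object)
    y_true = np.asarray(true_labels, dtype=object)
    y_pred = np.asarray(predicted_labels, dtype=object)
    order = list(class_order)
    uniq = sorted(set(subjects))
    if not uniq:
        raise ValueError("at least one subject required")

    rows: list[dict] = []
    for subj in uniq:
        mask = subjects == subj
        rep = metrics_from_confusion(
            confusion(y_true[mask], y_pred[mask], order), order)
        entry = {"subject": subj, "Acc": rep["Acc"], "Kappa": rep["Kappa"]}
        for cls in order:
            if (y_true[mask] == cls).any():
                for key in ("SE", "PPV", "F1", "TP", "FP", "TN", "FN"):
                    entry[f"{key}[{cls}]"] = rep["per_class"][cls][key]
            else:
                logger.warning(
                    "subject %s has no true %s epochs; per-class metrics "
                    "skipped", subj, cls)
        if scores is not None and len(order) == 2:
            a = auc(y_true[mask], np.asarray(scores)[mask], positive_label)
            if a is not None:
                entry["AUC"] = a
        rows.append(entry)

    keys = sorted({k for row in rows for k in row if k != "subject"})
    summary = {}
    for key in keys:
        vals = np.array([row[key] for row in rows if key in row], dtype=float)
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        summary[key] = {"mean": float(vals.mean()), "sd": sd,
                        "n_subjects": int(vals.size)}
    pooled = metrics_from_confusion(confusion(y_true, y_pred, order), order)
    if scores is not None and len(order) == 2:
        pooled["AUC"] = auc(y_true, np.asarray(scores), positive_label)
    return {"per_subject": summary, "pooled": pooled,
            "subject_rows": rows, "class_order": order}


def feature_screening(X, groups, subjects, feature_names=None,
                      alpha: float = 0.05) -> dict:
    """Per-feature Wilcoxon rank-sum screening with Bonferroni control.

    Each feature is z-scored within subject first (a subject-constant
    feature z-scores to zeros, logged); the two-sided rank-sum test then
    compares the two groups per feature, and the family-wise level ``alpha``
    is Bonferroni-divided by the number of features actually tested.
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups, dtype=object)
    subjects = np.asarray(subjects, dtype=object)
    uniq_groups = sorted(set(groups.astype(str)))
    if len(uniq_groups) != 2:
        raise ValueError(f"exactly two groups required, got {uniq_groups}")
    if any((groups == g).sum() == 0 for g in uniq_groups):
        raise ValueError("both groups must be non-empty")
    n_feat = X.shape[1]
    names = list(feature_names) if feature_names is not None else list(range(n_feat))

    Z = np.empty_like(X)
    for subj in set(subjects):
        mask = subjects == subj
        mu = X[mask].mean(axis=0)
        sd = X[mask].std(axis=0)
        flat = sd == 0
        if flat.any():
            logger.warning("subject %s: %d constant feature(s) z-scored to 0",
                           subj, int(flat.sum()))
        sd = np.where(flat, 1.0, sd)
        zs = (X[mask] - mu) / sd
        zs[:, flat] = 0.0
        Z[mask] = zs

    g0 = groups == uniq_groups[0]
    pvals = np.array([
        ranksums(Z[g0, j], Z[~g0, j]).pvalue for j in range(n_feat)
    ])
    threshold = alpha / n_feat
    return {
        "feature": names,
        "p_value": pvals.tolist(),
        "reject": (pvals < threshold).tolist(),
        "bonferroni_family_size": n_feat,
        "alpha_familywise": alpha,
        "groups": uniq_groups,
    }
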