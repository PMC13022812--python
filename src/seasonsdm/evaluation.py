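"""Discrimination metrics, TSS threshold optimization and global averaging.

AUC_ROC is the Mann-Whitney probability that a presence outscores a background
point (ties count one half).  AUC_PR is the area under the step-interpolated
precision-recall curve with equal scores processed as one block.  TSS
(sensitivity + specificity - 1) depends on a binarization threshold, which is
chosen on the validation split by exhaustive search; global ("any season")
metrics are the arithmetic mean of the four seasonal ones.  For archives with
no month information, seasonal probabilities are rescaled so each season's
threshold sits at 0.5 and combined with a per-point maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .occurrences import SEASONS


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return y


def auc_roc(scores, labels) -> float:
    """Area under the ROC curve via rank statistics (tie-aware)."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for AUC_ROC")
    ranks = rankdata(s)  # average ranks handle ties as half-wins
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_pr(scores, labels) -> float:
    """Area under the precision-recall step curve, descending-score sweep."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("at least one positive required for AUC_PR")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # block boundaries: positions where the score changes (ties form one block)
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    last_in_block = np.flatnonzero(np.r_[np.diff(s_sorted) != 0, True])
    tp_b = tp[last_in_block]
    fp_b = fp[last_in_block]
    recall = tp_b / n_pos
    precision = tp_b / (tp_b + fp_b)
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def tss_at(scores, labels, th: float) -> float:
    """TSS at threshold ``th`` with the rule: positive iff score >= th."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    pred = s >= th
    pos = y == 1
    sens = pred[pos].mean() if pos.any() else np.nan
    spec = (~pred[~pos]).mean() if (~pos).any() else np.nan
    return float(sens + spec - 1)


def optimize_tss_threshold(val_scores, val_labels) -> tuple[float, float]:
    """Threshold maximizing TSS on the validation data.

    Candidates are all distinct validation scores plus {0, 1}; classification
    is positive iff score >= threshold; ties on TSS resolve to the smallest
    threshold.  Returns (threshold, tss).
    """
    y = _check_binary(val_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to optimize a TSS threshold")
    s = np.asarray(val_scores, dtype=float)
    candidates = np.unique(np.r_[s, 0.0, 1.0])
    n_pos = y.sum()
    n_neg = len(y) - n_pos
    # vectorized sweep: for each candidate, sens = P(score>=th | pos), etc.
    ge = s[None, :] >= candidates[:, None]
    sens = (ge & (y == 1)).sum(axis=1) / n_pos
    spec = (~ge & (y == 0)).sum(axis=1) / n_neg
    tss = sens + spec - 1
    best = np.argmax(tss)  # argmax returns the first (smallest) candidate on ties
    return float(candidates[best]), float(tss[best])


def global_average(seasonal_metrics) -> float:
    """Arithmetic mean of the four seasonal metric values."""
    if isinstance(seasonal_metrics, dict):
        missing = [s for s in SEASONS if s not in seasonal_metrics]
        if missing:
            raise ValueError(f"missing seasons {missing}")
        vals = [seasonal_metrics[s] for s in SEASONS]
    else:
        vals = list(seasonal_metrics)
        if len(vals) != 4:
            raise ValueError(f"need exactly four seasonal values, got {len(vals)}")
    return float(np.mean(vals))


def rescale_probability(p, th, literal: bool = False):
    """Shift probabilities so the season threshold maps to 0.5.

    ``p_rescaled = clip(p - (th - 0.5), 0, 1)``: p == th maps exactly to 0.5,
    making seasons with different thresholds comparable on one 0.5 scale.
    ``literal=True`` applies p - th - 0.5 without the 0.5 anchor (unclipped
    reading of the printed formula), kept for comparison only.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or not 0 <= th <= 1:
        raise ValueError("p and th must lie in [0, 1]")
    if literal:
        return p - th - 0.5
    return np.clip(p - th + 0.5, 0.0, 1.0)


def any_season_score(rescaled: dict[str, np.ndarray] | np.ndarray,
                     aggregation: str = "max") -> np.ndarray:
    """Combine four rescaled seasonal probabilities into one per-point score.

    The default "any season" reading is the per-point maximum (suitable in at
    least one season); binary prediction is score >= 0.5.  Mean aggregation is
    available via config.
    """
    if isinstance(rescaled, dict):
        arr = np.stack([rescaled[s] for s in SEASONS])
    else:
        arr = np.asarray(rescaled, dtype=float)
        if arr.shape[0] != 4:
            raise ValueError("expected four seasonal probability arrays")
    if aggregation == "max":
        return arr.max(axis=0)
    if aggregation == "mean":
        return arr.mean(axis=0)
    raise ValueError(f"unknown aggregation {aggregation!r}")


def evaluate_by_region(scores, labels, region_ids, min_n: int = 100) -> dict:
    """Per-region AUC_ROC restricted to regions with >= ``min_n`` presences.

    Regions below the presence floor (or with one class only) are reported
    with a reason code instead of a metric.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    regions = np.asarray(region_ids)
    out = {}
    for r in np.unique(regions):
        m = regions == r
        n_pres = int(y[m].sum())
        if n_pres < min_n:
            out[r] = {"auc_roc": None, "reason": f"fewer than {min_n} presences ({n_pres})"}
        elif len(np.unique(y[m])) < 2:
            out[r] = {"auc_roc": None, "reason": "single class"}
        else:
            out[r] = {"auc_roc": auc_roc(s[m], y[m]), "n_presences": n_pres}
    return out


@dataclass
class EvalReport:
    """Per-season and global discrimination metrics with TSS thresholds."""

    family: str
    seasonal: dict[str, dict[str, float]] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def global_metrics(self) -> dict[str, float]:
        return {m: global_average({s: self.seasonal[s][m] for s in SEASONS})
                for m in ("auc_roc", "auc_pr", "tss")}

    def to_dict(self) -> dict:
        return {"family": self.family, "seasonal": self.seasonal,
                "global": self.global_metrics, "thresholds": self.thresholds,
                "counts": self.counts}


def evaluate_seasonal(
    val_scores: dict[str, np.ndarray], val_labels: dict[str, np.ndarray],
    test_scores: dict[str, np.ndarray], test_labels: dict[str, np.ndarray],
    family: str = "",
) -> EvalReport:
    """Full protocol: thresholds on validation, metrics on test, per season."""
    report = EvalReport(family=family)
    for s in SEASONS:
        th, _ = optimize_tss_threshold(val_scores[s], val_labels[s])
        report.thresholds[s] = th
        report.seasonal[s] = {
            "auc_roc": auc_roc(test_scores[s], test_labels[s]),
            "auc_pr": auc_pr(test_scores[s], test_labels[s]),
            "tss": tss_at(test_scores[s], test_labels[s], th),
        }
        report.counts[s] = {
            "n_validation": int(len(val_labels[s])),
            "n_test": int(len(test_labels[s])),
        }
    return report
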