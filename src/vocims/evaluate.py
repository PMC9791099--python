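"""Discrimination statistics from pooled out-of-fold probabilities.

AUC is computed through the Mann-Whitney identity (half credit for ties),
its 95% CI via the DeLong structural-component variance, the class
separation p-value as a two-sided rank-sum test on the probabilities, the
operating point by maximizing Youden's J over observed probability
cut-points, and sensitivity/specificity CIs as Clopper-Pearson exact
binomial intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import beta, norm, rankdata

from .errors import InvalidInputError, UndefinedStatisticError
from .selection import ranksum_pvalue

__all__ = [
    "EvalReport",
    "auc",
    "auc_ci",
    "class_separation_pvalue",
    "operating_point",
    "predictive_values",
    "sens_spec_ci",
    "evaluate_probabilities",
    "select_best_classifier",
]


@dataclass(frozen=True)
class EvalReport:
    """One Table-2/3 style row for a single classifier on one comparison."""

    classifier: str
    auc: float
    auc_ci_95: tuple[float, float]
    p_value: float
    threshold: float
    sensitivity: float
    sensitivity_ci_95: tuple[float, float] | None
    specificity: float
    specificity_ci_95: tuple[float, float] | None
    ppv: float | None
    npv: float | None
    confusion: dict[str, int]
    n_per_class: tuple[int, int]  # (n0, n1)

    def to_row(self) -> dict:
        """Serialized row with 2-decimal rounding (internal values stay exact)."""

        def r2(v):
            return None if v is None else round(float(v), 2)

        def ci(v):
            return None if v is None else [r2(v[0]), r2(v[1])]

        d = asdict(self)
        return {
            "classifier": d["classifier"],
            "p_value": round(float(d["p_value"]), 4),
            "auc": r2(d["auc"]),
            "auc_ci_95": ci(d["auc_ci_95"]),
            "sensitivity": r2(d["sensitivity"]),
            "sensitivity_ci_95": ci(d["sensitivity_ci_95"]),
            "specificity": r2(d["specificity"]),
            "specificity_ci_95": ci(d["specificity_ci_95"]),
            "ppv": r2(d["ppv"]),
            "npv": r2(d["npv"]),
            "threshold": float(d["threshold"]),
            "confusion": d["confusion"],
            "n_per_class": list(d["n_per_class"]),
        }


def _split(probabilities, labels):
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise UndefinedStatisticError("AUC needs exactly two classes in labels")
    pos = p[y == classes[1]]
    neg = p[y == classes[0]]
    return pos, neg


def auc(probabilities, labels) -> float:
    """Mann-Whitney AUC: P(score_1 > score_0) + 0.5 P(tie)."""
    pos, neg = _split(probabilities, labels)
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    m, n = pos.size, neg.size
    # structural components: v10[i] = mean_j psi(pos_i, neg_j), and vice versa
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc_ci(probabilities, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong-variance normal interval for the AUC, clipped to [0, 1]."""
    pos, neg = _split(probabilities, labels)
    if pos.size < 2 or neg.size < 2:
        raise UndefinedStatisticError("AUC CI needs >= 2 members per class")
    a = auc(probabilities, labels)
    var = _delong_variance(pos, neg)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return (float(max(0.0, a - half)), float(min(1.0, a + half)))


def class_separation_pvalue(probabilities, labels) -> float:
    """Two-sided rank-sum test on pooled out-of-fold probabilities."""
    pos, neg = _split(probabilities, labels)
    return ranksum_pvalue(pos, neg)


def operating_point(probabilities, labels) -> tuple[float, dict[str, int]]:
    """Youden-optimal cut over observed probabilities; returns (threshold, counts).

    A sample is called positive when its probability is >= the threshold.
    J-ties resolve toward higher sensitivity (i.e. the lower threshold).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    pos, neg = _split(p, y)
    best = None
    for t in np.unique(p):  # ascending: first max-J hit has highest sensitivity
        tp = int((pos >= t).sum())
        fn = pos.size - tp
        fp = int((neg >= t).sum())
        tn = neg.size - fp
        j = tp / pos.size + tn / neg.size - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(t), {"tp": tp, "fp": fp, "tn": tn, "fn": fn})
    return best[1], best[2]


def predictive_values(confusion: dict[str, int]) -> tuple[float | None, float | None]:
    """(PPV, NPV); ``None`` for empty denominators, never a silent 0."""
    tp, fp, tn, fn = (confusion[k] for k in ("tp", "fp", "tn", "fn"))
    if min(tp, fp, tn, fn) < 0:
        raise InvalidInputError("confusion counts must be non-negative")
    ppv = tp / (tp + fp) if tp + fp > 0 else None
    npv = tn / (tn + fn) if tn + fn > 0 else None
    return ppv, npv


def _clopper_pearson(k: int, n: int, level: float) -> tuple[float, float]:
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lo, hi


def sens_spec_ci(
    confusion: dict[str, int], level: float = 0.95
) -> dict[str, tuple[float, float] | None]:
    """Clopper-Pearson exact intervals for sensitivity and specificity."""
    tp, fp, tn, fn = (confusion[k] for k in ("tp", "fp", "tn", "fn"))
    out: dict[str, tuple[float, float] | None] = {}
    out["sensitivity"] = _clopper_pearson(tp, tp + fn, level) if tp + fn > 0 else None
    out["specificity"] = _clopper_pearson(tn, tn + fp, level) if tn + fp > 0 else None
    return out


def evaluate_probabilities(classifier: str, probabilities, labels) -> EvalReport:
    """Assemble the full report row for one classifier."""
    pos, neg = _split(probabilities, labels)
    threshold, confusion = operating_point(probabilities, labels)
    tp, fp, tn, fn = (confusion[k] for k in ("tp", "fp", "tn", "fn"))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv, npv = predictive_values(confusion)
    cis = sens_spec_ci(confusion)
    return EvalReport(
        classifier=classifier,
        auc=auc(probabilities, labels),
        auc_ci_95=auc_ci(probabilities, labels),
        p_value=class_separation_pvalue(probabilities, labels),
        threshold=threshold,
        sensitivity=sens,
        sensitivity_ci_95=cis["sensitivity"],
        specificity=spec,
        specificity_ci_95=cis["specificity"],
        ppv=ppv,
        npv=npv,
        confusion=confusion,
        n_per_class=(int(neg.size), int(pos.size)),
    )


def select_best_classifier(reports) -> EvalReport:
    """Maximal AUC; ties by smaller p-value, then fixed classifier-name order."""
    reports = list(reports)
    if not reports:
        raise InvalidInputError("no reports supplied")
    from .crossval import CLASSIFIER_NAMES

    def name_rank(r: EvalReport) -> int:
        return (
            CLASSIFIER_NAMES.index(r.classifier)
            if r.classifier in CLASSIFIER_NAMES
            else len(CLASSIFIER_NAMES)
        )

    return min(reports, key=lambda r: (-r.auc, r.p_value, name_rank(r)))
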