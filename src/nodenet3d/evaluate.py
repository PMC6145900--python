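"""ROC analysis, DeLong confidence intervals, Youden thresholding, calibration.

Nodal metastasis and extranodal extension are evaluated as two independent
binary endpoints.  The AUC is the Mann-Whitney pair statistic
``P(score_pos > score_neg) + 0.5 P(tie)``; its variance comes from DeLong
placement values, giving a normal-approximation confidence interval clipped
to [0, 1].  The operating threshold is the observed score that maximises the
Youden index ``J = sensitivity + specificity - 1`` (ties broken toward higher
specificity — the clinically conservative choice for ENE, where a false
positive escalates treatment).  Calibration is summarised by quintile bins of
predicted probability with a Hosmer-Lemeshow chi-square on ``bins - 2``
degrees of freedom.

The ENE endpoint is, by protocol, evaluated only on nodes with ROI diameter
>= 10 mm (sub-centimetre ENE is essentially absent pathologically, and
including trivially negative small nodes would inflate the metrics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "EvalReport",
    "roc_auc",
    "delong_ci",
    "roc_curve_points",
    "youden_threshold",
    "binary_metrics",
    "calibration",
    "evaluate_endpoint",
    "evaluate_ene_subset",
]


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to compute ROC statistics")


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney statistic: P(s+ > s-) + 0.5 P(s+ = s-)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)  # midranks handle ties
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values for positives (V10) and negatives (V01)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # placement of a positive: fraction of negatives it beats (ties half)
    v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
    v01 = np.array([np.mean((pos > n) + 0.5 * (pos == n)) for n in neg])
    return v10, v01


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation AUC interval with DeLong variance, clipped to [0,1]."""
    import warnings

    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    if labels.size < 10:
        raise ValueError("DeLong interval needs at least 10 observations")
    auc = roc_auc(scores, labels)
    v10, v01 = _placements(scores, labels)
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    if var <= 0:
        warnings.warn("degenerate DeLong variance (perfect separation); interval clipped")
        return (float(auc), float(min(auc, 1.0)))
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return (float(max(auc - half, 0.0)), float(min(auc + half, 1.0)))


def roc_curve_points(scores, labels) -> np.ndarray:
    """(fpr, tpr, threshold) rows over all observed thresholds, for plotting."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    thresholds = np.r_[np.inf, np.unique(scores)[::-1]]
    n_pos, n_neg = labels.sum(), (1 - labels).sum()
    rows = []
    for t in thresholds:
        pred = scores >= t
        tpr = (pred & (labels == 1)).sum() / n_pos
        fpr = (pred & (labels == 0)).sum() / n_neg
        rows.append((fpr, tpr, t))
    return np.array(rows)


def binary_metrics(predictions, labels) -> dict[str, float]:
    """Confusion-matrix metrics for binary predictions."""
    pred = np.asarray(predictions).astype(int)
    lab = np.asarray(labels).astype(int)
    if pred.size == 0:
        raise ValueError("empty input")
    tp = int(((pred == 1) & (lab == 1)).sum())
    tn = int(((pred == 0) & (lab == 0)).sum())
    fp = int(((pred == 1) & (lab == 0)).sum())
    fn = int(((pred == 0) & (lab == 1)).sum())

    def safe(num, den):
        return float(num / den) if den else float("nan")

    sens = safe(tp, tp + fn)
    spec = safe(tn, tn + fp)
    return {
        "accuracy": safe(tp + tn, pred.size),
        "sensitivity": sens,
        "specificity": spec,
        "ppv": safe(tp, tp + fp),
        "npv": safe(tn, tn + fn),
        "youden": sens + spec - 1,
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
    }


def youden_threshold(scores, labels) -> tuple[float, dict[str, float]]:
    """Threshold (from the observed scores) maximising J = sens + spec - 1.

    Prediction rule is ``score >= threshold``.  Among thresholds tied on J the
    one with higher specificity (i.e. the larger threshold) wins.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    best_t, best_j, best_metrics, best_spec = None, -np.inf, None, -np.inf
    for t in np.unique(scores):
        m = binary_metrics(scores >= t, labels)
        j = m["youden"]
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and m["specificity"] > best_spec):
            best_t, best_j, best_metrics, best_spec = float(t), j, m, m["specificity"]
    return best_t, best_metrics


def calibration(probabilities, labels, bins: int = 5) -> tuple[list[dict], float, float]:
    """Quantile-binned calibration table plus the Hosmer-Lemeshow test.

    Samples are sorted by predicted probability and divided into ``bins``
    groups whose sizes differ by at most one.  Returns (table, HL statistic,
    p-value) where the statistic is chi-square with ``bins - 2`` degrees of
    freedom.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if p.size < bins:
        raise ValueError("need at least as many samples as bins")
    if np.allclose(p, p[0]):
        raise ValueError("constant probabilities cannot be binned into quantiles")
    order = np.argsort(p, kind="stable")
    groups = np.array_split(order, bins)
    table = []
    hl = 0.0
    for g in groups:
        n = g.size
        mean_pred = float(p[g].mean())
        observed = int(y[g].sum())
        expected = float(p[g].sum())
        table.append(
            {"n": n, "mean_predicted": mean_pred, "observed_rate": observed / n}
        )
        denom = expected * (1 - expected / n)
        if denom > 0:
            hl += (observed - expected) ** 2 / denom
    p_value = float(stats.chi2.sf(hl, df=bins - 2))
    return table, float(hl), p_value


@dataclass
class EvalReport:
    """Per-endpoint evaluation summary — the comparison surface across models."""

    endpoint: str
    model: str
    n: int
    auc: float
    auc_ci95: tuple[float, float]
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    youden: float
    calibration_table: list[dict] = field(default_factory=list)
    hl_stat: float = float("nan")
    hl_p: float = float("nan")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["auc_ci95"] = list(self.auc_ci95)
        return d

    def to_text(self) -> str:
        lines = [
            f"{self.model} / {self.endpoint} (n={self.n})",
            f"  AUC            {self.auc:.2f} (95% CI {self.auc_ci95[0]:.2f}-{self.auc_ci95[1]:.2f})",
            f"  Accuracy       {100 * self.accuracy:.1f}%",
            f"  Sensitivity    {self.sensitivity:.2f}",
            f"  Specificity    {self.specificity:.2f}",
            f"  PPV            {self.ppv:.2f}",
            f"  NPV            {self.npv:.2f}",
            f"  Youden index   {self.youden:.2f}",
        ]
        if np.isfinite(self.hl_stat):
            lines.append(f"  Hosmer-Lemeshow chi2 {self.hl_stat:.2f} (p={self.hl_p:.3f})")
        return "\n".join(lines)


def evaluate_endpoint(
    scores,
    labels,
    endpoint: str = "ene",
    model: str = "model",
    with_calibration: bool = True,
) -> EvalReport:
    """Full single-endpoint evaluation at the Youden operating point."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    auc = roc_auc(scores, labels)
    try:
        ci = delong_ci(scores, labels)
    except ValueError:
        ci = (auc, auc)
    thr, m = youden_threshold(scores, labels)
    cal_table, hl, hl_p = [], float("nan"), float("nan")
    if with_calibration:
        try:
            cal_table, hl, hl_p = calibration(scores, labels)
        except ValueError:
            pass
    return EvalReport(
        endpoint=endpoint,
        model=model,
        n=int(labels.size),
        auc=auc,
        auc_ci95=ci,
        threshold=thr,
        accuracy=m["accuracy"],
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        ppv=m["ppv"],
        npv=m["npv"],
        youden=m["youden"],
        calibration_table=cal_table,
        hl_stat=hl,
        hl_p=hl_p,
    )


def evaluate_ene_subset(
    diameters_mm,
    nm_scores,
    ene_scores,
    nm_labels,
    ene_labels,
    model: str = "model",
    min_diameter_mm: float = 10.0,
) -> dict[str, EvalReport]:
    """Evaluate both endpoints: NM on all nodes, ENE on the >= 1 cm subset.

    The diameter bound is closed (a node at exactly 10.0 mm is included).
    """
    d = np.asarray(diameters_mm, dtype=np.float64)
    keep = d >= min_diameter_mm
    if not keep.any():
        raise ValueError("no nodes meet the ENE diameter threshold")
    return {
        "nm": evaluate_endpoint(nm_scores, nm_labels, "nm", model),
        "ene": evaluate_endpoint(
            np.asarray(ene_scores)[keep], np.asarray(ene_labels)[keep], "ene", model
        ),
    }
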