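"""Diagnostic-accuracy machinery for the score variants.

Confusion-matrix metrics (sensitivity, specificity, predictive values) with
Wilson score intervals; the Mann–Whitney AUC with DeLong placement-value
variance, confidence intervals and paired AUC comparison; Youden-index
cut-off selection; and a report builder that evaluates a panel of
threshold rules on a scored cohort the way diagnostic-accuracy tables are
usually presented (one row per rule, AUC from the continuous score,
operating characteristics at the cutoff).

Patients with an undefined score are excluded per score (complete-case per
row), and every exclusion is counted in the report — evaluating a score
that requires a lung-ultrasound exam automatically restricts to the
subcohort that had one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .records import ValidationError
from .scores import ThresholdRule, classify
from .derivation import association_pvalue

__all__ = [
    "ConfusionMatrix",
    "AccuracyMetrics",
    "RocResult",
    "confusion_from_predictions",
    "predictive_metrics",
    "auc_mann_whitney",
    "delong_ci",
    "delong_paired_pvalue",
    "youden_threshold",
    "roc_points",
    "roc_analysis",
    "evaluate_panel",
    "group_compare",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion-matrix counts must be non-negative")


@dataclass
class AccuracyMetrics:
    """Sn/Sp/PPV/NPV point estimates with Wilson CIs; undefined → None."""

    sn: Optional[float]
    sp: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    sn_ci: Optional[tuple[float, float]] = None
    sp_ci: Optional[tuple[float, float]] = None
    ppv_ci: Optional[tuple[float, float]] = None
    npv_ci: Optional[tuple[float, float]] = None
    level: float = 0.95


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def predictive_metrics(cm: ConfusionMatrix, level: float = 0.95) -> AccuracyMetrics:
    """Sensitivity, specificity and predictive values with Wilson CIs.

    A metric with a zero denominator is returned as ``None`` (with a
    ``None`` CI); the others are still computed.
    """

    def ratio(x: int, n: int):
        if n == 0:
            return None, None
        return x / n, wilson_ci(x, n, level)

    sn, sn_ci = ratio(cm.tp, cm.tp + cm.fn)
    sp, sp_ci = ratio(cm.tn, cm.tn + cm.fp)
    ppv, ppv_ci = ratio(cm.tp, cm.tp + cm.fp)
    npv, npv_ci = ratio(cm.tn, cm.tn + cm.fn)
    return AccuracyMetrics(sn, sp, ppv, npv, sn_ci, sp_ci, ppv_ci, npv_ci, level)


def confusion_from_predictions(
    predictions: Sequence[str], labels: Sequence[bool]
) -> ConfusionMatrix:
    """Tally positive/negative predictions against boolean labels.

    ``undetermined`` predictions are ignored (the caller logs them).
    """
    tp = fp = tn = fn = 0
    for pred, lab in zip(predictions, labels):
        if pred == "undetermined":
            continue
        if pred == "positive":
            tp += lab
            fp += not lab
        else:
            fn += lab
            tn += not lab
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def _clean_scores(scores, labels) -> tuple[np.ndarray, np.ndarray, int]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValidationError("scores and labels must have the same length")
    keep = ~np.isnan(s)
    n_excluded = int((~keep).sum())
    s, y = s[keep], y[keep]
    if y.all() or (~y).all():
        raise ValidationError("need at least one positive and one negative label")
    return s, y, n_excluded


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann–Whitney concordance probability.

    Ties count half; NaN scores are excluded pairwise.  Equals the
    trapezoidal area under the empirical ROC curve.
    """
    s, y, _ = _clean_scores(scores, labels)
    ranks = stats.rankdata(s)
    n1, n0 = int(y.sum()), int((~y).sum())
    u = ranks[y].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def _placement_values(s: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values.

    V10[i] for positive i: fraction of negatives below it (ties half);
    V01[j] for negative j: fraction of positives above it (ties half).
    Both have mean AUC.
    """
    pos, neg = s[y], s[~y]
    # counts via searchsorted on the sorted opposite group
    neg_sorted = np.sort(neg)
    lt = np.searchsorted(neg_sorted, pos, side="left")
    le = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (lt + 0.5 * (le - lt)) / len(neg)
    pos_sorted = np.sort(pos)
    gt = len(pos) - np.searchsorted(pos_sorted, neg, side="right")
    ge = len(pos) - np.searchsorted(pos_sorted, neg, side="left")
    v01 = (gt + 0.5 * (ge - gt)) / len(pos)
    return v10, v01


def delong_variance(scores, labels) -> tuple[float, float]:
    """(AUC, DeLong variance) from placement-value component variances."""
    s, y, _ = _clean_scores(scores, labels)
    v10, v01 = _placement_values(s, y)
    auc = float(v10.mean())
    var = 0.0
    if len(v10) >= 2:
        var += float(np.var(v10, ddof=1)) / len(v10)
    if len(v01) >= 2:
        var += float(np.var(v01, ddof=1)) / len(v01)
    return auc, var


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with a DeLong normal-approximation CI, clipped to [0, 1].

    Zero variance (e.g. perfect separation) degenerates the interval to
    the point estimate.
    """
    auc, var = delong_variance(scores, labels)
    if var == 0.0:
        return auc, auc, auc
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var)
    return auc, max(0.0, auc - half), min(1.0, auc + half)


def delong_paired_pvalue(scores_a, scores_b, labels) -> float:
    """Two-sided DeLong test for equality of two paired AUCs.

    Both scores must be observed on the same patients; rows where either
    score is NaN are dropped (pairwise-complete).  A zero variance of the
    AUC difference returns p = 1 by convention.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    keep = ~np.isnan(a) & ~np.isnan(b)
    a, b, y = a[keep], b[keep], y[keep]
    if y.all() or (~y).all():
        raise ValidationError("need both classes present")
    va10, va01 = _placement_values(a, y)
    vb10, vb01 = _placement_values(b, y)
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    n1, n0 = len(va10), len(va01)
    var = 0.0
    if n1 >= 2:
        s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1
    if n0 >= 2:
        s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    if var <= 0:
        return 1.0
    z = (auc_a - auc_b) / math.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def _sn_sp_at(s: np.ndarray, y: np.ndarray, t: float) -> tuple[float, float]:
    pred = s >= t
    sn = float((pred & y).sum() / y.sum())
    sp = float((~pred & ~y).sum() / (~y).sum())
    return sn, sp


def youden_threshold(scores, labels) -> tuple[float, float, float, float]:
    """Cut-off maximizing the Youden index J = Sn + Sp − 1.

    Exhaustive search over observed score values with the rule
    "positive iff score ≥ t"; ties broken toward the lowest threshold.
    Returns (threshold, J, Sn at threshold, Sp at threshold).
    """
    s, y, _ = _clean_scores(scores, labels)
    best = None
    for t in np.unique(s):
        sn, sp = _sn_sp_at(s, y, t)
        j = sn + sp - 1
        if best is None or j > best[1] + 1e-12:
            best = (float(t), j, sn, sp)
    return best


def roc_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC operating points: one row per candidate threshold.

    Thresholds are the sorted unique score values plus a sentinel above
    the maximum (the all-negative rule), with the "score ≥ t" convention.
    """
    s, y, _ = _clean_scores(scores, labels)
    thresholds = np.unique(s)
    rows = [(-np.inf, 1.0, 0.0)]
    for t in thresholds:
        sn, sp = _sn_sp_at(s, y, float(t))
        rows.append((float(t), sn, sp))
    rows.append((np.inf, 0.0, 1.0))
    return pd.DataFrame(rows, columns=["threshold", "sn", "sp"])


@dataclass
class RocResult:
    auc: float
    auc_ci: tuple[float, float]
    thresholds: np.ndarray
    sn: np.ndarray
    sp: np.ndarray
    youden_threshold: float
    youden_j: float
    level: float = 0.95


def roc_analysis(scores, labels, level: float = 0.95) -> RocResult:
    """Full ROC summary: AUC with DeLong CI, operating points, Youden cut-off."""
    auc, lo, hi = delong_ci(scores, labels, level)
    pts = roc_points(scores, labels)
    t, j, _, _ = youden_threshold(scores, labels)
    inner = pts.iloc[1:-1]
    return RocResult(
        auc=auc,
        auc_ci=(lo, hi),
        thresholds=inner["threshold"].to_numpy(),
        sn=inner["sn"].to_numpy(),
        sp=inner["sp"].to_numpy(),
        youden_threshold=t,
        youden_j=j,
        level=level,
    )


@dataclass
class AccuracyReport:
    """One evaluated rule per row, in the usual accuracy-table layout."""

    table: pd.DataFrame
    level: float = 0.95

    _COLUMNS = [
        "score", "rule", "cutoff", "n_included", "n_excluded",
        "auc", "auc_lo", "auc_hi",
        "sn", "sn_lo", "sn_hi", "sp", "sp_lo", "sp_hi",
        "ppv", "ppv_lo", "ppv_hi", "npv", "npv_lo", "npv_hi",
    ]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, na_rep="NA")

    def to_json(self) -> str:
        return self.table.to_json(orient="records", indent=2)


def evaluate_panel(
    scored_cohort: pd.DataFrame,
    rules: Sequence[ThresholdRule],
    level: float = 0.95,
) -> AccuracyReport:
    """Evaluate threshold rules on a scored cohort.

    ``scored_cohort`` needs a boolean ``vap_confirmed`` column and one
    column per rule's score (the ``lus`` rule reads ``lus_score``).  For
    each rule the AUC (DeLong CI) comes from the continuous score and
    Sn/Sp/PPV/NPV (Wilson CIs) from the dichotomized rule; rows with an
    undefined score are excluded for that rule only and counted in
    ``n_excluded``.
    """
    if "vap_confirmed" not in scored_cohort.columns:
        raise ValidationError("scored cohort lacks a vap_confirmed column")
    rows = []
    for rule in rules:
        col = "lus_score" if rule.score_name == "lus" else rule.score_name
        if col not in scored_cohort.columns:
            raise ValidationError(f"scored cohort lacks column {col!r}")
        s = pd.to_numeric(scored_cohort[col], errors="coerce").to_numpy(dtype=float)
        y = scored_cohort["vap_confirmed"].to_numpy(dtype=bool)
        keep = ~np.isnan(s)
        n_inc, n_exc = int(keep.sum()), int((~keep).sum())
        if n_inc == 0:
            raise ValidationError(
                f"no patient has a defined {rule.score_name} score; cannot evaluate"
            )
        auc, auc_lo, auc_hi = delong_ci(s[keep], y[keep], level)
        preds = [classify(v, rule) for v in s[keep]]
        m = predictive_metrics(confusion_from_predictions(preds, y[keep]), level)

        def unpack(est, ci):
            if est is None:
                return (np.nan, np.nan, np.nan)
            return (est, ci[0], ci[1])

        rows.append(
            (rule.score_name, rule.label, rule.cutoff, n_inc, n_exc,
             auc, auc_lo, auc_hi,
             *unpack(m.sn, m.sn_ci), *unpack(m.sp, m.sp_ci),
             *unpack(m.ppv, m.ppv_ci), *unpack(m.npv, m.npv_ci))
        )
    return AccuracyReport(pd.DataFrame(rows, columns=AccuracyReport._COLUMNS), level)


def group_compare(cohort: pd.DataFrame, variable: str, kind: str) -> float:
    """Two-group (VAP vs no-VAP) comparison p-value for one variable.

    ``categorical`` → chi-square/Fisher via :func:`association_pvalue` on
    the level × group cross-table; ``continuous_normal`` → Welch t-test;
    ``continuous_skewed`` → Mann–Whitney U (normal approximation with tie
    correction).
    """
    if variable not in cohort.columns:
        raise ValidationError(f"variable {variable!r} not in cohort")
    y = cohort["vap_confirmed"].astype(bool)
    if y.all() or (~y).all():
        raise ValidationError("both outcome groups must be non-empty")
    col = cohort[variable]
    if kind == "categorical":
        ct = pd.crosstab(col, y)
        return association_pvalue(ct.to_numpy())
    a = pd.to_numeric(col[y], errors="coerce").dropna()
    b = pd.to_numeric(col[~y], errors="coerce").dropna()
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("a group has no observed values")
    if kind == "continuous_normal":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if kind == "continuous_skewed":
        return float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
    raise ValidationError(f"unknown kind {kind!r}")
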