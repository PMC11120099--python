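"""Contingency-table statistics and log-odds-ratio score derivation.

This module turns a labelled cohort into a point-score table the way
clinical prediction rules are classically built: each candidate feature
level is cross-tabulated against the outcome, its odds ratio (OR) versus a
reference level is estimated, and points are assigned proportionally to the
log odds ratio, scaled so that the strongest predictor receives the maximum
number of points.

Odds ratios use the cross-product estimate with a Wald confidence interval
on the log scale; tables with a zero cell receive the Haldane–Anscombe
correction (+0.5 to every cell, flagged in the result).  Association
p-values follow the usual small-sample switch: Fisher's exact test when any
expected cell count is below 5, Pearson chi-square otherwise (for r×2
tables with small expected counts, the Freeman–Halton exact generalization
is computed by enumeration).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .records import PatientRecord, ValidationError

__all__ = [
    "ContingencyTable",
    "OddsRatioResult",
    "DerivedScoreTable",
    "odds_ratio",
    "or_wald_ci",
    "association_pvalue",
    "feature_contingency",
    "points_from_log_or",
    "LogOddsScorer",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts: (feature level vs reference) × (VAP vs no-VAP).

    ``a``/``b`` are level counts in the VAP / no-VAP groups; ``c``/``d``
    are the reference-level counts.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValidationError(f"cell {name}={v} must be a non-negative integer")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class OddsRatioResult:
    or_estimate: float
    log_or: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    level: float = 0.95
    p_value: Optional[float] = None
    corrected: bool = False


def _cells(ct: ContingencyTable) -> tuple[float, float, float, float, bool]:
    """Cell counts, Haldane–Anscombe corrected when any cell is zero."""
    if min(ct.a, ct.b, ct.c, ct.d) == 0:
        return ct.a + 0.5, ct.b + 0.5, ct.c + 0.5, ct.d + 0.5, True
    return float(ct.a), float(ct.b), float(ct.c), float(ct.d), False


def _check_margins(ct: ContingencyTable) -> None:
    if ct.a + ct.c == 0 or ct.b + ct.d == 0:
        raise ValidationError("empty outcome group: cannot estimate an odds ratio")


def odds_ratio(ct: ContingencyTable) -> OddsRatioResult:
    """Cross-product odds-ratio estimate for a 2×2 table."""
    _check_margins(ct)
    a, b, c, d, corrected = _cells(ct)
    est = (a * d) / (b * c)
    return OddsRatioResult(or_estimate=est, log_or=math.log(est), corrected=corrected)


def or_wald_ci(ct: ContingencyTable, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval for the odds ratio, on the log scale."""
    if not 0 < level < 1:
        raise ValidationError(f"CI level must be in (0, 1), got {level}")
    _check_margins(ct)
    a, b, c, d, _ = _cells(ct)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def odds_ratio_result(ct: ContingencyTable, level: float = 0.95) -> OddsRatioResult:
    """Odds ratio with Wald CI and association p-value in one result."""
    res = odds_ratio(ct)
    res.ci_low, res.ci_high = or_wald_ci(ct, level)
    res.level = level
    res.p_value = association_pvalue(ct)
    return res


def _freeman_halton_rx2(table: np.ndarray) -> float:
    """Exact two-sided p-value for an r×2 table with fixed margins.

    Enumerates every table with the observed margins; the p-value is the
    total probability of tables no more probable than the observed one
    (Freeman–Halton rule).  Feasible because for r×2 the tables factorize
    over rows: P(table) = Π C(r_i, a_i) / C(n, c1).
    """
    rows = table.sum(axis=1).astype(int)
    c1 = int(table[:, 0].sum())
    n = int(rows.sum())

    log_denom = math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1)

    def log_comb(m: int, k: int) -> float:
        return math.lgamma(m + 1) - math.lgamma(k + 1) - math.lgamma(m - k + 1)

    obs_logp = sum(log_comb(rows[i], int(table[i, 0])) for i in range(len(rows))) - log_denom

    total = 0.0
    # depth-first enumeration over first-column row counts
    def recurse(i: int, remaining: int, logp: float) -> None:
        nonlocal total
        if i == len(rows) - 1:
            if 0 <= remaining <= rows[i]:
                lp = logp + log_comb(rows[i], remaining) - log_denom
                if lp <= obs_logp + 1e-9:
                    total += math.exp(lp)
            return
        lo = max(0, remaining - int(rows[i + 1:].sum()))
        hi = min(rows[i], remaining)
        for k in range(lo, hi + 1):
            recurse(i + 1, remaining - k, logp + log_comb(rows[i], k))

    recurse(0, c1, 0.0)
    return min(total, 1.0)


def association_pvalue(
    table: Union[ContingencyTable, Sequence[Sequence[int]], np.ndarray],
) -> float:
    """Two-sided association p-value for a 2×2 or r×2 table.

    Uses Fisher's exact test (or its Freeman–Halton generalization for
    r > 2) when any expected cell count is below 5, otherwise the Pearson
    chi-square test with (r−1) degrees of freedom.
    """
    arr = table.as_array() if isinstance(table, ContingencyTable) else np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValidationError(f"expected an r×2 table, got shape {arr.shape}")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("degenerate table: a row or column margin is zero")
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if (expected < 5).any():
        if arr.shape[0] == 2:
            return float(stats.fisher_exact(arr)[1])
        return _freeman_halton_rx2(arr)
    return float(stats.chi2_contingency(arr, correction=False)[1])


def _cohort_frame(cohort) -> pd.DataFrame:
    if isinstance(cohort, pd.DataFrame):
        return cohort
    from .io import records_to_frame  # local import to avoid a cycle

    return records_to_frame(cohort)


#: Cohort-CSV column and reference level for each derivable feature.
FEATURE_REFERENCES: Mapping[str, str] = {
    "consolidation_type": "none",
    "size_band": "none",
    "laterality": "none",
    "bronchogram": "none",
}

#: Maximum points per feature in the published table (dynamic bronchogram,
#: the strongest predictor, anchors a 3-point scale; the rest use 2).
DEFAULT_MAX_POINTS: Mapping[str, int] = {
    "consolidation_type": 2,
    "size_band": 2,
    "laterality": 2,
    "bronchogram": 3,
}


def feature_contingency(
    cohort,
    feature: str,
    level: str,
    reference: str,
) -> ContingencyTable:
    """Cross-count a feature level against its reference by VAP status.

    ``cohort`` may be a list of :class:`PatientRecord` or a cohort-schema
    DataFrame.  Lung-ultrasound features are implicitly restricted to
    patients with an exam, because only those rows carry non-missing
    values.
    """
    if level == reference:
        raise ValidationError("level and reference must differ")
    df = _cohort_frame(cohort)
    if feature not in df.columns:
        raise ValidationError(f"feature {feature!r} not in cohort columns")
    col = df[feature].astype("string")
    for name, value in (("level", level), ("reference", reference)):
        if not (col == value).any():
            raise ValidationError(
                f"{name} category {value!r} absent from feature {feature!r}"
            )
    vap = df["vap_confirmed"].astype(bool)
    return ContingencyTable(
        a=int(((col == level) & vap).sum()),
        b=int(((col == level) & ~vap).sum()),
        c=int(((col == reference) & vap).sum()),
        d=int(((col == reference) & ~vap).sum()),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class DerivedScoreTable:
    """Data-driven points per feature level, with their provenance.

    ``points`` maps feature → level → points; ``scaling_unit`` is the
    log-OR worth one point for that feature; ``provenance`` keeps the OR
    behind each assignment.
    """

    points: dict[str, dict[str, int]]
    scaling_unit: dict[str, float]
    provenance: dict[str, dict[str, OddsRatioResult]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "points": self.points,
            "scaling_unit": self.scaling_unit,
            "provenance": {
                feat: {
                    lvl: {
                        "or": r.or_estimate,
                        "log_or": r.log_or,
                        "ci": [r.ci_low, r.ci_high],
                        "p_value": r.p_value,
                        "corrected": r.corrected,
                    }
                    for lvl, r in levels.items()
                }
                for feat, levels in self.provenance.items()
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DerivedScoreTable":
        payload = json.loads(text)
        return cls(
            points={f: {l: int(p) for l, p in lv.items()} for f, lv in payload["points"].items()},
            scaling_unit={f: float(u) for f, u in payload["scaling_unit"].items()},
        )


def points_from_log_or(
    feature_ors: Mapping[str, Union[OddsRatioResult, float]],
    max_points: int,
) -> dict[str, int]:
    """Assign integer points to feature levels from their odds ratios.

    The strongest level (largest log OR) anchors the scale: one point is
    worth ``max(log OR) / max_points``, each level gets its log OR divided
    by that unit, rounded half away from zero and clipped to
    ``[0, max_points]``.  Levels with OR ≤ 1 score 0.  Invariant to raising
    every OR to a common positive power.
    """
    if max_points < 1:
        raise ValidationError(f"max_points must be ≥ 1, got {max_points}")
    log_ors = {
        lvl: (r.log_or if isinstance(r, OddsRatioResult) else math.log(r))
        for lvl, r in feature_ors.items()
    }
    top = max(log_ors.values(), default=float("-inf"))
    if top <= 0:
        raise ValidationError("degenerate score: no feature level has OR > 1")
    unit = top / max_points
    return {
        lvl: min(max(_round_half_away(lo / unit), 0), max_points)
        for lvl, lo in log_ors.items()
    }


class LogOddsScorer:
    """Derive a lung-ultrasound point table from a labelled cohort.

    scikit-learn-style estimator: ``fit(X, y)`` cross-tabulates each
    configured feature level against its reference, estimates odds ratios,
    and converts log odds ratios to integer points.

    Parameters
    ----------
    features : mapping, optional
        feature → reference level; defaults to the four LUS features with
        the no-finding reference.
    max_points : mapping or int, optional
        Maximum points per feature; defaults to
        :data:`DEFAULT_MAX_POINTS` (3 for the bronchogram, 2 elsewhere,
        as in the published table).
    level : float, default 0.95
        Confidence level recorded in the provenance.

    Attributes
    ----------
    score_table_ : DerivedScoreTable
        Fitted points, scaling units and odds-ratio provenance.
    """

    def __init__(
        self,
        features: Optional[Mapping[str, str]] = None,
        max_points: Union[int, Mapping[str, int], None] = None,
        level: float = 0.95,
    ):
        self.features = features
        self.max_points = max_points
        self.level = level

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"features": self.features, "max_points": self.max_points, "level": self.level}

    def set_params(self, **params) -> "LogOddsScorer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _max_points_for(self, feature: str) -> int:
        mp = self.max_points if self.max_points is not None else DEFAULT_MAX_POINTS
        if isinstance(mp, int):
            return mp
        return int(mp[feature])

    def fit(self, X, y=None) -> "LogOddsScorer":
        """Fit on a cohort (records or DataFrame); ``y`` overrides the
        ``vap_confirmed`` column when given."""
        df = _cohort_frame(X).copy()
        if y is not None:
            df["vap_confirmed"] = np.asarray(y, dtype=bool)
        features = dict(self.features) if self.features is not None else dict(FEATURE_REFERENCES)

        points: dict[str, dict[str, int]] = {}
        units: dict[str, float] = {}
        provenance: dict[str, dict[str, OddsRatioResult]] = {}
        for feature, reference in features.items():
            col = df[feature].astype("string")
            levels = sorted(v for v in col.dropna().unique() if v != reference)
            ors = {
                lvl: odds_ratio_result(
                    feature_contingency(df, feature, lvl, reference), self.level
                )
                for lvl in levels
            }
            pts = points_from_log_or(ors, self._max_points_for(feature))
            pts[reference] = 0
            points[feature] = pts
            top = max(r.log_or for r in ors.values())
            units[feature] = top / self._max_points_for(feature)
            provenance[feature] = ors

        self.score_table_ = DerivedScoreTable(points, units, provenance)
        return self

    def fit_transform(self, X, y=None) -> DerivedScoreTable:
        return self.fit(X, y).score_table_
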